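"""Sum-to-zero-coded design matrices for the longitudinal factors.

The longitudinal analyses use three categorical predictors — ``area``
(brain region), ``time`` (measurement day treated as a factor) and ``diet``
— and their interactions.  Sum-to-zero contrasts make marginal (Type III)
Wald tests of each term meaningful in the presence of interactions, so the
same coding is used when simulating cohorts and when fitting, which also
makes noise-free simulation/fit round trips exact.

For a factor with ordered levels l_1..l_k, columns are built for l_1..l_{k-1}
as indicator(l_i) - indicator(l_k); interaction columns are element-wise
products.  Level ordering is deterministic: diet prefers (SD, HFD), area
prefers the anatomical ordering, time sorts numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_PREFERRED_ORDER = {
    "diet": ("SD", "HFD"),
    "area": ("hypothalamus", "hippocampus", "NAc", "ILA"),
}

#: data-frame column backing each model factor
FACTOR_SOURCE = {"area": "region", "time": "day", "diet": "diet"}


def factor_levels(values: pd.Series, factor: str) -> list:
    """Deterministic level ordering for a factor."""
    uniq = pd.unique(values)
    pref = _PREFERRED_ORDER.get(factor)
    if pref is not None:
        ordered = [l for l in pref if l in set(uniq)]
        ordered += sorted(set(uniq) - set(ordered))
        return ordered
    try:
        return sorted(uniq, key=float)
    except (TypeError, ValueError):
        return sorted(uniq, key=str)


def _sum_code(values: pd.Series, levels: list, factor: str) -> tuple[np.ndarray, list[str]]:
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels, got {levels}")
    cols = []
    names = []
    last = levels[-1]
    arr = values.to_numpy()
    for lev in levels[:-1]:
        col = (arr == lev).astype(float) - (arr == last).astype(float)
        cols.append(col)
        names.append(f"{factor}[S.{lev}]")
    return np.column_stack(cols), names


@dataclass
class DesignInfo:
    """Frozen description of a built design: term order, columns, levels."""

    terms: tuple[str, ...]
    column_names: list[str]
    term_slices: dict[str, slice]
    levels: dict[str, list]

    @property
    def n_columns(self) -> int:
        return len(self.column_names)


def build_design(
    df: pd.DataFrame,
    terms: tuple[str, ...],
    levels: dict[str, list] | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Design matrix with intercept plus the requested sum-coded terms.

    ``terms`` are factor names or ':'-joined interactions drawn from
    {area, time, diet}.  Passing ``levels`` (from a previous DesignInfo)
    reuses a coding, e.g. to build prediction rows.
    """
    n = len(df)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    slices = {"Intercept": slice(0, 1)}
    lv: dict[str, list] = {}

    def levels_of(factor: str) -> list:
        if factor in lv:
            return lv[factor]
        src = FACTOR_SOURCE.get(factor, factor)
        if levels is not None and factor in levels:
            lv[factor] = list(levels[factor])
        else:
            lv[factor] = factor_levels(df[src], factor)
        return lv[factor]

    pos = 1
    for term in terms:
        factors = term.split(":")
        mats, nameparts = [], []
        for f in factors:
            src = FACTOR_SOURCE.get(f, f)
            if src not in df.columns:
                raise ValueError(f"factor {f!r} needs column {src!r} in the table")
            m, nm = _sum_code(df[src], levels_of(f), f)
            mats.append(m)
            nameparts.append(nm)
        # kron-style expansion of the interaction columns
        block = mats[0]
        block_names = nameparts[0]
        for m, nm in zip(mats[1:], nameparts[1:]):
            block = np.concatenate(
                [block[:, [i]] * m for i in range(block.shape[1])], axis=1
            )
            block_names = [f"{a}:{b}" for a in block_names for b in nm]
        blocks.append(block)
        names.extend(block_names)
        slices[term] = slice(pos, pos + block.shape[1])
        pos += block.shape[1]

    X = np.concatenate(blocks, axis=1)
    return X, DesignInfo(tuple(terms), names, slices, lv)


def prediction_row(info: DesignInfo, cell: dict[str, object]) -> np.ndarray:
    """Design row for a single factor-level cell, under ``info``'s coding."""
    data = {}
    for factor, levs in info.levels.items():
        src = FACTOR_SOURCE.get(factor, factor)
        if factor not in cell:
            raise ValueError(f"cell must fix factor {factor!r}")
        if cell[factor] not in levs:
            raise ValueError(f"unknown level {cell[factor]!r} for factor {factor!r}")
        data[src] = [cell[factor]]
    df = pd.DataFrame(data)
    X, _ = build_design(df, info.terms, levels=info.levels)
    return X[0]
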