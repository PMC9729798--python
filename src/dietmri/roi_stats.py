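"""Region-of-interest extraction and filtering of parametric maps.

Four regions are summarised per animal and time point: the hypothalamus
(a 70-voxel rectangle), the hippocampus (two 30-voxel near-square blocks),
the nucleus accumbens (two 40-voxel ovals) and the infralimbic area
(a 20-voxel circle).  Manual per-animal delineation is replaced by a
deterministic geometric template that realizes those voxel counts exactly.

Before averaging, voxel values pass physiologic retention filters that
remove CSF-containing voxels and artifacts — strict inequalities
30 < T2 < 80 ms, 0 < ADC < 1200 um^2/s and MTR > 0 — and, after per-ROI
averaging, values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] within each
diet x day x region group are discarded as outliers (linear-interpolation
quartiles; groups smaller than 4 are left untouched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .param_maps import ParamMap

logger = logging.getLogger(__name__)

REGIONS = ("hypothalamus", "hippocampus", "NAc", "ILA")

#: strict retention bounds per MR parameter: value kept iff lo < v < hi
FILTER_BOUNDS: dict[str, tuple[float, float]] = {
    "T2": (30.0, 80.0),  # ms
    "ADC": (0.0, 1200.0),  # um^2/s
    "MTR": (0.0, np.inf),  # percent
}

ROI_TABLE_COLUMNS = (
    "animal_id",
    "sex",
    "diet",
    "day",
    "region",
    "parameter",
    "value",
    "n_voxels_used",
)


@dataclass(frozen=True)
class ROITemplate:
    """Deterministic ROI geometry on the acquisition matrix.

    ``voxel_counts`` are a template contract: the realized masks match them
    exactly.  ``slice_of`` records which acquisition slice each region sits
    on in the original two-slice protocol (hypothalamus/hippocampus on one,
    NAc/ILA on the other); the synthetic phantom collapses both onto a
    single plane, which the disjoint placements make possible.
    """

    voxel_counts: dict[str, int] = field(
        default_factory=lambda: {"hypothalamus": 70, "hippocampus": 60, "NAc": 80, "ILA": 20}
    )
    slice_of: dict[str, int] = field(
        default_factory=lambda: {"hypothalamus": 0, "hippocampus": 0, "NAc": 1, "ILA": 1}
    )


def _exact_count_blob(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float], n: int
) -> np.ndarray:
    """Boolean mask of exactly the n grid voxels closest to ``center`` in the
    elliptic metric with semi-axis ratio ``axes`` (deterministic tie-break)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2
    order = np.lexsort((cc.ravel(), rr.ravel(), d.ravel()))
    mask = np.zeros(shape, dtype=bool)
    flat = mask.ravel()
    flat[order[:n]] = True
    return mask


def make_roi_masks(
    template: ROITemplate | None = None, matrix: int = 128
) -> dict[str, np.ndarray]:
    """Per-region boolean masks on a ``matrix x matrix`` grid.

    Masks are pairwise disjoint and realize the template voxel counts
    exactly; a too-small matrix raises.
    """
    template = template or ROITemplate()
    if matrix < 48:
        raise ValueError("matrix too small to place the ROI template without overlap")
    s = matrix / 128.0  # positions scale with the matrix; counts do not

    def rc(r: float, c: float) -> tuple[float, float]:
        return (r * s, c * s)

    masks: dict[str, np.ndarray] = {}
    shape = (matrix, matrix)

    # hypothalamus: 7 x 10 rectangle = 70 voxels, midline ventral
    n = template.voxel_counts["hypothalamus"]
    r0, c0 = (int(88 * s), int(59 * s))
    h = 7
    w = int(np.ceil(n / h))
    rect = np.zeros(shape, dtype=bool)
    rect[r0 : r0 + h, c0 : c0 + w] = True
    extra = h * w - n
    if extra:
        rect_idx = np.argwhere(rect)
        rect[tuple(rect_idx[-extra:].T)] = False
    masks["hypothalamus"] = rect

    # hippocampus: two 5 x 6 blocks (30 voxels each), bilateral dorsal
    n_half = template.voxel_counts["hippocampus"] // 2
    hip = np.zeros(shape, dtype=bool)
    for c_left in (30, 92):
        r0, c0 = (int(36 * s), int(c_left * s))
        blk = np.zeros(shape, dtype=bool)
        blk[r0 : r0 + 5, c0 : c0 + 6] = True
        idx = np.argwhere(blk)
        blk[tuple(idx[n_half:].T)] = False
        hip |= blk
    masks["hippocampus"] = hip

    # NAc: two 40-voxel ovals, bilateral ventral
    n_half = template.voxel_counts["NAc"] // 2
    nac = np.zeros(shape, dtype=bool)
    for c_center in (32.0, 96.0):
        nac |= _exact_count_blob(shape, rc(72.0, c_center), (1.5, 1.0), n_half)
    masks["NAc"] = nac

    # ILA: one 20-voxel circle, midline dorsal
    masks["ILA"] = _exact_count_blob(
        shape, rc(24.0, 64.0), (1.0, 1.0), template.voxel_counts["ILA"]
    )

    for name, want in template.voxel_counts.items():
        got = int(masks[name].sum())
        if got != want:
            raise RuntimeError(f"{name} mask has {got} voxels, template specifies {want}")
    stack = np.stack(list(masks.values()))
    if stack.sum(axis=0).max() > 1:
        raise RuntimeError("ROI masks overlap")
    return masks


def masks_to_label_image(masks: dict[str, np.ndarray]) -> tuple[np.ndarray, dict[str, int]]:
    """Integer label image from boolean masks (labels assigned in REGIONS order)."""
    first = next(iter(masks.values()))
    labels = np.zeros(first.shape, dtype=np.int16)
    mapping = {}
    for i, (name, m) in enumerate(masks.items(), start=1):
        labels[m] = i
        mapping[name] = i
    return labels, mapping


def save_label_nifti(masks: dict[str, np.ndarray], path: str | Path) -> None:
    labels, _ = masks_to_label_image(masks)
    nib.save(nib.Nifti1Image(labels[:, :, np.newaxis].astype(np.int16), np.eye(4)), str(path))


def filter_map_values(values: np.ndarray, parameter: str) -> np.ndarray:
    """Retain values passing the strict physiologic bounds for ``parameter``.

    NaNs never pass.  The number of removed values is logged.
    """
    if parameter not in FILTER_BOUNDS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {list(FILTER_BOUNDS)}")
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        logger.warning("filter_map_values(%s): empty input", parameter)
        return values
    lo, hi = FILTER_BOUNDS[parameter]
    keep = (values > lo) & (values < hi)
    n_removed = int(values.size - keep.sum())
    if n_removed:
        logger.info("filter_map_values(%s): removed %d of %d", parameter, n_removed, values.size)
    return values[keep]


@dataclass
class ROIMean:
    value: float | None
    n_voxels_used: int
    reason: str = ""


def roi_mean(pmap: ParamMap, mask: np.ndarray, parameter: str | None = None) -> ROIMean:
    """Arithmetic mean over mask voxels that are fit-valid and filter-passing."""
    parameter = parameter or pmap.name
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.values.shape:
        raise ValueError("mask extent does not match the map")
    vox = pmap.values[mask & pmap.valid]
    retained = filter_map_values(vox, parameter)
    if retained.size == 0:
        reason = "no_valid_voxels" if vox.size == 0 else "all_voxels_filtered"
        return ROIMean(None, 0, reason)
    return ROIMean(float(retained.mean()), int(retained.size))


def iqr_fences(values: np.ndarray) -> tuple[float, float]:
    """Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR], linear-interpolation quartiles."""
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def remove_outliers_iqr(
    table: pd.DataFrame,
    value_col: str = "value",
    group_cols: tuple[str, ...] = ("diet", "day", "region"),
    min_group_size: int = 4,
) -> pd.DataFrame:
    """Drop rows outside the Tukey fences within each group.

    Groups smaller than ``min_group_size`` are returned untouched (fences on
    so few points are meaningless) and logged.
    """
    if table.empty:
        return table.copy()
    keep = np.ones(len(table), dtype=bool)
    for key, idx in table.groupby(list(group_cols), observed=True, sort=False).groups.items():
        vals = table.loc[idx, value_col].to_numpy(dtype=float)
        if len(vals) < min_group_size:
            logger.info("remove_outliers_iqr: group %s has %d < %d values; skipped", key, len(vals), min_group_size)
            continue
        lo, hi = iqr_fences(vals)
        out = (vals < lo) | (vals > hi)
        if out.any():
            logger.info("remove_outliers_iqr: group %s removed %d outliers", key, int(out.sum()))
            keep[table.index.get_indexer(idx)[out]] = False
    return table.loc[keep].copy()


def build_roi_table(
    entries: list[dict],
    masks: dict[str, np.ndarray],
    apply_outlier_rule: bool = True,
) -> pd.DataFrame:
    """Long-format ROI summary table from per-animal parametric maps.

    Each entry is a dict with keys ``animal_id``, ``sex``, ``diet``, ``day``
    and ``maps`` (a mapping parameter name -> ParamMap).  One row per
    animal x day x region x parameter; the IQR outlier rule is applied per
    diet x day x region group within each parameter.
    """
    rows = []
    seen = set()
    for entry in entries:
        for parameter, pmap in entry["maps"].items():
            for region, mask in masks.items():
                key = (entry["animal_id"], entry["day"], region, parameter)
                if key in seen:
                    raise ValueError(f"duplicate ROI table key {key}")
                seen.add(key)
                rm = roi_mean(pmap, mask, parameter)
                if rm.value is None:
                    logger.warning("build_roi_table: missing value for %s (%s)", key, rm.reason)
                    continue
                rows.append(
                    dict(
                        animal_id=entry["animal_id"],
                        sex=entry["sex"],
                        diet=entry["diet"],
                        day=entry["day"],
                        region=region,
                        parameter=parameter,
                        value=rm.value,
                        n_voxels_used=rm.n_voxels_used,
                    )
                )
    table = pd.DataFrame(rows, columns=list(ROI_TABLE_COLUMNS))
    if apply_outlier_rule and not table.empty:
        parts = [
            remove_outliers_iqr(sub)
            for _, sub in table.groupby("parameter", observed=True, sort=False)
        ]
        table = pd.concat(parts).sort_index().reset_index(drop=True)
    return table
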