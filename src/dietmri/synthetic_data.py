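"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the study's data streams:

* ``make_phantom`` / ``simulate_series`` — a region-labelled digital brain
  slice (four tissue ROIs embedded in an other-brain background with a CSF
  rim) imaged through any of the acquisition protocols, with optional
  Gaussian or Rician (magnitude) noise.  CSF truth values sit outside the
  downstream retention filters (T2 150 ms > 80 ms bound, ADC 2500 um^2/s >
  1200 bound, MTR 0), so filtering is genuinely exercised.
* ``simulate_cohort`` — a two-diet, two-sex, five-time-point, four-region
  longitudinal cohort whose log-scale response is X beta plus nested random
  effects (mouse intercept, area-within-mouse intercept, per-mouse time
  slope on day rescaled to [0, 1]) plus an AR(1) residual over time points
  within each mouse x area series; returned on the natural scale.
* ``make_basis_set`` / ``simulate_spectra`` — unit-area metabolite basis
  spectra (Gaussian peak mixtures at textbook chemical shifts) combined
  linearly with optional polynomial baseline and Gaussian noise.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_design
from .param_maps import ADC_B_SCALE, ImageSeries
from .protocols import AcquisitionProtocol, Geometry
from .roi_stats import REGIONS, ROITemplate, make_roi_masks

LABELS = {
    "background": 0,
    "other_brain": 1,
    "CSF": 2,
    "hypothalamus": 3,
    "hippocampus": 4,
    "NAc": 5,
    "ILA": 6,
}

#: default per-region ground truth: S0 (a.u.), T2 (ms), ADC (um^2/s), MTR (%)
DEFAULT_TRUTH: dict[str, dict[str, float]] = {
    "other_brain": {"S0": 1000.0, "T2": 55.0, "ADC": 750.0, "MTR": 30.0},
    "CSF": {"S0": 1800.0, "T2": 150.0, "ADC": 2500.0, "MTR": 0.0},
    "hypothalamus": {"S0": 1000.0, "T2": 45.0, "ADC": 800.0, "MTR": 35.0},
    "hippocampus": {"S0": 1000.0, "T2": 50.0, "ADC": 700.0, "MTR": 32.0},
    "NAc": {"S0": 1000.0, "T2": 48.0, "ADC": 650.0, "MTR": 38.0},
    "ILA": {"S0": 1000.0, "T2": 52.0, "ADC": 720.0, "MTR": 28.0},
}


@dataclass
class PhantomTruth:
    """A labelled slice plus per-region ground-truth MR parameters."""

    label_image: np.ndarray
    truth: dict[str, dict[str, float]]
    geometry: Geometry
    label_map: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    def region_mask(self, region: str) -> np.ndarray:
        return self.label_image == self.label_map[region]

    def parameter_image(self, parameter: str) -> np.ndarray:
        """Ground-truth parameter per voxel (NaN on background)."""
        out = np.full(self.label_image.shape, np.nan)
        for region, vals in self.truth.items():
            out[self.region_mask(region)] = vals[parameter]
        return out


def make_phantom(
    truth_spec: dict[str, dict[str, float]] | None = None,
    geometry: Geometry | None = None,
) -> PhantomTruth:
    """Deterministic digital phantom with template-sized tissue ROIs.

    The four analysis regions use the ROI template placements (exact voxel
    counts); the remaining brain is an ellipse of other-brain tissue with a
    CSF rim two voxels thick.
    """
    geometry = geometry or Geometry()
    if geometry.matrix <= 0:
        raise ValueError("degenerate geometry")
    truth = {k: dict(v) for k, v in DEFAULT_TRUTH.items()}
    for region, vals in (truth_spec or {}).items():
        if region not in truth:
            raise ValueError(f"unknown region {region!r}")
        truth[region].update(vals)
    for region, vals in truth.items():
        if vals["T2"] <= 0 or vals["ADC"] < 0 or not (0 <= vals["MTR"] < 100):
            raise ValueError(f"non-physical truth for {region}: {vals}")

    m = geometry.matrix
    labels = np.zeros((m, m), dtype=np.int16)
    rr, cc = np.mgrid[0:m, 0:m]
    cen = (m - 1) / 2.0
    r_out = 0.48 * m
    brain = ((rr - cen) / r_out) ** 2 + ((cc - cen) / (0.46 * m)) ** 2 <= 1.0
    inner = ((rr - cen) / (r_out - 2)) ** 2 + ((cc - cen) / (0.46 * m - 2)) ** 2 <= 1.0
    labels[brain] = LABELS["CSF"]
    labels[inner] = LABELS["other_brain"]
    masks = make_roi_masks(ROITemplate(), matrix=m)
    for region, mask in masks.items():
        if not inner[mask].all():
            raise ValueError("geometry too small: ROI template leaves the brain")
        labels[mask] = LABELS[region]
    missing = {r for r in LABELS if r != "background"} - set(truth)
    if missing:
        raise ValueError(f"truth table lacks regions {sorted(missing)}")
    return PhantomTruth(labels, truth, geometry)


def _noiseless_signals(phantom: PhantomTruth, protocol: AcquisitionProtocol) -> np.ndarray:
    shape = phantom.label_image.shape
    n_acq = protocol.n_acquisitions
    out = np.zeros(shape + (n_acq,), dtype=float)
    for region, vals in phantom.truth.items():
        mask = phantom.region_mask(region)
        if not mask.any():
            continue
        s0, t2, adc, mtr = vals["S0"], vals["T2"], vals["ADC"], vals["MTR"]
        if protocol.kind == "t2map":
            te = np.asarray(protocol.echo_times_ms)
            sig = s0 * np.exp(-te / t2)
        elif protocol.kind in ("dwi_male", "dwi_female", "dwi"):
            b = np.asarray(protocol.b_values)
            sig = s0 * np.exp(-b * adc * ADC_B_SCALE)
        elif protocol.kind == "mt_pair":
            sig = np.array([s0, s0 * (1.0 - mtr / 100.0)])
        else:
            raise ValueError(f"unknown protocol kind {protocol.kind!r}")
        out[mask] = sig
    return out


def simulate_series(
    phantom: PhantomTruth,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    noise_model: str = "rician",
    seed: int | None = None,
) -> ImageSeries:
    """Image the phantom through a protocol, with per-acquisition noise.

    ``rician`` replaces each voxel signal S by |S + n1 + i n2| with
    independent N(0, sigma) components (magnitude MRI); ``gaussian`` adds
    N(0, sigma); ``none`` returns the closed-form signal.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if phantom.geometry.matrix != protocol.geometry.matrix:
        raise ValueError("phantom and protocol geometries disagree")
    clean = _noiseless_signals(phantom, protocol)
    if noise_model == "none" or noise_sigma == 0.0:
        data = clean
    elif noise_model == "gaussian":
        rng = np.random.default_rng(seed)
        data = clean + rng.normal(0.0, noise_sigma, clean.shape)
    elif noise_model == "rician":
        rng = np.random.default_rng(seed)
        re = clean + rng.normal(0.0, noise_sigma, clean.shape)
        im = rng.normal(0.0, noise_sigma, clean.shape)
        data = np.hypot(re, im)
    else:
        raise ValueError("noise_model must be 'none', 'gaussian' or 'rician'")
    mask = phantom.label_image > 0
    return ImageSeries(data, protocol, mask=mask)


# ---------------------------------------------------------------------------
# longitudinal cohort


@dataclass
class CohortDesign:
    """Generating model of a longitudinal ROI cohort (log-scale response).

    ``beta`` maps sum-coded design-column names (see ``dietmri.design``) to
    log-scale coefficients; unnamed columns are zero.  Variance components
    are on the log scale; ``rho_ar`` correlates residuals of successive
    time points within each mouse x area series; the random time slope acts
    on day rescaled to [0, 1].
    """

    n_per_group: int = 8
    diets: tuple[str, ...] = ("SD", "HFD")
    sexes: tuple[str, ...] = ("male",)
    days: tuple[float, ...] = (0.0, 7.0, 14.0, 28.0, 70.0)
    regions: tuple[str, ...] = REGIONS
    parameter: str = "MTR"
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COHORT_BETA))
    sigma_mouse: float = 0.05
    sigma_area_in_mouse: float = 0.04
    sigma_time_slope: float = 0.03
    sigma_residual: float = 0.05
    rho_ar: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_mouse", "sigma_area_in_mouse", "sigma_time_slope", "sigma_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-1.0 < self.rho_ar < 1.0):
            raise ValueError("|rho_ar| must be < 1")
        days = tuple(float(d) for d in self.days)
        if sorted(set(days)) != list(days) or 0.0 not in days:
            raise ValueError("days must be strictly increasing and include day 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


#: default fixed effects: clear area and time structure, a ~10% diet effect,
#: small interactions — the scale of effects the study design anticipates
DEFAULT_COHORT_BETA: dict[str, float] = {
    "Intercept": math.log(35.0),
    "area[S.hypothalamus]": 0.10,
    "area[S.hippocampus]": -0.05,
    "area[S.NAc]": 0.06,
    "time[S.0.0]": -0.04,
    "time[S.7.0]": -0.02,
    "time[S.14.0]": 0.01,
    "time[S.28.0]": 0.02,
    "diet[S.SD]": -0.05,
    "diet[S.SD]:time[S.0.0]": 0.02,
    "diet[S.SD]:time[S.28.0]": -0.015,
}


def cohort_frame(design: CohortDesign) -> pd.DataFrame:
    """The design grid (no response): one row per mouse x day x region."""
    rows = []
    i = 0
    for sex in design.sexes:
        for diet in design.diets:
            for k in range(design.n_per_group):
                i += 1
                animal = f"{sex[0]}{diet}{k + 1:02d}"
                for day in design.days:
                    for region in design.regions:
                        rows.append(
                            dict(animal_id=animal, sex=sex, diet=diet, day=float(day), region=region)
                        )
    return pd.DataFrame(rows)


def simulate_cohort(design: CohortDesign, seed: int | None = None) -> pd.DataFrame:
    """Simulate the longitudinal ROI table on the natural scale.

    log(value) = X beta + b_mouse + b_area(mouse) + b_slope(mouse) * s(day)
    + AR(1) residual; value = exp(log value).  Returns the long-format
    table with the standard ROI columns.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    df = cohort_frame(design)
    # full-model design so any named coefficient can be set
    all_terms = ("area", "time", "diet", "area:time", "diet:time", "diet:area", "diet:area:time")
    n_levels = {"area": len(design.regions), "time": len(design.days), "diet": len(design.diets)}
    terms = tuple(
        t for t in all_terms if all(n_levels[f] >= 2 for f in t.split(":"))
    )
    X, info = build_design(df, terms)
    beta = np.zeros(info.n_columns)
    name_to_idx = {n: j for j, n in enumerate(info.column_names)}
    for name, value in design.beta.items():
        if name not in name_to_idx:
            raise ValueError(
                f"unknown coefficient {name!r}; valid names include e.g. "
                f"{info.column_names[:6]}"
            )
        beta[name_to_idx[name]] = value
    eta = X @ beta

    days = np.asarray(design.days, dtype=float)
    span = days.max() - days.min() if days.max() > days.min() else 1.0
    s_of_day = {d: (d - days.min()) / span for d in days}

    mice = df["animal_id"].unique()
    b_mouse = dict(zip(mice, rng.normal(0.0, design.sigma_mouse, len(mice))))
    b_slope = dict(zip(mice, rng.normal(0.0, design.sigma_time_slope, len(mice))))
    b_area = {
        (m, r): rng.normal(0.0, design.sigma_area_in_mouse)
        for m in mice
        for r in design.regions
    }
    # AR(1) residuals per mouse x area over the time-point index
    resid = np.empty(len(df))
    rho, sig = design.rho_ar, design.sigma_residual
    for (m, r), idx in df.groupby(["animal_id", "region"], sort=False).groups.items():
        idx = np.asarray(idx)
        order = np.argsort(df.loc[idx, "day"].to_numpy())
        e = np.empty(len(idx))
        z = rng.normal(0.0, 1.0, len(idx))
        e[0] = sig * z[0]
        for t in range(1, len(idx)):
            e[t] = rho * e[t - 1] + sig * math.sqrt(1.0 - rho**2) * z[t]
        resid[idx[order]] = e

    log_value = (
        eta
        + df["animal_id"].map(b_mouse).to_numpy()
        + np.array([b_area[(m, r)] for m, r in zip(df["animal_id"], df["region"])])
        + df["animal_id"].map(b_slope).to_numpy() * df["day"].map(s_of_day).to_numpy()
        + resid
    )
    out = df.copy()
    out["parameter"] = design.parameter
    out["value"] = np.exp(log_value)
    out["n_voxels_used"] = out["region"].map(dict(ROITemplate().voxel_counts)).astype("Int64")
    return out[
        ["animal_id", "sex", "diet", "day", "region", "parameter", "value", "n_voxels_used"]
    ]


# ---------------------------------------------------------------------------
# spectra


#: (chemical shift ppm, relative peak area) per metabolite; shapes are
#: Gaussian with ~0.025 ppm linewidth.  Shift values are textbook positions.
_METABOLITE_PEAKS: dict[str, list[tuple[float, float]]] = {
    "Ace": [(1.90, 1.0)],
    "Ala": [(1.47, 0.75), (3.77, 0.25)],
    "Asp": [(2.65, 0.5), (2.80, 0.25), (3.89, 0.25)],
    "Cho": [(3.19, 0.75), (4.05, 0.25)],
    "Cr": [(3.03, 0.6), (3.93, 0.4)],
    "GABA": [(1.89, 0.33), (2.28, 0.33), (3.01, 0.34)],
    "Glc": [(3.40, 0.35), (3.70, 0.35), (5.22, 0.30)],
    "Gln": [(2.12, 0.4), (2.45, 0.4), (3.75, 0.2)],
    "Glu": [(2.05, 0.4), (2.34, 0.4), (3.74, 0.2)],
    "Gly": [(3.55, 1.0)],
    "GPC": [(3.21, 0.7), (4.31, 0.3)],
    "Lac": [(1.33, 0.75), (4.10, 0.25)],
    "mI": [(3.52, 0.5), (3.61, 0.3), (4.05, 0.2)],
    "NAA": [(2.01, 0.8), (2.49, 0.1), (2.67, 0.1)],
    "PCh": [(3.22, 0.7), (4.16, 0.3)],
    "PCr": [(3.03, 0.55), (3.94, 0.45)],
    "Tau": [(3.25, 0.5), (3.42, 0.5)],
    "Lip09": [(0.90, 1.0)],
    "Lip13a": [(1.28, 1.0)],
    "Lip20": [(2.02, 0.7), (2.24, 0.3)],
    "MM14": [(1.40, 1.0)],
}

COMPOSITE_SUMS: dict[str, tuple[str, ...]] = {
    "Cho+GPC+PCh": ("Cho", "GPC", "PCh"),
    "mI+Gly": ("mI", "Gly"),
    "Cr+PCr": ("Cr", "PCr"),
    "Glu+Gln": ("Glu", "Gln"),
    "MM14+Lip13a": ("MM14", "Lip13a"),
}


@dataclass
class BasisSet:
    """Metabolite basis spectra on a common ppm grid, unit-area each."""

    ppm: np.ndarray
    spectra: dict[str, np.ndarray]

    @property
    def metabolites(self) -> list[str]:
        return list(self.spectra)

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.spectra[m] for m in self.spectra])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ppm": self.ppm, **self.spectra})


def make_basis_set(
    metabolites: tuple[str, ...] | None = None,
    ppm_range: tuple[float, float] = (0.2, 5.4),
    n_points: int = 2048,
    linewidth_ppm: float = 0.025,
) -> BasisSet:
    """Synthetic basis set: Gaussian peak mixtures, each normalized to unit area."""
    names = tuple(metabolites or _METABOLITE_PEAKS)
    unknown = set(names) - set(_METABOLITE_PEAKS)
    if unknown:
        raise ValueError(f"unknown metabolites {sorted(unknown)}")
    ppm = np.linspace(ppm_range[0], ppm_range[1], n_points)
    dppm = ppm[1] - ppm[0]
    spectra = {}
    for name in names:
        y = np.zeros_like(ppm)
        for shift, area in _METABOLITE_PEAKS[name]:
            y += area * np.exp(-0.5 * ((ppm - shift) / linewidth_ppm) ** 2)
        y = np.maximum(y, 0.0)
        total = y.sum() * dppm
        if total <= 0:
            raise ValueError(f"metabolite {name} has no peaks inside the ppm range")
        spectra[name] = y / total
    return BasisSet(ppm, spectra)


@dataclass
class SpectrumRecord:
    """One 1-D spectrum with acquisition metadata and stored ground truth."""

    ppm: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)
    true_amounts: dict[str, float] | None = None

    def __post_init__(self) -> None:
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


def simulate_spectra(
    basis: BasisSet,
    true_conc: dict[str, float],
    noise_sigma: float = 0.0,
    baseline_amplitude: float = 0.0,
    n_spectra: int = 1,
    seed: int | None = None,
    metadata: dict | None = None,
) -> list[SpectrumRecord]:
    """Linear-combination spectra: sum_i conc_i * basis_i + baseline + noise.

    The baseline is a random quadratic with coefficients scaled by
    ``baseline_amplitude`` (zero by default so fitting tests are exact).
    """
    unknown = set(true_conc) - set(basis.spectra)
    if unknown:
        raise ValueError(f"unknown metabolites {sorted(unknown)}")
    if any(v < 0 for v in true_conc.values()):
        raise ValueError("amounts must be >= 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    clean = np.zeros_like(basis.ppm)
    for name, amount in true_conc.items():
        clean = clean + amount * basis.spectra[name]
    x = np.linspace(-1.0, 1.0, len(basis.ppm))
    records = []
    for _ in range(n_spectra):
        y = clean.copy()
        if baseline_amplitude > 0:
            coef = rng.normal(0.0, baseline_amplitude, 3)
            y = y + coef[0] + coef[1] * x + coef[2] * x**2
        if noise_sigma > 0:
            y = y + rng.normal(0.0, noise_sigma, y.shape)
        records.append(
            SpectrumRecord(basis.ppm.copy(), y, dict(metadata or {}), dict(true_conc))
        )
    return records
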