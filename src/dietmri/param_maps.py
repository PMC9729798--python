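"""Voxelwise parametric map generation: T2, ADC and MTR.

T2 maps come from fitting each voxel's multi-echo signal to the
monoexponential decay S(TE) = S0 * exp(-TE/T2); ADC maps from fitting the
diffusion signal to S(b) = S0 * exp(-b * ADC), with b in s/mm^2 and ADC
reported in um^2/s (1 um^2/s = 1e-6 mm^2/s, so the exponent is
b * ADC * 1e-6); MTR maps from the voxelwise percent signal drop
MTR = (S0 - S_MT) / S0 * 100 between the saturation-off and saturation-on
images.

Both exponential fitters use a log-linear ordinary-least-squares fit as the
initializer (exact in the noise-free case) refined by a bounded, damped
Gauss-Newton iteration on the exponential model, which removes the bias the
log transform introduces under magnitude (Rician) noise.  Voxels that fail
to converge or land outside the physical bounds are flagged invalid and
carry NaN; they never raise and are excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

from .protocols import AcquisitionProtocol

# Physical bounds used during fitting.  Deliberately wider than the retention
# filters applied later at the ROI stage, so filtering happens once, at the
# documented point of the pipeline.
T2_BOUNDS_MS = (1.0, 2000.0)
ADC_BOUNDS = (0.0, 4000.0)  # um^2/s

_MAX_ITER = 200
_REL_TOL = 1e-8

#: exponent = b [s/mm^2] * ADC [um^2/s] * ADC_B_SCALE
ADC_B_SCALE = 1e-6


@dataclass
class ImageSeries:
    """A stack of 2-D acquisitions (rows x cols x n_acquisitions, a.u.)."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageSeries data must be rows x cols x n_acquisitions")
        n_acq = self.protocol.n_acquisitions
        allowed = {n_acq, n_acq * max(self.protocol.n_directions, 1)}
        if self.data.shape[2] not in allowed:
            raise ValueError(
                f"series has {self.data.shape[2]} acquisitions but the protocol "
                f"defines {n_acq} (x {self.protocol.n_directions} directions)"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI-1 with the acquisition index on the 4th dimension."""
        vox = self.protocol.geometry.voxel_size_um / 1000.0
        affine = np.diag([vox, vox, self.protocol.geometry.slice_thickness_mm, 1.0])
        img = nib.Nifti1Image(self.data[:, :, np.newaxis, :], affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, protocol: AcquisitionProtocol) -> "ImageSeries":
        arr = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if arr.ndim == 4:
            arr = arr[:, :, 0, :]
        return cls(arr, protocol)


@dataclass
class ParamMap:
    """A derived per-voxel parameter image with validity mask.

    Invalid voxels carry NaN in ``values`` and False in ``valid``; ``r2``
    holds the per-voxel coefficient of determination of the fit (NaN where
    not applicable, e.g. MTR).
    """

    name: str
    values: np.ndarray
    valid: np.ndarray
    units: str
    r2: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")

    def masked(self) -> np.ndarray:
        """Values with invalid voxels set to NaN."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.masked()[:, :, np.newaxis].astype(np.float64), np.eye(4))
        img.header["descrip"] = f"{self.name} [{self.units}]".encode()[:79]
        nib.save(img, str(path))


def _fit_monoexp(
    signals: np.ndarray,
    x: np.ndarray,
    rate_bounds: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit S = S0 * exp(-r * x) per row of ``signals`` (n_voxels, n_points).

    Returns (S0, rate, converged, r2).  Log-linear OLS initializer, then a
    damped Gauss-Newton refinement of the nonlinear least-squares problem
    with the rate clipped to ``rate_bounds``.
    """
    signals = np.asarray(signals, dtype=float)
    n_vox, n_pts = signals.shape
    x = np.asarray(x, dtype=float)

    ok = np.all(signals > 0, axis=1)
    s_safe = np.where(signals > 0, signals, 1.0)
    logs = np.log(s_safe)

    # weighted log-linear fit (weights ~ S^2 approximate the NLS objective)
    w = s_safe**2
    sw = w.sum(axis=1)
    xbar = (w * x).sum(axis=1) / sw
    ybar = (w * logs).sum(axis=1) / sw
    dx = x[np.newaxis, :] - xbar[:, np.newaxis]
    denom = (w * dx**2).sum(axis=1)
    denom = np.where(denom > 0, denom, np.nan)
    slope = (w * dx * (logs - ybar[:, np.newaxis])).sum(axis=1) / denom
    rate = np.clip(-slope, *rate_bounds)
    s0 = np.exp(ybar + rate * xbar)
    rate = np.where(ok & np.isfinite(rate), rate, np.nan)
    s0 = np.where(ok & np.isfinite(s0), s0, np.nan)

    active = ok & np.isfinite(rate)
    # Gauss-Newton on theta = (S0, r), residual = S0*exp(-r x) - y
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        e = np.exp(-rate[active, np.newaxis] * x[np.newaxis, :])
        model = s0[active, np.newaxis] * e
        resid = model - signals[active]
        j0 = e
        j1 = -s0[active, np.newaxis] * x[np.newaxis, :] * e
        a00 = (j0 * j0).sum(axis=1)
        a01 = (j0 * j1).sum(axis=1)
        a11 = (j1 * j1).sum(axis=1)
        g0 = (j0 * resid).sum(axis=1)
        g1 = (j1 * resid).sum(axis=1)
        det = a00 * a11 - a01 * a01
        det = np.where(np.abs(det) > 1e-300, det, np.nan)
        d_s0 = (a11 * g0 - a01 * g1) / det
        d_r = (a00 * g1 - a01 * g0) / det
        new_s0 = s0[active] - d_s0
        new_r = np.clip(rate[active] - d_r, *rate_bounds)
        step = np.maximum(
            np.abs(new_s0 - s0[active]) / np.maximum(np.abs(s0[active]), 1e-30),
            np.abs(new_r - rate[active]) / np.maximum(np.abs(rate[active]), 1e-30),
        )
        bad = ~np.isfinite(new_s0) | ~np.isfinite(new_r) | (new_s0 <= 0)
        new_s0 = np.where(bad, s0[active], new_s0)
        new_r = np.where(bad, rate[active], new_r)
        s0[active] = new_s0
        rate[active] = new_r
        still = step > _REL_TOL
        still &= ~bad
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    converged = ok & np.isfinite(rate) & np.isfinite(s0) & ~active
    with np.errstate(invalid="ignore"):
        model = s0[:, np.newaxis] * np.exp(-rate[:, np.newaxis] * x[np.newaxis, :])
        ss_res = ((signals - model) ** 2).sum(axis=1)
        ss_tot = ((signals - signals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), np.nan)
    return s0, rate, converged, r2


def _series_to_rows(series: ImageSeries) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    data = series.data
    shape = data.shape[:2]
    rows = data.reshape(-1, data.shape[2])
    if series.mask is not None:
        sel = series.mask.reshape(-1).astype(bool)
    else:
        sel = np.ones(rows.shape[0], dtype=bool)
    return rows, sel, shape


def fit_t2_map(series: ImageSeries) -> tuple[ParamMap, ParamMap]:
    """Voxelwise monoexponential T2 fit; returns (T2 map [ms], S0 map [a.u.])."""
    if series.protocol.kind != "t2map":
        raise ValueError("fit_t2_map requires a t2map protocol")
    te = np.asarray(series.protocol.echo_times_ms, dtype=float)
    if te.size < 3:
        raise ValueError("T2 fitting needs at least 3 echoes")
    rows, sel, shape = _series_to_rows(series)
    rate_bounds = (1.0 / T2_BOUNDS_MS[1], 1.0 / T2_BOUNDS_MS[0])
    s0 = np.full(rows.shape[0], np.nan)
    t2 = np.full(rows.shape[0], np.nan)
    valid = np.zeros(rows.shape[0], dtype=bool)
    r2 = np.full(rows.shape[0], np.nan)
    if sel.any():
        s0_f, rate, conv, r2_f = _fit_monoexp(rows[sel], te, rate_bounds)
        with np.errstate(divide="ignore"):
            t2_f = 1.0 / rate
        # rates pinned at the bounds are degenerate (no decay / instant decay)
        interior = (
            conv
            & (rate > rate_bounds[0] * (1 + 1e-9))
            & (rate < rate_bounds[1] * (1 - 1e-9))
            & (s0_f > 0)
        )
        s0[sel], t2[sel], valid[sel], r2[sel] = s0_f, t2_f, interior, r2_f
    t2[~valid] = np.nan
    meta = {"n_echoes": te.size}
    return (
        ParamMap("T2", t2.reshape(shape), valid.reshape(shape), "ms", r2.reshape(shape), meta),
        ParamMap("S0", s0.reshape(shape), valid.reshape(shape), "a.u.", r2.reshape(shape), meta),
    )


def fit_adc_map(series: ImageSeries, direction_average: str = "arithmetic") -> tuple[ParamMap, ParamMap]:
    """Voxelwise monoexponential diffusion fit; returns (ADC map [um^2/s], S0).

    When the series holds three orthogonal gradient directions per b-value
    (n_acquisitions = 3 * n_b), the direction signals are averaged before
    fitting (``arithmetic`` by default, ``geometric`` as the alternative).
    """
    if series.protocol.kind not in ("dwi_male", "dwi_female", "dwi"):
        raise ValueError("fit_adc_map requires a diffusion protocol")
    b = np.asarray(series.protocol.b_values, dtype=float)
    if b.size < 2:
        raise ValueError("ADC fitting needs at least 2 b-values")
    if np.unique(b).size != b.size:
        raise ValueError("b-values must be distinct")
    data = series.data
    if data.shape[2] == b.size * series.protocol.n_directions and series.protocol.n_directions > 1:
        nd = series.protocol.n_directions
        stacked = data.reshape(data.shape[0], data.shape[1], b.size, nd)
        if direction_average == "arithmetic":
            data = stacked.mean(axis=3)
        elif direction_average == "geometric":
            data = np.exp(np.log(np.maximum(stacked, 1e-300)).mean(axis=3))
        else:
            raise ValueError("direction_average must be 'arithmetic' or 'geometric'")
        series = ImageSeries(data, series.protocol, series.mask)
    rows, sel, shape = _series_to_rows(series)
    x = b * ADC_B_SCALE  # exponent = x * ADC[um^2/s]
    rate_bounds = ADC_BOUNDS
    s0 = np.full(rows.shape[0], np.nan)
    adc = np.full(rows.shape[0], np.nan)
    valid = np.zeros(rows.shape[0], dtype=bool)
    r2 = np.full(rows.shape[0], np.nan)
    if sel.any():
        s0_f, rate, conv, r2_f = _fit_monoexp(rows[sel], x, rate_bounds)
        interior = conv & (rate < rate_bounds[1] * (1 - 1e-9)) & (s0_f > 0)
        s0[sel], adc[sel], valid[sel], r2[sel] = s0_f, rate, interior, r2_f
    adc[~valid] = np.nan
    meta = {"b_values": b.tolist()}
    return (
        ParamMap("ADC", adc.reshape(shape), valid.reshape(shape), "um^2/s", r2.reshape(shape), meta),
        ParamMap("S0", s0.reshape(shape), valid.reshape(shape), "a.u.", r2.reshape(shape), meta),
    )


def compute_mtr_map(series_off: ImageSeries | np.ndarray, series_on: ImageSeries | np.ndarray) -> ParamMap:
    """Magnetization transfer ratio map, percent: (S0 - S_MT)/S0 * 100.

    ``series_off`` is the acquisition without the saturation pulse (S0),
    ``series_on`` the saturated one (S_MT).  Voxels with S0 = 0 are invalid;
    negative MTR values are retained in the map (their exclusion is a
    downstream filtering decision).
    """
    s0 = series_off.data[:, :, 0] if isinstance(series_off, ImageSeries) else np.asarray(series_off, float)
    smt = series_on.data[:, :, -1] if isinstance(series_on, ImageSeries) else np.asarray(series_on, float)
    if s0.shape != smt.shape:
        raise ValueError("MT on/off image shapes differ")
    valid = s0 != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (s0 - smt) / s0 * 100.0
    mtr[~valid] = np.nan
    return ParamMap("MTR", mtr, valid, "percent")


def mtr_from_pair(series: ImageSeries) -> ParamMap:
    """MTR from a single mt_pair series (acquisition 0 = off, 1 = on)."""
    if series.protocol.kind != "mt_pair":
        raise ValueError("mtr_from_pair requires an mt_pair protocol")
    return compute_mtr_map(series.data[:, :, 0], series.data[:, :, 1])
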