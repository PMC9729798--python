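"""Acquisition protocols and diffusion-weighting arithmetic.

The pipeline revolves around three quantitative acquisitions on a 128x128,
21 mm field-of-view axial slice (1.25 mm thick, 164 um in-plane voxels):

* a multi-echo T2 mapping series (TR 5000 ms, 50 echo times between 12 and
  600 ms),
* a diffusion-weighted series, either 9 b-values in (200, 2000) s/mm^2
  (the male protocol) or 3 b-values in (300, 1200) s/mm^2 (the female
  protocol), with gradient separation Delta = 20 ms and duration
  delta = 4 ms,
* a magnetization-transfer pair: one image with an off-resonance saturation
  pulse train (50 pulses, 550 Hz bandwidth, 5 ms, 5.5 uT, 1500 Hz offset)
  and one without it (TR 2500 ms, TE 9.8 ms).

`AcquisitionProtocol` is the declarative record both the simulator and the
map fitters consume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.675221874e8

PROTOCOL_KINDS = ("t2map", "dwi_male", "dwi_female", "mt_pair")


@dataclass(frozen=True)
class Geometry:
    """In-plane geometry of an axial acquisition."""

    fov_mm: float = 21.0
    matrix: int = 128
    slice_thickness_mm: float = 1.25

    @property
    def voxel_size_um(self) -> float:
        """In-plane voxel size in micrometres (FOV / matrix)."""
        return self.fov_mm / self.matrix * 1000.0

    def __post_init__(self) -> None:
        if self.matrix <= 0 or self.fov_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("geometry dimensions must be positive")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence parameters for one quantitative acquisition.

    ``echo_times_ms`` is populated for ``t2map`` protocols, ``b_values`` for
    diffusion protocols and ``mt_states`` ("off", "on") for the MT pair; the
    remaining entries are carried as metadata.
    """

    kind: str
    geometry: Geometry = field(default_factory=Geometry)
    tr_ms: float = 5000.0
    echo_times_ms: tuple[float, ...] = ()
    b_values: tuple[float, ...] = ()
    n_directions: int = 1
    delta_ms: float = 0.0
    Delta_ms: float = 0.0
    mt_states: tuple[str, ...] = ()
    metadata: dict[str, Any] = field(default_factory=dict, compare=False)

    @property
    def n_acquisitions(self) -> int:
        if self.kind == "t2map":
            return len(self.echo_times_ms)
        if self.kind in ("dwi_male", "dwi_female", "dwi"):
            return len(self.b_values)
        if self.kind == "mt_pair":
            return len(self.mt_states)
        raise ValueError(f"unknown protocol kind {self.kind!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionProtocol":
        d = json.loads(text)
        d["geometry"] = Geometry(**d["geometry"])
        for k in ("echo_times_ms", "b_values", "mt_states"):
            d[k] = tuple(d[k])
        return cls(**d)


def compute_b_value(gamma: float, delta_ms: float, Delta_ms: float, G_mT_per_m: float) -> float:
    """Diffusion weighting b = gamma^2 delta^2 G^2 (Delta - delta/3), in s/mm^2.

    Parameters
    ----------
    gamma : proton gyromagnetic ratio, rad s^-1 T^-1.
    delta_ms : gradient pulse duration, ms.
    Delta_ms : gradient pulse separation, ms.
    G_mT_per_m : gradient strength, mT/m.
    """
    if gamma < 0 or delta_ms < 0 or G_mT_per_m < 0:
        raise ValueError("gamma, delta and G must be non-negative")
    if Delta_ms <= delta_ms / 3.0:
        raise ValueError("Delta must exceed delta/3 for a positive diffusion time")
    delta_s = delta_ms * 1e-3
    Delta_s = Delta_ms * 1e-3
    G_T_per_m = G_mT_per_m * 1e-3
    b_si = gamma**2 * delta_s**2 * G_T_per_m**2 * (Delta_s - delta_s / 3.0)  # s/m^2
    return b_si * 1e-6  # s/mm^2


def solve_gradient_for_b(b: float, gamma: float, delta_ms: float, Delta_ms: float) -> float:
    """Gradient strength (mT/m) producing diffusion weighting ``b`` (s/mm^2)."""
    if b < 0:
        raise ValueError("b must be non-negative")
    if Delta_ms <= delta_ms / 3.0:
        raise ValueError("Delta must exceed delta/3")
    if delta_ms == 0:
        raise ValueError("delta must be positive to solve for G")
    delta_s = delta_ms * 1e-3
    Delta_s = Delta_ms * 1e-3
    b_si = b * 1e6
    G_T_per_m = np.sqrt(b_si / (gamma**2 * delta_s**2 * (Delta_s - delta_s / 3.0)))
    return float(G_T_per_m * 1e3)


def _default_protocol(kind: str) -> dict[str, Any]:
    geometry = Geometry()
    if kind == "t2map":
        return dict(
            kind=kind,
            geometry=geometry,
            tr_ms=5000.0,
            echo_times_ms=tuple(np.geomspace(12.0, 600.0, 50)),
        )
    if kind == "dwi_male":
        return dict(
            kind=kind,
            geometry=geometry,
            tr_ms=3000.0,
            b_values=tuple(np.linspace(200.0, 2000.0, 9)),
            n_directions=3,
            delta_ms=4.0,
            Delta_ms=20.0,
            metadata={"te_ms": 31.0, "readout": "4-shot EPI", "averages": 3},
        )
    if kind == "dwi_female":
        return dict(
            kind=kind,
            geometry=geometry,
            tr_ms=3000.0,
            b_values=(300.0, 750.0, 1200.0),
            n_directions=3,
            delta_ms=4.0,
            Delta_ms=20.0,
            metadata={"te_ms": 31.0, "readout": "4-shot EPI", "averages": 3},
        )
    if kind == "mt_pair":
        return dict(
            kind=kind,
            geometry=geometry,
            tr_ms=2500.0,
            mt_states=("off", "on"),
            metadata={
                "te_ms": 9.8,
                "mt_pulse": {
                    "n_pulses": 50,
                    "bandwidth_hz": 550.0,
                    "length_ms": 5.0,
                    "power_uT": 5.5,
                    "offset_hz": 1500.0,
                },
            },
        )
    raise ValueError(f"unknown protocol kind {kind!r}; expected one of {PROTOCOL_KINDS}")


def make_protocol(kind: str, overrides: dict[str, Any] | None = None) -> AcquisitionProtocol:
    """Build a default acquisition protocol, optionally overriding fields.

    Convenience override keys ``n_echoes`` (t2map: resample the log-spaced
    echo grid) and ``n_b_values`` (dwi: resample the linear b grid) are
    accepted in addition to the dataclass field names.
    """
    d = _default_protocol(kind)
    overrides = dict(overrides or {})
    if "n_echoes" in overrides:
        n = int(overrides.pop("n_echoes"))
        if n < 1:
            raise ValueError("n_echoes must be >= 1")
        d["echo_times_ms"] = tuple(np.geomspace(12.0, 600.0, n))
    if "n_b_values" in overrides:
        n = int(overrides.pop("n_b_values"))
        if n < 1:
            raise ValueError("n_b_values must be >= 1")
        lo, hi = d["b_values"][0], d["b_values"][-1]
        d["b_values"] = tuple(np.linspace(lo, hi, n))
    valid = {f.name for f in dataclasses.fields(AcquisitionProtocol)}
    for key, value in overrides.items():
        if key not in valid:
            raise ValueError(f"unknown protocol field {key!r}")
        d[key] = value
    proto = AcquisitionProtocol(**d)
    if any(te <= 0 for te in proto.echo_times_ms):
        raise ValueError("echo times must be positive")
    if any(b <= 0 for b in proto.b_values):
        raise ValueError("b-values must be positive")
    if proto.tr_ms <= 0:
        raise ValueError("TR must be positive")
    return proto
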