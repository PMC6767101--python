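"""Acquisition protocol for the 3D-cones UTE sodium sequence.

All sequence constants live in one validated dataclass.  Derived quantities
(kmax, dwell time, samples per readout, image matrix size) are computed from
the primary fields rather than stored, so a protocol can never be internally
inconsistent.

Conventions used throughout the package:

* k-space coordinates are in cycles/m,
* times are in ms unless the field name says otherwise (``delay_us``),
* gradients in mT/m, slew rate in T/m/s,
* the gyromagnetic ratio of 23Na is 11.262 MHz/T (fixed physical constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = ["AcquisitionProtocol", "GAMMA_NA_MHZ_PER_T"]

#: Gyromagnetic ratio of the 23Na nucleus, MHz/T.
GAMMA_NA_MHZ_PER_T = 11.262


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence constants of the two-site 3D-cones UTE protocol.

    Defaults are the matched two-site brain protocol: 4 mm isotropic nominal
    resolution over a 24 cm FOV, 10 ms readouts, 2184 readouts, 3 averages,
    166 kHz full readout bandwidth, 30 mT/m maximum gradient amplitude and
    120 T/m/s maximum slew rate, TE/TR = 0.5/100 ms, with a 5 us gradient
    delay applied at reconstruction.

    Note on the slew limit: the protocol is circulated with the slew rate
    printed as "120 mT/s", which is not a slew-rate unit; it is interpreted
    here as 120 T/m/s (equivalently 120 mT/m/ms), a standard clinical-gradient
    figure. The field is configurable.
    """

    fov_mm: float = 240.0
    voxel_mm: float = 4.0
    n_readouts: int = 2184
    readout_ms: float = 10.0
    bw_full_khz: float = 166.0
    gmax_mT_per_m: float = 30.0
    smax_T_per_m_per_s: float = 120.0
    te_ms: float = 0.5
    tr_ms: float = 100.0
    n_averages: int = 3
    delay_us: float = 5.0
    gamma_MHz_per_T: float = GAMMA_NA_MHZ_PER_T

    def __post_init__(self) -> None:
        positive = [
            "fov_mm", "voxel_mm", "n_readouts", "readout_ms", "bw_full_khz",
            "gmax_mT_per_m", "smax_T_per_m_per_s", "tr_ms", "n_averages",
            "gamma_MHz_per_T",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"protocol field {name!r} must be positive, "
                                 f"got {getattr(self, name)}")
        if self.te_ms < 0:
            raise ValueError("te_ms must be non-negative")
        if self.delay_us < 0:
            raise ValueError("delay_us must be non-negative")
        if self.voxel_mm > self.fov_mm:
            raise ValueError("voxel size exceeds FOV; matrix would be empty")
        if self.samples_per_readout < 1:
            raise ValueError("readout too short for one sample at this bandwidth")
        if self.te_ms + self.readout_ms > self.tr_ms:
            raise ValueError("readout does not fit within TR")

    # ------------------------------------------------------------------ derived
    @property
    def kmax_cycles_per_m(self) -> float:
        """Nominal-resolution k-space radius, 1/(2*voxel)."""
        return 1.0 / (2.0 * self.voxel_mm * 1e-3)

    @property
    def dwell_ms(self) -> float:
        """Sample dwell time, full-bandwidth convention (1/bw)."""
        return 1.0 / self.bw_full_khz

    @property
    def samples_per_readout(self) -> int:
        return int(self.readout_ms * self.bw_full_khz + 1e-9)

    @property
    def grid_size(self) -> int:
        """Reconstructed matrix size per axis (round(fov/voxel))."""
        return int(round(self.fov_mm / self.voxel_mm))

    @property
    def gamma_Hz_per_T(self) -> float:
        return self.gamma_MHz_per_T * 1e6

    # ---------------------------------------------------------------------- io
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AcquisitionProtocol":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown protocol fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "AcquisitionProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
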