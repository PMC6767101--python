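"""Digital head phantom for sodium-MRI simulation.

The phantom is a nested set of analytic solids — an outer CSF envelope, a
grey-matter shell, a white-matter core, two ventricular CSF ellipsoids — and
two cylindrical agar calibration tubes (24.5 mm diameter x 89 mm, 20 and
80 mM NaCl) placed laterally beside the head, as worn next to ear defenders
in the scanner.

Every solid has both an exact Fourier transform (used by the analytic
forward model, which avoids the inverse crime of simulating on the
reconstruction grid) and an indicator function (used to rasterise
partial-volume maps by supersampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import j1

__all__ = [
    "TissueProperties", "Ellipsoid", "Cylinder", "DigitalPhantom",
    "build_head_phantom", "default_tissues", "HeadGeometry",
]


@dataclass(frozen=True)
class TissueProperties:
    """Relaxation and concentration parameters of one compartment.

    T2* decay is biexponential with a short-component fraction
    ``frac_short``; brain-tissue and agar values are literature-typical
    defaults (they are not constrained by the two-site protocol itself) and
    are fully configurable.
    """

    name: str
    tsc_mM: float
    t1_ms: float
    t2s_short_ms: float
    t2s_long_ms: float
    frac_short: float

    def __post_init__(self) -> None:
        if self.tsc_mM < 0:
            raise ValueError("tsc_mM must be non-negative")
        if self.t1_ms <= 0 or self.t2s_short_ms <= 0 or self.t2s_long_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if not 0.0 <= self.frac_short <= 1.0:
            raise ValueError("frac_short must lie in [0, 1]")
        if self.t2s_short_ms > self.t2s_long_ms:
            raise ValueError("t2s_short_ms must not exceed t2s_long_ms")


def default_tissues(wm_mM: float = 41.8, gm_mM: float = 52.1,
                    csf_mM: float = 85.8) -> dict[str, TissueProperties]:
    """Default tissue table.

    Brain T1 values are ~22 ms for parenchyma and ~47 ms for CSF; at the
    protocol's TR = 100 ms this leaves CSF visibly T1-saturated, which is
    the mechanism behind the systematic underestimation of CSF sodium.
    """
    return {
        "wm": TissueProperties("wm", wm_mM, 22.0, 3.0, 20.0, 0.6),
        "gm": TissueProperties("gm", gm_mM, 22.0, 3.0, 20.0, 0.6),
        "csf": TissueProperties("csf", csf_mM, 47.0, 55.0, 55.0, 0.0),
        "tube20": TissueProperties("tube20", 20.0, 35.0, 5.0, 25.0, 0.6),
        "tube80": TissueProperties("tube80", 80.0, 35.0, 5.0, 25.0, 0.6),
    }


# ------------------------------------------------------------------ primitives

def _sphere_ft(q: np.ndarray) -> np.ndarray:
    """FT of the unit ball at radial frequency q (cycles per unit length)."""
    x = 2.0 * np.pi * q
    small = x < 1e-6
    x_safe = np.where(small, 1.0, x)
    out = (np.sin(x_safe) - x_safe * np.cos(x_safe)) / (2.0 * np.pi ** 2 * np.where(small, 1.0, q) ** 3)
    return np.where(small, 4.0 * np.pi / 3.0 * (1.0 - x ** 2 / 10.0), out)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; center and semi-axes in metres."""

    center_m: tuple[float, float, float]
    semi_axes_m: tuple[float, float, float]

    def fourier(self, k: np.ndarray) -> np.ndarray:
        a, b, c = self.semi_axes_m
        q = np.sqrt((a * k[..., 0]) ** 2 + (b * k[..., 1]) ** 2 + (c * k[..., 2]) ** 2)
        phase = np.exp(-2j * np.pi * (k @ np.asarray(self.center_m)))
        return a * b * c * _sphere_ft(q) * phase

    def indicator(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        a, b, c = self.semi_axes_m
        cx, cy, cz = self.center_m
        return (((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2) <= 1.0

    @property
    def volume_m3(self) -> float:
        a, b, c = self.semi_axes_m
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class Cylinder:
    """Finite circular cylinder along the z axis; dimensions in metres."""

    center_m: tuple[float, float, float]
    radius_m: float
    length_m: float

    def fourier(self, k: np.ndarray) -> np.ndarray:
        krho = np.hypot(k[..., 0], k[..., 1])
        x = 2.0 * np.pi * self.radius_m * krho
        small = x < 1e-8
        x_safe = np.where(small, 1.0, x)
        radial = np.where(small, 0.5 * (1.0 - x ** 2 / 8.0), j1(x_safe) / x_safe)
        axial = self.length_m * np.sinc(self.length_m * k[..., 2])
        phase = np.exp(-2j * np.pi * (k @ np.asarray(self.center_m)))
        return 2.0 * np.pi * self.radius_m ** 2 * radial * axial * phase

    def indicator(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_m
        return (np.hypot(x - cx, y - cy) <= self.radius_m) & \
               (np.abs(z - cz) <= self.length_m / 2.0)

    @property
    def volume_m3(self) -> float:
        return np.pi * self.radius_m ** 2 * self.length_m


@dataclass(frozen=True)
class HeadGeometry:
    """Default analytic geometry, all lengths in mm.

    The head is a thin subarachnoid CSF envelope over a thick GM shell and a
    WM core holding one large central ventricular CSF body (``offset 0``
    merges the lateral ventricles; a positive offset gives two disjoint
    ones).  Thicknesses are deliberate: GM is thick enough, and the
    ventricular body large enough, that each has pure (pv > 0.95) voxels
    well clear of the point-spread function, while the subarachnoid film is
    thinner than a voxel so — as for the sulcal CSF of real young brains —
    it contributes partial-volume signal but no pure-CSF mask voxels.
    The calibration tubes follow the physical cylinders: 24.5 mm diameter,
    89 mm length, lateral to the head.
    """

    envelope_semi_mm: tuple[float, float, float] = (71.5, 87.5, 61.5)
    gm_semi_mm: tuple[float, float, float] = (68.0, 84.0, 58.0)
    wm_semi_mm: tuple[float, float, float] = (46.0, 62.0, 36.0)
    ventricle_semi_mm: tuple[float, float, float] = (5.0, 15.0, 7.0)
    ventricle_offset_mm: float = 9.0

    @classmethod
    def verification(cls) -> "HeadGeometry":
        """Geometry for exact-recovery verification experiments.

        Replaces the realistic small lateral ventricles with one large
        central CSF body whose pure-voxel core clears the point-spread
        function, so that segmentation means can be compared against ground
        truth at the percent level.  The default (small-ventricle) geometry
        deliberately keeps the pure-CSF mask small — as in young healthy
        brains — which is what drives CSF's inferior reproducibility in the
        emulated study.
        """
        return cls(ventricle_semi_mm=(28.0, 40.0, 22.0), ventricle_offset_mm=0.0)
    tube_diameter_mm: float = 24.5
    tube_length_mm: float = 89.0
    tube_offset_mm: float = 95.0


@dataclass
class DigitalPhantom:
    """Rasterised and analytic description of one subject's scan scene.

    ``solids`` is an ordered list of ``(primitive, tissue, parent_tissue)``;
    the analytic scene amplitude is the sum over solids of
    ``a(tissue) - a(parent)`` times the primitive's FT, which composes the
    nested geometry exactly.
    """

    solids: list[tuple[object, str, str | None]]
    tissues: dict[str, TissueProperties]
    voxel_mm: float
    grid_size: int
    pv_maps: dict[str, np.ndarray] = field(default_factory=dict)
    label_volume: np.ndarray | None = None
    label_codes: dict[str, int] = field(default_factory=dict)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_mm * (self.grid_size // 2)
        return aff

    def head_mask(self, margin_voxels: int = 2) -> np.ndarray:
        """Binary mask of the head envelope, dilated by a safety margin."""
        from scipy.ndimage import binary_dilation
        env = next(prim for prim, tis, par in self.solids if tis == "csf" and par is None)
        x, y, z = self._voxel_centers_m()
        mask = env.indicator(x, y, z)
        return binary_dilation(mask, iterations=margin_voxels)

    def tube_masks_truth(self) -> dict[str, np.ndarray]:
        x, y, z = self._voxel_centers_m()
        return {tis: prim.indicator(x, y, z)
                for prim, tis, _ in self.solids if tis.startswith("tube")}

    def _voxel_centers_m(self):
        n = self.grid_size
        c = (np.arange(n) - n // 2) * self.voxel_mm * 1e-3
        return np.meshgrid(c, c, c, indexing="ij")

    def with_tissues(self, tissues: dict[str, TissueProperties]) -> "DigitalPhantom":
        return replace(self, tissues=tissues)


def _rasterize_pv(solids, tissue_names, grid_size, voxel_mm, supersample=3):
    """Partial-volume maps by supersampled evaluation of the nested solids."""
    n = grid_size
    vm = voxel_mm * 1e-3
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    base = (np.arange(n) - n // 2) * vm
    fine = (base[:, None] + sub[None, :] * vm).ravel()
    pv = {t: np.zeros((n, n, n)) for t in tissue_names}
    norm = supersample ** 3
    # evaluate per z-slab to bound memory
    fx, fy = np.meshgrid(fine, fine, indexing="ij")
    for iz in range(n):
        zs = fine[iz * supersample:(iz + 1) * supersample]
        owner = np.zeros((len(fine), len(fine), len(zs)), dtype=np.int16)
        for code, (prim, tis, par) in enumerate(solids, start=1):
            ind = prim.indicator(fx[..., None], fy[..., None], zs[None, None, :])
            owner[ind] = code
        for code, (prim, tis, par) in enumerate(solids, start=1):
            frac = (owner == code).reshape(n, supersample, n, supersample, len(zs))
            pv[tis][:, :, iz] += frac.sum(axis=(1, 3)).sum(axis=-1) / norm
    return pv


def build_head_phantom(tissues: dict[str, TissueProperties] | None = None,
                       geometry: HeadGeometry | None = None,
                       voxel_mm: float = 4.0, grid_size: int = 60,
                       rasterize: bool = True,
                       supersample: int = 3) -> DigitalPhantom:
    """Assemble the head + calibration-tube phantom.

    Solids are listed outermost-first so that later entries carve their
    compartment out of the enclosing one.  Raises if a tube intersects the
    head envelope.
    """
    tissues = dict(tissues) if tissues is not None else default_tissues()
    g = geometry or HeadGeometry()
    mm = 1e-3

    env = Ellipsoid((0, 0, 0), tuple(s * mm for s in g.envelope_semi_mm))
    gm = Ellipsoid((0, 0, 0), tuple(s * mm for s in g.gm_semi_mm))
    wm = Ellipsoid((0, 0, 0), tuple(s * mm for s in g.wm_semi_mm))
    if g.ventricle_offset_mm == 0.0:
        vents = [Ellipsoid((0, 0, 0), tuple(s * mm for s in g.ventricle_semi_mm))]
    else:
        vents = [Ellipsoid((sgn * g.ventricle_offset_mm * mm, 0, 0),
                           tuple(s * mm for s in g.ventricle_semi_mm))
                 for sgn in (-1, 1)]
        gap = 2 * g.ventricle_offset_mm - 2 * g.ventricle_semi_mm[0]
        if gap < 0:
            raise ValueError("bilateral ventricles overlap; the analytic "
                             "forward model requires disjoint solids")
    tubes = {
        "tube20": Cylinder((-g.tube_offset_mm * mm, 0, 0),
                           g.tube_diameter_mm * mm / 2, g.tube_length_mm * mm),
        "tube80": Cylinder((+g.tube_offset_mm * mm, 0, 0),
                           g.tube_diameter_mm * mm / 2, g.tube_length_mm * mm),
    }
    # tubes must clear the head envelope: check closest approach on the
    # envelope's x axis against the tube's bounding cylinder
    a = g.envelope_semi_mm[0]
    for name, tube in tubes.items():
        clearance = abs(tube.center_m[0]) * 1e3 - g.tube_diameter_mm / 2 - a
        if clearance < 0:
            raise ValueError(f"{name} intersects the head envelope "
                             f"(clearance {clearance:.1f} mm)")

    solids: list[tuple[object, str, str | None]] = [
        (env, "csf", None),
        (gm, "gm", "csf"),
        (wm, "wm", "gm"),
        *[(v, "csf_vent", "wm") for v in vents],
        (tubes["tube20"], "tube20", None),
        (tubes["tube80"], "tube80", None),
    ]

    phantom = DigitalPhantom(solids=solids, tissues=tissues,
                             voxel_mm=voxel_mm, grid_size=grid_size)
    if rasterize:
        names = ["csf", "gm", "wm", "csf_vent", "tube20", "tube80"]
        pv = _rasterize_pv(solids, names, grid_size, voxel_mm, supersample)
        # ventricular CSF is CSF for all downstream analysis
        pv["csf"] = pv["csf"] + pv.pop("csf_vent")
        phantom.pv_maps = pv
        codes = {t: i + 1 for i, t in enumerate(pv)}
        stack = np.stack([pv[t] for t in codes])
        label = np.where(stack.sum(0) > 0.5, np.argmax(stack, axis=0) + 1, 0)
        phantom.label_volume = label.astype(np.int16)
        phantom.label_codes = codes
    return phantom


def scene_fourier(phantom: DigitalPhantom, k: np.ndarray,
                  amplitude_of: dict[str, np.ndarray | float]) -> np.ndarray:
    """Analytic scene FT at sample positions k for given per-tissue amplitudes.

    ``amplitude_of`` maps tissue name -> scalar or per-sample amplitude
    (broadcastable against ``k[..., 0]``); ventricular CSF uses the "csf"
    amplitude.
    """
    def amp(name):
        if name is None:
            return 0.0
        key = "csf" if name == "csf_vent" else name
        return amplitude_of[key]

    out = np.zeros(k.shape[:-1], dtype=complex)
    for prim, tis, par in phantom.solids:
        delta = amp(tis) - amp(par)
        ft = prim.fourier(k)
        out += delta * ft
    return out
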