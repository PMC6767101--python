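"""Forward simulation of the two-site scan-rescan sodium study.

Signal model: at sample time ``t`` (ms since excitation) a compartment with
total sodium concentration ``tsc`` contributes

    tsc * (1 - exp(-TR/T1)) * (f_s * exp(-t/T2*_short) + (1-f_s) * exp(-t/T2*_long))

to the transverse signal density.  The k-space sample at ``k(t)`` is the
Fourier transform of that density over the scene: evaluated analytically
from the phantom's solid primitives (default, avoiding the inverse crime of
sharing a grid with the reconstruction) or by NUFFT of the rasterised
partial-volume maps (raster mode, for irregular phantoms).

A two-site cohort is generated by drawing each subject's true per-tissue
TSC once (truncated normal, reused at both sites) and letting sites differ
only through noise level, calibration gain and gradient delay — the minimal
structure behind the repeatability-vs-reproducibility ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .phantom import DigitalPhantom, TissueProperties, build_head_phantom, default_tissues, scene_fourier
from .protocol import AcquisitionProtocol
from .trajectory import ConesTrajectory, apply_delay_correction

__all__ = [
    "signal_weight", "simulate_kspace", "KSpaceData",
    "SiteSpec", "CohortSpec", "generate_cohort", "cohort_truths",
]


def signal_weight(tissue: TissueProperties, tr_ms: float,
                  t_ms: np.ndarray | float) -> np.ndarray | float:
    """T1-saturation times biexponential T2* amplitude at time t since excitation."""
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_ms must be non-negative")
    if tissue.t1_ms <= 0 or tissue.t2s_short_ms <= 0 or tissue.t2s_long_ms <= 0:
        raise ValueError("relaxation times must be positive")
    sat = 1.0 - np.exp(-tr_ms / tissue.t1_ms)
    decay = (tissue.frac_short * np.exp(-t / tissue.t2s_short_ms)
             + (1.0 - tissue.frac_short) * np.exp(-t / tissue.t2s_long_ms))
    return sat * decay


@dataclass
class KSpaceData:
    """Raw complex samples of one scan, with full provenance."""

    samples: np.ndarray
    protocol: AcquisitionProtocol
    noise_sd: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("k-space samples must be finite")


def simulate_kspace(phantom: DigitalPhantom, traj: ConesTrajectory,
                    protocol: AcquisitionProtocol, noise_sd: float = 0.0,
                    seed: int | np.random.SeedSequence | None = 0,
                    mode: str = "analytic", relaxation: bool = True,
                    gain: float = 1.0) -> KSpaceData:
    """Simulate raw k-space for one scan.

    ``traj`` is taken as the *realised* trajectory (apply the site's gradient
    delay before simulating).  Noise is i.i.d. complex Gaussian with per-
    channel SD ``noise_sd / sqrt(n_averages)`` — signal averaging is modelled
    through the SD rather than explicit repeats.  With ``relaxation=False``
    all saturation/decay factors are 1 (pure concentration imaging), the
    configuration used to isolate gridding/calibration errors.
    """
    if traj.k.shape[1] != protocol.samples_per_readout or \
            traj.n_readouts != protocol.n_readouts:
        raise ValueError("trajectory shape does not match protocol")

    t = traj.t  # ms since excitation, shared by readouts
    amps: dict[str, np.ndarray | float] = {}
    for name, tis in phantom.tissues.items():
        w = signal_weight(tis, protocol.tr_ms, t) if relaxation else 1.0
        amps[name] = tis.tsc_mM * w

    if mode == "analytic":
        samples = scene_fourier(phantom, traj.k, amps)
    elif mode == "raster":
        samples = _raster_fourier(phantom, traj, amps)
    else:
        raise ValueError(f"unknown simulation mode {mode!r}")

    samples = samples * gain
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = noise_sd / np.sqrt(protocol.n_averages)
        samples = samples + rng.normal(scale=s, size=samples.shape) \
            + 1j * rng.normal(scale=s, size=samples.shape)

    return KSpaceData(samples=samples, protocol=protocol, noise_sd=noise_sd,
                      provenance={"mode": mode, "relaxation": relaxation,
                                  "gain": gain,
                                  "seed": repr(seed),
                                  "delay_applied_us": traj.delay_applied_us})


def _raster_fourier(phantom: DigitalPhantom, traj: ConesTrajectory, amps) -> np.ndarray:
    """NUFFT of the rasterised pv maps, exact in the tissue dimension.

    The per-tissue static k-space is computed once; the per-sample relaxation
    amplitude then weights each tissue's contribution, so no time
    segmentation is needed.
    """
    from .gridding import GridSpec, forward_nufft

    if not phantom.pv_maps:
        raise ValueError("phantom has no pv maps; build with rasterize=True")
    spec = GridSpec(n=phantom.grid_size,
                    fov_m=phantom.grid_size * phantom.voxel_mm * 1e-3,
                    oversampling=2.0)
    voxel_vol = (phantom.voxel_mm * 1e-3) ** 3
    out = np.zeros(traj.k.shape[:2], dtype=complex)
    for name, pv in phantom.pv_maps.items():
        ft = forward_nufft(pv.astype(complex), traj.k_flat, spec).reshape(out.shape)
        out += np.asarray(amps[name]) * ft * voxel_vol
    return out


# ---------------------------------------------------------------------- cohort

@dataclass(frozen=True)
class SiteSpec:
    """Per-site acquisition character: noise, calibration gain, delay."""

    name: str
    noise_sd: float
    cal_gain: float = 1.0
    delay_us: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cal_gain <= 0:
            raise ValueError("cal_gain must be positive")


#: Per-sample complex noise SD per site, in the (m^3 * mM) units of the
#: analytic scene FT, stated for the full printed protocol (3.6M samples).
#: Set to the largest level at which automatic tube detection stays reliable
#: (20 mM tube SNR ~8); site B is twice site A, matching the study's
#: worse site-B repeatability.  See docs/methods.md for the calibration.
DEFAULT_SITE_NOISE = {"A": 3.5e-3, "B": 7.0e-3}


@dataclass
class CohortSpec:
    """Structure of the two-site scan-rescan cohort.

    Defaults mirror the 11-subject study: all subjects scanned twice at
    site A; at site B seven twice and four once.  Per-tissue means/SDs are
    the segmentation-analysis grand values (WM 41.8 +/- 6.7, GM 52.1 +/- 7.1,
    CSF 85.8 +/- 14.3 mM).
    """

    n_subjects: int = 11
    sites: list[SiteSpec] = field(default_factory=lambda: [
        SiteSpec("A", DEFAULT_SITE_NOISE["A"], cal_gain=1.0, delay_us=5.0),
        SiteSpec("B", DEFAULT_SITE_NOISE["B"], cal_gain=1.05, delay_us=5.0),
    ])
    scans_per_site: dict[str, list[int]] | None = None
    tsc_mean_mM: dict[str, float] = field(default_factory=lambda: {
        "wm": 41.8, "gm": 52.1, "csf": 85.8})
    tsc_sd_mM: dict[str, float] = field(default_factory=lambda: {
        "wm": 6.7, "gm": 7.1, "csf": 14.3})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if any(sd < 0 for sd in self.tsc_sd_mM.values()):
            raise ValueError("tsc_sd_mM values must be non-negative")
        if self.scans_per_site is None:
            per_b = [2] * min(7, self.n_subjects) + [1] * max(0, self.n_subjects - 7)
            self.scans_per_site = {"A": [2] * self.n_subjects,
                                   "B": per_b[: self.n_subjects]}
        for site, counts in self.scans_per_site.items():
            if len(counts) != self.n_subjects:
                raise ValueError(f"scans_per_site[{site!r}] must list one count "
                                 f"per subject")
            if any(c not in (1, 2) for c in counts):
                raise ValueError("scans per subject and site must be 1 or 2")


def _subject_seed(spec_seed: int, subject: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=spec_seed, spawn_key=(1, subject))


def _scan_seed(spec_seed: int, subject: int, site_idx: int, scan: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=spec_seed, spawn_key=(2, subject, site_idx, scan))


def cohort_truths(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject true TSC draws (truncated normal at 0, site-invariant).

    Seeded per subject via a documented spawn-key scheme, so enlarging the
    cohort never perturbs existing subjects.
    """
    rows = []
    for subj in range(spec.n_subjects):
        rng = np.random.default_rng(_subject_seed(spec.seed, subj))
        for tissue, mean in spec.tsc_mean_mM.items():
            sd = spec.tsc_sd_mM[tissue]
            if sd == 0:
                val = mean
            else:
                val = truncnorm.rvs(-mean / sd, np.inf, loc=mean, scale=sd,
                                    random_state=rng)
            rows.append({"subject": subj, "tissue": tissue,
                         "true_tsc_mM": float(val), "seed": spec.seed})
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, protocol: AcquisitionProtocol,
                    traj: ConesTrajectory, *, mode: str = "analytic",
                    relaxation: bool = True,
                    phantom_kwargs: dict | None = None,
                    ) -> tuple[Iterator[tuple[dict, KSpaceData, DigitalPhantom]], pd.DataFrame]:
    """Lazy generator of every scan in the cohort plus the ground-truth ledger.

    Yields ``(scan_info, kdata, phantom)`` per scan; subjects share one
    phantom geometry whose per-tissue concentrations are their drawn truths.
    Scans at a site differ only in the noise realisation; sites differ in
    noise SD, calibration gain and gradient delay.
    """
    truths = cohort_truths(spec)
    phantom_kwargs = phantom_kwargs or {}

    def scans():
        base = build_head_phantom(**phantom_kwargs)
        site_trajs = {}
        for si, site in enumerate(spec.sites):
            site_trajs[site.name] = apply_delay_correction(traj, site.delay_us) \
                if site.delay_us else traj
        for subj in range(spec.n_subjects):
            tr = truths[truths.subject == subj].set_index("tissue").true_tsc_mM
            tissues = dict(base.tissues)
            for tname in spec.tsc_mean_mM:
                tissues[tname] = TissueProperties(
                    tname, float(tr[tname]), tissues[tname].t1_ms,
                    tissues[tname].t2s_short_ms, tissues[tname].t2s_long_ms,
                    tissues[tname].frac_short)
            ph = base.with_tissues(tissues)
            for si, site in enumerate(spec.sites):
                for scan in range(spec.scans_per_site[site.name][subj]):
                    seed = _scan_seed(spec.seed, subj, si, scan)
                    kdata = simulate_kspace(ph, site_trajs[site.name], protocol,
                                            noise_sd=site.noise_sd, seed=seed,
                                            mode=mode, relaxation=relaxation,
                                            gain=site.cal_gain)
                    kdata.provenance.update({"subject": subj, "site": site.name,
                                             "scan": scan + 1})
                    info = {"subject": subj, "site": site.name, "scan": scan + 1,
                            "site_spec": site}
                    yield info, kdata, ph
    return scans(), truths
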