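"""3D-cones UTE k-space trajectory design and density compensation.

Each readout starts at the k-space centre (UTE) and spirals outward on the
surface of a cone; a set of cone polar angles covers the full sphere so the
sampled ball reaches ``kmax = 1/(2 * voxel)``.  The design is self-contained:
cone angles come from an equal-solid-angle partition of the sphere, and the
spiral twist on each cone is integrated numerically, winding as fast as the
gradient amplitude and slew-rate limits permit at each radius.  Fidelity is
asserted by constraint and coverage audits rather than by comparison with any
particular scanner waveform.

Gradient timing errors (eddy-current hysteresis) are compensated at
reconstruction by filtering the ideal coordinates with a causal exponential
kernel and evaluating them at times shifted by a fixed delay (5 us in the
two-site brain protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.spatial import Voronoi, ConvexHull

from .protocol import AcquisitionProtocol

__all__ = [
    "ConesTrajectory",
    "design_cones",
    "apply_delay_correction",
    "compute_density_weights",
    "audit_trajectory",
    "InfeasibleProtocolError",
]

# Safety fractions of the hardware limits used by the twist integrator.  The
# audit checks the *full* limits with finite differences, so these leave
# headroom for discretisation error.
_AMP_SAFETY = 0.95
_SLEW_SAFETY = 0.55
_RADIAL_SLEW_FRACTION = 0.3  # share of the slew budget reserved for the ramp
_MAX_TWIST_PER_DWELL_RAD = 0.5


class InfeasibleProtocolError(ValueError):
    """Raised when a protocol cannot reach kmax within its limits."""


@dataclass
class ConesTrajectory:
    """Sampled 3D-cones trajectory.

    Attributes
    ----------
    k : (n_readouts, n_samples, 3) float array
        k-space coordinates in cycles/m.  These are the *reconstruction*
        coordinates: after :func:`apply_delay_correction` they include the
        hysteresis/delay model.
    t : (n_samples,) float array
        Time since excitation of each sample, ms (shared by all readouts).
    w : (n_readouts, n_samples) float array or None
        Density-compensation weights (k-space volume per sample, in
        (cycles/m)^3), or None until computed.
    cone_angle : (n_readouts,) float array
        Polar angle of each readout's cone, rad.
    protocol : AcquisitionProtocol
    k_ideal : array
        The as-designed coordinates, kept so that delay corrections compose
        exactly (each correction re-derives from the ideal waveform).
    delay_applied_us, hysteresis_tau_us : float
        Delay model currently baked into ``k``.
    """

    k: np.ndarray
    t: np.ndarray
    cone_angle: np.ndarray
    protocol: AcquisitionProtocol
    w: np.ndarray | None = None
    k_ideal: np.ndarray | None = None
    delay_applied_us: float = 0.0
    hysteresis_tau_us: float = 0.0

    @property
    def n_readouts(self) -> int:
        return self.k.shape[0]

    @property
    def n_samples(self) -> int:
        return self.k.shape[1]

    @property
    def k_flat(self) -> np.ndarray:
        return self.k.reshape(-1, 3)

    def validate(self) -> None:
        if self.k.ndim != 3 or self.k.shape[2] != 3:
            raise ValueError("k must have shape (n_readouts, n_samples, 3)")
        if self.t.shape != (self.k.shape[1],):
            raise ValueError("t must have one entry per sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.w is not None and self.w.shape != self.k.shape[:2]:
            raise ValueError("w shape must match (n_readouts, n_samples)")


# --------------------------------------------------------------------- design

def _radial_profile(protocol: AcquisitionProtocol, t_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radius r(t) and its rate for a slew-ramp-then-constant-speed profile.

    The radial speed is tiny compared to the gradient budget (reaching kmax in
    a 10 ms readout needs ~1 mT/m), so nearly the whole budget is left for the
    azimuthal twist.  Returns (r, rdot) in cycles/m and cycles/m/s, with
    r exactly kmax at the final sample time.
    """
    gamma = protocol.gamma_Hz_per_T
    kmax = protocol.kmax_cycles_per_m
    T = t_s[-1]
    a_r = _RADIAL_SLEW_FRACTION * gamma * protocol.smax_T_per_m_per_s  # cycles/m/s^2
    v_amp = _AMP_SAFETY * gamma * protocol.gmax_mT_per_m * 1e-3

    # constant speed v with initial ramp a_r: kmax = v*T - v^2/(2 a_r)
    disc = T * T - 2.0 * kmax / a_r
    if disc <= 0:
        raise InfeasibleProtocolError(
            f"slew rate {protocol.smax_T_per_m_per_s} T/m/s cannot ramp to reach "
            f"kmax={kmax:.1f} cycles/m within the {T * 1e3:.3g} ms readout")
    v = a_r * (T - np.sqrt(disc))
    if v > v_amp:
        raise InfeasibleProtocolError(
            f"gradient amplitude limit {protocol.gmax_mT_per_m} mT/m is the binding "
            f"constraint: kmax={kmax:.1f} cycles/m unreachable in {T * 1e3:.3g} ms")
    t_ramp = v / a_r
    r = np.where(t_s < t_ramp,
                 0.5 * a_r * t_s ** 2,
                 0.5 * a_r * t_ramp ** 2 + v * (t_s - t_ramp))
    rdot = np.where(t_s < t_ramp, a_r * t_s, v)
    r = np.minimum(r, kmax)
    return r, rdot


def _cone_partition(protocol: AcquisitionProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Equal-solid-angle cone angles and per-cone readout counts.

    The number of cones is set by the Nyquist ring spacing at kmax
    (pi * kmax * FOV over the full polar range); readouts are split across
    cones as evenly as possible, summing exactly to ``n_readouts``.
    """
    fov_m = protocol.fov_mm * 1e-3
    n_cones = max(2, int(round(np.pi * protocol.kmax_cycles_per_m * fov_m)))
    n_cones = min(n_cones, protocol.n_readouts)
    # equal-solid-angle centres over the full sphere: cos(theta) uniform
    i = np.arange(1, n_cones + 1)
    cos_c = 1.0 - (2.0 * i - 1.0) / n_cones
    theta = np.arccos(np.clip(cos_c, -1.0, 1.0))
    counts = np.full(n_cones, protocol.n_readouts // n_cones, dtype=int)
    counts[: protocol.n_readouts % n_cones] += 1
    return theta, counts


def design_cones(protocol: AcquisitionProtocol, substeps: int = 4) -> ConesTrajectory:
    """Design the 3D-cones trajectory for a protocol.

    Integrates, per cone, a centre-out spiral whose azimuthal rate is the
    maximum permitted by the amplitude and slew limits at each radius
    (with safety margins for discretisation); rotated copies of the cone's
    spiral provide the cone's readouts.

    Raises
    ------
    InfeasibleProtocolError
        If kmax cannot be reached within the readout under the limits; the
        message names the binding constraint.
    """
    n_samp = protocol.samples_per_readout
    dt_s = protocol.dwell_ms * 1e-3
    dt_sub = dt_s / substeps
    t_sub = np.arange((n_samp - 1) * substeps + 1) * dt_sub
    t_ms = protocol.te_ms + np.arange(n_samp) * protocol.dwell_ms

    r_sub, rdot_sub = _radial_profile(protocol, t_sub)
    theta_c, counts = _cone_partition(protocol)

    gamma = protocol.gamma_Hz_per_T
    g_amp = _AMP_SAFETY * gamma * protocol.gmax_mT_per_m * 1e-3     # cycles/m/s
    s_lim = _SLEW_SAFETY * gamma * protocol.smax_T_per_m_per_s      # cycles/m/s^2
    phidot_cap = _MAX_TWIST_PER_DWELL_RAD / dt_s

    # golden-angle offset between cones decorrelates the spiral start angles
    golden = np.pi * (3.0 - np.sqrt(5.0))

    k = np.empty((protocol.n_readouts, n_samp, 3))
    cone_angle = np.empty(protocol.n_readouts)
    row = 0
    for ci, (theta, m) in enumerate(zip(theta_c, counts)):
        s_t = np.sin(theta)
        rho = r_sub * s_t
        rho_dot = rdot_sub * s_t
        with np.errstate(divide="ignore", invalid="ignore"):
            phidot_amp = np.sqrt(np.maximum(g_amp ** 2 - rdot_sub ** 2, 0.0)) / rho
            phidot_slew = np.sqrt(s_lim / rho)
        phidot = np.minimum(np.minimum(phidot_amp, phidot_slew), phidot_cap)
        phidot[rho <= 0] = phidot_cap
        psi = np.concatenate([[0.0], np.cumsum(0.5 * (phidot[1:] + phidot[:-1]) * dt_sub)])
        # sample every `substeps`-th point
        sel = slice(None, None, substeps)
        rho_s, psi_s, z_s = rho[sel], psi[sel], (r_sub * np.cos(theta))[sel]
        for j in range(m):
            phi0 = 2.0 * np.pi * j / m + golden * ci
            ang = psi_s + phi0
            k[row, :, 0] = rho_s * np.cos(ang)
            k[row, :, 1] = rho_s * np.sin(ang)
            k[row, :, 2] = z_s
            cone_angle[row] = theta
            row += 1
        del rho_dot  # radial tangential term is audited, not steered

    traj = ConesTrajectory(k=k, t=t_ms, cone_angle=cone_angle, protocol=protocol,
                           k_ideal=k.copy())
    traj.validate()
    return traj


# ------------------------------------------------------------ delay correction

def apply_delay_correction(traj: ConesTrajectory, delay_us: float,
                           hysteresis_tau_us: float | None = None) -> ConesTrajectory:
    """Apply the gradient-delay (hysteresis) correction to a trajectory.

    The ideal coordinates of each readout are filtered with the causal kernel
    ``(1/tau) * exp(-t/tau)`` (discrete one-pole equivalent) and evaluated at
    sample times shifted by ``delay_us``.  ``tau = 0`` (or None with a
    zero-bandwidth default) degenerates to a pure time shift.

    The correction always re-derives from the stored ideal waveform, with the
    delay accumulated across calls; correcting with delay ``a`` then ``b`` is
    therefore exactly the same as correcting once with ``a + b``.
    """
    if delay_us < 0:
        raise ValueError("delay_us must be non-negative")
    if hysteresis_tau_us is None:
        hysteresis_tau_us = traj.hysteresis_tau_us or traj.protocol.dwell_ms * 1e3
    if hysteresis_tau_us < 0:
        raise ValueError("hysteresis_tau_us must be non-negative")

    base = traj.k_ideal if traj.k_ideal is not None else traj.k
    total_us = traj.delay_applied_us + delay_us
    dt_us = (traj.t[1] - traj.t[0]) * 1e3

    if hysteresis_tau_us > 0:
        a = np.exp(-dt_us / hysteresis_tau_us)
        filt = np.empty_like(base)
        # one-pole IIR along the sample axis; k=0 initial state (gradients off)
        filt[:, 0, :] = (1.0 - a) * base[:, 0, :]
        for s in range(1, base.shape[1]):
            filt[:, s, :] = a * filt[:, s - 1, :] + (1.0 - a) * base[:, s, :]
    else:
        filt = base

    # evaluate at t - delay; before the first sample the gradients were off
    t_us = traj.t * 1e3
    t_query = t_us - total_us
    out = np.empty_like(base)
    for ax in range(3):
        out[..., ax] = np.apply_along_axis(
            lambda y: np.interp(t_query, t_us, y, left=0.0), 1, filt[..., ax])
    new = replace(traj, k=out, k_ideal=base,
                  delay_applied_us=total_us, hysteresis_tau_us=hysteresis_tau_us)
    return new


# -------------------------------------------------------- density compensation

def _voronoi_weights(points: np.ndarray, kmax: float) -> np.ndarray:
    """Voronoi cell volumes for unique sample points, clipped to the kmax ball.

    Clipping uses mirror points: every point in the outer shell is reflected
    about the kmax sphere, which places the shared Voronoi facet on (a chord
    approximation of) the sphere.  A sparse guard shell bounds any remaining
    open cells.
    """
    ndim = points.shape[1]
    n = len(points)
    if n < ndim + 1:
        raise ValueError(f"Voronoi weights need at least {ndim + 1} unique points, got {n}")
    radii = np.linalg.norm(points, axis=1)
    shell = radii > 0.85 * kmax
    mirrors = []
    if np.any(shell):
        p = points[shell]
        r = radii[shell]
        mirrors.append(p * ((2.0 * kmax - r) / r)[:, None])
    # sparse guard shell well outside the ball
    n_guard = 128 if ndim == 3 else 64
    i = np.arange(n_guard)
    if ndim == 3:
        z = 1.0 - 2.0 * (i + 0.5) / n_guard
        az = np.pi * (3.0 - np.sqrt(5.0)) * i
        s = np.sqrt(1.0 - z ** 2)
        guard = 1.6 * kmax * np.stack([s * np.cos(az), s * np.sin(az), z], axis=1)
    else:
        az = 2.0 * np.pi * i / n_guard
        guard = 1.6 * kmax * np.stack([np.cos(az), np.sin(az)], axis=1)
    aug = np.vstack([points] + mirrors + [guard])

    vor = Voronoi(aug)
    vols = np.empty(n)
    fallback = []
    for idx in range(n):
        region = vor.regions[vor.point_region[idx]]
        if -1 in region or len(region) < ndim + 1:
            fallback.append(idx)
            vols[idx] = np.nan
            continue
        verts = vor.vertices[region]
        try:
            vols[idx] = ConvexHull(verts).volume
        except Exception:
            fallback.append(idx)
            vols[idx] = np.nan
    if fallback:
        warnings.warn(f"{len(fallback)} Voronoi cells unbounded/degenerate; "
                      "assigned the median cell volume")
        vols[np.isnan(vols)] = np.nanmedian(vols)
    return vols


def _lattice_density_response(spec) -> float:
    """Kernel-autocorrelation response to a unit-weight Nyquist lattice.

    Self-calibration constant for the iterative weights: a uniform lattice
    with one sample per oversampled grid cell has, by definition, a cell
    volume of ``delta_k^3`` per sample; its grid/degrid density response at
    the lattice centre converts converged relative densities into absolute
    k-space volumes.
    """
    from .gridding import grid_samples, degrid_samples

    m = 9  # patch comfortably wider than the kernel support
    c = np.arange(m) - m // 2
    pts_u = np.stack(np.meshgrid(c, c, c, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts_u * spec.delta_k  # integer grid coords, centred on k = 0
    ones = np.ones(len(pts), dtype=complex)
    dens = degrid_samples(grid_samples(pts, ones, spec), pts, spec).real
    centre = np.all(pts_u == 0, axis=1)
    return float(dens[centre][0])


def _pipe_menon_weights(traj: ConesTrajectory, n_iter: int = 12) -> np.ndarray:
    """Iterative sampling-density weights (fixed point of w / (C * w)).

    C is the gridding-kernel autocorrelation: each iteration grids the
    current weights onto the oversampled Cartesian grid and reads them back
    at the sample positions.  Converged weights are converted to absolute
    k-space cell volumes by matching the interior density response to that
    of a unit-weight Nyquist lattice (samples at the edge of the sampled
    ball keep boundary-inflated weights; the reconstruction's apodization
    window suppresses them).
    """
    from .gridding import GridSpec, grid_samples, degrid_samples

    p = traj.protocol
    spec = GridSpec.for_protocol(p)
    pts = traj.k_flat
    w = np.ones(len(pts))
    for _ in range(n_iter):
        dens = degrid_samples(grid_samples(pts, w.astype(complex), spec), pts, spec).real
        w = w / np.maximum(dens, 1e-12 * dens.max())
    dens = degrid_samples(grid_samples(pts, w.astype(complex), spec), pts, spec).real
    interior = np.linalg.norm(pts, axis=1) < 0.75 * p.kmax_cycles_per_m
    c_star = float(np.median(dens[interior])) if interior.any() else float(np.median(dens))
    w *= spec.delta_k ** 3 * _lattice_density_response(spec) / c_star

    # Half-space boundary correction.  Samples within a kernel width of the
    # kmax sphere see a partially empty neighbourhood, so the fixed point
    # inflates their weights by ~1/m(d), m(d) being the fraction of the
    # kernel-autocorrelation mass within distance d of the boundary.
    # Multiplying back by m(d) restores (to first order) true cell volumes,
    # which would otherwise ring through unwindowed reconstructions.
    radii = np.linalg.norm(pts, axis=1)
    d_grid = (p.kmax_cycles_per_m - radii) / spec.delta_k
    w *= _halfspace_mass_fraction(spec, d_grid)

    # Radial-measure projection: centre-out sampling covers every k shell by
    # construction, so each shell's weights must integrate to the shell's
    # exact volume.  The kernel fixed point leaves percent-level radial
    # ripple (worst at the heavily duplicated centre); rescaling shell
    # totals — preserving relative weights within a shell — removes it.
    kmax = p.kmax_cycles_per_m
    # shell width follows the radial sampling density so sparse toy
    # trajectories do not leave unassigned (empty) shells
    n_shell = int(min(64, max(8, traj.n_samples // 4)))
    edges = np.linspace(0.0, kmax, n_shell + 1)
    idx = np.clip(np.searchsorted(edges, radii, side="right") - 1, 0, n_shell - 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    shell_sum = np.bincount(idx, weights=w, minlength=n_shell)
    scale = np.where(shell_sum > 0, shell_vol / np.maximum(shell_sum, 1e-300), 1.0)
    w *= scale[idx]
    return w.reshape(traj.k.shape[:2])


def _halfspace_mass_fraction(spec, d_grid_units: np.ndarray) -> np.ndarray:
    """CDF of the 1D gridding-kernel autocorrelation, evaluated at d.

    m(d) = mass of the autocorrelation within (-inf, d]; m(0) = 0.5 at a
    flat boundary, 1 beyond one kernel width inside.
    """
    table = spec.kernel_table()
    w_k = spec.kernel_width
    u = np.linspace(0.0, w_k / 2.0, len(table))
    phi = np.concatenate([table[::-1], table[1:]])          # symmetric kernel
    acorr = np.convolve(phi, phi)                            # support [-W, W]
    cdf = np.cumsum(acorr)
    cdf /= cdf[-1]
    t = np.linspace(-w_k, w_k, len(cdf))
    return np.interp(np.clip(d_grid_units, -w_k, w_k), t, cdf)


def compute_density_weights(traj: ConesTrajectory,
                            method: Literal["voronoi", "iterative"] = "iterative",
                            n_iter: int = 12) -> ConesTrajectory:
    """Populate per-sample density-compensation weights.

    ``voronoi`` computes exact Voronoi cell volumes (clipped to the kmax
    ball); duplicate sample positions (every UTE readout starts at k = 0)
    share their cell's volume equally.  ``iterative`` uses the
    kernel-convolution fixed-point method and scales well to full-size
    trajectories.
    """
    kmax = traj.protocol.kmax_cycles_per_m
    if method == "iterative":
        w = _pipe_menon_weights(traj, n_iter=n_iter)
        return replace(traj, w=w)
    if method != "voronoi":
        raise ValueError(f"unknown density-compensation method {method!r}")

    pts3 = traj.k_flat
    # drop a degenerate axis (planar toy trajectories) for the tessellation
    spans = np.ptp(pts3, axis=0)
    keep = spans > 1e-12 * max(spans.max(), 1.0)
    pts = pts3[:, keep] if keep.sum() in (2,) else pts3

    scale = max(kmax, 1e-12)
    key = np.round(pts / scale, 9)
    uniq, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        warnings.warn(f"{int((counts > 1).sum())} duplicated sample positions; "
                      "their Voronoi cell volume is shared equally")
    if len(uniq) < 4:
        raise ValueError("fewer than 4 unique sample points; Voronoi weights undefined")
    first = np.full(len(uniq), -1, dtype=int)
    seen = np.zeros(len(uniq), dtype=bool)
    for i, g in enumerate(inverse):
        if not seen[g]:
            first[g] = i
            seen[g] = True
    vols = _voronoi_weights(pts[first], kmax)
    w = (vols / counts)[inverse]
    return replace(traj, w=w.reshape(traj.k.shape[:2]))


# ---------------------------------------------------------------------- audit

def audit_trajectory(traj: ConesTrajectory, n_shells: int = 15) -> dict:
    """Independent finite-difference audit of hardware and coverage limits.

    Gradients are estimated as forward differences of k, slew as second
    differences; both are checked sample-by-sample against the protocol
    limits.  Radial coverage is checked with a ``kmax / n_shells`` histogram.
    """
    p = traj.protocol
    gamma = p.gamma_Hz_per_T
    dt = (traj.t[1] - traj.t[0]) * 1e-3
    g = np.diff(traj.k, axis=1) / (gamma * dt)          # T/m
    slew = np.diff(g, axis=1) / dt                       # T/m/s
    gmag = np.linalg.norm(g, axis=2)
    smag = np.linalg.norm(slew, axis=2)
    kmag = np.linalg.norm(traj.k, axis=2)
    hist, _ = np.histogram(kmag.ravel(), bins=n_shells,
                           range=(0.0, p.kmax_cycles_per_m))
    return {
        "n_readouts": traj.n_readouts,
        "n_samples": traj.n_samples,
        "frac_amp_ok": float(np.mean(gmag <= p.gmax_mT_per_m * 1e-3)),
        "frac_slew_ok": float(np.mean(smag <= p.smax_T_per_m_per_s)),
        "max_grad_mT_per_m": float(gmag.max() * 1e3),
        "max_slew_T_per_m_per_s": float(smag.max()),
        "max_k_cycles_per_m": float(kmag.max()),
        "kmax_cycles_per_m": p.kmax_cycles_per_m,
        "starts_at_center": bool(np.all(kmag[:, 0] < 1e-9)),
        "empty_shells": int(np.sum(hist == 0)),
        "coverage_ok": bool(np.all(hist > 0)),
    }
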