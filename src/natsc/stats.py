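"""Tissue masks, observer ROIs and test-retest statistics.

The statistics layer mirrors a two-site scan-rescan study design:

* repeatability — within-site agreement of scans 1 and 2, summarised by the
  RMS within-subject SD ``wsd = |x1 - x2|/sqrt(2)`` pooled over subjects,
  the within-subject CoV ``100 * wsd_pooled / grand_mean`` and the
  repeatability coefficient ``RC = 1.96 * sqrt(2) * wsd_pooled``;
* reproducibility — the same estimator applied to cross-site first-scan
  pairs;
* Bland-Altman limits of agreement, ``mean(d) +/- 1.96 * SD(d)`` with the
  sample (n-1) SD;
* interobserver agreement via ICC(2,1) — two-way random effects, absolute
  agreement, single rater — with F-distribution confidence intervals.

Manual ROI analysis is emulated by seeded spherical ROIs at deep-grey and
white-matter analog positions ("caudate", "putamen", "centrum semiovale"),
placed bilaterally and centre-jittered to represent an observer's hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import DigitalPhantom

__all__ = [
    "tissue_masks", "place_observer_rois", "region_means",
    "repeatability_stats", "reproducibility_stats", "bland_altman", "icc",
    "build_report", "RepeatabilityReport",
]


# ----------------------------------------------------------------------- masks

def tissue_masks(pv_maps: dict[str, np.ndarray], threshold: float = 0.95,
                 tissues: tuple[str, ...] = ("wm", "gm", "csf")) -> dict[str, np.ndarray]:
    """Per-tissue masks of voxels with partial-volume fraction > threshold.

    The inequality is strict; an empty mask triggers a warning, never a
    silent drop.
    """
    masks = {}
    for t in tissues:
        pv = np.asarray(pv_maps[t])
        if pv.min() < 0 or pv.max() > 1 + 1e-9:
            raise ValueError(f"pv map {t!r} not in [0, 1]")
        m = pv > threshold
        if not m.any():
            warnings.warn(f"tissue mask {t!r} is empty at threshold {threshold}")
        masks[t] = m
    return masks


#: ROI definitions: (region, tissue it must stay inside, unit direction in the
#: mid-compartment ellipsoid parametrisation).  Deep-grey analogs sit in the
#: GM shell, the centrum semiovale analog in the WM core; all bilateral.
_ROI_DIRECTIONS = {
    "caudate": ("gm", (0.64, 0.77, 0.0)),
    "putamen": ("gm", (0.94, 0.26, 0.22)),
    "centrum_semiovale": ("wm", (0.3, 0.45, 0.85)),
}


def place_observer_rois(phantom: DigitalPhantom, observer_jitter_mm: float = 2.0,
                        seed: int | np.random.SeedSequence = 0,
                        radius_mm: float = 6.0) -> dict[str, np.ndarray]:
    """Seeded spherical ROI masks emulating one observer's hand-drawn ROIs.

    Nominal centres lie mid-thickness of the host compartment along fixed
    bilateral directions; each centre is jittered by an isotropic Gaussian
    of SD ``observer_jitter_mm``.  Two different seeds emulate two
    observers.  An ROI reaching outside its host tissue is shrunk (with a
    warning) until it fits, never silently clipped.
    """
    rng = np.random.default_rng(seed)
    solids = {tis: prim for prim, tis, _ in phantom.solids}
    wm = solids["wm"]
    gm = solids["gm"]
    vent = solids.get("csf_vent")
    mid = {
        "gm": tuple((np.array(wm.semi_axes_m) + np.array(gm.semi_axes_m)) / 2.0),
        "wm": tuple((np.array(vent.semi_axes_m) + np.array(wm.semi_axes_m)) / 2.0)
        if vent is not None else tuple(np.array(wm.semi_axes_m) * 0.7),
    }
    n = phantom.grid_size
    c = (np.arange(n) - n // 2) * phantom.voxel_mm * 1e-3
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")

    rois: dict[str, np.ndarray] = {}
    for region, (tissue, direction) in _ROI_DIRECTIONS.items():
        u = np.asarray(direction) / np.linalg.norm(direction)
        pv_host = phantom.pv_maps[tissue]
        mask = np.zeros((n, n, n), dtype=bool)
        for sgn in (-1.0, 1.0):
            centre = sgn * u * np.asarray(mid[tissue])
            centre = centre + rng.normal(scale=observer_jitter_mm * 1e-3, size=3)
            r = radius_mm * 1e-3
            while r >= phantom.voxel_mm * 1e-3:
                sph = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2 <= r ** 2
                if sph.any() and pv_host[sph].min() > 0.5:
                    break
                r *= 0.8
            else:
                warnings.warn(f"ROI {region} ({'left' if sgn < 0 else 'right'}) "
                              "could not fit inside its tissue; using minimum radius")
                sph = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2 \
                    <= (phantom.voxel_mm * 1e-3) ** 2
            if r < radius_mm * 1e-3:
                warnings.warn(f"ROI {region} shrunk to {r * 1e3:.1f} mm to stay "
                              f"inside {tissue}")
            mask |= sph
        rois[region] = mask
    return rois


def region_means(tsc, masks: dict[str, np.ndarray], *, subject=None, site=None,
                 scan=None, observer: str = "auto") -> pd.DataFrame:
    """Arithmetic mean TSC over each mask, one tidy row per region."""
    values = getattr(tsc, "values", tsc)
    rows = []
    for region, mask in masks.items():
        mask = np.asarray(mask, bool)
        n_vox = int(mask.sum())
        row = {"subject": subject, "site": site, "scan": scan,
               "region": region, "observer": observer,
               "mean_tsc_mM": float(values[mask].mean()) if n_vox else np.nan,
               "n_voxels": n_vox, "flag_empty": n_vox == 0}
        if n_vox == 0:
            warnings.warn(f"empty mask for region {region!r}; row flagged")
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ estimators

def _paired(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of complete pairs")
    if arr.shape[0] < 1:
        raise ValueError("at least one complete pair required")
    return arr


def repeatability_stats(pairs) -> dict[str, float]:
    """Scan-rescan summary for one region at one site.

    ``wsd`` is the RMS within-subject SD, ``cov_pct`` the within-subject CoV
    in percent of the grand mean, and ``rc_mM = 1.96 * sqrt(2) * wsd`` the
    repeatability coefficient (the 95% bound on a scan-rescan difference).
    """
    arr = _paired(pairs)
    if arr.shape[0] < 2:
        raise ValueError("repeatability needs at least 2 complete pairs")
    wsd_i = np.abs(arr[:, 0] - arr[:, 1]) / np.sqrt(2.0)
    wsd = float(np.sqrt(np.mean(wsd_i ** 2)))
    grand = float(arr.mean())
    return {"wsd_mM": wsd,
            "cov_pct": 100.0 * wsd / grand if grand != 0 else np.inf,
            "rc_mM": 1.96 * np.sqrt(2.0) * wsd,
            "n_pairs": int(arr.shape[0])}


def reproducibility_stats(pairs) -> dict[str, float]:
    """Intersite summary: the repeatability estimator on cross-site
    first-scan pairs (site A scan 1 vs site B scan 1)."""
    return repeatability_stats(pairs)


def bland_altman(pairs) -> dict[str, float]:
    """Mean difference and 95% limits of agreement (sample SD, n-1)."""
    arr = _paired(pairs)
    if arr.shape[0] < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = arr[:, 1] - arr[:, 0]
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"mean_diff_mM": mean_diff,
            "loa_low_mM": mean_diff - 1.96 * sd,
            "loa_high_mM": mean_diff + 1.96 * sd,
            "n_pairs": int(arr.shape[0])}


def icc(ratings, alpha: float = 0.05) -> dict[str, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete (n_subjects, k_raters) matrix.  The 95% CI
    follows the F-distribution method (Satterthwaite degrees of freedom for
    the lower-variance composite).  Zero total variance is flagged with a
    NaN sentinel rather than raising.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (n_subjects, k>=2 raters)")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete")

    grand = x.mean()
    if np.allclose(x, grand):
        return {"icc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "undefined": True}

    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    point = (msr - mse) / denom if denom != 0 else np.nan

    # F-based CI, absolute-agreement single-rater form with Satterthwaite
    # degrees of freedom for the rater/error composite
    if mse > 0 and point < 1:
        a = (k * point) / (n * (1.0 - point))
        b = 1.0 + (k * point * (n - 1)) / (n * (1.0 - point))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        ci_high = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr)
        ci_low = float(np.clip(ci_low, -1.0, 1.0))
        ci_high = float(np.clip(ci_high, -1.0, 1.0))
    else:
        ci_low, ci_high = np.nan, np.nan
    return {"icc": float(np.clip(point, -1.0, 1.0)),
            "ci_low": float(ci_low), "ci_high": float(ci_high),
            "undefined": False}


# ---------------------------------------------------------------------- report

@dataclass
class RepeatabilityReport:
    """All study-level statistics plus the tidy tables they derive from."""

    per_scan_means: pd.DataFrame       # region x site x scan mean +/- SD
    grand_means: pd.DataFrame          # region-level mean +/- SD over all scans
    repeatability: pd.DataFrame        # per region x site: cov/wsd/rc
    reproducibility: pd.DataFrame      # per region: cross-site cov
    bland_altman_repeat: pd.DataFrame  # per site (pooled over regions)
    bland_altman_repro: dict[str, float]
    icc_interobserver: pd.DataFrame    # per region x site, scan 1
    measurements: pd.DataFrame = field(repr=False, default=None)

    def to_json_dict(self) -> dict[str, Any]:
        def df(d):
            return d.to_dict(orient="records") if d is not None else None
        return {
            "per_scan_means": df(self.per_scan_means),
            "grand_means": df(self.grand_means),
            "repeatability": df(self.repeatability),
            "reproducibility": df(self.reproducibility),
            "bland_altman_repeat": df(self.bland_altman_repeat),
            "bland_altman_repro": self.bland_altman_repro,
            "icc_interobserver": df(self.icc_interobserver),
        }


def _pivot_pairs(df: pd.DataFrame, col_a: str, col_b: str,
                 on: str) -> np.ndarray:
    """Complete (x_a, x_b) pairs per subject; incomplete subjects dropped."""
    piv = df.pivot_table(index="subject", columns=on, values="mean_tsc_mM",
                         aggfunc="first")
    if col_a not in piv.columns or col_b not in piv.columns:
        return np.empty((0, 2))
    piv = piv[[col_a, col_b]].dropna()
    return piv.to_numpy()


def build_report(measurements: pd.DataFrame) -> RepeatabilityReport:
    """Compute the full repeatability/reproducibility/interobserver report.

    ``measurements`` is the tidy table from :func:`region_means` over the
    whole cohort.  Segmentation rows (observer == "auto") drive the
    per-scan tables and the repeatability/reproducibility statistics;
    observer rows drive the ICC.  Subjects with a single scan at a site
    appear in per-scan means but never in paired statistics.
    """
    req = {"subject", "site", "scan", "region", "observer", "mean_tsc_mM"}
    if not req.issubset(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(req)}")
    seg = measurements[measurements.observer == "auto"]

    per_scan = (seg.groupby(["region", "site", "scan"])["mean_tsc_mM"]
                .agg(mean="mean", sd="std", n="count").reset_index())
    grand = (seg.groupby("region")["mean_tsc_mM"]
             .agg(mean="mean", sd="std", n="count").reset_index())

    rep_rows, ba_rep_rows = [], []
    for site in sorted(seg.site.unique()):
        s = seg[seg.site == site]
        pooled_pairs = []
        for region in sorted(s.region.unique()):
            pairs = _pivot_pairs(s[s.region == region], 1, 2, on="scan")
            if len(pairs) >= 2:
                st = repeatability_stats(pairs)
                rep_rows.append({"region": region, "site": site, **st})
                pooled_pairs.append(pairs)
        if pooled_pairs:
            allp = np.vstack(pooled_pairs)
            ba_rep_rows.append({"site": site, **bland_altman(allp)})
    repeat = pd.DataFrame(rep_rows)
    ba_repeat = pd.DataFrame(ba_rep_rows)

    repro_rows, repro_pairs_all = [], []
    scan1 = seg[seg.scan == 1]
    sites = sorted(seg.site.unique())
    if len(sites) >= 2:
        sa, sb = sites[0], sites[1]
        for region in sorted(scan1.region.unique()):
            pairs = _pivot_pairs(scan1[scan1.region == region], sa, sb, on="site")
            if len(pairs) >= 2:
                st = reproducibility_stats(pairs)
                repro_rows.append({"region": region, **st})
                repro_pairs_all.append(pairs)
    repro = pd.DataFrame(repro_rows)
    ba_repro = bland_altman(np.vstack(repro_pairs_all)) if repro_pairs_all else {}

    icc_rows = []
    obs = measurements[measurements.observer != "auto"]
    if not obs.empty:
        observers = sorted(obs.observer.unique())
        if len(observers) >= 2:
            o1, o2 = observers[:2]
            first = obs[obs.scan == 1]
            for (region, site), grp in first.groupby(["region", "site"]):
                piv = grp.pivot_table(index="subject", columns="observer",
                                      values="mean_tsc_mM", aggfunc="first")
                if {o1, o2}.issubset(piv.columns):
                    mat = piv[[o1, o2]].dropna().to_numpy()
                    if len(mat) >= 3:
                        icc_rows.append({"region": region, "site": site,
                                         **icc(mat)})
    icc_df = pd.DataFrame(icc_rows)

    return RepeatabilityReport(
        per_scan_means=per_scan, grand_means=grand, repeatability=repeat,
        reproducibility=repro, bland_altman_repeat=ba_repeat,
        bland_altman_repro=ba_repro, icc_interobserver=icc_df,
        measurements=measurements)
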