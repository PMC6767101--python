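"""Calibration-phantom detection and TSC map generation.

The two agar tubes (20 and 80 mM) in the field of view anchor a two-point
linear map from image intensity to concentration.  Tube voxels are outlined
automatically by intensity thresholding outside the head, eroded by one
voxel to shed the partial-volume rim, and labelled low/high by mean
intensity; the fitted line then converts the whole image to mM.  Because
the fit is re-derived from each image, any global intensity gain (coil
loading, scanner scaling) cancels exactly — the property that makes TSC
comparable across sites and vendors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

from .recon import ImageVolume

__all__ = ["Calibration", "TSCMap", "detect_calibration_tubes",
           "fit_calibration", "make_tsc_map", "TubeDetectionError"]


class TubeDetectionError(RuntimeError):
    """Automatic tube outlining failed; the message lists the candidates."""


@dataclass
class Calibration:
    """Two-point intensity-to-concentration calibration."""

    c_low_mM: float
    c_high_mM: float
    s_low: float
    s_high: float
    slope: float
    intercept: float
    tube_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def apply(self, intensity: np.ndarray) -> np.ndarray:
        return self.slope * intensity + self.intercept


@dataclass
class TSCMap:
    """Voxelwise total sodium concentration in mM."""

    values: np.ndarray
    affine: np.ndarray
    calibration: Calibration
    metadata: dict[str, Any] = field(default_factory=dict)


def detect_calibration_tubes(img: ImageVolume, head_mask: np.ndarray, *,
                             threshold_frac: float = 0.5,
                             seed_frac: float = 0.15,
                             volume_range_ml: tuple[float, float] = (10.0, 150.0),
                             min_elongation: float = 1.5,
                             ) -> tuple[dict[str, np.ndarray], dict[str, float], dict]:
    """Outline, erode and label the two calibration tubes.

    Candidate blobs outside the head are seeded at ``seed_frac`` of the
    robust (99.9th percentile) maximum of a box-smoothed image (with a
    median + 6 MAD noise floor) and filtered to the expected tube volume
    range and elongated shape.  Each of the two survivors is re-thresholded
    at ``threshold_frac`` of its *own* interior plateau — the
    intensity-based peel of partial-volume periphery voxels — then eroded
    one voxel in-plane, and implausibly thin end slices are dropped.
    Per-tube thresholding matters because a global fraction of the image
    maximum would treat the dim 20 mM tube and the bright 80 mM tube
    asymmetrically.

    Returns (eroded masks, per-tube plateau intensities, report).  The
    calibration statistic is the plateau (median of box-smoothed values
    over the eroded ROI), which is insensitive to Gibbs ringing and rim
    dilution; the report includes per-slice 2D ROI voxel counts.
    """
    head_mask = np.asarray(head_mask, bool)
    if head_mask.shape != img.values.shape:
        raise ValueError("head mask shape does not match image")
    outside = ~head_mask
    # candidate detection runs on a lightly smoothed image (matched filter
    # against voxel speckle); intensities are always read from the raw image
    smooth = ndimage.uniform_filter(img.values, size=3)
    robust_max = np.percentile(smooth[outside], 99.9)
    floor = np.median(smooth[outside])
    mad = np.median(np.abs(smooth[outside] - floor))
    thr = max(seed_frac * robust_max, floor + 6.0 * mad)
    cand = outside & (smooth > thr)

    voxel_ml = np.abs(np.linalg.det(img.affine[:3, :3])) / 1000.0
    lab = cc_label(cand, connectivity=1)
    props = []
    for rp in regionprops(lab):
        vol_ml = rp.num_pixels * voxel_ml
        extent = np.array(rp.bbox[3:]) - np.array(rp.bbox[:3])
        elong = extent.max() / max(np.sort(extent)[:2].mean(), 1.0)
        props.append({"label": rp.label, "vol_ml": vol_ml, "elong": elong,
                      "n": rp.num_pixels})
    keep = [p for p in props
            if volume_range_ml[0] <= p["vol_ml"] <= volume_range_ml[1]
            and p["elong"] >= min_elongation]
    keep.sort(key=lambda p: -p["n"])
    if len(keep) < 2:
        raise TubeDetectionError(
            f"expected 2 tube candidates, found {len(keep)}; all components: "
            + "; ".join(f"label {p['label']}: {p['vol_ml']:.1f} ml, "
                        f"elongation {p['elong']:.1f}" for p in props))
    keep = keep[:2]

    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    # ROIs are slice-wise 2D objects; the peripheral peel erodes in-plane
    # so partial end rings are not axially consumed
    struct_2d = np.zeros((3, 3, 1), dtype=bool)
    struct_2d[1, :, 0] = struct_2d[:, 1, 0] = True
    raw = {}
    for p in keep:
        m = lab == p["label"]
        # plateau reference from the blob's interior core, where the box
        # smoothing is bias-free for noise and ringing alike; membership
        # from the smoothed image, whose edge crossing is noise-stable
        rough = m & (smooth > 0.5 * np.percentile(smooth[m], 99.0))
        core = ndimage.binary_erosion(rough, structure=struct)
        plateau = float(np.median(smooth[core if core.any() else rough]))
        refined = m & (smooth > threshold_frac * plateau)
        er = ndimage.binary_erosion(refined, structure=struct_2d)
        # slice-wise outlining: axial blur spills a few near-axis voxels
        # past the tube ends; drop slices with less than 70% of the median
        # cross-section, as a per-slice ROI draughtsman would
        counts = er.sum(axis=(0, 1))
        ok = counts >= 0.7 * np.median(counts[counts > 0]) if counts.any() else counts > 0
        er = er & ok[None, None, :]
        if not er.any():
            raise TubeDetectionError(
                f"tube component {p['label']} vanished under one-voxel erosion")
        # the calibration statistic is the plateau of the eroded ROI: the
        # median of the box-smoothed values, which is insensitive to Gibbs
        # ringing and to the residual partial-volume rim that a plain mask
        # mean would dilute by several percent
        stat = float(np.median(smooth[er]))
        raw[p["label"]] = (er, stat)
    (l1, (e1, s1)), (l2, (e2, s2)) = raw.items()
    if s1 <= s2:
        (low, s_lo), (high, s_hi) = (e1, s1), (e2, s2)
    else:
        (low, s_lo), (high, s_hi) = (e2, s2), (e1, s1)
    masks = {"low": low, "high": high}
    means = {"low": s_lo, "high": s_hi}

    slice_counts = {name: [int(c) for c in m.sum(axis=(0, 1)) if c > 0]
                    for name, m in masks.items()}
    report = {"threshold": float(seed_frac * robust_max),
              "robust_max": float(robust_max),
              "per_slice_roi_voxels": slice_counts,
              "candidates": props}
    return masks, means, report


def fit_calibration(s_low: float, s_high: float, c_low_mM: float = 20.0,
                    c_high_mM: float = 80.0, *, through_origin: bool = False,
                    tube_masks: dict[str, np.ndarray] | None = None) -> Calibration:
    """Fit the two-point (or through-origin) intensity-to-mM line."""
    if s_low < 0 or s_high <= s_low:
        raise ValueError("calibration requires s_high > s_low >= 0; got "
                         f"s_low={s_low}, s_high={s_high}")
    if through_origin:
        slope = (c_low_mM + c_high_mM) / (s_low + s_high)
        intercept = 0.0
    else:
        slope = (c_high_mM - c_low_mM) / (s_high - s_low)
        intercept = c_low_mM - slope * s_low
    return Calibration(c_low_mM=c_low_mM, c_high_mM=c_high_mM,
                       s_low=s_low, s_high=s_high, slope=slope,
                       intercept=intercept, tube_masks=tube_masks or {})


def make_tsc_map(img: ImageVolume, cal: Calibration) -> TSCMap:
    """Voxelwise concentration map; negative values retained and flagged."""
    values = cal.apply(img.values)
    meta = {"n_negative_voxels": int(np.sum(values < 0)),
            "recon": dict(img.provenance)}
    return TSCMap(values=values, affine=img.affine, calibration=cal,
                  metadata=meta)


def calibrate_image(img: ImageVolume, head_mask: np.ndarray, *,
                    c_low_mM: float = 20.0, c_high_mM: float = 80.0,
                    threshold_frac: float = 0.5,
                    through_origin: bool = False) -> TSCMap:
    """Detect tubes, fit the calibration and map one image to mM."""
    masks, means, report = detect_calibration_tubes(
        img, head_mask, threshold_frac=threshold_frac)
    cal = fit_calibration(means["low"], means["high"], c_low_mM, c_high_mM,
                          through_origin=through_origin, tube_masks=masks)
    tsc = make_tsc_map(img, cal)
    tsc.metadata["tube_detection"] = {
        k: v for k, v in report.items() if k != "candidates"}
    return tsc
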