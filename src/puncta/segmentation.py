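"""Negative-control-calibrated thresholding and puncta measurement.

The segmentation threshold is chosen against the matched negative-control
image: the lowest intensity threshold at which the number of objects
detected on the negative control is at most ``max_allowed`` (default 3%) of
the objects detected on the experimental image.  Suprathreshold pixels are
grouped into 8-connected components; each component becomes one punctum
measured on the raw pixel values.  Puncta touching an (expanded) nuclear
mask can be removed, mirroring DAPI-based exclusion of somatic signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Punctum, PunctaSet, RoiSpec, feret_diameter_um

# 8-connectivity for components
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdCalibration:
    channel: str
    threshold: float
    neg_control_fraction: float
    max_allowed: float = 0.03


def _count_components(image: np.ndarray, threshold: float) -> int:
    _, n = ndimage.label(image > threshold, structure=_STRUCT8)
    return n


def calibrate_threshold(
    exp_image: np.ndarray,
    neg_image: np.ndarray,
    max_allowed: float = 0.03,
    channel: str = "",
    n_candidates: int = 256,
) -> ThresholdCalibration:
    """Lowest threshold with (neg objects) / (exp objects) <= max_allowed.

    Candidate thresholds are an even grid over the experimental intensity
    range.  Raising ``max_allowed`` can only lower (never raise) the
    returned threshold.
    """
    if exp_image.shape != neg_image.shape:
        raise ValueError("experimental and negative images must share dimensions")
    if not (0.0 < max_allowed < 1.0):
        raise ValueError("max_allowed must be in (0, 1)")
    lo = float(min(exp_image.min(), neg_image.min()))
    hi = float(exp_image.max())
    if hi <= lo:
        raise ValueError("experimental image has no dynamic range")
    candidates = np.linspace(lo, hi, n_candidates, endpoint=False)
    for t in candidates:
        n_exp = _count_components(exp_image, t)
        if n_exp == 0:
            continue
        n_neg = _count_components(neg_image, t)
        frac = n_neg / n_exp
        if frac <= max_allowed:
            return ThresholdCalibration(
                channel=channel,
                threshold=float(t),
                neg_control_fraction=float(frac),
                max_allowed=max_allowed,
            )
    raise ValueError(
        "no threshold keeps negative-control detections under the bound; "
        "the negative control resembles the experimental image - inspect inputs"
    )


def segment_channel(
    image: np.ndarray,
    threshold: float,
    roi: RoiSpec,
    channel: str = "",
    min_area_px: int = 1,
) -> PunctaSet:
    """8-connected suprathreshold components measured as puncta.

    Area = pixel count / pixel_scale²; centroid = unweighted pixel-center
    mean; Feret diameter = maximum caliper over pixel corner points;
    total/mean intensity from the raw pixel values.  Single-pixel components
    are retained by default.
    """
    if tuple(image.shape) != roi.shape:
        raise ValueError(f"image shape {image.shape} inconsistent with ROI {roi.shape}")
    labels, n = ndimage.label(image > threshold, structure=_STRUCT8)
    puncta = []
    s = roi.pixel_scale
    img = np.asarray(image, dtype=float)
    for obj_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == obj_idx
        rows, cols = np.nonzero(sub)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        npix = len(rows)
        if npix < min_area_px:
            continue
        pixels = frozenset(zip(rows.tolist(), cols.tolist()))
        vals = img[rows, cols]
        cx = float((cols + 0.5).mean() / s)
        cy = float((rows + 0.5).mean() / s)
        puncta.append(
            Punctum(
                id=len(puncta),
                channel=channel,
                centroid_xy=(cx, cy),
                area=npix / s**2,
                feret_diameter=feret_diameter_um(pixels, s),
                total_intensity=float(vals.sum()),
                mean_intensity=float(vals.mean()),
                pixels=pixels,
            )
        )
    return PunctaSet(
        channel,
        roi,
        puncta,
        provenance=f"segmented;threshold={threshold:g};min_area_px={min_area_px}",
    )


def exclude_nuclear(
    pset: PunctaSet,
    dapi_mask: BinaryMask,
    expansion_fraction: float = 0.10,
) -> Tuple[PunctaSet, int]:
    """Remove puncta overlapping the nuclear mask expanded by +10% area.

    Each nucleus component of equivalent-circle radius R is dilated by the
    radius r solving pi*(R+r)² = (1+expansion_fraction)*pi*R², i.e.
    r = R*(sqrt(1+f) - 1).  A punctum sharing any pixel with the expanded
    mask is removed.  Returns (filtered set, number removed).
    """
    if dapi_mask.roi != pset.roi:
        raise ValueError("mask and puncta must share the ROI")
    grid = dapi_mask.grid
    if not grid.any():
        return pset, 0
    labels, n = ndimage.label(grid, structure=_STRUCT8)
    # distance (in pixels) to the nearest nuclear pixel, plus which nucleus
    dist, (ir, ic) = ndimage.distance_transform_edt(~grid, return_indices=True)
    nearest_label = labels[ir, ic]
    growth = np.sqrt(1.0 + expansion_fraction) - 1.0
    radii_px = np.zeros(n + 1)
    for k in range(1, n + 1):
        area_px = np.count_nonzero(labels == k)
        radii_px[k] = np.sqrt(area_px / np.pi) * growth
    expanded = dist <= radii_px[nearest_label]

    from .core import materialize_pixels

    filled = materialize_pixels(pset)
    kept = []
    removed = 0
    for p in filled:
        hit = any(expanded[r, c] for r, c in p.pixels)  # type: ignore[union-attr]
        if hit:
            removed += 1
        else:
            kept.append(p)
    out = PunctaSet(
        pset.channel,
        pset.roi,
        kept,
        provenance=f"{pset.provenance};nuclear_excluded(+{expansion_fraction:.0%})",
    )
    return out, removed


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold, offered as an alternative initializer only."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(image)))


def match_to_truth(
    detected: PunctaSet,
    truth: PunctaSet,
    max_dist_um: float = 0.3,
) -> Tuple[int, int, int]:
    """Greedy nearest-centroid matching of detected vs ground-truth puncta.

    Returns (true positives, false positives, false negatives); each truth
    punctum may absorb at most one detection within ``max_dist_um``.
    """
    from scipy.spatial import cKDTree

    if len(truth) == 0:
        return 0, len(detected), 0
    if len(detected) == 0:
        return 0, 0, len(truth)
    tree = cKDTree(truth.centroids())
    dists, idx = tree.query(detected.centroids())
    used = set()
    tp = 0
    for d, j in sorted(zip(dists, idx)):
        if d <= max_dist_um and j not in used:
            used.add(j)
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    return tp, fp, fn
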