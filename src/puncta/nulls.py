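"""Rotation-based random-colocalization nulls.

Chance colocalization is estimated by rotating one channel 90° (clockwise,
square ROIs only) or 180° about the ROI center and re-measuring overlap
against the unrotated partner.  Rotation preserves per-channel abundance and
every per-punctum attribute, so any colocalization that survives it is
attributable to chance spatial coincidence at the observed densities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .colocalization import (
    ColocalizationMatrix,
    OverlapCriterion,
    pairwise_matrix,
    percent_of_pair,
    percent_of_reference,
    PERCENT_OF_PAIR,
    PERCENT_OF_REFERENCE,
)
from .core import Punctum, PunctaSet


def rotate_puncta(pset: PunctaSet, angle: int) -> PunctaSet:
    """Rotate a channel's puncta about the ROI center.

    ``angle`` is 90 (clockwise in image coordinates, requires a square ROI)
    or 180.  Centroids and pixel footprints move; area, Feret diameter and
    intensities are untouched.  Rotating twice by 180° is the identity.
    """
    if angle not in (90, 180):
        raise ValueError("angle must be 90 or 180")
    roi = pset.roi
    w, h = roi.width_um, roi.height_um
    if angle == 90 and abs(w - h) > 1e-9:
        raise ValueError("90° rotation requires a square ROI")
    n_rows, n_cols = roi.shape
    out = []
    for p in pset:
        x, y = p.centroid_xy
        if angle == 180:
            new_xy = (w - x, h - y)
        else:  # 90° clockwise: (x, y) -> (W - y, x)
            new_xy = (w - y, x)
        pixels = None
        if p.pixels is not None:
            if angle == 180:
                pixels = frozenset(
                    (n_rows - 1 - r, n_cols - 1 - c) for r, c in p.pixels
                )
            else:
                pixels = frozenset((c, n_rows - 1 - r) for r, c in p.pixels)
        out.append(
            Punctum(
                id=p.id,
                channel=p.channel,
                centroid_xy=new_xy,
                area=p.area,
                feret_diameter=p.feret_diameter,
                total_intensity=p.total_intensity,
                mean_intensity=p.mean_intensity,
                pixels=pixels,
            )
        )
    return PunctaSet(
        pset.channel, roi, out, provenance=f"{pset.provenance};rotated{angle}"
    )


def random_percent(
    a: PunctaSet,
    b: PunctaSet,
    crit: OverlapCriterion,
    angle: int = 90,
    normalization: str = PERCENT_OF_REFERENCE,
) -> Optional[float]:
    """Chance-level colocalization percentage with ``a`` rotated."""
    a_rot = rotate_puncta(a, angle)
    if normalization == PERCENT_OF_REFERENCE:
        return percent_of_reference(a_rot, b, crit)
    if normalization == PERCENT_OF_PAIR:
        return percent_of_pair(a_rot, b, crit)
    raise ValueError(f"unknown normalization {normalization!r}")


def random_matrix(
    sets: Sequence[PunctaSet],
    crit: OverlapCriterion,
    angle: int = 90,
    normalization: str = PERCENT_OF_REFERENCE,
) -> ColocalizationMatrix:
    """Pairwise matrix with the reference channel of each cell rotated.

    Matches the convention "rotated reference having unrotated target": the
    count in cell (ref, tgt) comes from rotating ``ref`` only.
    """
    if len(sets) < 2:
        raise ValueError("need at least two channels")
    channels = [s.channel for s in sets]
    if len(set(channels)) != len(channels):
        raise ValueError("duplicated channel labels")
    by_name = {s.channel: s for s in sets}
    counts = pd.DataFrame(0, index=channels, columns=channels, dtype=int)
    from .colocalization import colocalized_reference_ids

    rotated = {name: rotate_puncta(s, angle) for name, s in by_name.items()}
    for ref in channels:
        for tgt in channels:
            if ref == tgt:
                continue
            counts.loc[ref, tgt] = len(
                colocalized_reference_ids(rotated[ref], by_name[tgt], crit)
            )
    totals = {s.channel: len(s) for s in sets}
    return ColocalizationMatrix(channels, counts, totals, normalization)


def random_subtracted_matrix(
    sets: Sequence[PunctaSet],
    crit: OverlapCriterion,
    angle: int = 90,
    normalization: str = PERCENT_OF_REFERENCE,
) -> pd.DataFrame:
    """Experimental minus rotation-null percentages, cell-wise.

    Negative cells are retained as-is — clipping them would bias averages
    across replicates.
    """
    exp = pairwise_matrix(sets, crit, normalization)
    rand = random_matrix(sets, crit, angle, normalization)
    return exp.percent - rand.percent
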