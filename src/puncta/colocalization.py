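"""Object-based colocalization between smFISH channels.

Two overlap definitions are supported:

* ``pixel`` mode — a reference punctum is colocalized when its pixel
  footprint shares at least ``min_pixels`` (default 1) pixels with the union
  footprint of the target channel.  This mirrors object-intersection
  ("having") semantics of particle-analysis software.
* ``centroid`` mode — a reference punctum is colocalized when some target
  punctum lies at centroid-to-centroid distance strictly less than
  ``fraction x (Feret_A + Feret_B)/2``.  ``fraction=0.99`` corresponds to the
  lenient ">1% overlap" definition, ``fraction=0.50`` to the stringent
  ">50% overlap" definition.

Each reference punctum is counted at most once no matter how many partners
it touches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import PunctaSet, materialize_pixels, puncta_to_mask

PERCENT_OF_REFERENCE = "percent_of_reference"
PERCENT_OF_PAIR = "percent_of_pair"


@dataclass(frozen=True)
class OverlapCriterion:
    """Colocalization rule: pixel overlap or centroid distance."""

    mode: str = "pixel"
    fraction: float = 0.99
    min_pixels: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("pixel", "centroid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")


#: lenient ">1% overlap" centroid rule
LENIENT_CENTROID = OverlapCriterion(mode="centroid", fraction=0.99)
#: stringent ">50% overlap" centroid rule
STRINGENT_CENTROID = OverlapCriterion(mode="centroid", fraction=0.50)
#: 1-pixel object-intersection rule
PIXEL_OVERLAP = OverlapCriterion(mode="pixel")


def colocalized_reference_ids(
    a: PunctaSet, b: PunctaSet, crit: OverlapCriterion
) -> Set[int]:
    """Ids of puncta in ``a`` colocalized with at least one punctum of ``b``."""
    if a.roi != b.roi:
        raise ValueError("PunctaSets must share the ROI")
    if len(a) == 0 or len(b) == 0:
        return set()
    if crit.mode == "pixel":
        return _pixel_mode_ids(a, b, crit.min_pixels)
    return _centroid_mode_ids(a, b, crit.fraction)


def _pixel_mode_ids(a: PunctaSet, b: PunctaSet, min_pixels: int) -> Set[int]:
    a = materialize_pixels(a)
    b_mask = puncta_to_mask(materialize_pixels(b)).grid
    out: Set[int] = set()
    for p in a:
        shared = 0
        for row, col in p.pixels:  # type: ignore[union-attr]
            if b_mask[row, col]:
                shared += 1
                if shared >= min_pixels:
                    out.add(p.id)
                    break
    return out


def _centroid_mode_ids(a: PunctaSet, b: PunctaSet, fraction: float) -> Set[int]:
    for pset in (a, b):
        for p in pset:
            if p.feret_diameter is None or not np.isfinite(p.feret_diameter):
                raise ValueError(
                    f"punctum {p.id} in channel {pset.channel!r} lacks a Feret diameter"
                )
    xy_a = a.centroids()
    xy_b = b.centroids()
    r_a = a.radii()
    r_b = b.radii()
    tree = cKDTree(xy_b)
    # largest possible capture radius per reference punctum bounds the query
    max_rb = r_b.max()
    ids = a.ids()
    out: Set[int] = set()
    neighbours = tree.query_ball_point(xy_a, r=fraction * (r_a + max_rb))
    for i, cand in enumerate(neighbours):
        if not cand:
            continue
        cand = np.asarray(cand)
        d = np.sqrt(np.sum((xy_b[cand] - xy_a[i]) ** 2, axis=1))
        # strict inequality: "less than fraction x sum of radii"
        if np.any(d < fraction * (r_a[i] + r_b[cand])):
            out.add(ids[i])
    return out


def percent_of_reference(
    a: PunctaSet, b: PunctaSet, crit: OverlapCriterion
) -> Optional[float]:
    """100 x (colocalized reference puncta) / (total reference puncta).

    Returns None (missing, not 0) when the reference channel is empty.
    """
    if len(a) == 0:
        return None
    return 100.0 * len(colocalized_reference_ids(a, b, crit)) / len(a)


def percent_of_pair(
    a: PunctaSet, b: PunctaSet, crit: OverlapCriterion
) -> Optional[float]:
    """Colocalized puncta from both channels as % of the combined count.

    Symmetric in (a, b); each colocalized punctum counts once on its own
    side, so hub puncta are not double-counted.
    """
    if len(a) + len(b) == 0:
        return None
    n_a = len(colocalized_reference_ids(a, b, crit))
    n_b = len(colocalized_reference_ids(b, a, crit))
    return 100.0 * (n_a + n_b) / (len(a) + len(b))


@dataclass
class ColocalizationMatrix:
    """Reference x target percentage table with raw counts.

    ``counts.loc[ref, tgt]`` is the number of reference-channel puncta
    colocalized with the target channel.  Percentages depend on the
    normalization: per-reference (rows sum over the reference total) or
    per-pair (symmetric, combined-count denominator).
    """

    channels: List[str]
    counts: pd.DataFrame
    totals: Dict[str, int]
    normalization: str

    @property
    def percent(self) -> pd.DataFrame:
        out = pd.DataFrame(
            np.nan, index=self.channels, columns=self.channels, dtype=float
        )
        for ref in self.channels:
            for tgt in self.channels:
                if ref == tgt:
                    continue
                if self.normalization == PERCENT_OF_REFERENCE:
                    tot = self.totals[ref]
                    if tot > 0:
                        out.loc[ref, tgt] = 100.0 * self.counts.loc[ref, tgt] / tot
                else:
                    tot = self.totals[ref] + self.totals[tgt]
                    if tot > 0:
                        out.loc[ref, tgt] = (
                            100.0
                            * (self.counts.loc[ref, tgt] + self.counts.loc[tgt, ref])
                            / tot
                        )
        return out

    def subtract(self, other: "ColocalizationMatrix") -> pd.DataFrame:
        """Cell-wise percentage difference (experimental - random)."""
        return self.percent - other.percent


def pairwise_matrix(
    sets: Sequence[PunctaSet],
    crit: OverlapCriterion,
    normalization: str = PERCENT_OF_REFERENCE,
) -> ColocalizationMatrix:
    """All ordered (reference, target) colocalization counts for a panel.

    Twelve channels yield 66 unordered pairs; both normalizations are
    derived from the same ordered count table.
    """
    if len(sets) < 2:
        raise ValueError("need at least two channels")
    channels = [s.channel for s in sets]
    if len(set(channels)) != len(channels):
        raise ValueError("duplicated channel labels")
    if normalization not in (PERCENT_OF_REFERENCE, PERCENT_OF_PAIR):
        raise ValueError(f"unknown normalization {normalization!r}")
    counts = pd.DataFrame(0, index=channels, columns=channels, dtype=int)
    by_name = {s.channel: s for s in sets}
    for ref, tgt in combinations(channels, 2):
        counts.loc[ref, tgt] = len(
            colocalized_reference_ids(by_name[ref], by_name[tgt], crit)
        )
        counts.loc[tgt, ref] = len(
            colocalized_reference_ids(by_name[tgt], by_name[ref], crit)
        )
    totals = {s.channel: len(s) for s in sets}
    return ColocalizationMatrix(channels, counts, totals, normalization)


def colocalized_with_any(
    a: PunctaSet, others: Sequence[PunctaSet], crit: OverlapCriterion
) -> Set[int]:
    """Ids of ``a`` puncta colocalized with >= 1 punctum from any other channel.

    Equals the union over per-channel colocalized id sets (the "union of
    intersection layers" construction).
    """
    if not others:
        raise ValueError("others must be non-empty")
    out: Set[int] = set()
    for b in others:
        out |= colocalized_reference_ids(a, b, crit)
    return out
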