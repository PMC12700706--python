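"""Granule composition: singleton / dimer / multimer classification.

Each focal-channel punctum is classified by how many distinct partner
channels it colocalizes with: none (singleton), exactly one (dimer, recorded
per partner), or two or more (multimer, split by whether the designated
special partner — the highly abundant channel — is among them).  A rotated
null repeats the classification with the focal channel rotated.  Channels
can first be gated on a protein marker (e.g. an FMRP immunostain) so that
only marker-positive puncta enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Union

import pandas as pd

from .colocalization import (
    OverlapCriterion,
    PIXEL_OVERLAP,
    colocalized_reference_ids,
)
from .core import BinaryMask, PunctaSet
from .nulls import rotate_puncta

SINGLETON = "singleton"
MULTIMER_WITH_SPECIAL = "multimer_with_special"
MULTIMER_WITHOUT_SPECIAL = "multimer_without_special"


@dataclass
class CompositionSummary:
    """Percentages of focal puncta per composition category.

    ``dimer_per_partner[P]`` is the % of focal puncta colocalized with
    channel P and nothing else.  Categories partition the focal set, so
    singleton + sum(dimers) + both multimer categories = 100%.
    """

    focal: str
    partner_panel: List[str]
    special_partner: Optional[str]
    n_focal: int
    singleton: float
    dimer_per_partner: Dict[str, float]
    multimer_with_special: float
    multimer_without_special: float
    per_punctum: pd.DataFrame = field(repr=False, default=None)

    @property
    def total(self) -> float:
        return (
            self.singleton
            + sum(self.dimer_per_partner.values())
            + self.multimer_with_special
            + self.multimer_without_special
        )

    @property
    def colocalized_any(self) -> float:
        """% of focal puncta with at least one partner (100 - singleton)."""
        return 100.0 - self.singleton


def classify_composition(
    focal: PunctaSet,
    partners: Sequence[PunctaSet],
    special: Optional[str],
    crit: OverlapCriterion,
) -> Optional[CompositionSummary]:
    """Classify every focal punctum by its distinct partner channels.

    Partner multiplicity within one channel is not distinguishable under the
    layer-intersection construction, so a focal punctum overlapping two
    puncta of the same single channel is a dimer.  Returns None when the
    focal channel is empty.
    """
    if not partners:
        raise ValueError("partner panel must be non-empty")
    panel = [p.channel for p in partners]
    if special is not None and special not in panel:
        raise ValueError(f"special partner {special!r} not in panel {panel}")
    if len(focal) == 0:
        return None
    partner_sets: Dict[int, Set[str]] = {p.id: set() for p in focal}
    for b in partners:
        for fid in colocalized_reference_ids(focal, b, crit):
            partner_sets[fid].add(b.channel)
    n = len(focal)
    n_singleton = 0
    n_dimer: Dict[str, int] = {c: 0 for c in panel}
    n_multi_with = 0
    n_multi_without = 0
    rows = []
    for fid, chans in partner_sets.items():
        if not chans:
            cat = SINGLETON
            n_singleton += 1
        elif len(chans) == 1:
            (only,) = chans
            cat = f"dimer:{only}"
            n_dimer[only] += 1
        elif special is not None and special in chans:
            cat = MULTIMER_WITH_SPECIAL
            n_multi_with += 1
        else:
            cat = MULTIMER_WITHOUT_SPECIAL
            n_multi_without += 1
        rows.append(
            {"id": fid, "category": cat, "partners": ",".join(sorted(chans))}
        )
    return CompositionSummary(
        focal=focal.channel,
        partner_panel=panel,
        special_partner=special,
        n_focal=n,
        singleton=100.0 * n_singleton / n,
        dimer_per_partner={c: 100.0 * k / n for c, k in n_dimer.items()},
        multimer_with_special=100.0 * n_multi_with / n,
        multimer_without_special=100.0 * n_multi_without / n,
        per_punctum=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class MarkerGate:
    """Protein-marker gate: keep only puncta colocalized with the marker."""

    marker: Union[PunctaSet, BinaryMask]
    criterion: OverlapCriterion = PIXEL_OVERLAP


def gate_by_marker(
    sets: Sequence[PunctaSet], gate: MarkerGate
) -> List[PunctaSet]:
    """Reduce each channel to the puncta colocalized with the marker."""
    marker = gate.marker
    if isinstance(marker, BinaryMask):
        marker = _mask_to_puncta(marker)
    out = []
    for s in sets:
        if marker.roi != s.roi:
            raise ValueError("marker and channels must share the ROI")
        keep = colocalized_reference_ids(s, marker, gate.criterion)
        out.append(
            PunctaSet(
                s.channel,
                s.roi,
                [p for p in s if p.id in keep],
                provenance=f"{s.provenance};marker_gated",
            )
        )
    return out


def _mask_to_puncta(mask: BinaryMask) -> PunctaSet:
    """Connected components of a marker mask as a pseudo-channel."""
    from .segmentation import segment_channel

    img = mask.grid.astype(float)
    return segment_channel(img, 0.5, mask.roi, channel="__marker__")


def composition_null(
    focal: PunctaSet,
    partners: Sequence[PunctaSet],
    special: Optional[str],
    crit: OverlapCriterion,
    angle: int = 90,
) -> Optional[CompositionSummary]:
    """Composition of the rotated focal channel against unrotated partners."""
    return classify_composition(rotate_puncta(focal, angle), partners, special, crit)
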