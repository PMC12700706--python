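"""End-to-end pipeline: segment -> exclude nuclei -> colocalize -> null ->
subtract -> composition -> distributions.

The pipeline is deterministic under a fixed seed and configuration; every
output is stamped with a configuration hash and seed so identical runs
produce byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .colocalization import (
    OverlapCriterion,
    PERCENT_OF_REFERENCE,
    pairwise_matrix,
)
from .composition import classify_composition, composition_null
from .core import BinaryMask, RoiSpec
from .distributions import cluster_profiles, relative_histogram
from .io import read_image, read_puncta_csv, write_puncta_csv
from .nulls import random_matrix
from .segmentation import calibrate_threshold, exclude_nuclear, segment_channel

log = logging.getLogger("puncta")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    roi_width_um: float
    roi_height_um: float
    pixel_scale: float = 9.6679
    #: per-channel image paths; each entry: {"image": ..., "neg": ...}
    channel_images: Dict[str, Dict[str, str]] = field(default_factory=dict)
    #: alternatively, one puncta CSV carrying all channels
    puncta_csv: Optional[str] = None
    dapi_image: Optional[str] = None
    mode: str = "pixel"
    fraction: float = 0.99
    min_pixels: int = 1
    normalization: str = PERCENT_OF_REFERENCE
    null_angle: int = 90
    max_neg_fraction: float = 0.03
    explicit_thresholds: Dict[str, float] = field(default_factory=dict)
    composition_focal: Optional[str] = None
    composition_special: Optional[str] = None
    area_bin_width: float = 0.1
    area_open_tail: float = 1.0
    seed: int = 0

    def roi(self) -> RoiSpec:
        return RoiSpec(self.roi_width_um, self.roi_height_um, self.pixel_scale)

    def criterion(self) -> OverlapCriterion:
        return OverlapCriterion(
            mode=self.mode, fraction=self.fraction, min_pixels=self.min_pixels
        )

    def digest(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir: Path) -> Dict[str, object]:
    """Execute the full analysis and write stamped CSV outputs.

    Returns a bundle with the per-channel PunctaSets, colocalization
    matrices (experimental, random, subtracted), the composition summary
    (when a focal channel is configured), and area histograms.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roi = config.roi()
    crit = config.criterion()
    stamp = {"config_hash": config.digest(), "seed": config.seed, "version": __version__}

    # --- acquire puncta ---------------------------------------------------
    if config.puncta_csv:
        sets = read_puncta_csv(config.puncta_csv, roi)
        log.info("loaded %d channels from %s", len(sets), config.puncta_csv)
    elif config.channel_images:
        sets = {}
        dapi_mask = None
        if config.dapi_image:
            dapi = read_image(config.dapi_image)
            grid = dapi > dapi.mean()
            dapi_mask = BinaryMask(grid, roi)
        for name, paths in config.channel_images.items():
            img = read_image(paths["image"])
            if name in config.explicit_thresholds:
                thr = config.explicit_thresholds[name]
            elif "neg" in paths:
                cal = calibrate_threshold(
                    img, read_image(paths["neg"]), config.max_neg_fraction, channel=name
                )
                thr = cal.threshold
            else:
                raise ValueError(
                    f"channel {name!r}: no negative control and no explicit threshold"
                )
            pset = segment_channel(img, thr, roi, channel=name)
            n_before = len(pset)
            removed = 0
            if dapi_mask is not None:
                pset, removed = exclude_nuclear(pset, dapi_mask)
            log.info(
                "channel %s: threshold=%g detected=%d nuclear_excluded=%d kept=%d",
                name, thr, n_before, removed, len(pset),
            )
            sets[name] = pset
    else:
        raise ValueError("config must provide channel_images or puncta_csv")

    bundle: Dict[str, object] = {"sets": sets, "stamp": stamp}
    set_list = list(sets.values())
    write_puncta_csv(set_list, out_dir / "puncta.csv")

    # --- colocalization + null -------------------------------------------
    if len(set_list) >= 2:
        exp = pairwise_matrix(set_list, crit, config.normalization)
        rand = random_matrix(set_list, crit, config.null_angle, config.normalization)
        subtracted = exp.percent - rand.percent
        if (subtracted < 0).any().any():
            log.warning("random-subtracted matrix has negative cells (retained)")
        bundle.update(experimental=exp, random=rand, subtracted=subtracted)
        exp.percent.to_csv(out_dir / "colocalization_experimental.csv")
        rand.percent.to_csv(out_dir / "colocalization_random.csv")
        subtracted.to_csv(out_dir / "colocalization_subtracted.csv")
        exp.counts.to_csv(out_dir / "colocalization_counts.csv")

    # --- composition ------------------------------------------------------
    if config.composition_focal and config.composition_focal in sets:
        focal = sets[config.composition_focal]
        partners = [s for k, s in sets.items() if k != config.composition_focal]
        summary = classify_composition(
            focal, partners, config.composition_special, crit
        )
        null = composition_null(
            focal, partners, config.composition_special, crit, config.null_angle
        )
        bundle.update(composition=summary, composition_null=null)
        if summary is not None:
            rows = [
                {"category": "singleton", "experimental": summary.singleton,
                 "random": null.singleton},
            ]
            for part in summary.partner_panel:
                rows.append(
                    {"category": f"dimer:{part}",
                     "experimental": summary.dimer_per_partner[part],
                     "random": null.dimer_per_partner[part]}
                )
            rows.append(
                {"category": "multimer_with_special",
                 "experimental": summary.multimer_with_special,
                 "random": null.multimer_with_special}
            )
            rows.append(
                {"category": "multimer_without_special",
                 "experimental": summary.multimer_without_special,
                 "random": null.multimer_without_special}
            )
            pd.DataFrame(rows).to_csv(out_dir / "composition.csv", index=False)

    # --- area distributions ----------------------------------------------
    profiles = {}
    for name, s in sets.items():
        if len(s) == 0:
            continue
        h = relative_histogram(
            [p.area for p in s], config.area_bin_width, config.area_open_tail
        )
        profiles[name] = h.values
    if profiles:
        prof_df = pd.DataFrame(profiles).T
        bundle["area_profiles"] = prof_df
        prof_df.to_csv(out_dir / "area_profiles.csv")
        if len(prof_df) >= 2:
            clust = cluster_profiles(prof_df, metric="manhattan")
            bundle["area_clusters"] = clust
            (out_dir / "area_dendrogram.nwk").write_text(clust.newick())

    with open(out_dir / "run_stamp.json", "w") as fh:
        json.dump(stamp, fh, indent=2, sort_keys=True)
    return bundle
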