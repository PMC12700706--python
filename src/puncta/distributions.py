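"""Relative-% distributions, profile clustering, abundance correlation.

Puncta area (µm²) and normalized total intensity (total / mean per punctum,
which equals the pixel count on pixel-backed puncta) are summarized as
relative-% histograms with a final open tail bin.  Channel profiles are
hierarchically clustered (manhattan or euclidean distance, Ward-D2 linkage)
to recover families of similar distribution shapes, and random-subtracted
colocalization profiles are regressed against partner abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from .colocalization import ColocalizationMatrix
from .core import Punctum


def normalized_total_intensity(p: Punctum) -> float:
    """Total intensity divided by mean intensity.

    On pixel-backed puncta this equals the pixel count exactly, making the
    normalized intensity an image-acquisition-free proxy for puncta area —
    the reason area-profile and intensity-profile clustering agree.
    """
    if p.mean_intensity <= 0:
        raise ValueError(f"punctum {p.id}: mean_intensity must be positive")
    return p.total_intensity / p.mean_intensity


@dataclass
class RelativeHistogram:
    """Relative-% histogram with a final open bin.

    ``edges`` are the closed-bin left edges plus the open-tail start; the
    last value is the % of observations at or beyond ``open_tail_from``.
    Values sum to 100 (within rounding).
    """

    variable: str
    bin_width: float
    edges: np.ndarray
    values: np.ndarray  # relative % per bin
    sem: Optional[np.ndarray] = None  # across replicates, when averaged


def relative_histogram(
    values: Sequence[float],
    bin_width: float = 0.1,
    open_tail_from: float = 1.0,
    variable: str = "area_um2",
) -> RelativeHistogram:
    """Half-open bins [k*w, (k+1)*w) up to the open tail [tail, inf)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_closed = int(round(open_tail_from / bin_width))
    edges = np.arange(n_closed + 1) * bin_width
    counts, _ = np.histogram(vals, bins=np.append(edges, np.inf))
    pct = 100.0 * counts / vals.size
    return RelativeHistogram(variable, bin_width, edges, pct)


def average_histograms(hists: Sequence[RelativeHistogram]) -> RelativeHistogram:
    """Average per-replicate relative-% histograms (not pooled counts).

    Replicates are averaged on the percentage scale so each replicate
    contributes equally regardless of its puncta count; the SEM across
    replicates is attached.
    """
    if not hists:
        raise ValueError("no histograms to average")
    ref = hists[0]
    for h in hists[1:]:
        if not np.array_equal(h.edges, ref.edges):
            raise ValueError("histograms must share binning")
    stack = np.stack([h.values for h in hists])
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(len(hists)) if len(hists) > 1 else None
    )
    return RelativeHistogram(
        ref.variable, ref.bin_width, ref.edges, stack.mean(axis=0), sem
    )


@dataclass
class ClusterResult:
    items: List[str]
    distance_metric: str
    linkage_matrix: np.ndarray  # scipy hierarchy format; |items|-1 merges

    def cut(self, k: int) -> Dict[str, int]:
        """Flat cluster labels at k clusters, keyed by item."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.items, labels.tolist()))

    def newick(self) -> str:
        """Dendrogram serialized as a Newick string."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.items[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return walk(tree) + ";"


def cluster_profiles(
    profiles: pd.DataFrame,
    metric: str = "manhattan",
    linkage: str = "ward",
) -> ClusterResult:
    """Agglomerative clustering of row profiles under Ward-D2 linkage.

    The Ward linkage is applied to the chosen precomputed distances via the
    Lance-Williams recurrence on squared distances (the ward.D2 update);
    with manhattan inputs this follows the empirical (metric, linkage)
    pairing even though Ward's variance interpretation assumes
    squared-Euclidean geometry — fidelity to the established analysis over
    orthodoxy.  Deterministic given input order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two items to cluster")
    mat = profiles.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("profiles contain NaN rows")
    metric_name = "cityblock" if metric == "manhattan" else metric
    d = pdist(mat, metric=metric_name)
    z = hierarchy.linkage(d, method=linkage)
    return ClusterResult(list(profiles.index), metric, z)


def abundance_correlation(
    matrix: ColocalizationMatrix | pd.DataFrame,
    abundances: Dict[str, float],
    reference: str,
) -> Tuple[float, float]:
    """OLS of the reference channel's colocalization % against abundance.

    Accepts a colocalization matrix (raw or random-subtracted percentages)
    or a bare percentage DataFrame.  Returns (slope, R²) across the >= 3
    partner channels present in both inputs.
    """
    percent = matrix.percent if isinstance(matrix, ColocalizationMatrix) else matrix
    if reference not in percent.index:
        raise ValueError(f"reference {reference!r} not in matrix")
    xs, ys = [], []
    for tgt in percent.columns:
        if tgt == reference or tgt not in abundances:
            continue
        y = percent.loc[reference, tgt]
        if pd.notna(y):
            xs.append(abundances[tgt])
            ys.append(float(y))
    if len(xs) < 3:
        raise ValueError("need at least three partner points for a fit")
    fit = linregress(xs, ys)
    return float(fit.slope), float(fit.rvalue**2)
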