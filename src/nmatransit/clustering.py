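"""Hierarchical clustering of the expanded dissimilarity matrix.

Studies (comparison-level observations) are agglomerated from the pairwise
weighted Gower matrix.  Two model-selection steps are objective rather than
visual: the linkage method is the one whose dendrogram best preserves the
original dissimilarities, measured by the cophenetic correlation coefficient
(CCC, the Pearson correlation between the n(n-1)/2 input dissimilarities and
the tree's cophenetic distances); and the number of clusters maximises the
overall average silhouette width over cuts k = 2 .. n-1.

A treatment comparison whose rows land in two or more clusters is
*fragmented*; its rows outside the modal cluster are *eloping*.  Many clusters
and many fragmented comparisons signal imbalanced effect modifiers across the
network, i.e. potential intransitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

from .dataset import ComparisonTable
from .gower import DistMatrix

#: Lance-Williams linkage methods considered, in tie-break preference order.
LINKAGE_METHODS = ("average", "complete", "single", "weighted", "ward", "centroid", "median")

#: methods whose merge heights are guaranteed nondecreasing
MONOTONE_METHODS = frozenset({"single", "complete", "average", "weighted", "ward"})


def _as_condensed(dm) -> tuple[np.ndarray, int]:
    if isinstance(dm, DistMatrix):
        return dm.condensed(), dm.n
    arr = np.asarray(dm, dtype=float)
    if arr.ndim == 2:
        if np.isnan(arr).any():
            raise ValueError(
                "dissimilarity matrix contains undefined entries; resolve "
                "them before clustering"
            )
        return squareform(arr, checks=False), arr.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * len(arr))) / 2))
    return arr, n


def agglomerate(dm, method: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) for one method.

    Centroid/median linkage can produce height inversions on non-Euclidean
    input; these are flagged but kept, since cuts are by cluster count.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {method!r}; options: {LINKAGE_METHODS}")
    cond, _ = _as_condensed(dm)
    Z = hierarchy.linkage(cond, method=method)
    heights = Z[:, 2]
    if method not in MONOTONE_METHODS and np.any(np.diff(heights) < -1e-12):
        warnings.warn(
            f"{method} linkage produced non-monotone merge heights "
            "(inversions); the dendrogram is reported as computed",
            UserWarning,
            stacklevel=2,
        )
    return Z


def cophenetic_correlation(dm, Z: np.ndarray) -> float:
    """CCC: Pearson correlation of input vs cophenetic distances.

    NaN (flagged) when either vector has zero variance.
    """
    cond, _ = _as_condensed(dm)
    coph = hierarchy.cophenet(Z)
    if np.std(cond) == 0 or np.std(coph) == 0:
        warnings.warn("zero variance in distances; CCC undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(cond, coph)[0, 1])


def select_linkage(
    dm,
    methods: Sequence[str] = LINKAGE_METHODS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, dict]:
    """Pick the linkage with the highest CCC.

    Ties (at 1e-12) break by the fixed preference order of ``methods``; pass
    ``rng`` to restore randomised tie-breaking instead.
    """
    if not methods:
        raise ValueError("need at least one linkage method")
    ccc = {}
    for m in methods:
        ccc[m] = cophenetic_correlation(dm, agglomerate(dm, m))
    finite = {m: c for m, c in ccc.items() if np.isfinite(c)}
    if not finite:
        raise ValueError("CCC undefined for every linkage method")
    best_val = max(finite.values())
    tied = [m for m in methods if m in finite and finite[m] >= best_val - 1e-12]
    if rng is not None and len(tied) > 1:
        return str(rng.choice(tied)), ccc
    return tied[0], ccc


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Cluster labels (0-based, relabelled by first appearance) for k clusters."""
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    _, out = np.unique(labels, return_inverse=True)
    return out


def silhouette_widths(dm, labels: np.ndarray) -> np.ndarray:
    """Per-observation silhouette widths for a partition.

    ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` with a the mean within-cluster
    dissimilarity and b the smallest mean dissimilarity to another cluster;
    members of singleton clusters score 0 by convention.
    """
    cond_n = np.asarray(dm.values if isinstance(dm, DistMatrix) else dm, dtype=float)
    labels = np.asarray(labels)
    n = cond_n.shape[0]
    k = len(np.unique(labels))
    if not (2 <= k <= n - 1):
        raise ValueError(f"number of clusters must lie in [2, n-1]; got k={k}, n={n}")
    return silhouette_samples(cond_n, labels, metric="precomputed")


@dataclass
class SilhouetteProfile:
    """Overall average silhouette width per candidate cluster count."""

    per_k: dict  # k -> (widths array, overall average)
    optimal_k: int
    local_optima: list  # first few locally optimal k, best first

    @property
    def k_range(self) -> list:
        return sorted(self.per_k)

    def average(self, k: int) -> float:
        return self.per_k[k][1]

    @property
    def optimal_average(self) -> float:
        return self.average(self.optimal_k)


def silhouette_profile(
    dm, Z: np.ndarray, k_min: int = 2, k_max: Optional[int] = None, n_optima: int = 3
) -> SilhouetteProfile:
    """Silhouette profile over dendrogram cuts k = k_min .. k_max.

    The optimal partition maximises the overall average width; the first few
    local optima are reported too, since a near-tied coarser partition is
    often the more interpretable choice.
    """
    n = dm.n if isinstance(dm, DistMatrix) else np.asarray(dm).shape[0]
    if k_max is None:
        k_max = n - 1
    k_max = min(k_max, n - 1)
    if k_min < 2 or k_min > k_max:
        raise ValueError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    per_k = {}
    for k in range(k_min, k_max + 1):
        labels = cut_tree(Z, k)
        w = silhouette_widths(dm, labels)
        per_k[k] = (w, float(np.mean(w)))
    ks = sorted(per_k)
    avgs = {k: per_k[k][1] for k in ks}
    optimal_k = max(ks, key=lambda k: (avgs[k], -k))
    # local maxima of the profile curve
    loc = []
    for i, k in enumerate(ks):
        left = avgs[ks[i - 1]] if i > 0 else -np.inf
        right = avgs[ks[i + 1]] if i < len(ks) - 1 else -np.inf
        if avgs[k] >= left and avgs[k] >= right:
            loc.append(k)
    loc.sort(key=lambda k: (-avgs[k], k))
    return SilhouetteProfile(per_k, optimal_k, loc[:n_optima])


@dataclass
class FragmentationReport:
    """Cluster membership of each comparison and the fragmented set."""

    per_comparison: dict  # comparison -> {cluster: pct of its rows}
    fragmented: list  # comparisons spanning >= 2 clusters
    eloping_pct: dict  # comparison -> pct of rows outside the modal cluster
    n_clusters: int
    scenario: str  # none / a / b / c / d taxonomy tag
    elope_threshold_pct: float = 5.0

    def to_dict(self) -> dict:
        return {
            "per_comparison": {c: dict(v) for c, v in self.per_comparison.items()},
            "fragmented": list(self.fragmented),
            "eloping_pct": dict(self.eloping_pct),
            "n_clusters": self.n_clusters,
            "scenario": self.scenario,
            "elope_threshold_pct": self.elope_threshold_pct,
        }


def _scenario_tag(
    n_clusters: int,
    n_comparisons: int,
    n_fragmented: int,
    eloping: dict,
    elope_threshold_pct: float,
) -> str:
    """Coarse taxonomy of fragmentation severity.

    "none": no fragmented comparison.  "a": two or three clusters, few
    fragmented comparisons whose eloping share stays at or below the
    threshold — transitivity may be plausible.  "b": two clusters splitting
    the network into subnetworks, isolated fragmentation with larger eloping
    shares.  "c": two clusters but fragmentation affects most comparisons.
    "d": more than two clusters with widespread fragmentation.
    """
    if n_fragmented == 0:
        return "none"
    frag_frac = n_fragmented / n_comparisons
    small_elopes = all(
        eloping[c] <= elope_threshold_pct for c in eloping if eloping[c] > 0
    )
    if n_clusters <= 3 and small_elopes:
        return "a"
    if n_clusters == 2:
        return "b" if frag_frac <= 0.5 else "c"
    return "d"


def fragmented_comparisons(
    labels: np.ndarray,
    ct: ComparisonTable,
    elope_threshold_pct: float = 5.0,
) -> FragmentationReport:
    """Identify comparisons whose rows span two or more clusters."""
    labels = np.asarray(labels)
    if len(labels) != ct.n_rows:
        raise ValueError("labels must align with the comparison table rows")
    per: dict = {}
    eloping: dict = {}
    fragmented = []
    for comp in ct.comparisons:
        idx = ct.indices_of(comp)
        sub = labels[idx]
        clusters, counts = np.unique(sub, return_counts=True)
        pct = {int(c): 100.0 * n / len(sub) for c, n in zip(clusters, counts)}
        per[comp] = pct
        modal = clusters[np.argmax(counts)]
        eloping[comp] = 100.0 * (sub != modal).sum() / len(sub)
        if len(clusters) >= 2:
            fragmented.append(comp)
    n_clusters = len(np.unique(labels))
    scenario = _scenario_tag(
        n_clusters, ct.n_comparisons, len(fragmented), eloping, elope_threshold_pct
    )
    return FragmentationReport(per, fragmented, eloping, n_clusters, scenario,
                               elope_threshold_pct)


class TransitivityClustering(BaseEstimator, ClusterMixin):
    """Agglomerative clustering with CCC linkage and silhouette k selection.

    Accepts a precomputed square dissimilarity matrix (or a
    :class:`~nmatransit.gower.DistMatrix`) in ``fit``, in the spirit of
    sklearn clusterers with ``metric="precomputed"``.

    Parameters
    ----------
    linkage : str, default "auto"
        A Lance-Williams method, or "auto" to pick the highest-CCC method.
    n_clusters : int or "auto", default "auto"
        Partition size, or "auto" to maximise the overall average silhouette
        width over k = 2 .. n-1.
    methods : sequence of str
        Candidate linkage methods for "auto" selection (also the tie-break
        preference order).
    random_state : int or None
        Seed for randomised CCC tie-breaking; None keeps the deterministic
        preference order.
    k_max : int or None
        Upper bound for the silhouette scan (default n-1).

    Attributes
    ----------
    linkage_ : str
        Chosen linkage method.
    ccc_by_method_ : dict
        CCC per candidate method (only the chosen one when ``linkage`` fixed).
    merge_tree_ : ndarray
        scipy linkage matrix (n-1 merges).
    silhouette_profile_ : SilhouetteProfile
    n_clusters_ : int
    labels_ : ndarray
        Cluster label per observation at ``n_clusters_``.
    """

    def __init__(
        self,
        linkage: str = "auto",
        n_clusters="auto",
        methods: Sequence[str] = LINKAGE_METHODS,
        random_state: Optional[int] = None,
        k_max: Optional[int] = None,
    ):
        self.linkage = linkage
        self.n_clusters = n_clusters
        self.methods = methods
        self.random_state = random_state
        self.k_max = k_max

    def fit(self, X, y=None):
        dm = X
        if self.linkage == "auto":
            rng = (np.random.default_rng(self.random_state)
                   if self.random_state is not None else None)
            self.linkage_, self.ccc_by_method_ = select_linkage(dm, self.methods, rng)
        else:
            self.linkage_ = self.linkage
            Z0 = agglomerate(dm, self.linkage_)
            self.ccc_by_method_ = {self.linkage_: cophenetic_correlation(dm, Z0)}
        self.merge_tree_ = agglomerate(dm, self.linkage_)
        self.silhouette_profile_ = silhouette_profile(dm, self.merge_tree_,
                                                      k_max=self.k_max)
        if self.n_clusters == "auto":
            self.n_clusters_ = self.silhouette_profile_.optimal_k
        else:
            self.n_clusters_ = int(self.n_clusters)
        self.labels_ = cut_tree(self.merge_tree_, self.n_clusters_)
        self.silhouette_widths_ = self.silhouette_profile_.per_k.get(
            self.n_clusters_, (silhouette_widths(dm, self.labels_), None)
        )[0]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
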