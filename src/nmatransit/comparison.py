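"""Within- and between-comparison dissimilarities and their classification.

The expanded pairwise matrix ``{d}`` is condensed to the P observed treatment
comparisons.  The *within-comparison dissimilarity* ``D_p^W`` of a comparison
informed by h rows is the root mean square of the ``C(h, 2)`` pairwise Gower
values among those rows (the population standard deviation about zero: spread
from complete similarity, not from the mean).  The *between-comparison
dissimilarity* ``D_pp'^B`` is the RMS over the ``h * h'`` cross pairs.  Both
live in [0, 1] and populate the symmetric ``{D}_{P x P}`` matrix — within on
the diagonal, between off-diagonal.

Each entry is then classified against a threshold of "low" dissimilarity: the
median of an empirical predictive distribution for the I^2 statistic expected
in a future meta-analysis, indexed by outcome type, treatment-comparator type
and average study size.  An entry strictly below the threshold is "low";
otherwise it is "likely concerning".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import ComparisonTable
from .gower import DistMatrix

LOW = "low"
CONCERNING = "likely_concerning"


def _rms(values: np.ndarray) -> float:
    """Root mean square about zero (population form)."""
    v = np.asarray(values, dtype=float)
    return float(np.sqrt(np.mean(v**2)))


def _pair_values(dm: DistMatrix, idx_a: np.ndarray, idx_b: np.ndarray, within: bool):
    """Collect defined pair values of a block, counting dropped undefined pairs."""
    vals, n_undef = [], 0
    if within:
        pairs = [(idx_a[i], idx_a[j]) for i in range(len(idx_a)) for j in range(i + 1, len(idx_a))]
    else:
        pairs = [(i, j) for i in idx_a for j in idx_b]
    for i, j in pairs:
        if dm.defined[i, j]:
            vals.append(dm.values[i, j])
        else:
            n_undef += 1
    return np.asarray(vals), n_undef


def within_comparison_dissimilarity(dm: DistMatrix, ct: ComparisonTable, p: str) -> float:
    """RMS dissimilarity among the rows informing comparison ``p``.

    A single-study comparison has zero within-comparison dissimilarity.
    Returns NaN if every backing pair is undefined.
    """
    idx = ct.indices_of(p)
    if len(idx) == 1:
        return 0.0
    vals, n_undef = _pair_values(dm, idx, idx, within=True)
    if len(vals) == 0:
        warnings.warn(
            f"comparison {p!r}: all {n_undef} backing pair(s) undefined",
            UserWarning, stacklevel=2,
        )
        return float("nan")
    return _rms(vals)


def between_comparison_dissimilarity(
    dm: DistMatrix, ct: ComparisonTable, p: str, p2: str
) -> float:
    """RMS dissimilarity between the rows of comparisons ``p`` and ``p2``.

    Cross pairs coming from one multi-arm study (a study informing both
    comparisons) contribute their zero dissimilarity — they are elements of
    the designated block of ``{d}`` like any other pair.
    """
    if p == p2:
        raise ValueError("between-comparison dissimilarity needs two distinct comparisons")
    ia, ib = ct.indices_of(p), ct.indices_of(p2)
    vals, n_undef = _pair_values(dm, ia, ib, within=False)
    if len(vals) == 0:
        warnings.warn(
            f"comparisons {p!r} vs {p2!r}: all {n_undef} backing pair(s) undefined",
            UserWarning, stacklevel=2,
        )
        return float("nan")
    return _rms(vals)


@dataclass
class ComparisonDissimMatrix:
    """Symmetric ``{D}_{P x P}``: within on the diagonal, between off it."""

    comparisons: list
    values: np.ndarray  # P x P
    n_pairs: np.ndarray  # pair counts backing each cell

    @property
    def P(self) -> int:
        return len(self.comparisons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.comparisons, columns=self.comparisons)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_comparison_matrix(dm: DistMatrix, ct: ComparisonTable) -> ComparisonDissimMatrix:
    """Aggregate ``{d}`` into the comparison-level matrix ``{D}``."""
    comps = ct.comparisons
    P = len(comps)
    if P < 2:
        raise ValueError("need at least two observed comparisons")
    D = np.zeros((P, P))
    n_pairs = np.zeros((P, P), dtype=int)
    counts = ct.study_counts()
    for a in range(P):
        h = counts[comps[a]]
        D[a, a] = within_comparison_dissimilarity(dm, ct, comps[a])
        n_pairs[a, a] = math.comb(h, 2)
        for b in range(a + 1, P):
            D[a, b] = D[b, a] = between_comparison_dissimilarity(dm, ct, comps[a], comps[b])
            n_pairs[a, b] = n_pairs[b, a] = h * counts[comps[b]]
    return ComparisonDissimMatrix(list(comps), D, n_pairs)


# ---------------------------------------------------------------------------
# Threshold of "low" dissimilarity
# ---------------------------------------------------------------------------

OUTCOMES = ("all-cause mortality", "semi-objective", "subjective", "general")
COMPARATORS = ("pharm vs placebo/control", "pharm vs pharm", "non-pharmacological", "general")
SIZE_BUCKETS = ("<50", "50-200", ">200", "general")

#: median (threshold) and 95% interval of the predictive I^2 distribution
#: for a future meta-analysis with mixed outcome data, by design factors.
THRESHOLDS: dict = {
    ("general", "general", "general"): (0.13, (0.0002, 0.99)),
    # size < 50
    ("all-cause mortality", "pharm vs placebo/control", "<50"): (0.0007, (1e-6, 0.91)),
    ("all-cause mortality", "pharm vs pharm", "<50"): (0.0004, (1e-6, 0.76)),
    ("all-cause mortality", "non-pharmacological", "<50"): (0.0007, (1e-6, 0.87)),
    ("semi-objective", "pharm vs placebo/control", "<50"): (0.06, (0.00008, 0.97)),
    ("semi-objective", "pharm vs pharm", "<50"): (0.04, (0.00009, 0.89)),
    ("semi-objective", "non-pharmacological", "<50"): (0.06, (0.00006, 0.98)),
    ("subjective", "pharm vs placebo/control", "<50"): (0.25, (0.006, 0.94)),
    ("subjective", "pharm vs pharm", "<50"): (0.16, (0.01, 0.80)),
    ("subjective", "non-pharmacological", "<50"): (0.24, (0.003, 0.97)),
    # size 50-200
    ("all-cause mortality", "pharm vs placebo/control", "50-200"): (0.0007, (1e-6, 0.89)),
    ("all-cause mortality", "pharm vs pharm", "50-200"): (0.0004, (1e-6, 0.74)),
    ("all-cause mortality", "non-pharmacological", "50-200"): (0.0007, (1e-6, 0.86)),
    ("semi-objective", "pharm vs placebo/control", "50-200"): (0.06, (0.00008, 0.97)),
    ("semi-objective", "pharm vs pharm", "50-200"): (0.04, (0.00007, 0.90)),
    ("semi-objective", "non-pharmacological", "50-200"): (0.06, (0.00005, 0.98)),
    ("subjective", "pharm vs placebo/control", "50-200"): (0.25, (0.005, 0.94)),
    ("subjective", "pharm vs pharm", "50-200"): (0.16, (0.01, 0.79)),
    ("subjective", "non-pharmacological", "50-200"): (0.23, (0.003, 0.97)),
    # size > 200
    ("all-cause mortality", "pharm vs placebo/control", ">200"): (0.0008, (1e-6, 0.91)),
    ("all-cause mortality", "pharm vs pharm", ">200"): (0.0005, (1e-6, 0.75)),
    ("all-cause mortality", "non-pharmacological", ">200"): (0.0007, (1e-6, 0.88)),
    ("semi-objective", "pharm vs placebo/control", ">200"): (0.07, (0.0001, 0.97)),
    ("semi-objective", "pharm vs pharm", ">200"): (0.04, (0.00009, 0.91)),
    ("semi-objective", "non-pharmacological", ">200"): (0.06, (0.00006, 0.98)),
    ("subjective", "pharm vs placebo/control", ">200"): (0.28, (0.0006, 0.95)),
    ("subjective", "pharm vs pharm", ">200"): (0.18, (0.01, 0.82)),
    ("subjective", "non-pharmacological", ">200"): (0.26, (0.003, 0.97)),
}


def size_bucket(mean_study_size: float) -> str:
    """Bucket for the unweighted mean of study total sample sizes."""
    if mean_study_size < 50:
        return "<50"
    if mean_study_size <= 200:
        return "50-200"
    return ">200"


def lookup_threshold(
    outcome: str = "general",
    comparator: str = "general",
    size: str = "general",
) -> float:
    """Threshold of "low" dissimilarity for the given design factors.

    The general healthcare setting (all three factors ``"general"``) has
    threshold 0.13; otherwise all three factors must be specific.
    """
    key = (outcome, comparator, size)
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; options: {OUTCOMES}")
    if comparator not in COMPARATORS:
        raise ValueError(f"unknown comparator {comparator!r}; options: {COMPARATORS}")
    if size not in SIZE_BUCKETS:
        raise ValueError(f"unknown size bucket {size!r}; options: {SIZE_BUCKETS}")
    if "general" in key and key != ("general", "general", "general"):
        raise ValueError(
            "design factors must be all 'general' or all specific; "
            f"got {key}"
        )
    return THRESHOLDS[key][0]


@dataclass
class ClassifiedMatrix:
    """``{D}`` plus per-cell low / likely-concerning labels."""

    base: ComparisonDissimMatrix
    threshold: float
    labels: np.ndarray  # dtype=object, LOW or CONCERNING

    def n_low_offdiagonal(self) -> int:
        P = self.base.P
        iu = np.triu_indices(P, k=1)
        return int((self.labels[iu] == LOW).sum())

    def fraction_low_offdiagonal(self) -> float:
        P = self.base.P
        return self.n_low_offdiagonal() / (P * (P - 1) // 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.labels, index=self.base.comparisons, columns=self.base.comparisons
        )


def classify(cm: ComparisonDissimMatrix, threshold: float) -> ClassifiedMatrix:
    """Label each cell: strictly below the threshold is "low"."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    labels = np.where(cm.values < threshold, LOW, CONCERNING).astype(object)
    return ClassifiedMatrix(cm, threshold, labels)
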