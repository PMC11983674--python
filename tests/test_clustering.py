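"""Hierarchical clustering, CCC linkage selection, silhouettes, fragmentation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import squareform

from nmatransit import (
    CharacteristicSpec,
    LINKAGE_METHODS,
    Study,
    StudyDataset,
    agglomerate,
    cophenetic_correlation,
    cut_tree,
    expand_comparisons,
    fragmented_comparisons,
    select_linkage,
    silhouette_profile,
    silhouette_widths,
)

from conftest import set_partitions


def _square(cond, n):
    return squareform(np.asarray(cond), checks=False).reshape(n, n)


def _random_matrix(rng, n):
    cond = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
    return squareform(cond)


class TestAgglomerate:
    def test_two_observations_merge_at_their_distance(self):
        m = np.array([[0.0, 0.37], [0.37, 0.0]])
        Z = agglomerate(m, "average")
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.37)

    def test_forced_merge_order_average_linkage(self):
        # d(A,B) = 0.1, d(A,C) = d(B,C) = 0.9: AB first, then at 0.9
        m = squareform([0.1, 0.9, 0.9])
        Z = agglomerate(m, "average")
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)

    @pytest.mark.parametrize("method", ["single", "complete"])
    def test_heights_match_brute_force_cross_pair_oracle(self, method):
        """Naive agglomeration with min/max over cross pairs reproduces the
        merge heights on random 8-point matrices."""
        rng = np.random.default_rng(42)
        agg = min if method == "single" else max
        for _ in range(10):
            m = _random_matrix(rng, 8)
            Z = agglomerate(m, method)
            # brute force: merge closest clusters under the cross-pair rule
            clusters = [[i] for i in range(8)]
            heights = []
            while len(clusters) > 1:
                best = None
                for a, b in itertools.combinations(range(len(clusters)), 2):
                    d = agg(m[i, j] for i in clusters[a] for j in clusters[b])
                    if best is None or d < best[0]:
                        best = (d, a, b)
                d, a, b = best
                heights.append(d)
                merged = clusters[a] + clusters[b]
                clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
                clusters.append(merged)
            np.testing.assert_allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-12)

    def test_undefined_entries_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            agglomerate(m, "average")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown linkage"):
            agglomerate(np.zeros((2, 2)), "quadratic")


class TestCophenetic:
    def test_ultrametric_input_gives_ccc_one(self):
        # feed tree-implied distances back in: perfect preservation
        rng = np.random.default_rng(3)
        m = _random_matrix(rng, 9)
        Z = agglomerate(m, "average")
        from scipy.cluster.hierarchy import cophenet

        ultra = squareform(cophenet(Z))
        Z2 = agglomerate(ultra, "average")
        assert cophenetic_correlation(ultra, Z2) == pytest.approx(1.0, abs=1e-12)

    def test_four_point_hand_example(self):
        # d(A,B)=0.2, d(C,D)=0.3, cross: AC 0.8, AD 0.9, BC 1.0, BD 0.7.
        # average linkage: AB at 0.2, CD at 0.3, then at (0.8+0.9+1.0+0.7)/4.
        cond = np.array([0.2, 0.8, 0.9, 1.0, 0.7, 0.3])  # AB AC AD BC BD CD
        m = squareform(cond)
        Z = agglomerate(m, "average")
        manual_coph = np.array([0.2, 0.85, 0.85, 0.85, 0.85, 0.3])
        expected = np.corrcoef(cond, manual_coph)[0, 1]
        assert cophenetic_correlation(m, Z) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_ccc_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_matrix(rng, int(rng.integers(4, 10)))
        for method in ("average", "single", "ward"):
            c = cophenetic_correlation(m, agglomerate(m, method))
            assert -1 - 1e-12 <= c <= 1 + 1e-12

    def test_zero_variance_flagged_undefined(self):
        m = squareform([0.5, 0.5, 0.5])
        Z = agglomerate(m, "single")
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(cophenetic_correlation(m, Z))


class TestLinkageSelection:
    def test_argmax_ccc_selected(self):
        rng = np.random.default_rng(11)
        m = _random_matrix(rng, 10)
        best, ccc = select_linkage(m)
        finite = {k: v for k, v in ccc.items() if np.isfinite(v)}
        assert best in finite
        assert finite[best] == pytest.approx(max(finite.values()))

    def test_tie_breaks_by_preference_order(self):
        # two points: every linkage gives the same (degenerate) tree, and CCC
        # is undefined; on 3 equidistant-ish points all methods tie
        m = squareform([0.2, 0.4, 0.6])
        best, ccc = select_linkage(m, methods=("complete", "single", "average"))
        vals = list(ccc.values())
        assert np.allclose(vals, vals[0])
        assert best == "complete"  # first of the supplied preference order

    def test_seeded_random_tie_breaking_is_reproducible(self):
        m = squareform([0.2, 0.4, 0.6])
        picks = {select_linkage(m, rng=np.random.default_rng(s))[0] for s in range(20)}
        assert picks <= set(LINKAGE_METHODS)
        assert len(picks) > 1  # randomisation actually exercises the tie
        a = select_linkage(m, rng=np.random.default_rng(5))[0]
        b = select_linkage(m, rng=np.random.default_rng(5))[0]
        assert a == b


class TestSilhouette:
    def test_perfectly_separated_clusters_score_one(self):
        m = np.ones((4, 4)) - np.eye(4)
        m[0, 1] = m[1, 0] = 0.0
        m[2, 3] = m[3, 2] = 0.0
        w = silhouette_widths(m, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(w, 1.0)

    def test_singleton_cluster_member_scores_zero(self):
        m = squareform([0.1, 0.9, 0.8])
        w = silhouette_widths(m, np.array([0, 0, 1]))
        assert w[2] == 0.0

    def test_k_outside_range_rejected(self):
        m = squareform([0.1, 0.9, 0.8])
        with pytest.raises(ValueError):
            silhouette_widths(m, np.array([0, 0, 0]))
        with pytest.raises(ValueError):
            silhouette_widths(m, np.array([0, 1, 2]))

    def test_matches_exhaustive_oracle_on_all_partitions(self):
        """Every partition of 7 points agrees with the direct a/b definition."""
        rng = np.random.default_rng(19)
        n = 7
        m = _random_matrix(rng, n)
        for part in set_partitions(range(n)):
            k = len(part)
            if not (2 <= k <= n - 1):
                continue
            labels = np.empty(n, dtype=int)
            for ci, block in enumerate(part):
                labels[list(block)] = ci
            got = silhouette_widths(m, labels)
            for i in range(n):
                own = [j for j in range(n) if labels[j] == labels[i] and j != i]
                if not own:
                    expected = 0.0
                else:
                    a = np.mean([m[i, j] for j in own])
                    b = min(
                        np.mean([m[i, j] for j in range(n) if labels[j] == c])
                        for c in range(k) if c != labels[i]
                    )
                    expected = (b - a) / max(a, b)
                assert got[i] == pytest.approx(expected, abs=1e-12)


class TestProfileAndCuts:
    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_successive_cuts_are_nested(self, seed):
        """Going from k to k+1 clusters splits exactly one cluster."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        m = _random_matrix(rng, n)
        Z = agglomerate(m, "average")
        for k in range(2, n - 1):
            a, b = cut_tree(Z, k), cut_tree(Z, k + 1)
            # each finer cluster maps into exactly one coarser cluster
            mapping = {}
            for fine, coarse in zip(b, a):
                mapping.setdefault(fine, set()).add(coarse)
            assert all(len(v) == 1 for v in mapping.values())
            assert len(set(map(tuple, mapping.values()))) == k

    def test_profile_reports_argmax_and_local_optima(self):
        m = np.ones((6, 6)) - np.eye(6)
        for block in ([0, 1], [2, 3], [4, 5]):
            for i in block:
                for j in block:
                    m[i, j] = 0.0 if i != j else 0.0
        Z = agglomerate(m, "average")
        prof = silhouette_profile(m, Z)
        assert prof.optimal_k == 3
        assert prof.optimal_average == pytest.approx(1.0)
        assert prof.k_range == [2, 3, 4, 5]
        assert prof.local_optima[0] == 3


class TestFragmentation:
    def _table(self, design):
        specs = [CharacteristicSpec("x", "quantitative")]
        studies = [Study(f"S{i}", arms, {"x": float(i)})
                   for i, arms in enumerate(design)]
        return expand_comparisons(StudyDataset(studies, specs))

    def test_unfragmented_network(self):
        ct = self._table([("A", "B")] * 3 + [("A", "C")] * 2)
        rep = fragmented_comparisons(np.array([0, 0, 0, 1, 1]), ct)
        assert rep.fragmented == []
        assert rep.scenario == "none"
        for pct in rep.per_comparison.values():
            assert sum(pct.values()) == pytest.approx(100.0)

    def test_eloping_percentage(self):
        ct = self._table([("A", "B")] * 5 + [("A", "C")])
        rep = fragmented_comparisons(np.array([0, 0, 0, 0, 1, 1]), ct)
        assert rep.fragmented == ["A vs B"]
        assert rep.eloping_pct["A vs B"] == pytest.approx(20.0)
        assert rep.per_comparison["A vs B"] == {0: 80.0, 1: 20.0}

    def test_scenario_tags(self):
        ct = self._table([("A", "B")] * 5 + [("A", "C")] * 5)
        # two clusters, one fragmented comparison with 20% eloping -> "b"
        rep = fragmented_comparisons(np.array([0] * 5 + [1, 0, 1, 1, 1]), ct)
        assert rep.scenario == "b"
        # widespread fragmentation in two clusters -> "c"
        rep2 = fragmented_comparisons(np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1]), ct)
        assert rep2.scenario == "c"

    def test_labels_length_checked(self):
        ct = self._table([("A", "B"), ("A", "C")])
        with pytest.raises(ValueError, match="align"):
            fragmented_comparisons(np.array([0]), ct)
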