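"""RMS comparison-level dissimilarities, thresholds and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmatransit import (
    CharacteristicSpec,
    DistMatrix,
    Study,
    StudyDataset,
    between_comparison_dissimilarity,
    build_comparison_matrix,
    build_dissimilarity_matrix,
    classify,
    expand_comparisons,
    lookup_threshold,
    size_bucket,
    within_comparison_dissimilarity,
)
from nmatransit.comparison import CONCERNING, LOW

from conftest import random_mixed_dataset


def _dist_for(values_by_study, comparisons):
    """Tiny network: one binary characteristic is irrelevant; we inject the
    pairwise matrix directly to control the Gower values exactly."""
    specs = [CharacteristicSpec("x", "quantitative")]
    studies = [Study(f"S{i}", arms, {"x": 0.0})
               for i, arms in enumerate(comparisons)]
    ds = StudyDataset(studies, specs)
    ct = expand_comparisons(ds)
    n = ct.n_rows
    vals = np.zeros((n, n))
    for (i, j), v in values_by_study.items():
        vals[i, j] = vals[j, i] = v
    return DistMatrix(ct.labels, vals, np.ones((n, n), bool)), ct


class TestWithin:
    def test_rms_arithmetic(self):
        # three studies of one comparison with pair values {0.3, 0.4, 0.0}
        dm, ct = _dist_for({(0, 1): 0.3, (0, 2): 0.4, (1, 2): 0.0},
                           [("A", "B")] * 3 + [("A", "C")])
        got = within_comparison_dissimilarity(dm, ct, "A vs B")
        assert got == pytest.approx(math.sqrt((0.09 + 0.16 + 0.0) / 3))
        # cross pairs {0.3, 0.4} -> sqrt((0.09 + 0.16)/2) = 0.35355...
        dm2, ct2 = _dist_for({(0, 2): 0.3, (1, 2): 0.4},
                             [("A", "B"), ("A", "B"), ("A", "C")])
        got2 = between_comparison_dissimilarity(dm2, ct2, "A vs B", "A vs C")
        assert got2 == pytest.approx(0.35355, abs=5e-6)

    def test_single_study_comparison_is_zero(self):
        dm, ct = _dist_for({(0, 1): 0.9}, [("A", "B"), ("A", "C")])
        assert within_comparison_dissimilarity(dm, ct, "A vs C") == 0.0


class TestBetween:
    def test_extremes(self):
        dm0, ct0 = _dist_for({}, [("A", "B"), ("A", "C")])
        assert between_comparison_dissimilarity(dm0, ct0, "A vs B", "A vs C") == 0.0
        dm1, ct1 = _dist_for({(0, 1): 1.0}, [("A", "B"), ("A", "C")])
        assert between_comparison_dissimilarity(dm1, ct1, "A vs B", "A vs C") == 1.0

    def test_same_comparison_rejected(self):
        dm, ct = _dist_for({}, [("A", "B"), ("A", "C")])
        with pytest.raises(ValueError, match="distinct"):
            between_comparison_dissimilarity(dm, ct, "A vs B", "A vs B")

    def test_multiarm_same_study_zero_pairs_included(self):
        """The two comparisons of a 3-arm study contribute their zero pair."""
        specs = [CharacteristicSpec("x", "quantitative")]
        studies = [Study("S1", ("A", "B", "C"), {"x": 0.0}),
                   Study("S2", ("A", "B"), {"x": 10.0})]
        ds = StudyDataset(studies, specs)
        ct = expand_comparisons(ds)
        dm = build_dissimilarity_matrix(ct, ds=ds)
        # "A vs B" rows: S1 (x=0), S2 (x=10); "A vs C": S1 only.
        # cross pairs: (S1 AB, S1 AC) = 0 (same study) and (S2 AB, S1 AC) = 1
        got = between_comparison_dissimilarity(dm, ct, "A vs B", "A vs C")
        assert got == pytest.approx(math.sqrt((0.0 + 1.0) / 2))


class TestOracle:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_within_between_match_naive_loops(self, seed):
        import warnings

        ds = random_mixed_dataset(seed, missing_rate=0.1)
        ct = expand_comparisons(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = build_dissimilarity_matrix(ct, ds=ds)
            cm = build_comparison_matrix(dm, ct)
        comps = cm.comparisons
        for a, p in enumerate(comps):
            ia = ct.indices_of(p)
            vals = [dm.values[i, j] for ii, i in enumerate(ia) for j in ia[ii + 1:]
                    if dm.defined[i, j]]
            expected = math.sqrt(sum(v * v for v in vals) / len(vals)) if vals else 0.0
            if len(ia) == 1:
                expected = 0.0
            if vals or len(ia) == 1:
                assert cm.values[a, a] == pytest.approx(expected, abs=1e-12)
            for b in range(a + 1, len(comps)):
                ib = ct.indices_of(comps[b])
                cross = [dm.values[i, j] for i in ia for j in ib if dm.defined[i, j]]
                if cross:
                    expected = math.sqrt(sum(v * v for v in cross) / len(cross))
                    assert cm.values[a, b] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_rms_bounds_and_power_mean_inequality(self, seed):
        import warnings

        ds = random_mixed_dataset(seed, missing_rate=0.0)
        ct = expand_comparisons(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = build_dissimilarity_matrix(ct, ds=ds)
            cm = build_comparison_matrix(dm, ct)
        assert np.all(cm.values >= -1e-15) and np.all(cm.values <= 1 + 1e-15)
        # RMS >= arithmetic mean of the same values
        for a, p in enumerate(cm.comparisons):
            ia = ct.indices_of(p)
            vals = [dm.values[i, j] for ii, i in enumerate(ia) for j in ia[ii + 1:]]
            if vals:
                assert cm.values[a, a] >= np.mean(vals) - 1e-12

    def test_duplicating_the_closest_study_never_increases_within(self):
        """Appending a copy of the study closest to the rest of its comparison
        adds a zero pair plus duplicates of below-average pairs, so the RMS
        cannot increase."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            h = int(rng.integers(2, 6))
            specs = [CharacteristicSpec("x", "quantitative")]
            xs = rng.uniform(0, 10, size=h)
            studies = [Study(f"S{i}", ("A", "B"), {"x": float(x)})
                       for i, x in enumerate(xs)]
            ds = StudyDataset(studies + [Study("T", ("A", "C"), {"x": 0.0})], specs)
            ct = expand_comparisons(ds)
            dm = build_dissimilarity_matrix(ct, ds=ds)
            before = within_comparison_dissimilarity(dm, ct, "A vs B")
            # closest: smallest sum of squared dissimilarities to the others
            idx = ct.indices_of("A vs B")
            ssq = [(sum(dm.values[i, j] ** 2 for j in idx if j != i), i) for i in idx]
            best = min(ssq)[1]
            clone = Study("clone", ("A", "B"), dict(ct.rows[best].values))
            ds2 = StudyDataset(ds.studies + [clone], specs)
            ct2 = expand_comparisons(ds2)
            dm2 = build_dissimilarity_matrix(ct2, ds=ds2)
            after = within_comparison_dissimilarity(dm2, ct2, "A vs B")
            assert after <= before + 1e-12


class TestStructure:
    def test_matrix_layout_three_comparisons(self):
        dm, ct = _dist_for(
            {(0, 1): 0.2, (0, 2): 0.4, (1, 2): 0.6},
            [("A", "B"), ("A", "C"), ("B", "C")],
        )
        cm = build_comparison_matrix(dm, ct)
        assert cm.comparisons == ["A vs B", "A vs C", "B vs C"]
        np.testing.assert_allclose(np.diag(cm.values), 0.0)  # single-study each
        assert cm.values[1, 0] == cm.values[0, 1] == pytest.approx(0.2)
        assert cm.n_pairs[0, 1] == 1

    def test_pair_counts(self, fictional, fictional_table):
        dm = build_dissimilarity_matrix(fictional_table, ds=fictional)
        cm = build_comparison_matrix(dm, fictional_table)
        assert cm.n_pairs[0, 0] == 3  # C(3,2) for the three B-vs-A studies
        assert cm.n_pairs[0, 1] == 6  # 3 * 2 cross pairs


class TestThresholds:
    @pytest.mark.parametrize(
        "key,expected",
        [
            (("general", "general", "general"), 0.13),
            (("subjective", "pharm vs placebo/control", ">200"), 0.28),
            (("all-cause mortality", "pharm vs pharm", "<50"), 0.0004),
            (("semi-objective", "non-pharmacological", "50-200"), 0.06),
            (("subjective", "pharm vs pharm", ">200"), 0.18),
        ],
    )
    def test_lookup(self, key, expected):
        assert lookup_threshold(*key) == expected

    def test_unknown_enum_lists_options(self):
        with pytest.raises(ValueError, match="options"):
            lookup_threshold("objective", "general", "general")

    def test_size_bucket_from_mean_sample_size(self):
        assert size_bucket(283) == ">200"
        assert size_bucket(49.9) == "<50"
        assert size_bucket(200) == "50-200"


class TestClassification:
    def test_strictly_below_is_low(self):
        dm, ct = _dist_for({(0, 1): 0.26}, [("A", "B"), ("A", "C")])
        cm = build_comparison_matrix(dm, ct)
        cls = classify(cm, 0.28)
        assert cls.labels[0, 1] == LOW

    def test_equal_to_threshold_is_concerning(self):
        dm, ct = _dist_for({(0, 1): 0.28}, [("A", "B"), ("A", "C")])
        cls = classify(build_comparison_matrix(dm, ct), 0.28)
        assert cls.labels[0, 1] == CONCERNING

    def test_all_zero_matrix_all_low(self):
        dm, ct = _dist_for({}, [("A", "B"), ("A", "C"), ("B", "C")])
        cls = classify(build_comparison_matrix(dm, ct), 0.13)
        assert np.all(cls.labels == LOW)
        assert cls.fraction_low_offdiagonal() == 1.0
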