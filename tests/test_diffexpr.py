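"""Differential-expression screening: normalization, tests, calls, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cernet import diffexpr
from cernet.matrix import MatrixError

from conftest import make_matrix


class TestQuantileNormalize:
    def test_two_columns_become_sorted_row_means(self):
        em = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), n_pairs=1)
        out = diffexpr.quantile_normalize(em)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_identical_columns_are_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0])
        em = make_matrix(np.column_stack([col, col]), n_pairs=1)
        out = diffexpr.quantile_normalize(em)
        np.testing.assert_allclose(out.values.to_numpy(), em.values.to_numpy())

    def test_preserves_within_column_ranks(self):
        rng = np.random.default_rng(0)
        v = rng.normal(8, 1, size=(50, 6))
        em = make_matrix(v, n_pairs=3)
        out = diffexpr.quantile_normalize(em).values.to_numpy()
        for j in range(6):
            assert (np.argsort(out[:, j]) == np.argsort(v[:, j])).all()

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_on_ties_free_input(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(8, 1, size=(20, 4))
        em = make_matrix(v, n_pairs=2)
        once = diffexpr.quantile_normalize(em)
        twice = diffexpr.quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12)


class TestPairedTTest:
    def test_matches_direct_t_distribution_evaluation(self):
        diffs = np.array([0.8, 1.2, 0.9, 1.1])
        base = np.full(4, 8.0)
        vals = np.empty((1, 8))
        vals[0, 0::2] = base + diffs  # tumor
        vals[0, 1::2] = base  # normal
        em = make_matrix(vals, n_pairs=4)
        p = diffexpr.paired_t_test(em).loc["F000", "p_value"]
        t = diffs.mean() / (diffs.std(ddof=1) / 2.0)
        assert p == pytest.approx(2 * stats.t.sf(t, df=3), rel=1e-12)

    def test_all_zero_differences_give_p_one(self):
        vals = np.tile(np.array([8.0, 8.0, 9.0, 9.0, 7.0, 7.0]), (1, 1))
        em = make_matrix(vals, n_pairs=3)
        res = diffexpr.paired_t_test(em)
        assert res.loc["F000", "p_value"] == 1.0
        assert not res.loc["F000", "degenerate"]

    def test_constant_nonzero_difference_is_degenerate_p_zero(self):
        vals = np.array([[9.0, 8.0, 9.0, 8.0, 9.0, 8.0, 9.0, 8.0]])
        em = make_matrix(vals, n_pairs=4)
        res = diffexpr.paired_t_test(em)
        assert res.loc["F000", "p_value"] == 0.0
        assert bool(res.loc["F000", "degenerate"])

    def test_single_pair_rejected(self):
        em = make_matrix(np.array([[8.0, 7.0]]), n_pairs=1)
        with pytest.raises(MatrixError):
            diffexpr.paired_t_test(em)


class TestFoldChange:
    @pytest.mark.parametrize(
        "tumor,normal,expected_fc",
        [(9.0, 8.0, 2.0), (7.0, 8.0, 0.5), (8.0, 6.5, 2 ** 1.5)],
    )
    def test_geometric_mean_ratio(self, tumor, normal, expected_fc):
        vals = np.tile([tumor, normal], (1, 3))
        em = make_matrix(vals, n_pairs=3)
        fc = diffexpr.fold_change(em)
        assert fc.loc["F000", "fc"] == pytest.approx(expected_fc, rel=1e-12)
        assert 2 ** fc.loc["F000", "log2fc"] == pytest.approx(fc.loc["F000", "fc"])


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        assert diffexpr.bh_adjust([0.04])[0] == pytest.approx(0.04)
        np.testing.assert_allclose(diffexpr.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.1, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_monotonicity(self, pvals, rnd):
        q = diffexpr.bh_adjust(pvals)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q_perm = diffexpr.bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose(q_perm, [q[i] for i in perm], atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestScreenDE:
    # jitter values are binary-exact so the mean difference (hence fc) is exact
    def _matrix_with(self, diffs, jitter=(0.5, -0.5, 0.25, -0.25)):
        # per-pair differences diffs[i] + jitter, keeping mean(diff) = diffs
        vals = np.empty((len(diffs), 8))
        for i, d in enumerate(diffs):
            per_pair = d + np.asarray(jitter)
            vals[i, 0::2] = 8.0 + per_pair
            vals[i, 1::2] = 8.0
        return make_matrix(vals, n_pairs=4)

    def test_boundary_fold_change_two_is_up(self):
        em = self._matrix_with([1.0])  # fc exactly 2, small-variance p
        de = diffexpr.screen_de(em, mode="microarray")
        assert de.loc["F000", "fc"] == pytest.approx(2.0)
        assert de.loc["F000", "p_value"] < 0.05
        assert de.loc["F000", "regulation"] == "up"

    def test_boundary_half_is_down_and_big_p_is_ns(self):
        em = self._matrix_with([-1.0, 2.0])
        de = diffexpr.screen_de(em)
        assert de.loc["F000", "regulation"] == "down"
        # strong FC but noisy enough for large p -> ns
        noisy = self._matrix_with([0.3], jitter=(2.0, -1.5, 1.0, -0.3))
        de2 = diffexpr.screen_de(noisy)
        assert de2.loc["F000", "p_value"] > 0.05
        assert de2.loc["F000", "regulation"] == "ns"

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(3)
        em = make_matrix(rng.normal(8, 1, (100, 8)), n_pairs=4)
        de = diffexpr.screen_de(em)
        assert set(de["regulation"]) <= {"up", "down", "ns"}
        assert len(de) == 100
        up, down = set(diffexpr.regulated_ids(de, "up")), set(diffexpr.regulated_ids(de, "down"))
        assert not (up & down)

    def test_validation_preset_strict_boundary(self):
        em = self._matrix_with([1.0])
        de = diffexpr.screen_de(em, mode="validation")
        assert de.loc["F000", "regulation"] == "ns"  # fc == 2 not > 2


class TestIntersect:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B"}, {"C"}, []),
            ({"A", "B"}, {"A", "B"}, ["A", "B"]),
            ({"A", "B", "C"}, {"B", "C", "D"}, ["B", "C"]),
        ],
    )
    def test_exact_sorted_intersection(self, a, b, expected):
        assert diffexpr.intersect_sets(a, b) == expected


class TestCandidateFilter:
    @staticmethod
    def _annotation(rows):
        return pd.DataFrame(
            rows,
            columns=["accession", "chromosome", "feature_class", "length_nt", "lnc_category"],
        ).set_index("accession")

    @staticmethod
    def _de(rows):
        df = pd.DataFrame(
            rows,
            columns=["accession", "log2fc", "p_value", "regulation",
                     "mean_log2_tumor", "mean_log2_normal"],
        ).set_index("accession")
        df["fc"] = 2.0 ** df["log2fc"]
        return df

    def test_each_rule_removes_and_survivor_is_ranked(self):
        de = self._de([
            ("KEEP", -3.0, 0.001, "down", 4.5, 7.5),
            ("DIM", -2.5, 0.001, "down", 3.0, 6.0),     # intensity floor
            ("SEXCHR", 2.8, 0.001, "up", 8.0, 5.0),     # chrX
            ("LONG", 2.6, 0.001, "up", 8.0, 5.0),       # >= 2 kb
            ("EXSENSE", -2.2, 0.001, "down", 4.0, 7.4), # exonic sense
            ("SMALL", 1.5, 0.01, "up", 8.1, 6.6),       # survives, ranks after KEEP
            ("NS", 0.1, 0.9, "ns", 8.0, 8.0),
        ])
        ann = self._annotation([
            ("KEEP", "chr3", "lncRNA", 1500, "intergenic"),
            ("DIM", "chr2", "lncRNA", 1500, "intergenic"),
            ("SEXCHR", "chrX", "lncRNA", 1500, "intergenic"),
            ("LONG", "chr5", "lncRNA", 2500, "intergenic"),
            ("EXSENSE", "chr1", "lncRNA", 900, "exonic-sense"),
            ("SMALL", "chr9", "lncRNA", 800, "antisense"),
            ("NS", "chr1", "lncRNA", 700, "intergenic"),
        ])
        cands, removed = diffexpr.candidate_filter(de, ann)
        assert list(cands.index) == ["KEEP", "SMALL"]
        assert removed.loc["DIM", "rule"] == "intensity"
        assert removed.loc["SEXCHR", "rule"] == "sex_chromosome"
        assert removed.loc["LONG", "rule"] == "length"
        assert removed.loc["EXSENSE", "rule"] == "exonic_sense"
        assert "NS" not in cands.index and "NS" not in removed.index

    def test_missing_annotation_names_feature(self):
        de = self._de([("ORPHAN", 2.0, 0.01, "up", 8.0, 6.0)])
        ann = self._annotation([("OTHER", "chr1", "lncRNA", 500, "intergenic")])
        with pytest.raises(KeyError, match="ORPHAN"):
            diffexpr.candidate_filter(de, ann)
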