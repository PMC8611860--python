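"""Seed matching, correlation selection, partial correlation, MMI networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet import cerna
from cernet.cerna import CeRNATriplet

from conftest import make_matrix

RNA = st.text(alphabet="ACGU", min_size=0, max_size=60)


class TestSeedExtraction:
    @pytest.mark.parametrize(
        "mirna,seed", [("AUGGCUAAGCG", "UGGCUA"), ("ACGUACGUA", "CGUACG")]
    )
    def test_positions_two_to_seven(self, mirna, seed):
        assert cerna.seed_of(mirna) == seed

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cerna.seed_of("AUGGCU")

    def test_dna_input_normalized(self):
        assert cerna.seed_of("ATGGCTAAGCG") == "UGGCUA"

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            cerna.normalize_rna("AUGXCUA")


class TestSeedMatch:
    def test_worked_example_site_at_three(self):
        # seed UGGCUA -> site UAGCCA
        assert cerna.seed_match_sites("AUGGCUAAGCG", "GGGUAGCCAGG") == (3,)

    def test_absent_site_gives_none(self):
        assert cerna.has_seed_match("mir", "AUGGCUAAGCG", "t", "GGGGGGGGGG") is None

    def test_overlapping_sites_both_reported(self):
        assert cerna.seed_match_sites("AUGGCUAAGCG", "UAGCCAUAGCCA") == (0, 6)

    def test_match_invariant_positions_decode_site(self):
        m = cerna.has_seed_match("mir", "AUGGCUAAGCG", "t", "GGGUAGCCAGGUAGCCA")
        assert m.positions == (3, 11)
        target = "GGGUAGCCAGGUAGCCA"
        for p in m.positions:
            assert target[p:p + 6] == m.site

    @settings(deadline=None, max_examples=300)
    @given(st.text(alphabet="ACGU", min_size=7, max_size=25), RNA)
    def test_agrees_with_naive_substring_oracle(self, mirna, target):
        site = cerna.reverse_complement_rna(cerna.seed_of(mirna))
        naive = tuple(
            p for p in range(len(target) - 5) if target[p:p + 6] == site
        )
        assert cerna.seed_match_sites(mirna, target) == naive


class TestPairwiseCorrelation:
    def test_identical_profiles_give_one(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(8, 1, 10)
        lnc = make_matrix(prof[None, :], n_pairs=5, feature_ids=["L1"])
        mrna = make_matrix(prof[None, :], n_pairs=5, feature_ids=["M1"])
        corr = cerna.pairwise_correlation(lnc, mrna, "tumor")
        assert corr.loc["L1", "M1"] == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(1)
        n = 1000
        lnc = make_matrix(rng.normal(8, 1, (1, 2 * n)), n_pairs=n, feature_ids=["L1"])
        mrna = make_matrix(rng.normal(8, 1, (1, 2 * n)), n_pairs=n, feature_ids=["M1"])
        corr = cerna.pairwise_correlation(lnc, mrna, "tumor")
        assert abs(corr.loc["L1", "M1"]) < 3 / np.sqrt(n)

    def test_constant_feature_is_undefined(self):
        lnc = make_matrix(np.full((1, 8), 8.0), n_pairs=4, feature_ids=["L1"])
        rng = np.random.default_rng(2)
        mrna = make_matrix(rng.normal(8, 1, (1, 8)), n_pairs=4, feature_ids=["M1"])
        corr = cerna.pairwise_correlation(lnc, mrna, "tumor")
        assert np.isnan(corr.loc["L1", "M1"])

    def test_too_few_samples_rejected(self):
        lnc = make_matrix(np.ones((1, 4)), n_pairs=2, feature_ids=["L1"])
        mrna = make_matrix(np.ones((1, 4)), n_pairs=2, feature_ids=["M1"])
        with pytest.raises(ValueError):
            cerna.pairwise_correlation(lnc, mrna, "tumor")


class TestPercentileThreshold:
    def test_nearest_rank_on_101_values(self):
        vals = np.round(np.arange(101) / 100.0, 2)
        df = pd.DataFrame(vals[None, :], index=["L1"], columns=[f"M{i}" for i in range(101)])
        thr, selected = cerna.percentile_threshold({"tumor": df, "normal": df}, q=99)
        assert thr["tumor"] == pytest.approx(0.99)
        assert selected == [("L1", "M100")]

    def test_degenerate_equal_distribution_selects_nothing(self):
        df = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"), columns=list("xyz"))
        _, selected = cerna.percentile_threshold({"tumor": df, "normal": df}, q=99)
        assert selected == []

    def test_exceedance_required_in_both_conditions(self):
        base = np.zeros((1, 100))
        tumor = base.copy()
        tumor[0, 0] = 0.9  # exceeds only in tumor
        cols = [f"M{i}" for i in range(100)]
        t = pd.DataFrame(tumor, index=["L1"], columns=cols)
        n = pd.DataFrame(base, index=["L1"], columns=cols)
        _, selected = cerna.percentile_threshold({"tumor": t, "normal": n}, q=99)
        assert selected == []
        _, either = cerna.percentile_threshold({"tumor": t, "normal": n}, q=99, rule="either")
        assert either == [("L1", "M0")]

    def test_all_undefined_rejected(self):
        df = pd.DataFrame(np.full((2, 2), np.nan), index=list("ab"), columns=list("xy"))
        with pytest.raises(ValueError):
            cerna.percentile_threshold({"tumor": df, "normal": df})


class TestPartialCorrelation:
    @pytest.mark.parametrize(
        "rxy,rxz,rzy,expected",
        [
            (0.5, 0.0, 0.0, 0.5),
            (0.48, 0.8, 0.6, 0.0),
            (0.6, 0.5, 0.5, 0.35 / 0.75),
        ],
    )
    def test_formula_values(self, rxy, rxz, rzy, expected):
        assert cerna.partial_correlation(rxy, rxz, rzy) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_conditioning_raises(self):
        with pytest.raises(cerna.DegenerateCorrelationError):
            cerna.partial_correlation(0.5, 1.0, 0.3)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_residual_correlation_oracle(self, seed):
        # correlating the OLS residuals of X|Z and Y|Z reproduces the formula
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(60)
        x = -0.7 * z + 0.6 * rng.standard_normal(60)
        y = -0.7 * z + 0.6 * rng.standard_normal(60)
        c = np.corrcoef([x, y, z])
        got = cerna.partial_correlation(c[0, 1], c[0, 2], c[2, 1])
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert got == pytest.approx(oracle, abs=1e-10)


def _triplet(x="L1", z="R1", y="M1", sens=0.5):
    return CeRNATriplet(
        lncrna=x, mirna=z, mrna=y, rho_xy_normal=0.8, rho_xy_tumor=0.8,
        rho_xz=-0.7, rho_zy=-0.7, rho_xy_given_z=0.8 - sens, sensitivity=sens,
    )


class TestNetwork:
    def test_single_triplet_network(self):
        g = cerna.build_network([_triplet()])
        assert set(g.nodes) == {"L1", "M1"}
        assert g.nodes["L1"]["kind"] == "lncRNA"
        assert g.edges["L1", "M1"]["mediators"] == "R1"

    def test_shared_pair_unions_mediators(self):
        g = cerna.build_network([_triplet(z="R1"), _triplet(z="R2")])
        assert g.number_of_edges() == 1
        assert g.edges["L1", "M1"]["mediators"] == "R1,R2"

    def test_empty_network_and_pair_conservation(self):
        assert cerna.build_network([]).number_of_nodes() == 0
        trips = [_triplet(), _triplet(z="R2"), _triplet(y="M2"), _triplet(x="L2")]
        g = cerna.build_network(trips)
        assert g.number_of_edges() == len({(t.lncrna, t.mrna) for t in trips})

    def test_sif_export_one_line_per_edge(self, tmp_path):
        g = cerna.build_network([_triplet(), _triplet(z="R2")])
        p = tmp_path / "net.sif"
        cerna.export_network(g, p, "sif")
        assert p.read_text() == "L1\tmediates:R1,R2\tM1\n"

    def test_graphml_round_trip(self, tmp_path):
        g = cerna.build_network([_triplet(), _triplet(y="M2", z="R9")])
        p = tmp_path / "net.graphml"
        cerna.export_network(g, p, "graphml")
        back = cerna.network_from_graphml(p)
        assert set(back.nodes) == set(g.nodes)
        for u, v, data in g.edges(data=True):
            assert back.edges[u, v]["mediators"] == data["mediators"]

    def test_graphml_byte_deterministic_and_empty_valid(self, tmp_path):
        g = cerna.build_network([_triplet()])
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        cerna.export_network(g, p1, "graphml")
        cerna.export_network(g, p2, "graphml")
        assert p1.read_bytes() == p2.read_bytes()
        empty = tmp_path / "empty.graphml"
        cerna.export_network(cerna.build_network([]), empty, "graphml")
        assert cerna.network_from_graphml(empty).number_of_nodes() == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            cerna.export_network(cerna.build_network([]), tmp_path / "x", "dot")
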