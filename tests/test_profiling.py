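"""Quantile normalization, LFC vs vehicle, marker selection, GCT I/O."""

import numpy as np
import pandas as pd
import pytest

from ctscreen.gct import GctError, read_gct, write_gct
from ctscreen.profiling import (
    ProfilingError,
    lfc,
    marker_permutation_pvalues,
    marker_selection,
    quantile_normalize,
    top_markers,
)
from ctscreen.simulate import simulate_profiles


@pytest.fixture
def profile_data():
    spec = {"G0001": {"inducer": 2.0, "inhibitor": -2.0},
            "G0002": {"inducer": -1.5, "inhibitor": 1.5}}
    matrix, design = simulate_profiles(20, marker_spec=spec, noise_sd=0.2, seed=21)
    return matrix, design, spec


def _groups(matrix):
    a = [c for c in matrix.columns if c.startswith("inducer")]
    b = [c for c in matrix.columns if c.startswith("inhibitor")]
    return a, b


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        col = [3.0, 1.0, 2.0]
        m = pd.DataFrame({"s1": col, "s2": col, "s3": col})
        assert np.allclose(quantile_normalize(m), m)

    def test_all_columns_share_one_sorted_vector(self, profile_data):
        matrix, _, _ = profile_data
        qn = quantile_normalize(matrix)
        ref = np.sort(qn.iloc[:, 0].to_numpy())
        for col in qn.columns:
            assert np.allclose(np.sort(qn[col].to_numpy()), ref)

    def test_3x3_matches_hand_sort_average_unsort_oracle(self):
        m = pd.DataFrame(
            {"s1": [5.0, 2.0, 3.0], "s2": [4.0, 1.0, 6.0], "s3": [9.0, 7.0, 8.0]},
            index=["g1", "g2", "g3"],
        )
        # by hand: sorted columns (2,3,5), (1,4,6), (7,8,9); row means (10/3, 5, 20/3)
        expected = pd.DataFrame(
            {"s1": [20 / 3, 10 / 3, 5.0], "s2": [5.0, 10 / 3, 20 / 3],
             "s3": [20 / 3, 10 / 3, 5.0]},
            index=["g1", "g2", "g3"],
        )
        assert np.allclose(quantile_normalize(m), expected)

    def test_idempotent_with_equal_column_means(self, profile_data):
        matrix, _, _ = profile_data
        qn = quantile_normalize(matrix)
        assert np.allclose(quantile_normalize(qn), qn)
        means = qn.mean(axis=0).to_numpy()
        assert np.allclose(means, means[0])

    def test_single_sample_rejected(self):
        with pytest.raises(ProfilingError):
            quantile_normalize(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestLfc:
    def test_treated_equal_to_vehicle_gives_zero(self):
        m = pd.DataFrame({"v1": [4.0, 8.0], "v2": [4.0, 8.0],
                          "t1": [4.0, 8.0], "t2": [4.0, 8.0]}, index=["g1", "g2"])
        design = pd.DataFrame(
            {"treatment": ["DMSO", "DMSO", "drug", "drug"],
             "is_vehicle": [True, True, False, False]},
            index=["v1", "v2", "t1", "t2"],
        )
        assert np.allclose(lfc(m, design), 0.0)

    def test_exact_doubling_gives_lfc_one(self):
        m = pd.DataFrame({"v1": [4.0], "v2": [4.0], "t1": [8.0], "t2": [8.0]},
                         index=["g1"])
        design = pd.DataFrame(
            {"treatment": ["DMSO", "DMSO", "drug", "drug"],
             "is_vehicle": [True, True, False, False]},
            index=["v1", "v2", "t1", "t2"],
        )
        assert lfc(m, design).iloc[0, 0] == pytest.approx(1.0)

    def test_matches_bruteforce_per_gene_oracle(self, profile_data):
        matrix, design, _ = profile_data
        result = lfc(matrix, design)
        vehicle = [s for s in matrix.columns if s.startswith("DMSO")]
        treated = [s for s in matrix.columns if s.startswith("inducer")]
        for gene in matrix.index[:8]:
            expected = np.mean([np.log2(matrix.loc[gene, s]) for s in treated]) - \
                np.mean([np.log2(matrix.loc[gene, s]) for s in vehicle])
            assert result.loc[gene, "inducer_6h"] == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_global_positive_scaling(self, profile_data):
        matrix, design, _ = profile_data
        assert np.allclose(lfc(matrix * 37.5, design), lfc(matrix, design), atol=1e-10)

    def test_condition_without_vehicle_raises(self, profile_data):
        matrix, design, _ = profile_data
        bad = design.copy()
        bad.loc[bad["treatment"] == "inducer", "timepoint"] = "24h"
        with pytest.raises(ProfilingError, match="no matched vehicle"):
            lfc(matrix, bad)

    def test_spiked_genes_recover_their_lfc(self, profile_data):
        # estimator SE is noise_sd*sqrt(2/3) = 0.166 here; allow 4 SE
        matrix, design, spec = profile_data
        result = lfc(matrix, design)
        assert result.loc["G0001", "inducer_6h"] == pytest.approx(2.0, abs=0.67)
        assert result.loc["G0001", "inhibitor_6h"] == pytest.approx(-2.0, abs=0.67)


class TestMarkerSelection:
    def test_identical_groups_score_zero(self):
        m = pd.DataFrame({"a1": [1.0, 5.0], "a2": [2.0, 6.0],
                          "b1": [1.0, 5.0], "b2": [2.0, 6.0]}, index=["g1", "g2"])
        scores = marker_selection(m, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(scores["score"], 0.0)

    def test_antisymmetric_under_group_swap(self, profile_data):
        matrix, _, _ = profile_data
        a, b = _groups(matrix)
        ab = marker_selection(np.log2(matrix), a, b)
        ba = marker_selection(np.log2(matrix), b, a)
        assert np.allclose(ba["score"].loc[ab.index], -ab["score"], atol=1e-12)
        assert list(ba.sort_values("rank").index) == list(
            ab.sort_values("rank").index[::-1]
        )

    def test_matches_snr_formula_oracle_on_10_gene_fixture(self):
        spec = {"G0003": {"inducer": 3.0, "inhibitor": -3.0}}
        matrix, _ = simulate_profiles(10, marker_spec=spec, noise_sd=0.3, seed=4)
        values = np.log2(matrix)
        a, b = _groups(matrix)
        scores = marker_selection(values, a, b)
        for gene in values.index:
            va, vb = values.loc[gene, a], values.loc[gene, b]
            sda = max(va.std(ddof=1), max(0.2 * abs(va.mean()), 1e-8))
            sdb = max(vb.std(ddof=1), max(0.2 * abs(vb.mean()), 1e-8))
            expected = (va.mean() - vb.mean()) / (sda + sdb)
            assert scores.loc[gene, "score"] == pytest.approx(expected, rel=1e-10)
        assert scores["rank"].loc["G0003"] == 1  # largest opposite-sign response

    def test_ranks_are_a_permutation_matching_descending_scores(self, profile_data):
        matrix, _, _ = profile_data
        a, b = _groups(matrix)
        scores = marker_selection(np.log2(matrix), a, b)
        assert sorted(scores["rank"]) == list(range(1, len(scores) + 1))
        ordered = scores.sort_values("rank")["score"].to_numpy()
        assert (np.diff(ordered) <= 1e-12).all()

    def test_invariant_to_sample_order_within_groups(self, profile_data):
        matrix, _, _ = profile_data
        a, b = _groups(matrix)
        s1 = marker_selection(np.log2(matrix), a, b)
        s2 = marker_selection(np.log2(matrix), a[::-1], b[::-1])
        assert np.allclose(s1["score"], s2["score"])

    def test_undersized_group_rejected(self, profile_data):
        matrix, _, _ = profile_data
        a, b = _groups(matrix)
        with pytest.raises(ProfilingError, match=">= 2 samples"):
            marker_selection(np.log2(matrix), a[:1], b)

    def test_permutation_pvalues_flag_the_spiked_gene(self):
        spec = {"G0001": {"inducer": 4.0, "inhibitor": -4.0}}
        matrix, _ = simulate_profiles(12, marker_spec=spec, noise_sd=0.2, seed=8)
        a, b = _groups(matrix)
        p = marker_permutation_pvalues(np.log2(matrix), a, b, n_permutations=200, seed=1)
        assert p.loc["G0001"] == p.min()


class TestTopMarkers:
    def test_tails_in_rank_order_match_sort_then_slice_oracle(self, profile_data):
        matrix, _, _ = profile_data
        a, b = _groups(matrix)
        scores = marker_selection(np.log2(matrix), a, b)
        got = top_markers(scores, 3)
        ordered = scores.sort_values("score", ascending=False).index.tolist()
        assert got == ordered[:3] + ordered[-3:]
        assert len(got) == 6

    def test_sixty_gene_layout_from_thirty_per_tail(self):
        matrix, _ = simulate_profiles(100, noise_sd=0.2, seed=2)
        a, b = _groups(matrix)
        scores = marker_selection(np.log2(matrix), a, b)
        assert len(top_markers(scores, 30)) == 60

    def test_zero_tail_is_empty_and_oversize_rejected(self, profile_data):
        matrix, _, _ = profile_data
        a, b = _groups(matrix)
        scores = marker_selection(np.log2(matrix), a, b)
        assert top_markers(scores, 0) == []
        with pytest.raises(ProfilingError):
            top_markers(scores, len(scores))


class TestGct:
    def test_v12_round_trip(self, tmp_path, profile_data):
        matrix, _, _ = profile_data
        path = tmp_path / "m.gct"
        write_gct(matrix, path, version="1.2")
        assert path.read_text().startswith("#1.2\n20\t9\n")
        again = read_gct(path)
        assert list(again.index) == list(matrix.index)
        assert list(again.columns) == list(matrix.columns)
        assert np.allclose(again, matrix, rtol=1e-9)

    def test_v13_round_trip(self, tmp_path, profile_data):
        matrix, _, _ = profile_data
        path = tmp_path / "m13.gct"
        write_gct(matrix, path, version="1.3")
        assert path.read_text().startswith("#1.3\n")
        again = read_gct(path)
        assert np.allclose(again, matrix, rtol=1e-9)

    def test_bad_version_and_shape_rejected(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("#2.0\n1\t1\nName\tDescription\ts1\ng\td\t1.0\n")
        with pytest.raises(GctError, match="version"):
            read_gct(p)
        p.write_text("#1.2\n2\t1\nName\tDescription\ts1\ng\td\t1.0\n")
        with pytest.raises(GctError):
            read_gct(p)
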