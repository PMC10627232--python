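import numpy as np
import pytest
from scipy import stats

from seqrubric.stats_gate import (
    dunn_pairwise,
    normality_branch,
    pairwise_significance,
    tukey_pairwise,
)


def gaussian_groups(rng, k=4, n=100, shift=0.0):
    return {
        f"seq{i}": rng.normal(i * shift, 1.0, n) for i in range(k)
    }


class TestNormalityBranch:
    def test_gaussian_samples_choose_parametric(self):
        rng = np.random.default_rng(0)
        branch, warnings = normality_branch(gaussian_groups(rng, n=150))
        assert branch == "parametric"
        assert not warnings

    def test_bimodal_group_forces_nonparametric(self):
        rng = np.random.default_rng(1)
        groups = gaussian_groups(rng, n=150)
        groups["seq0"] = np.concatenate(
            [rng.normal(-6, 0.3, 75), rng.normal(6, 0.3, 75)]
        )
        branch, _ = normality_branch(groups)
        assert branch == "nonparametric"

    def test_tiny_samples_fall_back_with_warning(self):
        groups = {"a": np.array([1.0, 2.0]), "b": np.array([2.0, 3.0])}
        branch, warnings = normality_branch(groups)
        assert branch == "nonparametric"
        assert warnings


class TestPairwiseSignificance:
    def test_null_groups_show_no_significance(self):
        rng = np.random.default_rng(7)
        res = pairwise_significance(gaussian_groups(rng, shift=0.0, n=25))
        assert not any(
            res.significant(a, b)
            for a in res.sequence_ids
            for b in res.sequence_ids
            if a != b
        )

    def test_strong_separation_detected_on_both_branches(self):
        rng = np.random.default_rng(3)
        groups = {"lo": rng.normal(0, 1, 25), "hi": rng.normal(10, 1, 25),
                  "mid1": rng.normal(0.1, 1, 25), "mid2": rng.normal(0.2, 1, 25)}
        for branch in ("parametric", "nonparametric"):
            res = pairwise_significance(groups, branch=branch)
            assert res.significant("lo", "hi")
            assert res.branch == branch

    def test_all_identical_values_degenerate_to_p_one(self):
        groups = {s: np.full(10, 3.0) for s in "abcd"}
        res = pairwise_significance(groups)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_array_equal(res.p_matrix[off], 1.0)

    def test_location_shift_changes_no_p_value(self):
        rng = np.random.default_rng(9)
        groups = gaussian_groups(rng, shift=0.4, n=40)
        res1 = pairwise_significance(groups, branch="nonparametric")
        res2 = pairwise_significance(
            {k: v + 1000.0 for k, v in groups.items()}, branch="nonparametric"
        )
        np.testing.assert_allclose(res1.p_matrix, res2.p_matrix, equal_nan=True)

    def test_relabeling_permutes_p_matrix(self):
        rng = np.random.default_rng(11)
        groups = gaussian_groups(rng, shift=0.8, n=30)
        res = pairwise_significance(groups, branch="parametric")
        order = ["seq2", "seq0", "seq3", "seq1"]
        res_p = pairwise_significance(
            {k: groups[k] for k in order}, branch="parametric"
        )
        for a in order:
            for b in order:
                if a == b:
                    continue
                i, j = res.sequence_ids.index(a), res.sequence_ids.index(b)
                i2, j2 = res_p.sequence_ids.index(a), res_p.sequence_ids.index(b)
                assert res.p_matrix[i, j] == pytest.approx(
                    res_p.p_matrix[i2, j2], rel=1e-6
                )

    def test_omnibus_gate_suppresses_pairwise_findings(self):
        rng = np.random.default_rng(21)
        # many groups of pure noise: occasionally a pair can look extreme,
        # but the gate reports nothing when the omnibus is quiet
        groups = gaussian_groups(rng, k=4, n=10)
        gated = pairwise_significance(groups, branch="parametric", omnibus_gate=True)
        if gated.omnibus_p >= gated.alpha:
            off = ~np.eye(4, dtype=bool)
            np.testing.assert_array_equal(gated.p_matrix[off], 1.0)

    def test_central_tendency_follows_branch(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.exponential(1, 50), "b": rng.exponential(1, 50)}
        res = pairwise_significance(groups, branch="nonparametric")
        assert res.central["a"] == pytest.approx(np.median(groups["a"]))
        res_p = pairwise_significance(groups, branch="parametric")
        assert res_p.central["a"] == pytest.approx(np.mean(groups["a"]))


class TestPosthocOracles:
    def test_tukey_approximation_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, 30) for m in (0.0, 0.3, 0.8, 1.5)]
        mine = tukey_pairwise(groups)
        ref = stats.tukey_hsd(*groups).pvalue
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                # psturng clips below 0.001 and above 0.9
                assert mine[i, j] == pytest.approx(
                    np.clip(ref[i, j], 0.001, 0.9), abs=0.015
                )

    def test_dunn_against_direct_two_group_formula(self):
        rng = np.random.default_rng(8)
        g = [rng.normal(0, 1, 20), rng.normal(1.2, 1, 25)]
        p = dunn_pairwise(g, adjust="none")[0, 1]
        pooled = np.concatenate(g)
        ranks = stats.rankdata(pooled)
        r1, r2 = ranks[:20].mean(), ranks[20:].mean()
        N = pooled.size
        se = np.sqrt(N * (N + 1) / 12 * (1 / 20 + 1 / 25))
        expected = 2 * stats.norm.sf(abs(r1 - r2) / se)
        assert p == pytest.approx(expected)

    def test_bonferroni_adjustment_scales_by_pair_count(self):
        rng = np.random.default_rng(13)
        g = [rng.normal(i * 0.3, 1, 15) for i in range(4)]
        raw = dunn_pairwise(g, adjust="none")
        bon = dunn_pairwise(g, adjust="bonferroni")
        np.testing.assert_allclose(
            bon[0, 1], min(raw[0, 1] * 6, 1.0), rtol=1e-12
        )
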