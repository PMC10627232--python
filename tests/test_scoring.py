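import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqrubric.examples import example_category_scores
from seqrubric.scoring import (
    Weights,
    category_scores,
    enumerate_gate_oracle,
    gated_rank_scores,
    ledger_from_category_scores,
    ledger_from_metric_scores,
    rescale_ties,
)
from seqrubric.stats_gate import SignificanceResult


def significance_from_pairs(ids, central, sig_pairs, alpha=0.05):
    """Build a SignificanceResult from an explicit set of significant
    pairs (p=0.001) with everything else at p=1."""
    k = len(ids)
    P = np.full((k, k), 1.0)
    np.fill_diagonal(P, np.nan)
    for a, b in sig_pairs:
        i, j = ids.index(a), ids.index(b)
        P[i, j] = P[j, i] = 0.001
    return SignificanceResult(
        "GTV", "m", list(ids), "parametric",
        dict(zip(ids, central)), dict.fromkeys(ids, 1.0),
        P, omnibus_p=0.001, alpha=alpha,
    )


class TestRescaleTies:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([4, 2, 2, 1], [4, 2.5, 2.5, 1]),
            ([1, 1, 1, 1], [2.5, 2.5, 2.5, 2.5]),
            ([4, 3, 2, 1], [4, 3, 2, 1]),
            ([4, 2, 2, 2], [4, 2, 2, 2]),
            ([3, 1, 1], [3, 1.5, 1.5]),
        ],
    )
    def test_worked_examples(self, raw, expected):
        np.testing.assert_allclose(rescale_ties(raw), expected)

    @settings(derandomize=True, deadline=None)
    @given(st.integers(2, 8), st.data())
    def test_conservation_sum_is_s_times_s_plus_1_over_2(self, s, data):
        raw = data.draw(
            st.lists(st.integers(1, s), min_size=s, max_size=s)
        )
        out = rescale_ties(raw)
        assert out.sum() == pytest.approx(s * (s + 1) / 2)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            rescale_ties([5, 2, 2, 1])


class TestGatedRankScores:
    ids = ["w", "x", "y", "z"]

    def test_no_significance_gives_all_tied_midpoint(self):
        res = significance_from_pairs(self.ids, [4, 3, 2, 1], [])
        scores = gated_rank_scores(res, "higher")
        assert set(scores.values()) == {2.5}

    def test_full_significance_gives_full_ranking(self):
        res = significance_from_pairs(
            self.ids, [4, 3, 2, 1],
            list(itertools.combinations(self.ids, 2)),
        )
        assert gated_rank_scores(res, "higher") == {
            "w": 4.0, "x": 3.0, "y": 2.0, "z": 1.0
        }

    def test_best_vs_all_others_only(self):
        res = significance_from_pairs(
            self.ids, [4, 3, 2, 1], [("w", "x"), ("w", "y"), ("w", "z")]
        )
        assert gated_rank_scores(res, "higher") == {
            "w": 4.0, "x": 2.0, "y": 2.0, "z": 2.0
        }

    def test_lower_is_better_direction_flips_order(self):
        res = significance_from_pairs(
            self.ids, [4, 3, 2, 1],
            list(itertools.combinations(self.ids, 2)),
        )
        assert gated_rank_scores(res, "lower") == {
            "w": 1.0, "x": 2.0, "y": 3.0, "z": 4.0
        }

    def test_partial_boundary_requires_full_cross_significance(self):
        # w>x>y>z; w sig vs y,z and x sig vs y,z -> boundary after position 2
        pairs = [("w", "y"), ("w", "z"), ("x", "y"), ("x", "z")]
        res = significance_from_pairs(self.ids, [4, 3, 2, 1], pairs)
        assert gated_rank_scores(res, "higher") == {
            "w": 3.5, "x": 3.5, "y": 1.5, "z": 1.5
        }

    def test_missing_p_values_treated_as_nonsignificant(self):
        res = significance_from_pairs(
            self.ids, [4, 3, 2, 1],
            list(itertools.combinations(self.ids, 2)),
        )
        res.p_matrix[0, 1] = res.p_matrix[1, 0] = np.nan
        scores = gated_rank_scores(res, "higher")
        assert scores["w"] == scores["x"] == 3.5

    @pytest.mark.parametrize("s", [3, 4])
    def test_matches_enumeration_oracle_for_all_matrices(self, s):
        ids = [f"q{i}" for i in range(s)]
        central = list(range(s, 0, -1))
        all_pairs = list(itertools.combinations(ids, 2))
        for bits in itertools.product([0, 1], repeat=len(all_pairs)):
            sig = [p for p, b in zip(all_pairs, bits) if b]
            res = significance_from_pairs(ids, central, sig)
            got = gated_rank_scores(res, "higher")
            want = enumerate_gate_oracle(ids, {frozenset(p) for p in sig})
            assert got == want, (bits, got, want)

    def test_adding_significance_never_lowers_the_upper_tier(self):
        ids = ["a", "b", "c"]
        base_pairs = [("a", "c")]
        more_pairs = [("a", "c"), ("a", "b")]
        base = gated_rank_scores(
            significance_from_pairs(ids, [3, 2, 1], base_pairs), "higher"
        )
        more = gated_rank_scores(
            significance_from_pairs(ids, [3, 2, 1], more_pairs), "higher"
        )
        assert more["a"] >= base["a"]


@pytest.fixture(scope="module")
def ledger():
    return ledger_from_category_scores(example_category_scores())


class TestLedgerArithmetic:

    def test_category_sum_example(self):
        # category sums (13, 9.5, 8, 9.5) -> normalized (4, 2.5, 1, 2.5)
        ms = pd.DataFrame(
            {("Pty", "snr"): [13.0, 9.5, 8.0, 9.5]},
            index=["s1", "s2", "s3", "s4"],
        )
        ms.columns = pd.MultiIndex.from_tuples(ms.columns)
        out = category_scores(ms, categories={"snr_cnr": ["snr"]})
        np.testing.assert_allclose(
            out[("Pty", "snr_cnr")].to_numpy(), [4, 2.5, 1, 2.5]
        )

    def test_total_scores_match_published_row(self, ledger):
        np.testing.assert_allclose(
            ledger.totals.loc["Non-FS", ["GTV", "LN", "Par", "Pty"]],
            [7.5, 7.5, 8.5, 13.0],
        )
        assert ledger.totals.loc["SPAIR 4", "LN"] == pytest.approx(14.5)

    def test_normalized_totals_match_published_row(self, ledger):
        assert ledger.normalized_totals.loc["SPAIR 1", "GTV"] == pytest.approx(3.5)
        np.testing.assert_allclose(
            ledger.normalized_totals.loc["Non-FS", ["GTV", "LN", "Par", "Pty"]],
            [1, 1, 1, 4],
        )

    def test_combined_totals_and_ranks_match_published_row(self, ledger):
        np.testing.assert_allclose(
            ledger.combined_total.to_numpy(), [36.5, 41.0, 36.0, 46.5]
        )
        np.testing.assert_allclose(
            ledger.combined_normalized.to_numpy(), [1, 3, 2, 4]
        )
        # the by-total variant ranks the combined totals directly
        np.testing.assert_allclose(
            ledger.combined_normalized_by_total.to_numpy(), [2, 3, 1, 4]
        )

    def test_conservation_at_every_normalization_stage(self, ledger):
        S = len(ledger.sequences)
        expect = S * (S + 1) / 2
        for struct in ledger.structures:
            assert ledger.normalized_totals[struct].sum() == pytest.approx(expect)
            for cat in ledger.category_scores[struct].columns:
                assert ledger.category_scores[(struct, cat)].sum() == pytest.approx(expect)
        assert ledger.combined_normalized.sum() == pytest.approx(expect)

    def test_winner_is_strictly_top_sequence(self, ledger):
        assert ledger.winner() == "SPAIR 4"

    def test_structure_agnostic_metric_broadcasts(self):
        scores = {
            (None, "fat_snr"): {"a": 2.0, "b": 1.0},
            ("GTV", "snr"): {"a": 1.0, "b": 2.0},
            ("Par", "snr"): {"a": 1.0, "b": 2.0},
        }
        ledger = ledger_from_metric_scores(scores, ["GTV", "Par"])
        # fat_snr appears under both structures
        assert ledger.metric_scores[("GTV", "fat_snr")]["a"] == 2.0
        assert ledger.metric_scores[("Par", "fat_snr")]["a"] == 2.0

    def test_category_weight_changes_totals(self):
        cat = example_category_scores()
        heavy = ledger_from_category_scores(
            cat, weights=Weights(category={"conspicuity": 2.0})
        )
        base = ledger_from_category_scores(cat)
        assert heavy.totals.loc["SPAIR 4", "LN"] == pytest.approx(
            base.totals.loc["SPAIR 4", "LN"] + 4.0
        )
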