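"""The significance-gated scoring rubric.

Every metric yields, per structure, a score between 1 and S (S = number
of candidate sequences, best = S).  A sequence may only out-score another
when its performance difference is statistically significant against
every lower-scored sequence, so sequences collapse into tiers separated
only by fully-significant boundaries; tied sequences are rescaled to the
average of the ranks they span (e.g. raw {4, 2, 2, 1} → {4, 2.5, 2.5, 1}).

Metric scores are then summed per analysis category and renormalized to
ranks within each structure (so categories with many metrics weigh the
same as categories with one), summed across categories into total scores
and normalized totals, and finally summed across structures into the
combined total and combined normalized score per sequence.  Optional
weights apply at each of the three summing joints (per metric, per
category, per structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats_gate import SignificanceResult

#: Scoring direction per metric.  ``fat_snr`` is lower-is-better (high
#: residual fat signal means poor suppression); HD95 lower is better.
METRIC_DIRECTIONS: dict[str, str] = {
    "snr": "higher",
    "fat_snr": "lower",
    "cnr_fat": "higher",
    "cnr_muscle": "higher",
    "conspicuity": "higher",
    "dsc": "higher",
    "hd95": "lower",
    "grade": "higher",
    "comment": "higher",
}

#: Analysis categories and their member metrics.
CATEGORIES: dict[str, list[str]] = {
    "snr_cnr": ["snr", "fat_snr", "cnr_fat", "cnr_muscle"],
    "conspicuity": ["conspicuity"],
    "pairwise_distance": ["dsc", "hd95"],
    "segmentor": ["grade", "comment"],
}

#: Metrics computed once per sequence (no structure); their metric score
#: is broadcast to every structure before category summation.
STRUCTURE_AGNOSTIC: frozenset[str] = frozenset({"fat_snr"})


@dataclass
class Weights:
    """Optional multiplicative weights, default 1 everywhere."""

    metric: dict[str, float] = field(default_factory=dict)
    category: dict[str, float] = field(default_factory=dict)
    structure: dict[str, float] = field(default_factory=dict)

    def w_metric(self, m: str) -> float:
        return float(self.metric.get(m, 1.0))

    def w_category(self, c: str) -> float:
        return float(self.category.get(c, 1.0))

    def w_structure(self, s: str) -> float:
        return float(self.structure.get(s, 1.0))

    def is_default(self) -> bool:
        return not (self.metric or self.category or self.structure)


def rescale_ties(raw_scores) -> np.ndarray:
    """Rescale tied scores to the average rank they span.

    The input is a per-sequence score vector forming descending tiers
    over {1..S}; equal values receive the arithmetic mean of the
    consecutive ranks their tie group covers, so the output always sums
    to S(S+1)/2.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.ndim != 1 or raw.size == 0 or not np.all(np.isfinite(raw)):
        raise ValueError("raw scores must be a non-empty finite vector")
    S = raw.size
    if np.any(raw < 1) or np.any(raw > S):
        raise ValueError(f"raw scores must lie in [1, {S}]")
    return rankdata(raw, method="average")


def rank_scores(values, direction: str = "higher") -> np.ndarray:
    """Average-rank scores in [1, S] (S = best) for a value vector."""
    v = np.asarray(values, dtype=float)
    if direction == "lower":
        v = -v
    elif direction != "higher":
        raise ValueError(f"unknown direction {direction!r}")
    return rankdata(v, method="average")


def gated_rank_scores(
    result: SignificanceResult, direction: str = "higher"
) -> dict[str, float]:
    """Metric scores per sequence under the significance gate.

    Sequences are ordered best→worst by central tendency; a tier boundary
    is placed between ordered positions i and i+1 only when every
    sequence at or above i differs significantly from every sequence at
    or below i+1.  Tier members share the average of the ranks the tier
    spans; with no placeable boundary all sequences share one tier
    (score (S+1)/2).
    """
    ids = result.sequence_ids
    S = len(ids)
    cent = np.array([result.central[s] for s in ids], dtype=float)
    keys = -cent if direction == "higher" else cent
    if direction not in ("higher", "lower"):
        raise ValueError(f"unknown direction {direction!r}")
    order = np.argsort(keys, kind="stable")  # best first
    boundaries = [
        cut
        for cut in range(1, S)
        if all(
            result.significant(ids[order[a]], ids[order[b]])
            for a in range(cut)
            for b in range(cut, S)
        )
    ]
    edges = [0, *boundaries, S]
    scores = np.empty(S)
    for lo, hi in zip(edges, edges[1:]):
        # tier at ordered positions lo..hi-1 spans ranks S-lo .. S-hi+1
        tier_score = (2 * S - lo - hi + 1) / 2.0
        scores[order[lo:hi]] = tier_score
    return {s: float(v) for s, v in zip(ids, scores)}


@dataclass
class ScoreLedger:
    """All scoring stages for one study.

    ``metric_scores`` and ``category_scores`` are sequence × (structure,
    name) tables; ``totals``/``normalized_totals`` are sequence ×
    structure; the combined series are per sequence.  Two combined
    normalizations are kept: the default ranks each sequence's sum of
    normalized total scores, the variant ranks the combined totals.
    """

    sequences: list[str]
    structures: list[str]
    metric_scores: pd.DataFrame
    category_scores: pd.DataFrame
    totals: pd.DataFrame
    normalized_totals: pd.DataFrame
    combined_total: pd.Series
    combined_normalized: pd.Series
    combined_normalized_by_total: pd.Series
    weights: Weights = field(default_factory=Weights)

    def winner(self) -> str | None:
        """Sequence with the strictly highest combined normalized score,
        or ``None`` if the top is tied."""
        top = self.combined_normalized.max()
        leaders = self.combined_normalized[self.combined_normalized == top]
        return str(leaders.index[0]) if len(leaders) == 1 else None

    def to_table(self) -> pd.DataFrame:
        """Category scores plus totals in a sequences × structures ×
        stages layout mirroring the published score table."""
        rows = {}
        for cat in self.category_scores.columns.get_level_values(1).unique():
            rows[cat] = self.category_scores.xs(cat, axis=1, level=1)
        rows["total"] = self.totals
        rows["normalized_total"] = self.normalized_totals
        table = pd.concat(rows, axis=0, names=["stage", "sequence"])
        table = table.reset_index().melt(
            id_vars=["stage", "sequence"], var_name="structure", value_name="score"
        )
        combined = pd.concat(
            [
                pd.DataFrame(
                    {
                        "stage": stage,
                        "sequence": self.sequences,
                        "structure": "all",
                        "score": series.loc[self.sequences].to_numpy(),
                    }
                )
                for stage, series in [
                    ("combined_total", self.combined_total),
                    ("combined_normalized", self.combined_normalized),
                    ("combined_normalized_by_total", self.combined_normalized_by_total),
                ]
            ]
        )
        return pd.concat([table, combined], ignore_index=True)

    def to_dict(self) -> dict:
        def df_dict(df: pd.DataFrame) -> dict:
            return {
                str(seq): {
                    "/".join(str(p) for p in (col if isinstance(col, tuple) else (col,))): float(v)
                    for col, v in row.items()
                }
                for seq, row in df.iterrows()
            }

        return {
            "sequences": self.sequences,
            "structures": self.structures,
            "metric_scores": df_dict(self.metric_scores),
            "category_scores": df_dict(self.category_scores),
            "totals": df_dict(self.totals),
            "normalized_totals": df_dict(self.normalized_totals),
            "combined_total": {k: float(v) for k, v in self.combined_total.items()},
            "combined_normalized": {
                k: float(v) for k, v in self.combined_normalized.items()
            },
            "combined_normalized_by_total": {
                k: float(v) for k, v in self.combined_normalized_by_total.items()
            },
            "weights_default": self.weights.is_default(),
        }


def category_scores(
    metric_scores: pd.DataFrame,
    categories: dict[str, list[str]] | None = None,
    weights: Weights | None = None,
) -> pd.DataFrame:
    """Normalized category scores from metric scores.

    ``metric_scores``: sequences × MultiIndex(structure, metric), with
    structure-agnostic metrics already broadcast.  Per (structure,
    category) the weighted metric-score sum is ranked across sequences
    with average-rank ties; empty categories are dropped.
    """
    categories = categories or CATEGORIES
    weights = weights or Weights()
    structures = metric_scores.columns.get_level_values(0).unique()
    cols: dict[tuple[str, str], np.ndarray] = {}
    for struct in structures:
        block = metric_scores[struct]
        for cat, members in categories.items():
            present = [m for m in members if m in block.columns]
            if not present:
                continue
            sums = sum(
                block[m].to_numpy() * weights.w_metric(m) for m in present
            )
            cols[(struct, cat)] = rank_scores(sums, "higher")
    out = pd.DataFrame(cols, index=metric_scores.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["structure", "category"])
    return out


def total_scores(
    category_table: pd.DataFrame, weights: Weights | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Totals (weighted category sums) and normalized totals (ranks of
    totals within each structure), per (sequence, structure)."""
    weights = weights or Weights()
    structures = category_table.columns.get_level_values(0).unique()
    totals = pd.DataFrame(index=category_table.index)
    for struct in structures:
        block = category_table[struct]
        totals[struct] = sum(
            block[c].to_numpy() * weights.w_category(c) for c in block.columns
        )
    normalized = totals.apply(lambda col: rank_scores(col.to_numpy(), "higher"))
    return totals, normalized


def combined_scores(
    totals: pd.DataFrame,
    normalized_totals: pd.DataFrame,
    weights: Weights | None = None,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Combined total and the two combined-normalized variants.

    Combined total = (structure-weighted) sum of totals.  The default
    combined normalized score ranks each sequence's weighted sum of
    normalized total scores; the by-total variant ranks the combined
    totals directly.
    """
    weights = weights or Weights()
    w = pd.Series(
        {s: weights.w_structure(str(s)) for s in totals.columns}, dtype=float
    )
    combined_total = (totals * w).sum(axis=1)
    norm_sum = (normalized_totals * w).sum(axis=1)
    combined_normalized = pd.Series(
        rank_scores(norm_sum.to_numpy(), "higher"), index=totals.index
    )
    by_total = pd.Series(
        rank_scores(combined_total.to_numpy(), "higher"), index=totals.index
    )
    return combined_total, combined_normalized, by_total


def ledger_from_metric_scores(
    scores: dict[tuple[str | None, str], dict[str, float]],
    structures: list[str],
    categories: dict[str, list[str]] | None = None,
    weights: Weights | None = None,
) -> ScoreLedger:
    """Assemble the full ledger from gated metric scores.

    ``scores`` maps (structure or None, metric) → {sequence: score};
    a None structure marks a structure-agnostic metric, broadcast to all
    structures.
    """
    weights = weights or Weights()
    sequences = sorted({seq for d in scores.values() for seq in d})
    cols = {}
    for (struct, metric), per_seq in scores.items():
        targets = structures if struct is None else [struct]
        for t in targets:
            cols[(t, metric)] = [per_seq[s] for s in sequences]
    ms = pd.DataFrame(cols, index=sequences)
    ms.columns = pd.MultiIndex.from_tuples(ms.columns, names=["structure", "metric"])
    ms = ms.sort_index(axis=1)
    cat = category_scores(ms, categories, weights)
    return ledger_from_category_scores(cat, weights=weights, metric_scores=ms)


def ledger_from_category_scores(
    category_table: pd.DataFrame,
    weights: Weights | None = None,
    metric_scores: pd.DataFrame | None = None,
) -> ScoreLedger:
    """Assemble totals, normalized totals and combined scores from a
    normalized-category-score table (sequences × (structure, category))."""
    weights = weights or Weights()
    totals, normalized = total_scores(category_table, weights)
    combined_total, combined_norm, by_total = combined_scores(
        totals, normalized, weights
    )
    if metric_scores is None:
        metric_scores = pd.DataFrame(index=category_table.index)
    return ScoreLedger(
        sequences=[str(s) for s in category_table.index],
        structures=[str(s) for s in category_table.columns.get_level_values(0).unique()],
        metric_scores=metric_scores,
        category_scores=category_table,
        totals=totals,
        normalized_totals=normalized,
        combined_total=combined_total,
        combined_normalized=combined_norm,
        combined_normalized_by_total=by_total,
        weights=weights,
    )


def enumerate_gate_oracle(
    central_order: list[str], significant_pairs: set[frozenset[str]]
) -> dict[str, float]:
    """Brute-force reference for the tier rule, used for validation.

    Enumerates all partitions of the best→worst ordering into contiguous
    tiers, keeps those where every cross-tier pair (in any two distinct
    tiers) is significant, picks the finest, and assigns average ranks.
    Independent of :func:`gated_rank_scores`' boundary scan.
    """
    S = len(central_order)
    best = None
    for cuts in _all_cut_sets(S):
        tiers = _tiers_from_cuts(central_order, cuts)
        ok = all(
            frozenset((a, b)) in significant_pairs
            for t1, t2 in combinations(tiers, 2)
            for a in t1
            for b in t2
        )
        if ok and (best is None or len(cuts) > len(best)):
            best = cuts
    tiers = _tiers_from_cuts(central_order, best or [])
    scores: dict[str, float] = {}
    rank = S
    for tier in tiers:
        avg = (rank + (rank - len(tier) + 1)) / 2.0
        for s in tier:
            scores[s] = avg
        rank -= len(tier)
    return scores


def _all_cut_sets(S: int):
    positions = list(range(1, S))
    for r in range(len(positions) + 1):
        yield from (list(c) for c in combinations(positions, r))


def _tiers_from_cuts(order: list[str], cuts: list[int]) -> list[list[str]]:
    edges = [0, *sorted(cuts), len(order)]
    return [order[a:b] for a, b in zip(edges, edges[1:])]
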