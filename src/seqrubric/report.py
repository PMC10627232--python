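"""Human-readable reporting of a completed scoring run."""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .pipeline import significance_to_records
from .scoring import ScoreLedger
from .stats_gate import SignificanceResult


def render_report(
    ledger: ScoreLedger,
    significance: list[SignificanceResult] | None = None,
) -> str:
    """Score matrix, per-metric summaries and a ranked verdict.

    The verdict names the sequence with the strictly highest combined
    normalized score, or states that no sequence is distinguishable when
    the top is tied.
    """
    buf = StringIO()
    w = buf.write
    w("Sequence scoring report\n")
    w("=======================\n\n")

    w("Score matrix (rows: scoring stage / category; columns: structure)\n\n")
    for seq in ledger.sequences:
        w(f"Sequence {seq}\n")
        block = pd.DataFrame(
            {
                struct: ledger.category_scores.loc[seq, struct]
                for struct in ledger.structures
            }
        )
        block.loc["total"] = ledger.totals.loc[seq]
        block.loc["normalized_total"] = ledger.normalized_totals.loc[seq]
        w(block.to_string(float_format=lambda v: f"{v:g}"))
        w(
            f"\ncombined total {ledger.combined_total[seq]:g}; "
            f"combined normalized {ledger.combined_normalized[seq]:g} "
            f"(by-total variant {ledger.combined_normalized_by_total[seq]:g})\n\n"
        )

    if significance:
        w("Per-metric summary (central tendency ± dispersion; mean±SD on the\n"
          "parametric branch, median±IQR otherwise)\n\n")
        for rec in significance_to_records(significance):
            label = rec["structure"] if rec["structure"] is not None else "(all structures)"
            cells = ", ".join(
                f"{s}: {rec['central'][s]:.3g}±{rec['dispersion'][s]:.3g}"
                for s in rec["sequences"]
            )
            w(
                f"- {label} / {rec['metric']} [{rec['branch']}, omnibus "
                f"p={rec['omnibus_p']:.3g}]: {cells}\n"
            )
        w("\n")

    ranking = ledger.combined_normalized.sort_values(ascending=False)
    w("Verdict\n-------\n")
    w("Ranking (combined normalized score): ")
    w(", ".join(f"{s}={v:g}" for s, v in ranking.items()))
    w("\n")
    winner = ledger.winner()
    if winner is None:
        w("No sequence distinguishable: the top combined score is tied.\n")
    else:
        w(f"Winning sequence: {winner}\n")
    if not ledger.weights.is_default():
        w(
            "Note: non-default weights in effect "
            f"(metric={ledger.weights.metric}, "
            f"category={ledger.weights.category}, "
            f"structure={ledger.weights.structure})\n"
        )
    return buf.getvalue()
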