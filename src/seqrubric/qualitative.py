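"""Observer grades and the comment metric.

Observers rank the candidate sequences per structure (grade 1 = most
preferred) and may leave a free-text comment, pre-classified into
positive / neutral / negative (or none).  Grades are converted to
higher-is-better scores (``n_sequences + 1 − rank``) so every metric
shares one direction convention in the statistics layer.  The comment
metric for one (sequence, structure, subject) is::

    (n_positive − n_negative) / n_possible   ∈ [−1, 1]

where ``n_possible`` counts observers who left any comment; neutral
comments sit in the denominator only, encoding a neutral baseline
opinion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import MetricSample

log = logging.getLogger(__name__)

COMMENT_CATEGORIES = ("positive", "neutral", "negative", "none")

#: Required columns of the qualitative CSV.
QUALITATIVE_COLUMNS = ("subject", "sequence", "structure", "observer", "grade", "comment")


def comment_metric(n_positive: int, n_negative: int, n_possible: int) -> float:
    """(n_positive − n_negative) / n_possible, the net opinion fraction."""
    if n_possible < 1:
        raise ValueError("n_possible must be >= 1")
    if n_positive < 0 or n_negative < 0 or n_positive + n_negative > n_possible:
        raise ValueError(
            f"inconsistent counts: {n_positive}+{n_negative} > {n_possible}"
        )
    return (n_positive - n_negative) / n_possible


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(QUALITATIVE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"qualitative table missing columns {sorted(missing)}")
    bad = set(records["comment"].dropna()) - set(COMMENT_CATEGORIES)
    if bad:
        raise ValueError(f"unknown comment categories {sorted(bad)}")
    return records


def grade_samples(
    records: pd.DataFrame, n_sequences: int | None = None
) -> dict[tuple[str, str], MetricSample]:
    """Pooled grade-score samples per (sequence, structure).

    One value per (observer, subject): ``n_sequences + 1 − grade``, so
    higher is better.  Missing grades are excluded with a warning.  Full
    tables yield samples of size observers × subjects.
    """
    records = validate_records(records)
    if n_sequences is None:
        n_sequences = records["sequence"].nunique()
    out: dict[tuple[str, str], MetricSample] = {}
    for (seq, struct), grp in records.groupby(["sequence", "structure"], sort=True):
        grades = pd.to_numeric(grp["grade"], errors="coerce")
        ok = grades.notna()
        if not ok.all():
            log.warning(
                "%d missing grade(s) excluded for (%s, %s)",
                int((~ok).sum()), seq, struct,
            )
        grp = grp[ok]
        scores = n_sequences + 1 - grades[ok].to_numpy(dtype=float)
        prov = [(s, o, None) for s, o in zip(grp["subject"], grp["observer"])]
        out[(seq, struct)] = MetricSample(
            metric_name="grade",
            sequence_id=str(seq),
            structure_label=str(struct),
            values=scores,
            provenance=prov,
        )
    return out


def comment_tallies(records: pd.DataFrame) -> pd.DataFrame:
    """Counts of positive/negative/possible comments per
    (sequence, structure, subject); ``none`` rows do not count as
    possible comments."""
    records = validate_records(records)
    def _tally(grp: pd.DataFrame) -> pd.Series:
        c = grp["comment"].fillna("none")
        return pd.Series(
            {
                "n_positive": int((c == "positive").sum()),
                "n_negative": int((c == "negative").sum()),
                "n_possible": int((c != "none").sum()),
            }
        )
    return (
        records.groupby(["sequence", "structure", "subject"], sort=True)
        .apply(_tally, include_groups=False)
        .reset_index()
    )


def comment_samples(
    records: pd.DataFrame,
) -> dict[tuple[str, str], MetricSample]:
    """Comment-metric samples per (sequence, structure), one value per
    subject (observer count is inside the formula, so the sample size is
    the number of subjects).  Subjects with no comments at all contribute
    a neutral 0."""
    tallies = comment_tallies(records)
    out: dict[tuple[str, str], MetricSample] = {}
    for (seq, struct), grp in tallies.groupby(["sequence", "structure"], sort=True):
        vals, prov = [], []
        for row in grp.itertuples(index=False):
            if row.n_possible == 0:
                vals.append(0.0)
            else:
                vals.append(
                    comment_metric(row.n_positive, row.n_negative, row.n_possible)
                )
            prov.append((row.subject, None, None))
        out[(seq, struct)] = MetricSample(
            metric_name="comment",
            sequence_id=str(seq),
            structure_label=str(struct),
            values=np.asarray(vals),
            provenance=prov,
        )
    return out
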