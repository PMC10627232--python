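"""Bundled worked example: a completed normalized-category-score table.

A four-way sequence comparison (one nonsuppressed T2-weighted sequence
and three fat-suppressed SPAIR variants) scored over four head-and-neck
structures — the gross tumor volume (GTV), metastatic lymph nodes (LN),
parotid glands (Par) and pterygoid muscles (Pty) — in the four analysis
categories.  Feeding this table to the rubric reproduces the downstream
totals, normalized totals and combined scores, and is the quickest way to
see the scoring arithmetic end to end.
"""

from __future__ import annotations

import pandas as pd

SEQUENCES = ["Non-FS", "SPAIR 1", "SPAIR 3", "SPAIR 4"]
STRUCTURES = ["GTV", "LN", "Par", "Pty"]
EXAMPLE_CATEGORIES = ["snr_cnr", "conspicuity", "pairwise_distance", "segmentor"]

_SCORES = {
    # sequence -> category -> (GTV, LN, Par, Pty)
    "Non-FS": {
        "snr_cnr": (1.0, 2.0, 4.0, 2.5),
        "conspicuity": (1.5, 1.0, 1.0, 4.0),
        "pairwise_distance": (2.5, 2.0, 1.0, 4.0),
        "segmentor": (2.5, 2.5, 2.5, 2.5),
    },
    "SPAIR 1": {
        "snr_cnr": (3.0, 2.0, 2.0, 2.5),
        "conspicuity": (3.5, 2.5, 3.5, 2.5),
        "pairwise_distance": (2.5, 2.0, 3.0, 2.0),
        "segmentor": (2.5, 2.5, 2.5, 2.5),
    },
    "SPAIR 3": {
        "snr_cnr": (3.0, 2.0, 2.0, 2.5),
        "conspicuity": (1.5, 2.5, 2.0, 1.0),
        "pairwise_distance": (2.5, 2.0, 3.0, 2.0),
        "segmentor": (2.5, 2.5, 2.5, 2.5),
    },
    "SPAIR 4": {
        "snr_cnr": (3.0, 4.0, 2.0, 2.5),
        "conspicuity": (3.5, 4.0, 3.5, 2.5),
        "pairwise_distance": (2.5, 4.0, 3.0, 2.0),
        "segmentor": (2.5, 2.5, 2.5, 2.5),
    },
}


def example_category_scores() -> pd.DataFrame:
    """Normalized category scores, sequences × (structure, category)."""
    cols = {}
    for seq in SEQUENCES:
        for cat in EXAMPLE_CATEGORIES:
            for struct, v in zip(STRUCTURES, _SCORES[seq][cat]):
                cols.setdefault((struct, cat), {})[seq] = v
    df = pd.DataFrame(cols).loc[SEQUENCES]
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["structure", "category"]
    )
    return df.sort_index(axis=1)
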