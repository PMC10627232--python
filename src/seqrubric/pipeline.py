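"""End-to-end orchestration: metrics → pooling → statistics → rubric.

The unit of comparison is the sequence-structure pair.  Paired organs
(parotids, pterygoids) are analyzed as single structures: left and right
values pool into one sample, matching the single per-organ columns of the
final score table.

Sample-size bookkeeping per (sequence, structure):

* SNR / CNR — one value per subject (observer ROIs are averaged);
* conspicuity — one value per occupied slice per observer per subject,
  trimmed to the inner 90% band;
* Dice / HD95 — one value per unordered observer pair per subject,
  trimmed to the inner 90% band;
* grades — observers × subjects; comment metric — one value per subject.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import qualitative as qual
from .agreement import pairwise_agreement
from .conspicuity import conspicuity_values
from .data_model import (
    MetricSample,
    SequenceStructurePair,
    StructureMask,
    VolumeImage,
    load_mask,
    load_volume,
)
from .intensity import mean_signal, noise_sd
from .scoring import (
    CATEGORIES,
    METRIC_DIRECTIONS,
    ScoreLedger,
    Weights,
    gated_rank_scores,
    ledger_from_metric_scores,
)
from .stats_gate import SignificanceResult, pairwise_significance

log = logging.getLogger(__name__)

#: Metrics whose pooled stacks get the inner-percentile outlier filter.
FILTERED_METRICS = frozenset({"conspicuity", "dsc", "hd95"})

#: Organ used as the muscle reference for CNR.
MUSCLE_REFERENCE = "pterygoid"


def organ_of(component_label: str) -> str:
    parts = component_label.rsplit("_", 1)
    return parts[0] if parts[-1] in ("L", "R") else component_label


@dataclass
class Study:
    """In-memory study: volumes, reference masks, observer masks,
    qualitative table.  The phantom generator produces a compatible
    object; :func:`load_study` builds one from a manifest."""

    volumes: dict[tuple[str, str], VolumeImage]
    truth_masks: dict[tuple[str, str], StructureMask]
    observer_masks: dict[tuple[str, str, str, str], StructureMask]
    qualitative: pd.DataFrame | None = None

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s for s, _ in self.volumes})

    @property
    def sequence_ids(self) -> list[str]:
        return sorted({q for _, q in self.volumes})

    @property
    def observer_ids(self) -> list[str]:
        return sorted({o for _, _, _, o in self.observer_masks})


def components_by_organ(study) -> dict[str, list[str]]:
    comps = sorted({c for _, _, c, _ in study.observer_masks})
    out: dict[str, list[str]] = {}
    for c in comps:
        out.setdefault(organ_of(c), []).append(c)
    return out


def _observer_masks_for(study, subj, seq, components) -> list[StructureMask]:
    return [
        m
        for (s, q, c, _), m in study.observer_masks.items()
        if s == subj and q == seq and c in components and not m.is_empty
    ]


def compute_intensity_table(study) -> pd.DataFrame:
    """Tidy per-subject SNR / fat SNR / CNR values."""
    organs = components_by_organ(study)
    rows = []
    for subj in study.subject_ids:
        noise = study.truth_masks[(subj, "noise")]
        fat = study.truth_masks[(subj, "fat")]
        for seq in study.sequence_ids:
            vol = study.volumes[(subj, seq)]
            sd = noise_sd(vol, noise)
            fat_snr = mean_signal(vol, [fat]) / sd
            rows.append((subj, seq, None, "fat_snr", fat_snr, None, None))
            organ_snr = {}
            for organ, comps in organs.items():
                masks = _observer_masks_for(study, subj, seq, comps)
                organ_snr[organ] = mean_signal(vol, masks) / sd
            for organ, s in organ_snr.items():
                rows.append((subj, seq, organ, "snr", s, None, None))
                rows.append((subj, seq, organ, "cnr_fat", s - fat_snr, None, None))
                if organ != MUSCLE_REFERENCE and MUSCLE_REFERENCE in organ_snr:
                    # CNR vs muscle is degenerate for the muscle itself
                    rows.append(
                        (subj, seq, organ, "cnr_muscle",
                         s - organ_snr[MUSCLE_REFERENCE], None, None)
                    )
    return _tidy(rows)


def compute_conspicuity_table(study) -> pd.DataFrame:
    """Tidy slice-wise conspicuity values per observer mask."""
    rows = []
    skipped = 0
    for (subj, seq, comp, obs), mask in sorted(study.observer_masks.items()):
        if mask.is_empty:
            continue
        vol = study.volumes[(subj, seq)]
        values, slices, skip = conspicuity_values(vol, mask)
        skipped += len(skip)
        organ = organ_of(comp)
        for v, z in zip(values, slices):
            rows.append((subj, seq, organ, "conspicuity", v, obs, z))
    if skipped:
        log.info("conspicuity: %d slice(s) skipped (empty core or ring)", skipped)
    return _tidy(rows)


def compute_agreement_table(study) -> pd.DataFrame:
    """Tidy per-observer-pair Dice and HD95 values."""
    organs = components_by_organ(study)
    rows = []
    for subj in study.subject_ids:
        for seq in study.sequence_ids:
            for organ, comps in organs.items():
                for comp in comps:
                    masks = _observer_masks_for(study, subj, seq, [comp])
                    if len(masks) < 2:
                        log.warning(
                            "<2 observer masks for (%s, %s, %s); pairwise "
                            "metrics skipped", subj, seq, comp,
                        )
                        continue
                    pair = SequenceStructurePair(seq, comp, subj, masks)
                    dsc, hd = pairwise_agreement(pair)
                    for sample in (dsc, hd):
                        for v, (s, op, _) in zip(sample.values, sample.provenance):
                            rows.append((s, seq, organ, sample.metric_name, v, op, None))
    return _tidy(rows)


def _tidy(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["subject", "sequence", "structure", "metric", "value",
                 "observer", "slice"],
    )


def pooled_samples(
    metrics_table: pd.DataFrame,
    qualitative: pd.DataFrame | None,
    inner_fraction: float = 0.90,
) -> dict[tuple[str | None, str], dict[str, MetricSample]]:
    """Pool tidy metric rows into per-(structure, metric, sequence)
    samples, applying the inner-percentile filter where prescribed."""
    out: dict[tuple[str | None, str], dict[str, MetricSample]] = {}
    table = metrics_table.copy()
    table["structure"] = table["structure"].where(table["structure"].notna(), None)
    for (metric, struct), grp in table.groupby(["metric", "structure"], dropna=False, sort=True):
        struct = None if pd.isna(struct) else struct
        key = (struct, metric)
        out[key] = {}
        for seq, sgrp in grp.groupby("sequence", sort=True):
            prov = list(
                zip(sgrp["subject"], sgrp["observer"], sgrp["slice"])
            )
            sample = MetricSample(
                metric_name=metric,
                sequence_id=str(seq),
                structure_label=struct,
                values=sgrp["value"].to_numpy(dtype=float),
                provenance=prov,
            )
            if metric in FILTERED_METRICS:
                sample = sample.filter(inner_fraction)
            out[key][str(seq)] = sample
    if qualitative is not None and len(qualitative):
        n_seq = qualitative["sequence"].nunique()
        for (seq, struct), sample in qual.grade_samples(qualitative, n_seq).items():
            out.setdefault((struct, "grade"), {})[seq] = sample
        for (seq, struct), sample in qual.comment_samples(qualitative).items():
            out.setdefault((struct, "comment"), {})[seq] = sample
    return out


@dataclass
class PipelineResult:
    metrics_table: pd.DataFrame
    samples: dict[tuple[str | None, str], dict[str, MetricSample]]
    significance: list[SignificanceResult]
    metric_scores: dict[tuple[str | None, str], dict[str, float]]
    ledger: ScoreLedger

    def significance_for(
        self, structure: str | None, metric: str
    ) -> SignificanceResult:
        for r in self.significance:
            if r.structure_label == structure and r.metric_name == metric:
                return r
        raise KeyError((structure, metric))


def analyze_study(
    study,
    *,
    alpha: float = 0.05,
    inner_fraction: float = 0.90,
    omnibus_gate: bool = True,
    dunn_adjust: str = "bonferroni",
    weights: Weights | None = None,
    categories: dict[str, list[str]] | None = None,
) -> PipelineResult:
    """Run metrics, pooling, the statistics gate and the rubric."""
    tables = [
        compute_intensity_table(study),
        compute_conspicuity_table(study),
        compute_agreement_table(study),
    ]
    metrics_table = pd.concat(tables, ignore_index=True)
    return score_from_tables(
        metrics_table,
        study.qualitative,
        alpha=alpha,
        inner_fraction=inner_fraction,
        omnibus_gate=omnibus_gate,
        dunn_adjust=dunn_adjust,
        weights=weights,
        categories=categories,
    )


def score_from_tables(
    metrics_table: pd.DataFrame,
    qualitative: pd.DataFrame | None = None,
    *,
    alpha: float = 0.05,
    inner_fraction: float = 0.90,
    omnibus_gate: bool = True,
    dunn_adjust: str = "bonferroni",
    weights: Weights | None = None,
    categories: dict[str, list[str]] | None = None,
) -> PipelineResult:
    """Statistics gate plus rubric on already-computed tidy metrics."""
    weights = weights or Weights()
    categories = categories or CATEGORIES
    samples = pooled_samples(metrics_table, qualitative, inner_fraction)

    significance: list[SignificanceResult] = []
    metric_scores: dict[tuple[str | None, str], dict[str, float]] = {}
    for (struct, metric), per_seq in sorted(
        samples.items(), key=lambda kv: (kv[0][0] or "", kv[0][1])
    ):
        if len(per_seq) < 2:
            log.warning("metric %s/%s present for <2 sequences; skipped", struct, metric)
            continue
        values = {s: smp.values for s, smp in per_seq.items()}
        result = pairwise_significance(
            values,
            metric_name=metric,
            structure_label=struct,
            alpha=alpha,
            omnibus_gate=omnibus_gate,
            dunn_adjust=dunn_adjust,
        )
        significance.append(result)
        metric_scores[(struct, metric)] = gated_rank_scores(
            result, METRIC_DIRECTIONS.get(metric, "higher")
        )

    structures = sorted({s for s, _ in metric_scores if s is not None})
    ledger = ledger_from_metric_scores(
        metric_scores, structures, categories, weights
    )
    return PipelineResult(
        metrics_table=metrics_table,
        samples=samples,
        significance=significance,
        metric_scores=metric_scores,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# manifest I/O

MANIFEST_COLUMNS = ("path", "kind", "subject", "sequence", "structure", "observer")


def load_study(manifest_path, qualitative_path=None) -> Study:
    """Build a study from a manifest CSV mapping files to their tags.

    ``kind`` is ``volume`` or ``mask``; reference masks use the ``fat``
    and ``noise`` structure labels with observer ``truth``.  Masks are
    validated against their subject's volume lattice.
    """
    manifest_path = Path(manifest_path)
    mf = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(mf.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    base = manifest_path.parent
    volumes: dict[tuple[str, str], VolumeImage] = {}
    for row in mf[mf["kind"] == "volume"].itertuples(index=False):
        p = Path(row.path)
        volumes[(str(row.subject), str(row.sequence))] = load_volume(
            p if p.is_absolute() else base / p, str(row.sequence), str(row.subject)
        )
    truth_masks: dict[tuple[str, str], StructureMask] = {}
    observer_masks: dict[tuple[str, str, str, str], StructureMask] = {}
    for row in mf[mf["kind"] == "mask"].itertuples(index=False):
        p = Path(row.path)
        subj, seq = str(row.subject), str(row.sequence)
        ref = volumes.get((subj, seq)) or next(
            (v for (s, _), v in volumes.items() if s == subj), None
        )
        mask = load_mask(
            p if p.is_absolute() else base / p,
            str(row.structure),
            str(row.observer),
            subj,
            seq,
            reference=ref,
        )
        if row.structure in ("fat", "noise"):
            truth_masks[(subj, str(row.structure))] = mask
        else:
            observer_masks[(subj, seq, str(row.structure), str(row.observer))] = mask
    qualitative = None
    if qualitative_path is not None:
        qualitative = qual.validate_records(pd.read_csv(qualitative_path))
    return Study(volumes, truth_masks, observer_masks, qualitative)


def significance_to_records(results: list[SignificanceResult]) -> list[dict]:
    recs = []
    for r in results:
        recs.append(
            {
                "structure": r.structure_label,
                "metric": r.metric_name,
                "branch": r.branch,
                "omnibus_p": r.omnibus_p,
                "alpha": r.alpha,
                "sequences": r.sequence_ids,
                "central": r.central,
                "dispersion": r.dispersion,
                "p_matrix": [
                    [None if not np.isfinite(p) else float(p) for p in row]
                    for row in r.p_matrix
                ],
                "warnings": r.warnings,
            }
        )
    return recs


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics_table.to_csv(out / "metrics.csv", index=False)
    (out / "significance.json").write_text(
        json.dumps(significance_to_records(result.significance), indent=1)
    )
    (out / "ledger.json").write_text(
        json.dumps(result.ledger.to_dict(), indent=1, sort_keys=True)
    )
    result.ledger.to_table().to_csv(out / "score_table.csv", index=False)
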