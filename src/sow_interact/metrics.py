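"""Confusion-matrix evaluation for the interaction classifiers.

Per modality (one-vs-rest): sensitivity TP/(TP+FN), specificity
TN/(FP+TN), precision TP/(TP+FP) and their harmonic-mean F-score.
Globally: accuracy (correct predictions over all observations) and the
macro F-score (unweighted mean of the per-modality F-scores; a
frequency-weighted variant is available).  A metric whose denominator
is zero is reported as None — never coerced to 0 — and excluded from
macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metric_suite",
    "evaluate",
    "cohens_kappa",
    "report_to_dataframe",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single modality."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ModalityMetrics:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f_score: float | None


@dataclass(frozen=True)
class MetricsReport:
    per_modality: dict[str, ModalityMetrics]
    counts: dict[str, ConfusionCounts]
    accuracy: float
    macro_f: float | None
    weighted_f: float | None


def confusion(truth: Sequence, pred: Sequence, modality) -> ConfusionCounts:
    """Count TP/FN/FP/TN for one modality (one-vs-rest)."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(pred)} pred")
    if len(truth) == 0:
        raise ValueError("empty label sequences")
    tp = fn = fp = tn = 0
    for t, p in zip(truth, pred):
        if t == modality:
            if p == modality:
                tp += 1
            else:
                fn += 1
        else:
            if p == modality:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metric_suite(counts: Mapping[str, ConfusionCounts]) -> MetricsReport:
    """Per-modality metrics plus global accuracy and macro/weighted F."""
    if not counts:
        raise ValueError("no modalities supplied")
    ns = {m: c.n for m, c in counts.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(f"modalities disagree on total n: {ns}")
    n = next(iter(ns.values()))

    per: dict[str, ModalityMetrics] = {}
    for m, c in counts.items():
        sens = _ratio(c.tp, c.tp + c.fn)
        spec = _ratio(c.tn, c.fp + c.tn)
        prec = _ratio(c.tp, c.tp + c.fp)
        if prec is None or sens is None or prec + sens == 0:
            f = None
        else:
            f = 2 * (prec * sens) / (prec + sens)
        per[m] = ModalityMetrics(sensitivity=sens, specificity=spec,
                                 precision=prec, f_score=f)

    if len(counts) == 1:
        # single one-vs-rest table: correct = TP + TN
        c = next(iter(counts.values()))
        accuracy = (c.tp + c.tn) / n
    else:
        # full modality set: each correct prediction is the TP of
        # exactly one modality
        accuracy = sum(c.tp for c in counts.values()) / n

    defined = {m: per[m].f_score for m in counts if per[m].f_score is not None}
    macro_f = sum(defined.values()) / len(defined) if defined else None
    support = {m: counts[m].tp + counts[m].fn for m in defined}
    tot = sum(support.values())
    weighted_f = (
        sum(defined[m] * support[m] for m in defined) / tot if tot else None
    )
    return MetricsReport(per_modality=per, counts=dict(counts),
                         accuracy=accuracy, macro_f=macro_f,
                         weighted_f=weighted_f)


def evaluate(truth: Sequence, pred: Sequence,
             modalities: Sequence | None = None) -> MetricsReport:
    """Full report from raw label vectors (modalities default to those seen)."""
    if modalities is None:
        modalities = sorted(set(truth) | set(pred))
    return metric_suite({m: confusion(truth, pred, m) for m in modalities})


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    p_e is the chance agreement from the raters' marginal label
    frequencies.  Returns NaN when both raters are constant and
    identical (p_e = 1, agreement beyond chance undefined).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label sequences")
    labels = sorted(set(labels_a) | set(labels_b))
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    freq_a = {c: sum(a == c for a in labels_a) / n for c in labels}
    freq_b = {c: sum(b == c for b in labels_b) / n for c in labels}
    p_e = sum(freq_a[c] * freq_b[c] for c in labels)
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def report_to_dataframe(report: MetricsReport, **context) -> pd.DataFrame:
    """Tabular layout: one row per modality plus the global summary."""
    rows = []
    for m, mm in report.per_modality.items():
        rows.append({**context, "modality": m,
                     "n": report.counts[m].tp + report.counts[m].fn,
                     "sensitivity": mm.sensitivity,
                     "specificity": mm.specificity,
                     "precision": mm.precision,
                     "f_score": mm.f_score,
                     "macro_f": report.macro_f,
                     "accuracy": report.accuracy})
    return pd.DataFrame(rows)
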