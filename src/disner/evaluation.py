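"""Mention-level precision/recall/F1 and the put-back bootstrap.

Matching is exact-span: a predicted mention counts as a true positive iff
a gold mention with identical (start, end) offsets exists in the same
document.  Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean; a metric with a zero denominator is reported as 0.

The bootstrap resamples whole documents with replacement ("put-back"
sampling, 100 rounds by default), recomputes F1 per round, and reports a
percentile confidence interval at the requested level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import AnnotationError, Mention

__all__ = [
    "EvalReport",
    "BootstrapReport",
    "match_mentions",
    "prf",
    "evaluate_documents",
    "bootstrap_f1",
]


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalReport":
        p, r, f = prf(tp, fp, fn)
        return cls(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f)

    def as_dict(self) -> dict:
        return {
            "matching": "exact-span",
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


@dataclass(frozen=True)
class BootstrapReport:
    point: EvalReport
    rounds: int
    level: float
    f1_low: float
    f1_high: float

    def as_dict(self) -> dict:
        d = self.point.as_dict()
        d.update(
            rounds=self.rounds, level=self.level,
            f1_low=self.f1_low, f1_high=self.f1_high,
        )
        return d


def _check_non_overlapping(mentions: Sequence[Mention], which: str) -> None:
    ordered = sorted(mentions)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise AnnotationError(
                f"overlapping {which} mentions ({a.start},{a.end}) / ({b.start},{b.end})"
            )


def match_mentions(
    gold: Sequence[Mention], predicted: Sequence[Mention]
) -> tuple[int, int, int]:
    """Exact-span matching within one document; returns (tp, fp, fn)."""
    _check_non_overlapping(gold, "gold")
    _check_non_overlapping(predicted, "predicted")
    gold_spans = {(m.start, m.end) for m in gold}
    pred_spans = {(m.start, m.end) for m in predicted}
    tp = len(gold_spans & pred_spans)
    return tp, len(pred_spans) - tp, len(gold_spans) - tp


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 from counts; zero-denominator metrics are 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def evaluate_documents(
    gold_docs: Sequence[Sequence[Mention]],
    predicted_docs: Sequence[Sequence[Mention]],
) -> EvalReport:
    """Counts summed over aligned per-document mention lists."""
    if len(gold_docs) != len(predicted_docs):
        raise ValueError("gold and predicted document lists differ in length")
    tp = fp = fn = 0
    for g, p in zip(gold_docs, predicted_docs):
        a, b, c = match_mentions(g, p)
        tp, fp, fn = tp + a, fp + b, fn + c
    return EvalReport.from_counts(tp, fp, fn)


def bootstrap_f1(
    gold_docs: Sequence[Sequence[Mention]],
    predicted_docs: Sequence[Sequence[Mention]],
    rounds: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapReport:
    """Document-level put-back bootstrap of the F1 score.

    Each round draws n documents with replacement and recomputes F1; the
    interval is the percentile interval of the round scores at ``level``.
    Deterministic for a fixed seed.
    """
    n = len(gold_docs)
    if n == 0:
        raise ValueError("cannot bootstrap an empty document list")
    if len(predicted_docs) != n:
        raise ValueError("gold and predicted document lists differ in length")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    per_doc = [match_mentions(g, p) for g, p in zip(gold_docs, predicted_docs)]
    counts = np.asarray(per_doc, dtype=np.int64)  # n x (tp, fp, fn)
    rng = np.random.default_rng(seed)
    scores = np.empty(rounds)
    for r in range(rounds):
        pick = rng.integers(0, n, size=n)
        tp, fp, fn = counts[pick].sum(axis=0)
        scores[r] = prf(int(tp), int(fp), int(fn))[2]
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(scores, [alpha, 1.0 - alpha])
    point = evaluate_documents(gold_docs, predicted_docs)
    return BootstrapReport(
        point=point, rounds=rounds, level=level,
        f1_low=float(low), f1_high=float(high),
    )
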