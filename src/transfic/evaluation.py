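"""Proxy-dataset labeling, MCC/ACC cutoff sweeps and boundary calibration.

No curated set of true driver and passenger mutations exists, so evaluation
relies on proxy labels: mutations recurring across many tumor samples, or
occurring in known cancer genes, are enriched in drivers (positives), while
non-recurrent mutations outside such genes are enriched in passengers
(negatives). Classifier quality over a score column is summarized by sweeping
a decision cutoff over the full score range and retaining the maximum
Matthews correlation coefficient (MCC) plus the accuracy at that same cutoff;
MCC is preferred because the proxy sets are heavily negative-skewed.

Category boundaries are calibrated from complementary cumulative
distributions (CCDF): the low/medium boundary keeps ~95% of highly recurrent
mutations above it, and the medium/high boundary keeps at most ~25% of
non-recurrent mutations above it.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .errors import CalibrationError, DomainError
from .models import Confusion, EvalResult, Label, LabeledDataset, LabeledRecord, ScoredVariant

__all__ = [
    "recurrence_counts",
    "label_by_recurrence",
    "label_by_gene_list",
    "dataset_from_scores",
    "mcc",
    "acc",
    "sweep_cutoffs",
    "Ccdf",
    "ccdf",
    "calibrate_boundaries",
]

RecurrenceKey = Callable[[ScoredVariant], Tuple[str, str]]


def _default_key(v: ScoredVariant) -> Tuple[str, str]:
    return (v.gene_id, v.variant_id)


def recurrence_counts(
    mutations: Iterable[ScoredVariant], key: RecurrenceKey = _default_key
) -> Dict[Tuple[str, str], int]:
    """Sample recurrence per mutation identity.

    Recurrence is the summed ``sample_count`` over all records sharing the
    key (gene id + variant id by default); with the default per-row count of
    1 this is simply the number of rows observed.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for v in mutations:
        counts[key(v)] = counts.get(key(v), 0) + v.sample_count
    return counts


def _collapse(
    mutations: Iterable[ScoredVariant], tool: str, key: RecurrenceKey
) -> Dict[Tuple[str, str], ScoredVariant]:
    """First scored record per mutation identity, restricted to ``tool``."""
    first: Dict[Tuple[str, str], ScoredVariant] = {}
    for v in mutations:
        if tool in v.scores:
            first.setdefault(key(v), v)
    return first


def label_by_recurrence(
    mutations: Sequence[ScoredVariant],
    tool: str,
    pos_min: int = 2,
    neg_exact: int = 1,
    key: RecurrenceKey = _default_key,
    name: str | None = None,
) -> LabeledDataset:
    """Recurrence-based proxy labels.

    positive when recurrence >= ``pos_min``; negative when recurrence equals
    ``neg_exact``; intermediate recurrences are excluded from both subsets
    (e.g. ``pos_min=5, neg_exact=1`` drops counts 2-4). Mutations lacking a
    score for ``tool`` are excluded.
    """
    if not pos_min > neg_exact >= 1:
        raise DomainError(f"need pos_min > neg_exact >= 1, got {pos_min}, {neg_exact}")
    counts = recurrence_counts(mutations, key)
    records: List[LabeledRecord] = []
    for k, v in _collapse(mutations, tool, key).items():
        r = counts[k]
        if r >= pos_min:
            label = Label.POSITIVE
        elif r == neg_exact:
            label = Label.NEGATIVE
        else:
            continue
        records.append(LabeledRecord(v.variant_id, v.gene_id, v.scores[tool], label))
    return LabeledDataset(name or f"recurrence{pos_min}+/{neg_exact}", tuple(records))


def label_by_gene_list(
    mutations: Sequence[ScoredVariant],
    tool: str,
    driver_genes: Set[str],
    key: RecurrenceKey = _default_key,
    name: str | None = None,
) -> LabeledDataset:
    """Gene-list proxy labels (Cancer-Gene-Census style).

    positive when the harboring gene is in ``driver_genes``; negative when it
    is not *and* the mutation is non-recurrent (recurrence == 1); recurrent
    mutations outside the list are excluded.
    """
    if not driver_genes:
        raise DomainError("driver_genes must be non-empty")
    counts = recurrence_counts(mutations, key)
    records: List[LabeledRecord] = []
    for k, v in _collapse(mutations, tool, key).items():
        if v.gene_id in driver_genes:
            label = Label.POSITIVE
        elif counts[k] == 1:
            label = Label.NEGATIVE
        else:
            continue
        records.append(LabeledRecord(v.variant_id, v.gene_id, v.scores[tool], label))
    return LabeledDataset(name or "gene-list", tuple(records))


def dataset_from_scores(
    scored: Iterable[Tuple[str, str, float]],
    positives: Set[str],
    negatives: Set[str],
    name: str = "dataset",
) -> LabeledDataset:
    """Build a dataset from (variant_id, gene_id, score) triples and id sets."""
    records = []
    for vid, gene, score in scored:
        if vid in positives:
            records.append(LabeledRecord(vid, gene, score, Label.POSITIVE))
        elif vid in negatives:
            records.append(LabeledRecord(vid, gene, score, Label.NEGATIVE))
    return LabeledDataset(name, tuple(records))


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient.

    ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``; 0 when any
    marginal is zero (the standard convention for the undefined denominator).
    """
    for c in (tp, fp, tn, fn):
        if c < 0:
            raise DomainError(f"confusion counts must be non-negative, got {(tp, fp, tn, fn)}")
    if tp + fp + tn + fn == 0:
        raise DomainError("confusion matrix is empty")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def acc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Overall accuracy ``(tp + tn) / (tp + fp + fn + tn)``."""
    for c in (tp, fp, tn, fn):
        if c < 0:
            raise DomainError(f"confusion counts must be non-negative, got {(tp, fp, tn, fn)}")
    total = tp + fp + tn + fn
    if total == 0:
        raise DomainError("confusion matrix is empty")
    return (tp + tn) / total


def sweep_cutoffs(dataset: LabeledDataset) -> EvalResult:
    """Full-range cutoff sweep retaining the maximum MCC.

    Candidate cutoffs are the sorted distinct scores plus one value above the
    maximum (the predict-nothing-positive cutoff); the prediction rule is
    ``score >= cutoff => positive``. Ties on MCC break toward the smaller
    cutoff. Accuracy and the confusion matrix are reported at the winning
    cutoff.
    """
    pos = np.sort([r.score for r in dataset.records if r.label is Label.POSITIVE])
    neg = np.sort([r.score for r in dataset.records if r.label is Label.NEGATIVE])
    if pos.size == 0:
        raise DomainError(f"dataset {dataset.name!r} has no positive records")
    if neg.size == 0:
        raise DomainError(f"dataset {dataset.name!r} has no negative records")

    all_scores = np.concatenate([pos, neg])
    cutoffs = np.unique(all_scores)
    cutoffs = np.append(cutoffs, cutoffs[-1] + 1.0)

    # score >= cutoff is positive: counts via binary search on sorted arrays
    tp = pos.size - np.searchsorted(pos, cutoffs, side="left")
    fp = neg.size - np.searchsorted(neg, cutoffs, side="left")
    fn = pos.size - tp
    tn = neg.size - fp

    with np.errstate(invalid="ignore"):
        denom = np.sqrt(
            (tp + fp).astype(float) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mccs = np.where(denom > 0, (tp * tn - fp * fn) / np.where(denom > 0, denom, 1.0), 0.0)

    best = int(np.argmax(mccs))  # argmax takes the first = smallest cutoff on ties
    confusion = Confusion(tp=int(tp[best]), fp=int(fp[best]), tn=int(tn[best]), fn=int(fn[best]))
    return EvalResult(
        best_cutoff=float(cutoffs[best]),
        max_mcc=float(mccs[best]),
        acc_at_best=acc(confusion.tp, confusion.fp, confusion.tn, confusion.fn),
        confusion_at_best=confusion,
    )


class Ccdf:
    """Empirical complementary cumulative distribution of a score sample.

    ``ccdf(t)`` is the fraction of scores >= ``t``: a right-continuous,
    monotone non-increasing step function with ``ccdf(min - 1) = 1`` and
    ``ccdf(max + eps) = 0``.
    """

    def __init__(self, scores: Sequence[float]):
        arr = np.sort(np.asarray(scores, dtype=float))
        if arr.size == 0:
            raise DomainError("ccdf requires at least one score")
        if not np.all(np.isfinite(arr)):
            raise DomainError("ccdf scores must be finite")
        self._sorted = arr

    @property
    def support(self) -> np.ndarray:
        """Sorted distinct observed scores."""
        return np.unique(self._sorted)

    def __call__(self, threshold: float) -> float:
        n = self._sorted.size
        return float(n - np.searchsorted(self._sorted, threshold, side="left")) / n


def ccdf(scores: Sequence[float]) -> Ccdf:
    return Ccdf(scores)


def calibrate_boundaries(
    highrec_scores: Sequence[float],
    nonrec_scores: Sequence[float],
    high_retention: float = 0.95,
    nonrec_max: float = 0.25,
) -> Tuple[float, float]:
    """Derive (low_upper, high_lower) category boundaries from score samples.

    ``low_upper`` is the largest observed highly-recurrent score ``t`` with
    ``ccdf_highrec(t) >= high_retention`` (so ~``high_retention`` of highly
    recurrent mutations score above the low category); ``high_lower`` is the
    smallest observed non-recurrent score ``t`` with
    ``ccdf_nonrec(t) <= nonrec_max`` (so the high category holds at most
    ~``nonrec_max`` of non-recurrent mutations). Thresholds come from the
    observed score grids, not from interpolation.
    """
    ch = Ccdf(highrec_scores)
    cn = Ccdf(nonrec_scores)
    low_candidates = [t for t in ch.support if ch(t) >= high_retention]
    # ccdf(min) == 1, so there is always at least one candidate
    low_upper = float(max(low_candidates))
    high_candidates = [t for t in cn.support if cn(t) <= nonrec_max]
    if not high_candidates:
        raise CalibrationError(
            f"no observed score keeps the high category below {nonrec_max:.0%} "
            "of the non-recurrent distribution"
        )
    high_lower = float(min(high_candidates))
    if not low_upper < high_lower:
        raise CalibrationError(
            f"calibrated boundaries crossed: low_upper={low_upper} >= high_lower={high_lower}"
        )
    return low_upper, high_lower
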