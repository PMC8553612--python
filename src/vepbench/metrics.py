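"""Confusion matrices and the per-truth-set diagnostic metric panel.

For each tool–threshold combination versus a truth set, definite calls are
tallied into a 2×2 table (TP: called DEL and truly DEL; TN: called TOL and
truly TOL; FP: called DEL but TOL; FN: called TOL but DEL) — variants with
INDETERMINATE or MISSING calls are excluded. From the table come
prevalence, detection prevalence, sensitivity, specificity, PPV, NPV,
balanced accuracy (the primary pan-performance metric), F1, and MCC. AUC
is rank-based (Mann–Whitney with ties counted half) on the raw scores and
therefore threshold-free: variants indeterminate under a spec still
contribute.

Metrics with a zero denominator are flagged undefined, never silently
zeroed — a silent zero would corrupt the unweighted mean across the five
gene-specific truth sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .constants import (
    DEL,
    TOL,
    CALL_DEL,
    CALL_TOL,
    HIGHER_IS_DELETERIOUS,
    DIRECTIONS,
)
from .errors import DataError
from .truthset import TruthSet

__all__ = [
    "ConfusionCounts",
    "MetricPanel",
    "confusion_counts",
    "metric_panel",
    "auc",
    "mean_across_genes",
    "median_score_by_class",
]

PANEL_METRICS = (
    "prevalence",
    "detection_prevalence",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "balanced_accuracy",
    "f1",
    "mcc",
    "auc",
    "variant_inclusion",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 tally; cells may be half-integers after a Haldane correction."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion cells must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def empty(self) -> bool:
        return self.total == 0

    def inverted(self) -> "ConfusionCounts":
        """Relabel the dichotomy wholesale: DEL and TOL swap roles in both
        the calls and the truth set (positives become negatives)."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)

    def calls_inverted(self) -> "ConfusionCounts":
        """Flip every prediction (DEL call becomes TOL and vice versa)
        while the truth labels stay put."""
        return ConfusionCounts(tp=self.fn, fp=self.tn, tn=self.fp, fn=self.tp)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.tp, self.fp, self.tn, self.fn)


def confusion_counts(calls: pd.Series, ts: TruthSet) -> ConfusionCounts:
    """Tally definite calls against the truth set.

    Only variants present in the truth set with a DEL or TOL call enter
    the table. A column with zero definite calls yields the empty tally
    (flagged via ``ConfusionCounts.empty``), not an error.
    """
    aligned = calls.reindex(ts.keys)
    truth = ts.labels
    is_del_call = aligned == CALL_DEL
    is_tol_call = aligned == CALL_TOL
    tp = int((is_del_call & (truth == DEL)).sum())
    fp = int((is_del_call & (truth == TOL)).sum())
    tn = int((is_tol_call & (truth == TOL)).sum())
    fn = int((is_tol_call & (truth == DEL)).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class MetricPanel:
    """Full metric panel; None marks an undefined (zero-denominator) metric."""

    counts: ConfusionCounts
    prevalence: float | None = None
    detection_prevalence: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    balanced_accuracy: float | None = None
    f1: float | None = None
    mcc: float | None = None
    auc: float | None = None
    variant_inclusion: float | None = None
    # how many gene panels contributed to each metric when aggregated
    n_contributing: Mapping[str, int] | None = None

    def metric(self, name: str) -> float | None:
        return getattr(self, name)

    def defined(self, name: str) -> bool:
        return getattr(self, name) is not None

    def to_dict(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in PANEL_METRICS}


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metric_panel(
    c: ConfusionCounts,
    auc_value: float | None = None,
    variant_inclusion: float | None = None,
) -> MetricPanel:
    """Compute the panel from a confusion tally.

    AUC and variant inclusion are computed elsewhere (they need raw scores
    and the full truth set) and attached here for reporting.
    """
    if c.empty:
        raise DataError("cannot compute metrics from an empty confusion table")
    tp, fp, tn, fn = c.as_tuple()
    total = c.total
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    ba = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    f1 = (
        2.0 * ppv * sens / (ppv + sens)
        if ppv is not None and sens is not None and (ppv + sens) > 0
        else None
    )
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den > 0 else None
    return MetricPanel(
        counts=c,
        prevalence=_ratio(tp + fn, total),
        detection_prevalence=_ratio(tp + fp, total),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        balanced_accuracy=ba,
        f1=f1,
        mcc=float(mcc) if mcc is not None else None,
        auc=auc_value,
        variant_inclusion=variant_inclusion,
    )


def auc(
    scores: pd.Series,
    ts: TruthSet,
    direction: str = HIGHER_IS_DELETERIOUS,
) -> tuple[float | None, bool]:
    """Rank-based (Mann–Whitney) AUC with ties counted one half.

    Direction-aware: a perfect lower-is-deleterious tool scores 1.0.
    Returns (auc, defined); single-class or empty input is undefined.
    """
    if direction not in DIRECTIONS:
        raise DataError(f"bad direction {direction!r}")
    values = pd.to_numeric(scores.reindex(ts.keys), errors="coerce")
    mask = values.notna()
    values = values[mask].to_numpy(dtype=float)
    truth = ts.labels[mask]
    n_del = int((truth == DEL).sum())
    n_tol = int((truth == TOL).sum())
    if n_del == 0 or n_tol == 0:
        return None, False
    if direction != HIGHER_IS_DELETERIOUS:
        values = -values
    ranks = rankdata(values)  # average ranks: ties count 1/2
    rank_sum_del = float(ranks[(truth == DEL).to_numpy()].sum())
    u = rank_sum_del - n_del * (n_del + 1) / 2.0
    return u / (n_del * n_tol), True


def mean_across_genes(panels: Sequence[MetricPanel]) -> MetricPanel:
    """Unweighted arithmetic mean of each metric over gene-specific panels.

    A metric undefined in some gene is averaged over the genes where it is
    defined, and the number of contributing genes is recorded. Counts are
    summed for reference only; derived metrics are NOT recomputed from the
    pooled table.
    """
    if not panels:
        raise DataError("mean_across_genes needs at least one panel")
    values: dict[str, float | None] = {}
    n_contributing: dict[str, int] = {}
    for m in PANEL_METRICS:
        defined = [p.metric(m) for p in panels if p.metric(m) is not None]
        n_contributing[m] = len(defined)
        values[m] = float(np.mean(defined)) if defined else None
    pooled = ConfusionCounts(
        tp=sum(p.counts.tp for p in panels),
        fp=sum(p.counts.fp for p in panels),
        tn=sum(p.counts.tn for p in panels),
        fn=sum(p.counts.fn for p in panels),
    )
    return MetricPanel(counts=pooled, n_contributing=n_contributing, **values)


def median_score_by_class(
    scores: pd.Series, classes: pd.Series
) -> dict[str, float]:
    """Per-class median raw score, including classes outside the truth set.

    Used to ask where assay-intermediate variants score relative to the
    deleterious and tolerated medians. Classes with no scored variant are
    omitted.
    """
    values = pd.to_numeric(scores, errors="coerce")
    out: dict[str, float] = {}
    for cls, sub in values.groupby(classes):
        sub = sub.dropna()
        if len(sub):
            out[str(cls)] = float(sub.median())
    return out
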