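"""Positive and negative likelihood ratios with CIs, Haldane correction,
and score-band analyses.

PLR = sensitivity / (1 − specificity) quantifies evidence toward
pathogenicity of a DEL call. The NLR here follows the benignity-oriented
convention used for clinical evidence calibration: NLR = specificity /
(1 − sensitivity), the true-negative rate over the false-negative rate, so
values above 1 are evidence toward benignity. The conventional ratio
(1 − sensitivity)/specificity is emitted alongside to avoid ambiguity.

When any 2×2 cell is zero the Haldane correction adds 0.5 to all four
cells before ratio and variance estimation. 95% confidence intervals use
the standard log-SE method: exp(ln L̂ ± 1.96·SE) with
SE_lnPLR = sqrt(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)) and the TP↔TN,
FP↔FN swap for the NLR.

Banded analyses compare a closed score band against a reference region
(e.g. scores 0.8–1.0 versus <0.7 for pathogenicity; 0–0.4 versus >0.7 for
benignity), excluding variants in neither region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEL, TOL
from .errors import DataError
from .metrics import ConfusionCounts
from .truthset import TruthSet

__all__ = [
    "LRResult",
    "BandDefinition",
    "haldane_correct",
    "likelihood_ratios",
    "conventional_nlr",
    "banded_lr",
    "mean_lr_across_genes",
    "default_bands",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class LRResult:
    """One likelihood ratio with its 95% CI and correction provenance."""

    kind: str  # "PLR" or "NLR"
    estimate: float
    ci_low: float
    ci_high: float
    haldane_applied: bool
    counts_used: ConfusionCounts
    method: str = "log-se"

    def __post_init__(self) -> None:
        if self.estimate <= 0:
            raise DataError("likelihood ratio must be positive")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise DataError("CI must bracket the estimate")


@dataclass(frozen=True)
class BandDefinition:
    """A closed score band compared against a reference half-line.

    ``kind`` selects the reported ratio: "PLR" bands sit above the working
    threshold and are compared to the low-score reference (evidence toward
    pathogenicity of a score falling in the band); "NLR" bands sit below
    and are compared to the high-score reference (evidence toward
    benignity). The band and reference regions must not intersect;
    variants in neither are excluded.
    """

    band_low: float
    band_high: float
    reference_comparator: str  # "<", "<=", ">", ">="
    reference_cutoff: float
    kind: str = "PLR"

    def __post_init__(self) -> None:
        if self.band_low > self.band_high:
            raise DataError("band_low must be <= band_high")
        if self.kind not in ("PLR", "NLR"):
            raise DataError(f"band kind must be PLR or NLR, got {self.kind!r}")
        if self.reference_comparator not in ("<", "<=", ">", ">="):
            raise DataError(f"bad comparator {self.reference_comparator!r}")
        # disjointness of [band_low, band_high] and the reference half-line
        c = self.reference_cutoff
        if self.reference_comparator == "<" and self.band_low < c:
            raise DataError("band intersects reference region")
        if self.reference_comparator == "<=" and self.band_low <= c:
            raise DataError("band intersects reference region")
        if self.reference_comparator == ">" and self.band_high > c:
            raise DataError("band intersects reference region")
        if self.reference_comparator == ">=" and self.band_high >= c:
            raise DataError("band intersects reference region")

    def in_band(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.band_low) & (values <= self.band_high)

    def in_reference(self, values: np.ndarray) -> np.ndarray:
        ops = {
            "<": np.less,
            "<=": np.less_equal,
            ">": np.greater,
            ">=": np.greater_equal,
        }
        return ops[self.reference_comparator](values, self.reference_cutoff)


def haldane_correct(c: ConfusionCounts) -> tuple[ConfusionCounts, bool]:
    """Add 0.5 to every cell iff any cell is zero; idempotent by design."""
    if min(c.as_tuple()) > 0:
        return c, False
    return (
        ConfusionCounts(tp=c.tp + 0.5, fp=c.fp + 0.5, tn=c.tn + 0.5, fn=c.fn + 0.5),
        True,
    )


def _lr_from_cells(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    """Generic two-proportion ratio with log-SE CI.

    Ratio = (a/(a+c)) / (b/(b+d)); SE on the log scale is
    sqrt(1/a − 1/(a+c) + 1/b − 1/(b+d)).
    """
    est = (a / (a + c)) / (b / (b + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + c) + 1.0 / b - 1.0 / (b + d))
    log_est = math.log(est)
    return est, math.exp(log_est - Z95 * se), math.exp(log_est + Z95 * se)


def likelihood_ratios(c: ConfusionCounts) -> tuple[LRResult, LRResult]:
    """(PLR, NLR) with 95% CIs; Haldane-corrects zero cells first.

    PLR = sens/(1−spec) = (TP/(TP+FN)) / (FP/(FP+TN));
    NLR (benignity-oriented) = spec/(1−sens) = (TN/(TN+FP)) / (FN/(FN+TP)).
    """
    if c.empty:
        raise DataError("cannot compute likelihood ratios from empty counts")
    corrected, applied = haldane_correct(c)
    tp, fp, tn, fn = corrected.as_tuple()
    plr_est, plr_lo, plr_hi = _lr_from_cells(tp, fp, fn, tn)
    nlr_est, nlr_lo, nlr_hi = _lr_from_cells(tn, fn, fp, tp)
    return (
        LRResult("PLR", plr_est, plr_lo, plr_hi, applied, corrected),
        LRResult("NLR", nlr_est, nlr_lo, nlr_hi, applied, corrected),
    )


def conventional_nlr(nlr: LRResult) -> float:
    """The textbook negative likelihood ratio (1−sens)/spec = 1/NLR here."""
    return 1.0 / nlr.estimate


def banded_lr(
    scores: pd.Series, ts: TruthSet, band: BandDefinition
) -> tuple[LRResult | None, bool]:
    """Likelihood ratio of a score band against its reference region.

    Restricts to truth-set variants scoring in band ∪ reference. For a
    PLR band the ratio is P(band | DEL) / P(band | TOL); for an NLR band
    it is P(band | TOL) / P(band | DEL) — both conditioned on the
    restricted region. Zero cells take the Haldane path. Returns
    (result, defined); an empty band ∪ reference is undefined.
    """
    values = pd.to_numeric(scores.reindex(ts.keys), errors="coerce")
    mask = values.notna()
    vals = values[mask].to_numpy(dtype=float)
    truth = ts.labels[mask].to_numpy()
    in_band = band.in_band(vals)
    in_ref = band.in_reference(vals)
    used = in_band | in_ref
    if not used.any():
        return None, False
    is_del = truth == DEL
    is_tol = truth == TOL
    counts = ConfusionCounts(
        tp=int((in_band & is_del).sum()),
        fp=int((in_band & is_tol).sum()),
        fn=int((in_ref & is_del).sum()),
        tn=int((in_ref & is_tol).sum()),
    )
    if counts.empty:
        return None, False
    corrected, applied = haldane_correct(counts)
    tp, fp, tn, fn = corrected.as_tuple()
    if band.kind == "PLR":
        est, lo, hi = _lr_from_cells(tp, fp, fn, tn)
    else:
        est, lo, hi = _lr_from_cells(fp, tp, tn, fn)
    return LRResult(band.kind, est, lo, hi, applied, corrected), True


def mean_lr_across_genes(
    results: Sequence[LRResult], pooling: str = "arithmetic"
) -> LRResult:
    """Unweighted mean of per-gene likelihood ratios.

    Default: arithmetic means of the estimates and of the CI bounds.
    ``pooling="log"`` takes geometric means instead (means on the log
    scale). The pooling mode is recorded in the result's method field.
    """
    if not results:
        raise DataError("mean_lr_across_genes needs at least one result")
    kinds = {r.kind for r in results}
    if len(kinds) > 1:
        raise DataError(f"cannot average mixed LR kinds: {kinds}")
    if pooling == "arithmetic":
        est = float(np.mean([r.estimate for r in results]))
        lo = float(np.mean([r.ci_low for r in results]))
        hi = float(np.mean([r.ci_high for r in results]))
    elif pooling == "log":
        est = float(np.exp(np.mean([np.log(r.estimate) for r in results])))
        lo = float(np.exp(np.mean([np.log(r.ci_low) for r in results])))
        hi = float(np.exp(np.mean([np.log(r.ci_high) for r in results])))
    else:
        raise DataError(f"unknown pooling mode {pooling!r}")
    pooled = ConfusionCounts(
        tp=sum(r.counts_used.tp for r in results),
        fp=sum(r.counts_used.fp for r in results),
        tn=sum(r.counts_used.tn for r in results),
        fn=sum(r.counts_used.fn for r in results),
    )
    return LRResult(
        kind=results[0].kind,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        haldane_applied=any(r.haldane_applied for r in results),
        counts_used=pooled,
        method=f"mean-of-gene-LRs ({pooling})",
    )


def default_bands(threshold: float = 0.7) -> list[BandDefinition]:
    """The published band layout for [0, 1] metapredictor scores.

    Pathogenicity bands above the working threshold compared to scores
    below it, and benignity bands below compared to scores above it.
    """
    return [
        BandDefinition(0.9, 1.0, "<", threshold, kind="PLR"),
        BandDefinition(0.8, 1.0, "<", threshold, kind="PLR"),
        BandDefinition(0.8, 0.9, "<", threshold, kind="PLR"),
        BandDefinition(0.7, 0.8, "<", 0.7, kind="PLR"),
        BandDefinition(0.5, 0.7, ">", threshold, kind="NLR"),
        BandDefinition(0.4, 0.5, ">", threshold, kind="NLR"),
        BandDefinition(0.0, 0.5, ">", threshold, kind="NLR"),
        BandDefinition(0.0, 0.4, ">", threshold, kind="NLR"),
    ]
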