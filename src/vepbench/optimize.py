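"""Balanced-accuracy-optimal cutoffs by grid iteration, plus cross-gene consensus.

For each tool and gene-specific truth set, candidate cutoffs start at the
lowest observed score and advance in steps of 2% of the observed score
range (tools live on heterogeneous scales — some unbounded — so the step
is relative by default; an absolute-step mode suits [0, 1] tools). The
search stops once the candidate exceeds the maximum observed score. At
each candidate the scores are dichotomized (strictly above the cutoff is
deleterious for a higher-is-deleterious tool, strictly below for the
mirrored direction) and balanced accuracy computed; the lowest cutoff
attaining the maximal BA is returned.

The consensus threshold is the unweighted mean of the per-gene optima,
re-evaluated against each gene-specific truth set and the combined set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import DEL, TOL, HIGHER_IS_DELETERIOUS, DIRECTIONS
from .errors import DataError
from .truthset import TruthSet

__all__ = [
    "GridSearchOutcome",
    "ThresholdSearchResult",
    "dichotomize_ba",
    "optimize_threshold",
    "consensus_and_evaluate",
]


@dataclass(frozen=True)
class GridSearchOutcome:
    """Best cutoff found on one truth set, with the BA it achieves."""

    cutoff: float
    balanced_accuracy: float
    n_candidates: int
    step: float


@dataclass(frozen=True)
class ThresholdSearchResult:
    """Per-gene optima plus the consensus threshold and its evaluation."""

    tool_name: str
    per_gene_optima: Mapping[str, float]
    per_gene_ba_at_optimum: Mapping[str, float]
    consensus_cutoff: float
    per_gene_ba_at_consensus: Mapping[str, float]
    combined_ba_at_consensus: float | None
    search_step: float


def _prepare(scores: pd.Series, ts: TruthSet) -> tuple[np.ndarray, np.ndarray]:
    values = pd.to_numeric(scores.reindex(ts.keys), errors="coerce")
    mask = values.notna().to_numpy()
    vals = values.to_numpy(dtype=float)[mask]
    truth = ts.labels.to_numpy()[mask]
    return vals, truth


def dichotomize_ba(
    values: np.ndarray,
    truth: np.ndarray,
    cutoff: float,
    direction: str = HIGHER_IS_DELETERIOUS,
) -> float | None:
    """BA of the binary rule score > cutoff ⇒ DEL (mirrored for lower-is-del).

    Returns None when either truth class has no scored variant.
    """
    if direction == HIGHER_IS_DELETERIOUS:
        call_del = values > cutoff
    else:
        call_del = values < cutoff
    is_del = truth == DEL
    is_tol = truth == TOL
    n_del = int(is_del.sum())
    n_tol = int(is_tol.sum())
    if n_del == 0 or n_tol == 0:
        return None
    sens = float((call_del & is_del).sum()) / n_del
    spec = float((~call_del & is_tol).sum()) / n_tol
    return (sens + spec) / 2.0


def optimize_threshold(
    scores: pd.Series,
    ts: TruthSet,
    direction: str = HIGHER_IS_DELETERIOUS,
    step_fraction: float = 0.02,
    absolute_step: float | None = None,
) -> GridSearchOutcome:
    """Grid search for the BA-optimal dichotomizing cutoff.

    Candidates run from the lowest observed score in increments of
    ``step_fraction`` × (max − min) (or ``absolute_step`` if given) and
    stop once above the maximum observed score. Ties break toward the
    lowest cutoff. Rejects single-class truth sets and constant scores.
    """
    if direction not in DIRECTIONS:
        raise DataError(f"bad direction {direction!r}")
    values, truth = _prepare(scores, ts)
    if len(values) == 0:
        raise DataError("no scored truth-set variants")
    if (truth == DEL).sum() == 0 or (truth == TOL).sum() == 0:
        raise DataError("threshold optimization needs both truth classes scored")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DataError("all scores identical: no grid to search")
    step = absolute_step if absolute_step is not None else step_fraction * (hi - lo)
    if step <= 0:
        raise DataError("grid step must be positive")
    # grid: lo, lo+step, ... first value strictly above hi terminates
    n_steps = int(np.floor((hi - lo) / step)) + 1
    candidates = lo + step * np.arange(n_steps + 1)
    candidates = candidates[candidates <= hi + step]  # one step past max at most
    best_cutoff: float | None = None
    best_ba = -np.inf
    for cut in candidates:
        if cut > hi:
            break
        ba = dichotomize_ba(values, truth, float(cut), direction)
        if ba is not None and ba > best_ba + 1e-12:
            best_ba = ba
            best_cutoff = float(cut)
    return GridSearchOutcome(
        cutoff=best_cutoff,
        balanced_accuracy=float(best_ba),
        n_candidates=int((candidates <= hi).sum()),
        step=float(step),
    )


def consensus_and_evaluate(
    tool_name: str,
    scores: pd.Series,
    gene_truthsets: Mapping[str, TruthSet],
    combined: TruthSet | None = None,
    direction: str = HIGHER_IS_DELETERIOUS,
    step_fraction: float = 0.02,
) -> ThresholdSearchResult:
    """Optimize per gene, average the optima, re-evaluate everywhere.

    The consensus cutoff is the unweighted mean of the per-gene optimal
    cutoffs; BA at that single consensus value is then computed for each
    gene-specific truth set and for the combined set.
    """
    if not gene_truthsets:
        raise DataError("consensus needs at least one gene truth set")
    optima: dict[str, float] = {}
    ba_at_opt: dict[str, float] = {}
    steps: list[float] = []
    for gene, ts in gene_truthsets.items():
        outcome = optimize_threshold(scores, ts, direction, step_fraction)
        optima[gene] = outcome.cutoff
        ba_at_opt[gene] = outcome.balanced_accuracy
        steps.append(outcome.step)
    consensus = float(np.mean(list(optima.values())))
    ba_at_consensus: dict[str, float] = {}
    for gene, ts in gene_truthsets.items():
        values, truth = _prepare(scores, ts)
        ba = dichotomize_ba(values, truth, consensus, direction)
        if ba is not None:
            ba_at_consensus[gene] = ba
    combined_ba = None
    if combined is not None:
        values, truth = _prepare(scores, combined)
        combined_ba = dichotomize_ba(values, truth, consensus, direction)
    return ThresholdSearchResult(
        tool_name=tool_name,
        per_gene_optima=optima,
        per_gene_ba_at_optimum=ba_at_opt,
        consensus_cutoff=consensus,
        per_gene_ba_at_consensus=ba_at_consensus,
        combined_ba_at_consensus=combined_ba,
        search_step=float(np.mean(steps)),
    )
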