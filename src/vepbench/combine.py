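"""Tool combinations under the full-concordance model.

A combination keeps a variant only when every member tool makes a
definite call (DEL or TOL) and all calls agree; discordant variants drop
out. The combined call column then feeds the ordinary metric machinery.
Any apparent gain in balanced accuracy must be read against the dropout
this exclusion causes, so the dropout fraction is reported both over
variants where all members made definite calls (the default denominator)
and over all truth-set variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CALL_MISSING, CALL_INDETERMINATE, DEFINITE_CALLS
from .errors import DataError
from .metrics import ConfusionCounts, MetricPanel, confusion_counts, metric_panel
from .truthset import TruthSet

__all__ = ["ConcordanceResult", "combine_concordant", "rank_and_pair"]


@dataclass(frozen=True)
class ConcordanceResult:
    """Combined call column for a set of member specs, with dropout accounting."""

    member_specs: tuple[str, ...]
    combined_calls: pd.Series
    n_all_definite: int  # variants where every member made a definite call
    n_retained: int  # of those, the concordant ones
    dropout_fraction: float  # discordant / all-definite
    dropout_fraction_all: float  # discordant / all variants in the key space

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise DataError("dropout_fraction outside [0, 1]")


def combine_concordant(columns: pd.DataFrame) -> ConcordanceResult:
    """Combine ≥2 call columns under full concordance.

    A variant keeps the common call iff every member's call is definite
    and identical; variants where some member is MISSING/INDETERMINATE are
    'incomplete' (not counted as discordant), and variants where all
    members are definite but disagree are the discordant dropout.
    """
    if columns.shape[1] < 2:
        raise DataError("concordance combination needs at least two columns")
    calls = columns.to_numpy(dtype=object)
    definite = np.isin(calls, DEFINITE_CALLS)
    all_definite = definite.all(axis=1)
    first = calls[:, 0]
    agree = (calls == first[:, None]).all(axis=1)
    retained = all_definite & agree
    n_all_definite = int(all_definite.sum())
    n_retained = int(retained.sum())
    n_discordant = n_all_definite - n_retained
    # non-retained variants are MISSING if any member was missing, else
    # indeterminate (discordant or in some member's indeterminate zone);
    # for reporting only — both are excluded from confusion counts
    any_missing = (calls == CALL_MISSING).any(axis=1)
    combined = np.where(retained, first, CALL_INDETERMINATE)
    combined = np.where(~retained & any_missing, CALL_MISSING, combined)
    return ConcordanceResult(
        member_specs=tuple(columns.columns),
        combined_calls=pd.Series(combined, index=columns.index, dtype=object),
        n_all_definite=n_all_definite,
        n_retained=n_retained,
        dropout_fraction=(n_discordant / n_all_definite) if n_all_definite else 0.0,
        dropout_fraction_all=(n_discordant / len(columns)) if len(columns) else 0.0,
    )


def _mean_ba_on_retained(
    result: ConcordanceResult, gene_truthsets: Mapping[str, TruthSet]
) -> tuple[float | None, int]:
    """Unweighted mean BA over genes, computed on the retained variants."""
    bas = []
    for ts in gene_truthsets.values():
        counts = confusion_counts(result.combined_calls, ts)
        if counts.empty:
            continue
        panel = metric_panel(counts)
        if panel.balanced_accuracy is not None:
            bas.append(panel.balanced_accuracy)
    return (float(np.mean(bas)) if bas else None, len(bas))


def rank_and_pair(
    call_table: pd.DataFrame,
    mean_panels: Mapping[str, MetricPanel],
    gene_truthsets: Mapping[str, TruthSet],
    top_k: int = 12,
) -> pd.DataFrame:
    """Pair the best-BA specs and evaluate every pair under concordance.

    Specs are ranked by mean-across-genes balanced accuracy (ties broken
    by MCC, then spec label); the top ``top_k`` are combined pairwise.
    Each pair's BA is the gene-wise mean on its retained variants. Output
    rows are sorted by pair BA, descending.
    """
    ranked = sorted(
        (name for name in mean_panels if mean_panels[name].balanced_accuracy is not None),
        key=lambda name: (
            -mean_panels[name].balanced_accuracy,
            -(mean_panels[name].mcc if mean_panels[name].mcc is not None else -np.inf),
            name,
        ),
    )
    if len(ranked) < 2:
        raise DataError("pairing needs at least two ranked specs")
    if top_k > len(ranked):
        top = ranked
    else:
        top = ranked[:top_k]
    rows = []
    for a, b in itertools.combinations(top, 2):
        result = combine_concordant(call_table[[a, b]])
        mean_ba, n_genes = _mean_ba_on_retained(result, gene_truthsets)
        rows.append(
            {
                "members": f"{a}+{b}",
                "n_all_definite": result.n_all_definite,
                "n_retained": result.n_retained,
                "dropout_fraction": result.dropout_fraction,
                "dropout_fraction_all": result.dropout_fraction_all,
                "mean_ba": mean_ba,
                "n_genes": n_genes,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "members",
            "n_all_definite",
            "n_retained",
            "dropout_fraction",
            "dropout_fraction_all",
            "mean_ba",
            "n_genes",
        ],
    )
    return frame.sort_values(
        by=["mean_ba", "members"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
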