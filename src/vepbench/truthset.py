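"""Truth-set curation from per-variant assay records.

Functional truth sets retain only missense variants away from the two
exonic bases flanking intron–exon boundaries (potentially spliceogenic),
whose assay outcomes are unanimous and not intermediate: unanimous
nonfunctional becomes DEL, unanimous functional becomes TOL. Every
dropped variant is logged with exactly one reason, applying the rules in
the fixed precedence non-missense > splice-flank > discordant >
intermediate.

ClinVar truth sets are restricted to variants already in the functional
truth set: P/LP at any star rating become DEL; B/LB at one star or more
become TOL; everything else is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .constants import (
    DEL,
    TOL,
    FUNCTIONAL,
    NONFUNCTIONAL,
    ASSAY_INTERMEDIATE,
    MISSENSE,
    REASON_NON_MISSENSE,
    REASON_SPLICE_FLANK,
    REASON_DISCORDANT,
    REASON_INTERMEDIATE,
)
from .errors import DataError

__all__ = [
    "VariantRecord",
    "TruthSet",
    "AssayRule",
    "classify_assay_scores",
    "curate_functional_truthset",
    "build_clinvar_truthset",
    "truthset_summary",
    "records_to_frame",
    "frame_to_records",
]


@dataclass(frozen=True)
class VariantRecord:
    """One variant with its assay outcomes and optional ClinVar annotation."""

    variant_key: str
    gene: str
    consequence: str = MISSENSE
    splice_flank: bool = False
    assay_outcomes: tuple[str, ...] = ()
    clinvar_class: str | None = None
    clinvar_stars: int = 0


@dataclass
class TruthSet:
    """Curated variant → {DEL, TOL} mapping, stratified by gene.

    ``labels`` and ``genes`` are aligned Series indexed by variant_key.
    """

    labels: pd.Series
    genes: pd.Series
    provenance: str = "functional"

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, dtype=object)
        self.genes = pd.Series(self.genes, dtype=object)
        if not self.labels.index.equals(self.genes.index):
            raise DataError("labels and genes must share the same variant keys")
        if self.labels.index.has_duplicates:
            raise DataError("duplicate variant keys in truth set")
        bad = set(self.labels.unique()) - {DEL, TOL}
        if bad:
            raise DataError(f"truth-set labels outside {{DEL, TOL}}: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def keys(self) -> pd.Index:
        return self.labels.index

    @property
    def gene_strata(self) -> dict[str, pd.Index]:
        return {
            str(g): self.labels.index[self.genes == g]
            for g in self.genes.unique()
        }

    def n_class(self, label: str) -> int:
        return int((self.labels == label).sum())

    def stratum(self, gene: str) -> "TruthSet":
        mask = self.genes == gene
        return TruthSet(self.labels[mask], self.genes[mask], self.provenance)

    @classmethod
    def from_mapping(
        cls,
        entries: Mapping[str, str],
        genes: Mapping[str, str],
        provenance: str = "functional",
    ) -> "TruthSet":
        keys = list(entries)
        return cls(
            labels=pd.Series([entries[k] for k in keys], index=keys),
            genes=pd.Series([genes[k] for k in keys], index=keys),
            provenance=provenance,
        )


@dataclass(frozen=True)
class AssayRule:
    """Numeric rule mapping one assay's raw score to an outcome.

    For ``higher_is_functional`` assays, scores at or above
    ``functional_min`` are functional and scores at or below
    ``nonfunctional_max`` are nonfunctional; anything between is
    intermediate. Mirrored when ``higher_is_functional`` is False.
    """

    assay_name: str
    nonfunctional_max: float
    functional_min: float
    higher_is_functional: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.nonfunctional_max, self.functional_min
        if self.higher_is_functional and not lo < hi:
            raise DataError(
                f"{self.assay_name}: nonfunctional_max must be < functional_min"
            )
        if not self.higher_is_functional and not lo > hi:
            raise DataError(
                f"{self.assay_name}: nonfunctional_max must be > functional_min"
            )

    def classify(self, score: float) -> str:
        if self.higher_is_functional:
            if score >= self.functional_min:
                return FUNCTIONAL
            if score <= self.nonfunctional_max:
                return NONFUNCTIONAL
        else:
            if score <= self.functional_min:
                return FUNCTIONAL
            if score >= self.nonfunctional_max:
                return NONFUNCTIONAL
        return ASSAY_INTERMEDIATE


def classify_assay_scores(
    scores: Mapping[str, Sequence[float]] | pd.DataFrame,
    rules: Sequence[AssayRule],
) -> list[tuple[str, ...]]:
    """Apply per-assay cutoff rules to raw score columns.

    ``scores`` holds one column per assay (named as in ``rules``); returns
    one outcome tuple per row, ordered as the rules.
    """
    frame = pd.DataFrame(scores)
    missing = [r.assay_name for r in rules if r.assay_name not in frame.columns]
    if missing:
        raise DataError(f"assay score columns missing: {missing}")
    outcome_cols = [
        [rule.classify(float(v)) for v in frame[rule.assay_name]] for rule in rules
    ]
    return [tuple(col[i] for col in outcome_cols) for i in range(len(frame))]


def _as_records(records: Iterable[VariantRecord] | pd.DataFrame) -> list[VariantRecord]:
    if isinstance(records, pd.DataFrame):
        return frame_to_records(records)
    return list(records)


def frame_to_records(frame: pd.DataFrame) -> list[VariantRecord]:
    """Build VariantRecords from a table (e.g. the simulator's output)."""
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        outcomes = d.get("assay_outcomes", ())
        if isinstance(outcomes, str):
            outcomes = tuple(s for s in outcomes.split(";") if s)
        cv = d.get("clinvar_class")
        if pd.isna(cv) if not isinstance(cv, str) else False:
            cv = None
        out.append(
            VariantRecord(
                variant_key=str(d["variant_key"]),
                gene=str(d["gene"]),
                consequence=str(d.get("consequence", MISSENSE)),
                splice_flank=bool(d.get("splice_flank", False)),
                assay_outcomes=tuple(outcomes or ()),
                clinvar_class=cv,
                clinvar_stars=int(d.get("clinvar_stars") or 0),
            )
        )
    return out


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Serialize records to the canonical TSV-ready table."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_key": r.variant_key,
                "gene": r.gene,
                "consequence": r.consequence,
                "splice_flank": r.splice_flank,
                "assay_outcomes": ";".join(r.assay_outcomes),
                "clinvar_class": r.clinvar_class,
                "clinvar_stars": r.clinvar_stars,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_key",
            "gene",
            "consequence",
            "splice_flank",
            "assay_outcomes",
            "clinvar_class",
            "clinvar_stars",
        ],
    )


def curate_functional_truthset(
    records: Iterable[VariantRecord] | pd.DataFrame,
) -> tuple[TruthSet, pd.DataFrame]:
    """Curate the functional truth set and log one reason per exclusion.

    A variant is retained iff it is missense, not splice-flanking, all its
    assay outcomes agree, and the agreed outcome is not intermediate.
    Unanimous nonfunctional → DEL; unanimous functional → TOL. The
    exclusion log has columns (variant_key, gene, reason) with the first
    matching reason in precedence order.
    """
    recs = _as_records(records)
    seen: set[str] = set()
    labels: dict[str, str] = {}
    genes: dict[str, str] = {}
    excluded: list[dict[str, str]] = []
    for r in recs:
        if r.variant_key in seen:
            raise DataError(f"duplicate variant key {r.variant_key!r}")
        seen.add(r.variant_key)
        if not r.assay_outcomes:
            raise DataError(f"{r.variant_key}: no assay outcomes")
        reason = None
        if r.consequence != MISSENSE:
            reason = REASON_NON_MISSENSE
        elif r.splice_flank:
            reason = REASON_SPLICE_FLANK
        elif len(set(r.assay_outcomes)) > 1:
            reason = REASON_DISCORDANT
        elif r.assay_outcomes[0] == ASSAY_INTERMEDIATE:
            reason = REASON_INTERMEDIATE
        if reason is not None:
            excluded.append(
                {"variant_key": r.variant_key, "gene": r.gene, "reason": reason}
            )
            continue
        outcome = r.assay_outcomes[0]
        if outcome not in (FUNCTIONAL, NONFUNCTIONAL):
            raise DataError(
                f"{r.variant_key}: unknown assay outcome {outcome!r}"
            )
        labels[r.variant_key] = DEL if outcome == NONFUNCTIONAL else TOL
        genes[r.variant_key] = r.gene
    truth = TruthSet.from_mapping(labels, genes, provenance="functional")
    log = pd.DataFrame(excluded, columns=["variant_key", "gene", "reason"])
    return truth, log


def build_clinvar_truthset(
    records: Iterable[VariantRecord] | pd.DataFrame,
    functional_keys: Iterable[str],
) -> TruthSet:
    """ClinVar truth set over variants in the functional truth set.

    P/LP (any star rating) → DEL; B/LB with at least one star → TOL; all
    other annotations (VUS, no stars on the benign arm, unannotated) drop.
    """
    recs = _as_records(records)
    allowed = set(functional_keys)
    labels: dict[str, str] = {}
    genes: dict[str, str] = {}
    for r in recs:
        if r.variant_key not in allowed:
            continue
        if r.clinvar_class in ("P", "LP"):
            labels[r.variant_key] = DEL
        elif r.clinvar_class in ("B", "LB") and r.clinvar_stars >= 1:
            labels[r.variant_key] = TOL
        else:
            continue
        genes[r.variant_key] = r.gene
    return TruthSet.from_mapping(labels, genes, provenance="clinvar")


def truthset_summary(ts: TruthSet) -> pd.DataFrame:
    """Per-gene and overall DEL/TOL counts and prevalence.

    Prevalence = DEL / (DEL + TOL). An empty stratum gets a ``defined``
    flag of False rather than a NaN that would propagate silently.
    """
    rows = []
    for gene in sorted(ts.genes.unique(), key=str):
        sub = ts.labels[ts.genes == gene]
        rows.append(_summary_row(str(gene), sub))
    rows.append(_summary_row("ALL", ts.labels))
    return pd.DataFrame(
        rows, columns=["stratum", "n", "n_del", "n_tol", "prevalence", "defined"]
    )


def _summary_row(name: str, labels: pd.Series) -> dict[str, Any]:
    n_del = int((labels == DEL).sum())
    n_tol = int((labels == TOL).sum())
    total = n_del + n_tol
    return {
        "stratum": name,
        "n": total,
        "n_del": n_del,
        "n_tol": n_tol,
        "prevalence": (n_del / total) if total else None,
        "defined": bool(total),
    }
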