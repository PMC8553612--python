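"""Harmonization of raw tool outputs into DEL/TOL/INDETERMINATE/MISSING calls.

Each tool–threshold combination is a declarative :class:`ToolThresholdSpec`
authored on the tool's native scale: a TOL rule and a DEL rule, each a
comparator plus cutoff. Binary specs partition the score line; nonbinary
specs leave a gap — the indeterminate zone — between the two regions.
Boundary comparators are part of the spec (published combinations mix
"<0.4", "≤0.7", ">0.5"), never a global convention, and rules for
lower-is-deleterious tools are written directly on the raw scale rather
than being flipped.

Two published exclusion rules operate at the tool level: a combination is
dropped if it produces no discrimination (all calls identical) or if it
produces values for under 25% of truth-set variants. INDETERMINATE and
MISSING stay distinct end to end: both are excluded from confusion counts
and both reduce variant inclusion, but only MISSING counts against
coverage — an indeterminate call is still a produced value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import (
    CALL_DEL,
    CALL_TOL,
    CALL_INDETERMINATE,
    CALL_MISSING,
    DEFINITE_CALLS,
    HIGHER_IS_DELETERIOUS,
    DIRECTIONS,
)
from .errors import ConfigError, DataError

__all__ = [
    "Rule",
    "ToolThresholdSpec",
    "apply_threshold_spec",
    "build_call_table",
    "discrimination_filter",
    "coverage_filter",
    "variant_inclusion",
    "apply_tool_filters",
    "specs_to_dicts",
    "specs_from_dicts",
    "load_specs",
    "save_specs",
]

_COMPARATORS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class Rule:
    """One half-line region of the score axis: comparator plus cutoff."""

    comparator: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ConfigError(f"unknown comparator {self.comparator!r}")

    def satisfied(self, scores: np.ndarray) -> np.ndarray:
        return _COMPARATORS[self.comparator](scores, self.cutoff)

    @property
    def is_lower(self) -> bool:
        return self.comparator in ("<", "<=")

    def covers_boundary(self) -> bool:
        return self.comparator in ("<=", ">=")


def _regions_overlap(a: Rule, b: Rule) -> bool:
    """Do two half-line regions intersect?"""
    if a.is_lower == b.is_lower:
        return True  # same side: always overlap
    lower, upper = (a, b) if a.is_lower else (b, a)
    if lower.cutoff > upper.cutoff:
        return True
    if lower.cutoff == upper.cutoff:
        return lower.covers_boundary() and upper.covers_boundary()
    return False


def _regions_partition(a: Rule, b: Rule) -> bool:
    """Do two disjoint half-line regions jointly cover the whole line?"""
    lower, upper = (a, b) if a.is_lower else (b, a)
    return lower.cutoff == upper.cutoff and (
        lower.covers_boundary() != upper.covers_boundary()
        or (lower.covers_boundary() and upper.covers_boundary())
    )


@dataclass(frozen=True)
class ToolThresholdSpec:
    """Declarative rule turning one tool's raw output into calls.

    Continuous specs carry a ``tol_rule`` and a ``del_rule``; a score
    satisfying the DEL rule is called DEL, one satisfying the TOL rule is
    called TOL, anything between is INDETERMINATE and an absent value is
    MISSING. Categorical specs instead carry ``categorical_map``; raw
    categories missing from the map yield MISSING.
    """

    tool_name: str
    spec_name: str
    direction: str = HIGHER_IS_DELETERIOUS
    tol_rule: Rule | None = None
    del_rule: Rule | None = None
    categorical_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"{self.spec_name}: bad direction {self.direction!r}")
        if self.categorical_map is not None:
            bad = set(self.categorical_map.values()) - set(DEFINITE_CALLS)
            if bad:
                raise ConfigError(
                    f"{self.spec_name}: categorical map targets must be DEL/TOL, got {bad}"
                )
            return
        if self.tol_rule is None or self.del_rule is None:
            raise ConfigError(
                f"{self.spec_name}: continuous spec needs both tol_rule and del_rule"
            )
        if self.tol_rule.is_lower == self.del_rule.is_lower:
            raise ConfigError(
                f"{self.spec_name}: TOL and DEL rules must face opposite directions"
            )
        if _regions_overlap(self.tol_rule, self.del_rule):
            raise ConfigError(
                f"{self.spec_name}: TOL and DEL regions overlap "
                f"({self.tol_rule} vs {self.del_rule})"
            )

    @property
    def categorical(self) -> bool:
        return self.categorical_map is not None

    @property
    def binary(self) -> bool:
        """True when the two regions partition the score line (no gap)."""
        if self.categorical:
            return True
        return _regions_partition(self.tol_rule, self.del_rule)


def apply_threshold_spec(scores: pd.Series, spec: ToolThresholdSpec) -> pd.Series:
    """One call per variant: DEL, TOL, INDETERMINATE, or MISSING.

    ``scores`` is indexed by variant_key; numeric for continuous specs,
    category labels for categorical specs. Unparseable numeric cells are
    treated as missing.
    """
    if spec.categorical:
        def call_cat(v: Any) -> str:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return CALL_MISSING
            return spec.categorical_map.get(str(v), CALL_MISSING)

        return scores.map(call_cat).astype(object).rename(spec.spec_name)

    values = pd.to_numeric(scores, errors="coerce").to_numpy(dtype=float)
    calls = np.full(len(values), CALL_INDETERMINATE, dtype=object)
    present = ~np.isnan(values)
    calls[~present] = CALL_MISSING
    with np.errstate(invalid="ignore"):
        calls[present & spec.del_rule.satisfied(values)] = CALL_DEL
        calls[present & spec.tol_rule.satisfied(values)] = CALL_TOL
    return pd.Series(calls, index=scores.index, name=spec.spec_name, dtype=object)


def build_call_table(
    score_table: pd.DataFrame, specs: Sequence[ToolThresholdSpec]
) -> pd.DataFrame:
    """Apply every spec to its tool column; one call column per spec."""
    missing = [s.spec_name for s in specs if s.tool_name not in score_table.columns]
    if missing:
        raise DataError(f"score table lacks columns for specs: {missing}")
    cols = {
        s.spec_name: apply_threshold_spec(score_table[s.tool_name], s) for s in specs
    }
    return pd.DataFrame(cols, index=score_table.index)


def discrimination_filter(column: pd.Series) -> tuple[bool, str | None]:
    """Drop combinations that never discriminate.

    Returns (keep, reason). A column whose non-missing calls are all
    identical carries no information (e.g. a spec that calls everything
    deleterious); a column with no calls at all is degenerate.
    """
    if column.empty:
        raise DataError("empty call column")
    present = column[column != CALL_MISSING]
    if present.empty:
        return False, "no calls"
    uniques = present.unique()
    if len(uniques) == 1:
        return False, f"no discrimination: all calls {uniques[0]}"
    return True, None


def coverage_filter(
    column: pd.Series, truth_keys: Iterable[str], min_fraction: float = 0.25
) -> tuple[bool, str | None]:
    """Drop combinations producing values for under ``min_fraction`` of variants.

    The denominator is the full truth set; INDETERMINATE counts as covered
    (the tool produced a value), MISSING does not. Exclusion is strict:
    exactly 25% coverage is kept.
    """
    keys = pd.Index(truth_keys)
    if not len(keys):
        raise DataError("empty truth set for coverage filter")
    calls = column.reindex(keys, fill_value=CALL_MISSING)
    covered = (calls != CALL_MISSING).sum() / len(keys)
    if covered < min_fraction:
        return False, f"coverage {covered:.1%} < {min_fraction:.0%}"
    return True, None


def variant_inclusion(
    column: pd.Series, truth_keys: Iterable[str]
) -> tuple[float | None, bool]:
    """Fraction of truth-set variants receiving a definite DEL/TOL call.

    Both MISSING and INDETERMINATE diminish inclusion. Returns
    (fraction, defined); an empty truth set is flagged undefined.
    """
    keys = pd.Index(truth_keys)
    if not len(keys):
        return None, False
    calls = column.reindex(keys, fill_value=CALL_MISSING)
    definite = calls.isin(DEFINITE_CALLS).sum()
    return float(definite / len(keys)), True


def apply_tool_filters(
    call_table: pd.DataFrame,
    truth_keys: Iterable[str],
    min_coverage: float = 0.25,
) -> tuple[list[str], pd.DataFrame]:
    """Run both published exclusion rules over every spec column.

    Returns (surviving spec names, exclusion table with columns
    spec_name/filter/reason).
    """
    keys = pd.Index(truth_keys)
    survivors: list[str] = []
    dropped: list[dict[str, str]] = []
    for name in call_table.columns:
        col = call_table[name].reindex(keys, fill_value=CALL_MISSING)
        keep, reason = discrimination_filter(col)
        if not keep:
            dropped.append(
                {"spec_name": name, "filter": "discrimination", "reason": reason}
            )
            continue
        keep, reason = coverage_filter(col, keys, min_coverage)
        if not keep:
            dropped.append({"spec_name": name, "filter": "coverage", "reason": reason})
            continue
        survivors.append(name)
    return survivors, pd.DataFrame(
        dropped, columns=["spec_name", "filter", "reason"]
    )


# --------------------------------------------------------------------------
# Spec (de)serialization — YAML/JSON round-trips byte-stable
# --------------------------------------------------------------------------


def specs_to_dicts(specs: Sequence[ToolThresholdSpec]) -> list[dict[str, Any]]:
    out = []
    for s in specs:
        d: dict[str, Any] = {
            "tool_name": s.tool_name,
            "spec_name": s.spec_name,
            "direction": s.direction,
        }
        if s.categorical:
            d["categorical_map"] = dict(s.categorical_map)
        else:
            d["tol_rule"] = {"comparator": s.tol_rule.comparator, "cutoff": s.tol_rule.cutoff}
            d["del_rule"] = {"comparator": s.del_rule.comparator, "cutoff": s.del_rule.cutoff}
        out.append(d)
    return out


def specs_from_dicts(dicts: Iterable[Mapping[str, Any]]) -> list[ToolThresholdSpec]:
    specs = []
    seen: set[str] = set()
    for d in dicts:
        kwargs = dict(d)
        for key in ("tol_rule", "del_rule"):
            if kwargs.get(key) is not None:
                r = kwargs[key]
                kwargs[key] = Rule(comparator=r["comparator"], cutoff=float(r["cutoff"]))
        spec = ToolThresholdSpec(**kwargs)
        if spec.spec_name in seen:
            raise ConfigError(f"duplicate spec_name {spec.spec_name!r}")
        seen.add(spec.spec_name)
        specs.append(spec)
    return specs


def load_specs(path: str | Path) -> list[ToolThresholdSpec]:
    """Load threshold specs from a YAML or JSON list."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"threshold spec file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, list):
        raise ConfigError(f"{path}: expected a list of threshold specs")
    return specs_from_dicts(data)


def save_specs(specs: Sequence[ToolThresholdSpec], path: str | Path) -> None:
    path = Path(path)
    data = specs_to_dicts(specs)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
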