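"""Synthetic gene-stratified truth sets and class-conditional tool scores.

The evaluation framework is exercised end-to-end on simulated data that
mirrors the statistical structure of multiplexed functional assay (MAVE)
truth sets: five gene strata of very different size and deleterious
fraction, per-variant assay outcomes (including intermediate and
discordant ones that curation must drop), and per-tool continuous or
categorical scores whose class-conditional distributions, direction,
indeterminate behaviour and missingness are all configurable.

Class counts are allocated deterministically by rounding (a sampling mode
is available behind ``allocate="sampled"``), so composition invariants are
exact and every downstream stage can be tested against closed-form
operating points via :func:`analytic_operating_point`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    DEL,
    TOL,
    INTERMEDIATE,
    DISCORDANT,
    FUNCTIONAL,
    NONFUNCTIONAL,
    ASSAY_INTERMEDIATE,
    MISSENSE,
    HIGHER_IS_DELETERIOUS,
    LOWER_IS_DELETERIOUS,
    DIRECTIONS,
)
from .errors import ConfigError

__all__ = [
    "GeneProfile",
    "ScoreDistribution",
    "ToolScoreProfile",
    "SimulationConfig",
    "default_gene_profiles",
    "default_tool_profiles",
    "generate_truthset",
    "generate_tool_scores",
    "analytic_operating_point",
]

# Published per-gene truth-set sizes and (rounded) deleterious fractions
# for the five MAVE datasets the framework emulates.
_PAPER_GENES = (
    ("BRCA1", 1641, 0.23),
    ("BRCA2", 188, 0.34),
    ("MSH2", 4783, 0.08),
    ("PTEN", 957, 0.20),
    ("TP53", 1867, 0.22),
)


def _round_half_up(x: float) -> int:
    """Deterministic round-half-away-from-zero for non-negative x."""
    return int(np.floor(x + 0.5))


def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent random stream per (seed, labels) tuple.

    CRC32 of the labels (stable across processes, unlike ``hash``) feeds a
    SeedSequence, so adding a tool or gene never perturbs other streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(lab.encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneProfile:
    """Composition of one gene stratum.

    Fractions apply to ``n_variants``; whatever remains after the
    deleterious, assay-intermediate and assay-discordant allocations is
    tolerated. ``deleterious_fraction`` is therefore the DEL fraction of
    the *curated* stratum when the other two fractions are zero.
    """

    gene_name: str
    n_variants: int
    deleterious_fraction: float
    intermediate_fraction: float = 0.0
    discordant_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ConfigError(f"{self.gene_name}: n_variants must be >= 0")
        fracs = (
            self.deleterious_fraction,
            self.intermediate_fraction,
            self.discordant_fraction,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError(f"{self.gene_name}: fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ConfigError(
                f"{self.gene_name}: class fractions sum to {sum(fracs):.3f} > 1"
            )

    def class_counts(self) -> dict[str, int]:
        """Deterministic rounded allocation of the four variant classes."""
        n_del = _round_half_up(self.n_variants * self.deleterious_fraction)
        n_int = _round_half_up(self.n_variants * self.intermediate_fraction)
        n_disc = _round_half_up(self.n_variants * self.discordant_fraction)
        n_tol = self.n_variants - n_del - n_int - n_disc
        if n_tol < 0:
            raise ConfigError(
                f"{self.gene_name}: rounded class counts exceed n_variants"
            )
        return {DEL: n_del, TOL: n_tol, INTERMEDIATE: n_int, DISCORDANT: n_disc}


class _PointMass:
    """Degenerate distribution at a single value (rvs/cdf only)."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size: int, random_state: np.random.Generator) -> np.ndarray:
        return np.full(size, self.value)

    def cdf(self, x):
        return np.where(np.asarray(x, dtype=float) >= self.value, 1.0, 0.0)


@dataclass(frozen=True)
class ScoreDistribution:
    """Parametric class-conditional score density on the tool's scale.

    Supported kinds:

    ``beta``    params a, b — Beta(a, b) rescaled to [score_min, score_max]
    ``uniform`` params low, high — uniform on [low, high] (native scale)
    ``normal``  params mean, sd — normal truncated to [score_min, score_max]
    ``point``   params value — point mass (degenerate)
    """

    kind: str
    params: Mapping[str, float]

    def frozen(self, score_min: float, score_max: float):
        p = dict(self.params)
        width = score_max - score_min
        if self.kind == "beta":
            return stats.beta(p["a"], p["b"], loc=score_min, scale=width)
        if self.kind == "uniform":
            low, high = p["low"], p["high"]
            if not (score_min <= low < high <= score_max):
                raise ConfigError(
                    f"uniform support [{low}, {high}] outside score range"
                )
            return stats.uniform(loc=low, scale=high - low)
        if self.kind == "normal":
            mean, sd = p["mean"], p["sd"]
            a, b = (score_min - mean) / sd, (score_max - mean) / sd
            return stats.truncnorm(a, b, loc=mean, scale=sd)
        if self.kind == "point":
            return _PointMass(p["value"])
        raise ConfigError(f"unknown distribution kind {self.kind!r}")

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScoreDistribution":
        return cls(kind=d["kind"], params=dict(d["params"]))


@dataclass(frozen=True)
class ToolScoreProfile:
    """Generative model for one tool's raw output.

    Continuous tools draw from ``del_distribution`` / ``tol_distribution``
    given the variant's truth class; assay-intermediate and discordant
    variants draw from an even mixture of the two, which reproduces the
    observed behaviour of intermediate variants scoring between the class
    medians. Categorical tools instead emit labels from per-class call
    probabilities. Entries are masked missing at ``missing_rate``.
    """

    tool_name: str
    score_min: float = 0.0
    score_max: float = 1.0
    direction: str = HIGHER_IS_DELETERIOUS
    del_distribution: ScoreDistribution | None = None
    tol_distribution: ScoreDistribution | None = None
    missing_rate: float = 0.0
    categorical: bool = False
    # class -> {category label -> probability}; classes DEL/TOL required,
    # INTERMEDIATE/DISCORDANT fall back to the DEL/TOL average.
    call_probabilities: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"{self.tool_name}: bad direction {self.direction!r}")
        if not self.score_min < self.score_max:
            raise ConfigError(f"{self.tool_name}: score_min must be < score_max")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(f"{self.tool_name}: missing_rate outside [0, 1]")
        if self.categorical:
            if self.call_probabilities is None:
                raise ConfigError(
                    f"{self.tool_name}: categorical profile needs call_probabilities"
                )
            for cls in (DEL, TOL):
                probs = self.call_probabilities.get(cls)
                if not probs:
                    raise ConfigError(
                        f"{self.tool_name}: call_probabilities missing class {cls}"
                    )
                total = sum(probs.values())
                if not np.isclose(total, 1.0):
                    raise ConfigError(
                        f"{self.tool_name}: {cls} call probabilities sum to {total}"
                    )
        else:
            if self.del_distribution is None or self.tol_distribution is None:
                raise ConfigError(
                    f"{self.tool_name}: continuous profile needs both densities"
                )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "tool_name": self.tool_name,
            "score_min": self.score_min,
            "score_max": self.score_max,
            "direction": self.direction,
            "missing_rate": self.missing_rate,
            "categorical": self.categorical,
        }
        if self.categorical:
            d["call_probabilities"] = {
                cls: dict(p) for cls, p in self.call_probabilities.items()
            }
        else:
            d["del_distribution"] = self.del_distribution.to_dict()
            d["tol_distribution"] = self.tol_distribution.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ToolScoreProfile":
        kwargs = dict(d)
        for key in ("del_distribution", "tol_distribution"):
            if kwargs.get(key) is not None:
                kwargs[key] = ScoreDistribution.from_dict(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset; seed-deterministic."""

    gene_profiles: Sequence[GeneProfile]
    tool_profiles: Sequence[ToolScoreProfile]
    seed: int = 0
    # fraction of curatable DEL variants annotated P/LP and of TOL variants
    # annotated B/LB (1 star), to exercise the ClinVar truth-set path
    clinvar_plp_rate: float = 0.0
    clinvar_blb_rate: float = 0.0
    allocate: str = "rounded"  # or "sampled"

    def __post_init__(self) -> None:
        names = [g.gene_name for g in self.gene_profiles]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate gene names in gene_profiles")
        tools = [t.tool_name for t in self.tool_profiles]
        if len(set(tools)) != len(tools):
            raise ConfigError("duplicate tool names in tool_profiles")
        if self.allocate not in ("rounded", "sampled"):
            raise ConfigError(f"unknown allocation mode {self.allocate!r}")
        for rate in (self.clinvar_plp_rate, self.clinvar_blb_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("ClinVar annotation rates must lie in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "allocate": self.allocate,
            "clinvar_plp_rate": self.clinvar_plp_rate,
            "clinvar_blb_rate": self.clinvar_blb_rate,
            "gene_profiles": [
                {
                    "gene_name": g.gene_name,
                    "n_variants": g.n_variants,
                    "deleterious_fraction": g.deleterious_fraction,
                    "intermediate_fraction": g.intermediate_fraction,
                    "discordant_fraction": g.discordant_fraction,
                }
                for g in self.gene_profiles
            ],
            "tool_profiles": [t.to_dict() for t in self.tool_profiles],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        return cls(
            gene_profiles=tuple(
                GeneProfile(**g) for g in d.get("gene_profiles", ())
            ),
            tool_profiles=tuple(
                ToolScoreProfile.from_dict(t) for t in d.get("tool_profiles", ())
            ),
            seed=int(d.get("seed", 0)),
            clinvar_plp_rate=float(d.get("clinvar_plp_rate", 0.0)),
            clinvar_blb_rate=float(d.get("clinvar_blb_rate", 0.0)),
            allocate=d.get("allocate", "rounded"),
        )


def default_gene_profiles() -> tuple[GeneProfile, ...]:
    """The five published gene strata (sizes and deleterious fractions)."""
    return tuple(
        GeneProfile(gene_name=g, n_variants=n, deleterious_fraction=f)
        for g, n, f in _PAPER_GENES
    )


def default_tool_profiles() -> tuple[ToolScoreProfile, ...]:
    """Three synthetic tools spanning the behaviours the pipeline handles.

    A well-separated higher-is-deleterious metapredictor, a
    lower-is-deleterious tool with weaker separation and more missingness,
    and a categorical caller.
    """
    return (
        ToolScoreProfile(
            tool_name="metaA",
            del_distribution=ScoreDistribution("beta", {"a": 8.0, "b": 2.0}),
            tol_distribution=ScoreDistribution("beta", {"a": 2.0, "b": 8.0}),
            missing_rate=0.02,
        ),
        ToolScoreProfile(
            tool_name="lowB",
            direction=LOWER_IS_DELETERIOUS,
            del_distribution=ScoreDistribution("beta", {"a": 2.0, "b": 5.0}),
            tol_distribution=ScoreDistribution("beta", {"a": 5.0, "b": 2.0}),
            missing_rate=0.05,
        ),
        ToolScoreProfile(
            tool_name="catC",
            categorical=True,
            call_probabilities={
                DEL: {"D": 0.88, "T": 0.12},
                TOL: {"D": 0.25, "T": 0.75},
            },
            missing_rate=0.05,
        ),
    )


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

_ASSAY_OUTCOMES_BY_CLASS = {
    DEL: (NONFUNCTIONAL,),
    TOL: (FUNCTIONAL,),
    INTERMEDIATE: (ASSAY_INTERMEDIATE,),
    DISCORDANT: (FUNCTIONAL, NONFUNCTIONAL),
}


def generate_truthset(config: SimulationConfig) -> pd.DataFrame:
    """Generate the per-variant record table for a simulated dataset.

    Returns a DataFrame with one row per variant and columns
    ``variant_key, gene, consequence, splice_flank, assay_outcomes,
    sim_class, clinvar_class, clinvar_stars``. ``sim_class`` is the
    generative ground truth (DEL/TOL/INTERMEDIATE/DISCORDANT); curation
    recovers DEL/TOL and drops the rest. Deterministic for a fixed config.
    """
    rows: list[dict[str, Any]] = []
    for profile in config.gene_profiles:
        if config.allocate == "rounded":
            counts = profile.class_counts()
        else:
            rng = _stream(config.seed, "__alloc__", profile.gene_name)
            p_del = profile.deleterious_fraction
            p_int = profile.intermediate_fraction
            p_disc = profile.discordant_fraction
            draw = rng.multinomial(
                profile.n_variants,
                [p_del, p_int, p_disc, 1.0 - p_del - p_int - p_disc],
            )
            counts = {
                DEL: int(draw[0]),
                INTERMEDIATE: int(draw[1]),
                DISCORDANT: int(draw[2]),
                TOL: int(draw[3]),
            }
        classes: list[str] = []
        for cls in (DEL, TOL, INTERMEDIATE, DISCORDANT):
            classes.extend([cls] * counts[cls])
        # interleave classes deterministically so key order is not a label
        order = _stream(config.seed, "__order__", profile.gene_name).permutation(
            len(classes)
        )
        classes = [classes[i] for i in order]
        for i, cls in enumerate(classes):
            rows.append(
                {
                    "variant_key": f"{profile.gene_name}:v{i:06d}",
                    "gene": profile.gene_name,
                    "consequence": MISSENSE,
                    "splice_flank": False,
                    "assay_outcomes": list(_ASSAY_OUTCOMES_BY_CLASS[cls]),
                    "sim_class": cls,
                    "clinvar_class": None,
                    "clinvar_stars": 0,
                }
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "variant_key",
            "gene",
            "consequence",
            "splice_flank",
            "assay_outcomes",
            "sim_class",
            "clinvar_class",
            "clinvar_stars",
        ],
    )
    if len(records) and (config.clinvar_plp_rate > 0 or config.clinvar_blb_rate > 0):
        _annotate_clinvar(records, config)
    return records


def _annotate_clinvar(records: pd.DataFrame, config: SimulationConfig) -> None:
    """Assign P/LP to a fraction of DEL and B/LB (1 star) to TOL, in place."""
    for gene, sub in records.groupby("gene", sort=False):
        rng = _stream(config.seed, "__clinvar__", str(gene))
        for cls, rate, labels in (
            (DEL, config.clinvar_plp_rate, ("P", "LP")),
            (TOL, config.clinvar_blb_rate, ("B", "LB")),
        ):
            idx = sub.index[sub["sim_class"] == cls]
            k = _round_half_up(len(idx) * rate)
            if k == 0:
                continue
            chosen = rng.choice(idx, size=k, replace=False)
            for j, rec_idx in enumerate(np.sort(chosen)):
                records.at[rec_idx, "clinvar_class"] = labels[j % 2]
                records.at[rec_idx, "clinvar_stars"] = 1


def generate_tool_scores(
    records: pd.DataFrame,
    profiles: Sequence[ToolScoreProfile],
    seed: int,
) -> pd.DataFrame:
    """Draw the per-variant raw score table for each tool profile.

    One independent random stream per (tool, gene) pair, so adding a tool
    or gene leaves all other draws untouched. Continuous tools yield float
    columns with NaN for missing entries; categorical tools yield object
    columns with None for missing. Same seed, same table.
    """
    if not len(profiles):
        raise ConfigError("no tool profiles supplied")
    names = [p.tool_name for p in profiles]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate tool names in profiles")
    required = {"variant_key", "gene", "sim_class"}
    if not required <= set(records.columns):
        raise ConfigError(f"records table lacks columns {required - set(records.columns)}")

    table = pd.DataFrame(index=pd.Index(records["variant_key"], name="variant_key"))
    for profile in profiles:
        col = pd.Series(
            index=table.index,
            dtype=object if profile.categorical else float,
        )
        for gene, sub in records.groupby("gene", sort=False):
            rng = _stream(seed, profile.tool_name, str(gene))
            values = _draw_for_gene(profile, sub["sim_class"].to_numpy(), rng)
            missing = rng.random(len(sub)) < profile.missing_rate
            if profile.categorical:
                values = np.where(missing, None, values)
            else:
                values = np.where(missing, np.nan, values)
            col.loc[sub["variant_key"].to_numpy()] = values
        if not profile.categorical:
            col = col.astype(float)
        table[profile.tool_name] = col
    return table


def _draw_for_gene(
    profile: ToolScoreProfile, classes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(classes)
    if profile.categorical:
        out = np.empty(n, dtype=object)
        probs = {cls: dict(p) for cls, p in profile.call_probabilities.items()}
        # intermediate/discordant fall back to the DEL/TOL average
        cats = sorted(set(probs[DEL]) | set(probs[TOL]))
        mixed = {
            c: 0.5 * probs[DEL].get(c, 0.0) + 0.5 * probs[TOL].get(c, 0.0)
            for c in cats
        }
        for cls in np.unique(classes):
            mask = classes == cls
            p = probs.get(cls, mixed)
            labels = sorted(p)
            weights = np.array([p[lab] for lab in labels], dtype=float)
            weights = weights / weights.sum()
            out[mask] = rng.choice(labels, size=mask.sum(), p=weights)
        return out

    del_rv = profile.del_distribution.frozen(profile.score_min, profile.score_max)
    tol_rv = profile.tol_distribution.frozen(profile.score_min, profile.score_max)
    out = np.empty(n, dtype=float)
    for cls in np.unique(classes):
        mask = classes == cls
        k = int(mask.sum())
        if cls == DEL:
            out[mask] = del_rv.rvs(size=k, random_state=rng)
        elif cls == TOL:
            out[mask] = tol_rv.rvs(size=k, random_state=rng)
        else:
            # even mixture: intermediates score between the class medians
            pick_del = rng.random(k) < 0.5
            vals = np.where(
                pick_del,
                del_rv.rvs(size=k, random_state=rng),
                tol_rv.rvs(size=k, random_state=rng),
            )
            out[mask] = vals
    return out


def analytic_operating_point(
    profile: ToolScoreProfile, cutoff: float
) -> tuple[float, float]:
    """Closed-form (sensitivity, specificity) of a continuous profile at a cutoff.

    For a higher-is-deleterious tool a variant is called DEL when its score
    exceeds the cutoff, so sensitivity = 1 − F_del(cutoff) and
    specificity = F_tol(cutoff); mirrored for lower-is-deleterious tools.
    Serves as the oracle for parameter-recovery tests.
    """
    if profile.categorical:
        raise ConfigError("analytic operating point undefined for categorical tools")
    del_rv = profile.del_distribution.frozen(profile.score_min, profile.score_max)
    tol_rv = profile.tol_distribution.frozen(profile.score_min, profile.score_max)
    if profile.direction == HIGHER_IS_DELETERIOUS:
        sensitivity = 1.0 - float(del_rv.cdf(cutoff))
        specificity = float(tol_rv.cdf(cutoff))
    else:
        sensitivity = float(del_rv.cdf(cutoff))
        specificity = 1.0 - float(tol_rv.cdf(cutoff))
    return sensitivity, specificity
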