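"""Configured, reproducible end-to-end evaluation runs.

A run executes: curation → harmonization → tool-level filters → metric
panels (per gene, combined, unweighted mean across genes, optional
ClinVar) → likelihood ratios → banded analyses → threshold optimization →
concordance combinations, writing TSV reports plus a machine-readable
manifest (package and library versions, seed, config hash, row-count
reconciliation). Identical config and seed produce byte-identical output.

Inputs come either from TSV tables on disk or from the synthetic-data
generator when the config carries a ``simulate`` section.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata as importlib_metadata
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import combine as combine_mod
from . import harmonize, io, likelihood, metrics, optimize, simulate, truthset
from .constants import DEL, TOL, HIGHER_IS_DELETERIOUS
from .errors import ConfigError, DataError

__all__ = ["RunConfig", "run_evaluation"]

_STAGES = ("curate", "metrics", "lr", "bands", "optimize", "combine")


@dataclass
class RunConfig:
    """Validated run configuration; round-trips through YAML unchanged."""

    raw: dict[str, Any]
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if not isinstance(self.raw, dict):
            raise ConfigError("run config must be a mapping")
        if "simulate" not in self.raw and "inputs" not in self.raw:
            raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
        opts = self.options
        if opts.get("auc_mode", "raw") not in ("raw", "dichotomized"):
            raise ConfigError("options.auc_mode must be 'raw' or 'dichotomized'")
        if opts.get("lr_pooling", "arithmetic") not in ("arithmetic", "log"):
            raise ConfigError("options.lr_pooling must be 'arithmetic' or 'log'")
        if opts.get("dropout_denominator", "definite") not in ("definite", "all"):
            raise ConfigError("options.dropout_denominator must be 'definite' or 'all'")
        if "inputs" in self.raw:
            for key in ("records_table", "score_table", "truthset_table"):
                p = self.raw["inputs"].get(key)
                if p is not None and not self._resolve(p).exists():
                    raise ConfigError(f"inputs.{key} does not exist: {p}")
        specs = self.raw.get("specs_file")
        if specs not in (None, "default") and not self._resolve(specs).exists():
            raise ConfigError(f"specs_file does not exist: {specs}")

    def _resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text())
        return cls(raw=data, base_dir=path.parent)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def options(self) -> dict[str, Any]:
        return dict(self.raw.get("options", {}) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def _load_simulation(section: Mapping[str, Any], seed: int) -> simulate.SimulationConfig:
    d = dict(section or {})
    if d.get("gene_profiles", "default") == "default":
        genes = simulate.default_gene_profiles()
    else:
        genes = tuple(simulate.GeneProfile(**g) for g in d["gene_profiles"])
    if d.get("tool_profiles", "default") == "default":
        tools = simulate.default_tool_profiles()
    else:
        tools = tuple(simulate.ToolScoreProfile.from_dict(t) for t in d["tool_profiles"])
    return simulate.SimulationConfig(
        gene_profiles=genes,
        tool_profiles=tools,
        seed=int(d.get("seed", seed)),
        clinvar_plp_rate=float(d.get("clinvar_plp_rate", 0.0)),
        clinvar_blb_rate=float(d.get("clinvar_blb_rate", 0.0)),
        allocate=d.get("allocate", "rounded"),
    )


def _spec_direction(specs: list[harmonize.ToolThresholdSpec], tool: str) -> str:
    for s in specs:
        if s.tool_name == tool:
            return s.direction
    return HIGHER_IS_DELETERIOUS


def _panel_rows(name_ts: str, spec_name: str, panel: metrics.MetricPanel) -> list[dict]:
    rows = []
    for m in metrics.PANEL_METRICS:
        v = panel.metric(m)
        rows.append(
            {
                "truth_set": name_ts,
                "spec_name": spec_name,
                "metric": m,
                "value": v,
                "defined": v is not None,
            }
        )
    c = panel.counts
    for cell, v in zip(("tp", "fp", "tn", "fn"), c.as_tuple()):
        rows.append(
            {
                "truth_set": name_ts,
                "spec_name": spec_name,
                "metric": cell,
                "value": v,
                "defined": True,
            }
        )
    return rows


def run_evaluation(
    config: RunConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = _STAGES,
) -> dict[str, Any]:
    """Execute the configured pipeline and write the report bundle.

    Returns the manifest dictionary (also written to manifest.json).
    Any stage rejection raises ConfigError/DataError, which the CLI maps
    to nonzero exit codes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    seed = config.seed
    manifest: dict[str, Any] = {
        "package": "vepbench",
        "versions": _versions(),
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.raw,
        "counts": {},
    }
    counts = manifest["counts"]

    # ---- inputs -----------------------------------------------------------
    if "simulate" in config.raw:
        sim_cfg = _load_simulation(config.raw["simulate"], seed)
        records_frame = simulate.generate_truthset(sim_cfg)
        score_table = simulate.generate_tool_scores(
            records_frame, sim_cfg.tool_profiles, sim_cfg.seed
        )
        io.write_records_table(records_frame, outdir / "records.tsv")
        io.write_score_table(records_frame, score_table, outdir / "scores.tsv")
        sim_classes = pd.Series(
            records_frame["sim_class"].to_numpy(),
            index=records_frame["variant_key"].to_numpy(),
        )
    else:
        inputs = config.raw["inputs"]
        records_frame = io.read_records_table(config._resolve(inputs["records_table"]))
        table, coerced = io.read_score_table(config._resolve(inputs["score_table"]))
        counts["coerced_cells"] = coerced
        score_table = table.drop(columns=["gene"])
        sim_classes = None
    counts["n_records"] = int(len(records_frame))

    # ---- curation ---------------------------------------------------------
    ts_all, exclusions = truthset.curate_functional_truthset(records_frame)
    io.write_truthset(ts_all, outdir / "truthset.tsv")
    io.write_tsv(exclusions, outdir / "exclusions.tsv")
    summary = truthset.truthset_summary(ts_all)
    io.write_tsv(summary, outdir / "truthset_summary.tsv")
    counts["n_truthset"] = int(len(ts_all))
    counts["n_excluded"] = int(len(exclusions))
    if counts["n_truthset"] + counts["n_excluded"] != counts["n_records"]:
        raise DataError("curation dropped rows silently")  # conservation check

    gene_truthsets = {g: ts_all.stratum(g) for g in sorted(ts_all.gene_strata)}
    named_truthsets: dict[str, truthset.TruthSet] = {**gene_truthsets, "ALL": ts_all}
    clinvar_ts = truthset.build_clinvar_truthset(records_frame, ts_all.keys)
    if len(clinvar_ts):
        named_truthsets["CLINVAR"] = clinvar_ts
        counts["n_clinvar"] = int(len(clinvar_ts))

    if "curate" in stages and stages == ("curate",):
        _write_manifest(manifest, outdir)
        return manifest

    # ---- harmonization and tool filters ----------------------------------
    specs_file = config.raw.get("specs_file", "default")
    specs_path = (
        _data_path("default_specs.yaml")
        if specs_file in (None, "default")
        else config._resolve(specs_file)
    )
    specs = harmonize.load_specs(specs_path)
    counts["n_specs_loaded"] = len(specs)
    call_table = harmonize.build_call_table(score_table, specs)
    survivors, spec_exclusions = harmonize.apply_tool_filters(
        call_table, ts_all.keys, float(opts.get("min_coverage", 0.25))
    )
    io.write_tsv(spec_exclusions, outdir / "filters.tsv")
    counts["n_specs_surviving"] = len(survivors)
    specs_by_name = {s.spec_name: s for s in specs}
    surviving_specs = [specs_by_name[n] for n in survivors]

    # ---- metric panels ----------------------------------------------------
    auc_mode = opts.get("auc_mode", "raw")
    long_rows: list[dict] = []
    panels: dict[tuple[str, str], metrics.MetricPanel] = {}
    mean_panels: dict[str, metrics.MetricPanel] = {}
    for spec in surviving_specs:
        col = call_table[spec.spec_name]
        raw = score_table[spec.tool_name]
        gene_panels = []
        for ts_name, ts in named_truthsets.items():
            c = metrics.confusion_counts(col, ts)
            if c.empty:
                continue
            auc_value = _auc_for(spec, raw, col, ts, auc_mode)
            incl, _ = harmonize.variant_inclusion(col, ts.keys)
            panel = metrics.metric_panel(c, auc_value=auc_value, variant_inclusion=incl)
            panels[(ts_name, spec.spec_name)] = panel
            long_rows.extend(_panel_rows(ts_name, spec.spec_name, panel))
            if ts_name in gene_truthsets:
                gene_panels.append(panel)
        if gene_panels:
            mean_panel = metrics.mean_across_genes(gene_panels)
            mean_panels[spec.spec_name] = mean_panel
            long_rows.extend(_panel_rows("MEAN", spec.spec_name, mean_panel))
    metrics_long = pd.DataFrame(
        long_rows, columns=["truth_set", "spec_name", "metric", "value", "defined"]
    )
    if "metrics" in stages:
        io.write_tsv(metrics_long, outdir / "metrics_long.tsv")
        wide = metrics_long.pivot_table(
            index=["truth_set", "spec_name"],
            columns="metric",
            values="value",
            aggfunc="first",
        ).reset_index()
        io.write_tsv(wide, outdir / "metrics_wide.tsv")
        counts["metrics_rows"] = int(len(metrics_long))
        # intermediate-variant behaviour: per-tool medians by simulated class
        if sim_classes is not None:
            med_rows = []
            for spec in surviving_specs:
                if spec.categorical:
                    continue
                meds = metrics.median_score_by_class(
                    score_table[spec.tool_name].set_axis(sim_classes.index),
                    sim_classes,
                )
                for cls, v in sorted(meds.items()):
                    med_rows.append(
                        {"tool_name": spec.tool_name, "class": cls, "median_score": v}
                    )
            io.write_tsv(
                pd.DataFrame(
                    med_rows, columns=["tool_name", "class", "median_score"]
                ).drop_duplicates(),
                outdir / "median_scores.tsv",
            )

    # ---- likelihood ratios ------------------------------------------------
    if "lr" in stages:
        lr_rows = []
        pooling = opts.get("lr_pooling", "arithmetic")
        for spec in surviving_specs:
            col = call_table[spec.spec_name]
            per_gene: dict[str, tuple] = {}
            for ts_name, ts in named_truthsets.items():
                c = metrics.confusion_counts(col, ts)
                if c.empty:
                    continue
                try:
                    plr, nlr = likelihood.likelihood_ratios(c)
                except DataError:
                    continue
                lr_rows.append(_lr_row(ts_name, spec.spec_name, plr, nlr))
                if ts_name in gene_truthsets:
                    per_gene[ts_name] = (plr, nlr)
            if per_gene:
                plr_m = likelihood.mean_lr_across_genes(
                    [v[0] for v in per_gene.values()], pooling
                )
                nlr_m = likelihood.mean_lr_across_genes(
                    [v[1] for v in per_gene.values()], pooling
                )
                lr_rows.append(_lr_row("MEAN", spec.spec_name, plr_m, nlr_m))
        lr_frame = pd.DataFrame(
            lr_rows,
            columns=[
                "truth_set",
                "spec_name",
                "plr",
                "plr_ci_low",
                "plr_ci_high",
                "nlr",
                "nlr_ci_low",
                "nlr_ci_high",
                "nlr_conventional",
                "haldane_applied",
                "method",
            ],
        )
        io.write_tsv(lr_frame, outdir / "lr.tsv")
        counts["lr_rows"] = int(len(lr_frame))

    # ---- banded analysis --------------------------------------------------
    if "bands" in stages:
        band_rows = []
        bands_cfg = dict(config.raw.get("bands", {}) or {})
        band_tools = bands_cfg.get("tools", [])
        if bands_cfg.get("definitions"):
            band_defs = [
                likelihood.BandDefinition(**d) for d in bands_cfg["definitions"]
            ]
        else:
            band_defs = likelihood.default_bands(
                float(bands_cfg.get("threshold", 0.7))
            )
        pooling = opts.get("lr_pooling", "arithmetic")
        for tool in band_tools:
            if tool not in score_table.columns:
                raise ConfigError(f"bands.tools entry {tool!r} not in score table")
            raw = score_table[tool]
            for band in band_defs:
                per_gene_results = []
                for ts_name, ts in named_truthsets.items():
                    res, defined = likelihood.banded_lr(raw, ts, band)
                    if not defined:
                        continue
                    band_rows.append(_band_row(ts_name, tool, band, res))
                    if ts_name in gene_truthsets:
                        per_gene_results.append(res)
                if per_gene_results:
                    mean_res = likelihood.mean_lr_across_genes(per_gene_results, pooling)
                    band_rows.append(_band_row("MEAN", tool, band, mean_res))
        bands_frame = pd.DataFrame(
            band_rows,
            columns=[
                "truth_set",
                "tool_name",
                "kind",
                "band_low",
                "band_high",
                "reference",
                "estimate",
                "ci_low",
                "ci_high",
                "haldane_applied",
            ],
        )
        io.write_tsv(bands_frame, outdir / "bands.tsv")
        counts["band_rows"] = int(len(bands_frame))

    # ---- threshold optimization -------------------------------------------
    if "optimize" in stages:
        opt_rows = []
        step_fraction = float(opts.get("step_fraction", 0.02))
        continuous_tools = sorted(
            {s.tool_name for s in surviving_specs if not s.categorical}
        )
        for tool in continuous_tools:
            direction = _spec_direction(surviving_specs, tool)
            try:
                result = optimize.consensus_and_evaluate(
                    tool,
                    score_table[tool],
                    gene_truthsets,
                    combined=ts_all,
                    direction=direction,
                    step_fraction=step_fraction,
                )
            except DataError:
                continue
            for gene in result.per_gene_optima:
                opt_rows.append(
                    {
                        "tool_name": tool,
                        "gene": gene,
                        "optimal_cutoff": result.per_gene_optima[gene],
                        "ba_at_optimum": result.per_gene_ba_at_optimum[gene],
                        "consensus_cutoff": result.consensus_cutoff,
                        "ba_at_consensus": result.per_gene_ba_at_consensus.get(gene),
                    }
                )
            opt_rows.append(
                {
                    "tool_name": tool,
                    "gene": "ALL",
                    "optimal_cutoff": None,
                    "ba_at_optimum": None,
                    "consensus_cutoff": result.consensus_cutoff,
                    "ba_at_consensus": result.combined_ba_at_consensus,
                }
            )
        opt_frame = pd.DataFrame(
            opt_rows,
            columns=[
                "tool_name",
                "gene",
                "optimal_cutoff",
                "ba_at_optimum",
                "consensus_cutoff",
                "ba_at_consensus",
            ],
        )
        io.write_tsv(opt_frame, outdir / "thresholds.tsv")
        counts["threshold_rows"] = int(len(opt_frame))

    # ---- concordance combinations -----------------------------------------
    if "combine" in stages:
        top_k = int(opts.get("top_k", 12))
        try:
            pairs = combine_mod.rank_and_pair(
                call_table[survivors], mean_panels, gene_truthsets, top_k=top_k
            )
        except DataError:
            pairs = pd.DataFrame()
        io.write_tsv(pairs, outdir / "combinations.tsv")
        counts["combination_rows"] = int(len(pairs))
        threeway = opts.get("threeway") or []
        if threeway:
            rows = []
            for members in threeway:
                missing = [m for m in members if m not in call_table.columns]
                if missing:
                    raise ConfigError(f"threeway members not found: {missing}")
                result = combine_mod.combine_concordant(call_table[list(members)])
                c = metrics.confusion_counts(result.combined_calls, ts_all)
                panel = metrics.metric_panel(c) if not c.empty else None
                rows.append(
                    {
                        "members": "+".join(members),
                        "n_retained": result.n_retained,
                        "dropout_fraction": result.dropout_fraction,
                        "dropout_fraction_all": result.dropout_fraction_all,
                        "ba_all": panel.balanced_accuracy if panel else None,
                    }
                )
            io.write_tsv(pd.DataFrame(rows), outdir / "combinations_kway.tsv")

    _write_manifest(manifest, outdir)
    return manifest


def _auc_for(
    spec: harmonize.ToolThresholdSpec,
    raw: pd.Series,
    calls: pd.Series,
    ts: truthset.TruthSet,
    auc_mode: str,
) -> float | None:
    if spec.categorical or auc_mode == "dichotomized":
        numeric = calls.map({DEL: 1.0, TOL: 0.0})
        value, defined = metrics.auc(numeric, ts, HIGHER_IS_DELETERIOUS)
    else:
        value, defined = metrics.auc(raw, ts, spec.direction)
    return value if defined else None


def _lr_row(ts_name, spec_name, plr, nlr) -> dict:
    return {
        "truth_set": ts_name,
        "spec_name": spec_name,
        "plr": plr.estimate,
        "plr_ci_low": plr.ci_low,
        "plr_ci_high": plr.ci_high,
        "nlr": nlr.estimate,
        "nlr_ci_low": nlr.ci_low,
        "nlr_ci_high": nlr.ci_high,
        "nlr_conventional": likelihood.conventional_nlr(nlr),
        "haldane_applied": plr.haldane_applied or nlr.haldane_applied,
        "method": plr.method,
    }


def _band_row(ts_name, tool, band, res) -> dict:
    return {
        "truth_set": ts_name,
        "tool_name": tool,
        "kind": band.kind,
        "band_low": band.band_low,
        "band_high": band.band_high,
        "reference": f"{band.reference_comparator}{band.reference_cutoff}",
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "haldane_applied": res.haldane_applied,
    }


def _versions() -> dict[str, str]:
    out = {}
    for pkg in ("vepbench", "numpy", "scipy", "pandas"):
        try:
            out[pkg] = importlib_metadata.version(pkg)
        except importlib_metadata.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
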