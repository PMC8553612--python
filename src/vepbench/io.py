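"""Tabular interchange: TSV readers/writers for variant tables and reports.

TSV (tab-delimited, UTF-8, header row) is the canonical interchange
format. The variant score table starts with ``variant_key`` and ``gene``
columns followed by metadata and one column per tool; the variant record
table carries curation fields with assay outcomes ";"-joined. VCF
ingestion is deliberately out of scope: tool scores arrive pre-extracted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .truthset import TruthSet

__all__ = [
    "read_score_table",
    "write_score_table",
    "read_records_table",
    "write_records_table",
    "write_truthset",
    "read_truthset",
    "write_tsv",
]

_NA_VALUES = ["", "NA", "na", "N/A", ".", "NaN", "nan", "None"]


def read_score_table(
    path: str | Path,
    tool_columns: Sequence[str] | None = None,
    categorical_tools: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read the per-variant score table.

    Returns (table indexed by variant_key, per-tool count of unparseable
    numeric cells coerced to missing). ``tool_columns`` restricts and
    validates the tool columns; by default every column after the
    mandatory ``variant_key``/``gene`` pair and any non-tool metadata is
    kept as-is. Duplicate variant keys are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"score table not found: {path}")
    frame = pd.read_csv(
        path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False
    )
    for col in ("variant_key", "gene"):
        if col not in frame.columns:
            raise DataError(f"{path}: missing mandatory column {col!r}")
    if frame["variant_key"].duplicated().any():
        dup = frame.loc[frame["variant_key"].duplicated(), "variant_key"].iloc[0]
        raise DataError(f"{path}: duplicate variant_key {dup!r}")
    frame = frame.set_index("variant_key")
    if tool_columns is not None:
        missing = [c for c in tool_columns if c not in frame.columns]
        if missing:
            raise DataError(f"{path}: missing tool columns {missing}")
        tools = list(tool_columns)
    else:
        tools = [c for c in frame.columns if c != "gene"]
    coerced: dict[str, int] = {}
    for col in tools:
        if col in categorical_tools:
            continue
        raw = frame[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        n_bad = int((numeric.isna() & raw.notna()).sum())
        if n_bad:
            coerced[col] = n_bad
        frame[col] = numeric
    return frame, coerced


def write_score_table(
    records: pd.DataFrame, scores: pd.DataFrame, path: str | Path
) -> None:
    """Write variant_key/gene plus one column per tool."""
    genes = records.set_index("variant_key")["gene"]
    out = scores.copy()
    out.insert(0, "gene", genes.reindex(out.index))
    out.index.name = "variant_key"
    out.to_csv(path, sep="\t")


def read_records_table(path: str | Path) -> pd.DataFrame:
    """Read the variant record (curation input) table."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"records table not found: {path}")
    frame = pd.read_csv(
        path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False
    )
    required = {"variant_key", "gene", "consequence", "splice_flank", "assay_outcomes"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if frame["variant_key"].duplicated().any():
        raise DataError(f"{path}: duplicate variant keys")
    frame["splice_flank"] = frame["splice_flank"].map(
        {"True": True, "False": False, "1": True, "0": False}
    )
    if frame["splice_flank"].isna().any():
        raise DataError(f"{path}: unparseable splice_flank values")
    if "clinvar_stars" in frame.columns:
        frame["clinvar_stars"] = (
            pd.to_numeric(frame["clinvar_stars"], errors="coerce").fillna(0).astype(int)
        )
    return frame


def write_records_table(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    if "assay_outcomes" in out.columns and len(out):
        first = out["assay_outcomes"].iloc[0]
        if isinstance(first, (list, tuple)):
            out["assay_outcomes"] = out["assay_outcomes"].map(";".join)
    if "sim_class" in out.columns:
        out = out.drop(columns=["sim_class"])
    out.to_csv(path, sep="\t", index=False)


def write_truthset(ts: TruthSet, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"variant_key": ts.keys, "gene": ts.genes.to_numpy(), "label": ts.labels.to_numpy()}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_truthset(path: str | Path, provenance: str = "functional") -> TruthSet:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"truth-set table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_key", "gene", "label"}
    if not required <= set(frame.columns):
        raise DataError(f"{path}: truth set needs columns {sorted(required)}")
    return TruthSet(
        labels=pd.Series(frame["label"].to_numpy(), index=frame["variant_key"]),
        genes=pd.Series(frame["gene"].to_numpy(), index=frame["variant_key"]),
        provenance=provenance,
    )


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
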