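"""CSV interchange with provenance headers.

Every table the pipeline writes carries ``# soilstoich`` comment lines with
the config hash and master seed, so any output file can be traced to the run
that produced it; readers skip comment lines transparently.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assign import LibraryEntry
from .formula import parse_formula
from .tables import FeatureTable, StudyDesign

# %.17g round-trips IEEE-754 doubles exactly, so write->read is the identity
FLOAT_FORMAT = "%.17g"


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a frame as CSV with optional ``# key: value`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_feature_table(
    table: FeatureTable, path: str | Path, provenance: dict | None = None
) -> None:
    write_csv(table.to_dataframe(), path, provenance)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read and validate a feature-table CSV.

    Schema: feature_id, mz, rt_min, then one intensity column per sample.
    Errors name the offending column or feature id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = read_csv(path)
    for col in df.columns:
        if col == "feature_id":
            continue
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value {df.loc[row, col]!r} in column {col!r} "
                f"(feature {df.loc[row, 'feature_id'] if 'feature_id' in df else row})"
            )
        df[col] = pd.to_numeric(df[col])
    return FeatureTable.from_dataframe(df)


def write_design(design: StudyDesign, path: str | Path, provenance: dict | None = None) -> None:
    df = design.to_dataframe()
    prov = dict(provenance or {})
    if design.reference_group:
        prov["reference_group"] = design.reference_group
    if design.internal_standard_ids:
        prov["internal_standards"] = ",".join(design.internal_standard_ids)
    write_csv(df, path, prov)


def _header_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_design(path: str | Path) -> StudyDesign:
    path = Path(path)
    meta = _header_metadata(path)
    df = read_csv(path)
    return StudyDesign.from_dataframe(
        df,
        reference_group=meta.get("reference_group"),
        internal_standard_ids=(
            meta["internal_standards"].split(",") if "internal_standards" in meta else []
        ),
    )


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Compound-library CSV: name, neutral_mass or formula, rt_min."""
    df = read_csv(path)
    if "name" not in df.columns or "rt_min" not in df.columns:
        raise ValueError("library CSV needs 'name' and 'rt_min' columns")
    entries = []
    for _, row in df.iterrows():
        if "formula" in df.columns and isinstance(row.get("formula"), str) and row["formula"]:
            entries.append(
                LibraryEntry.from_formula(
                    str(row["name"]), parse_formula(row["formula"]), float(row["rt_min"])
                )
            )
        elif "neutral_mass" in df.columns and np.isfinite(row.get("neutral_mass", np.nan)):
            entries.append(
                LibraryEntry(str(row["name"]), float(row["neutral_mass"]), float(row["rt_min"]))
            )
        else:
            raise ValueError(f"library entry {row.get('name')!r} has neither formula nor mass")
    return entries
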