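"""Readers and writers for the tabular formats the pipeline consumes.

Fish metadata travels as CSV (id, species, zone, reef, length_mm, weight_g,
age_yr); OTU tables as TSV with samples as rows and OTU ids as columns (a
``transpose`` flag accommodates tools that emit the other orientation);
taxonomy as TSV (otu_id + ranked lineage columns). Validation errors name
the offending column or row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "read_fish_csv",
    "read_otu_table",
    "read_taxonomy",
    "write_otu_table",
    "write_table",
]

FISH_COLUMNS = ("id", "species", "zone", "reef", "length_mm", "weight_g", "age_yr")


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


def read_fish_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the fish metadata table."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FISH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate fish id(s) {sorted(set(dup))}")
    for col in ("length_mm", "weight_g"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col} at row(s) {list(bad[:5])} "
                f"(value {df.loc[bad[0], col]!r})"
            )
        df[col] = coerced
        if (df[col] <= 0).any():
            row = df.index[df[col] <= 0][0]
            raise SchemaError(f"{path}: non-positive {col} at row {row}")
    df["age_yr"] = pd.to_numeric(df["age_yr"], errors="coerce")
    # reef nested in exactly one zone
    nest = df.groupby("reef")["zone"].nunique()
    multi = nest[nest > 1]
    if len(multi):
        raise SchemaError(f"{path}: reef(s) in multiple zones: {list(multi.index)}")
    return df


def read_otu_table(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Read an OTU count TSV (samples as rows unless ``transpose``)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise SchemaError(f"{path}: duplicate sample id(s) {dup}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise SchemaError(f"{path}: non-numeric counts ({e})") from e
    if (df.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative counts present")
    return df.round().astype(int)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "otu_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'otu_id' column")
    return df.set_index("otu_id")


def write_otu_table(otu: pd.DataFrame, path: str | Path, provenance: str | None = None) -> None:
    _write(otu, path, sep="\t", index_label="sample", provenance=provenance)


def write_table(df: pd.DataFrame, path: str | Path, provenance: str | None = None,
                index: bool = False) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    _write(df, path, sep=sep, index_label=df.index.name if index else None,
           provenance=provenance, index=index)


def _write(df, path, sep, index_label, provenance, index=True):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep=sep, index=index, index_label=index_label)
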