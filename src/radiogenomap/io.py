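"""Plain-text readers and writers.

Dialects: expression and count matrices are TSV (gene rows, sample columns,
header row, missing values written as the literal ``NA``); semantic features
travel as a CSV plus a codebook CSV (``feature_id,type,levels`` with ordered
level labels pipe-separated); survival tables are CSV
(``sample,time,event[,cohort,histology_group]``); gene sets are GMT
(name, description, tab-separated gene ids). All files are UTF-8. Writing then
reading any object reproduces it exactly (full float precision, orders
preserved).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_features_csv",
    "write_features_csv",
    "read_codebook_csv",
    "write_codebook_csv",
    "read_survival_csv",
    "write_survival_csv",
    "read_gmt",
    "write_gmt",
]

_NA = "NA"


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, keep_default_na=False, na_values=[_NA]
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    df.index = df.index.astype(str)
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=_NA)


def read_features_csv(path, codebook: dict | None = None) -> pd.DataFrame:
    """Patients x features CSV; values are integer codes (or NA).

    When a codebook is given, every feature column must be declared in it.
    """
    df = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[_NA])
    df.index = df.index.astype(str)
    if codebook is not None:
        undeclared = [c for c in df.columns if c not in codebook]
        if undeclared:
            raise ValueError(f"{path}: feature column(s) not in codebook: {undeclared}")
    return df


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, na_rep=_NA)


def read_codebook_csv(path) -> dict:
    """Codebook CSV -> {feature_id: {"type": ..., "levels": [...] | None}}."""
    df = pd.read_csv(path, keep_default_na=False)
    expected = ["feature_id", "type", "levels"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: codebook columns must be {expected}, got {list(df.columns)}")
    book = {}
    for _, row in df.iterrows():
        ftype = row["type"]
        if ftype not in ("binary", "ordinal"):
            raise ValueError(f"{path}: feature {row['feature_id']!r} has unknown type {ftype!r}")
        levels = [l for l in str(row["levels"]).split("|") if l] or None
        if ftype == "ordinal" and not levels:
            raise ValueError(f"{path}: ordinal feature {row['feature_id']!r} declares no levels")
        book[str(row["feature_id"])] = {"type": ftype, "levels": levels if ftype == "ordinal" else None}
    return book


def write_codebook_csv(codebook: dict, path) -> None:
    rows = [
        {
            "feature_id": fid,
            "type": spec["type"],
            "levels": "|".join(spec["levels"]) if spec.get("levels") else "",
        }
        for fid, spec in codebook.items()
    ]
    pd.DataFrame(rows, columns=["feature_id", "type", "levels"]).to_csv(path, index=False)


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[_NA])
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival table missing column {col!r}")
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event indicators must be 0/1")
    df["sample"] = df["sample"].astype(str)
    return df


def write_survival_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into (name, description, genes) triples, in file order."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            out.append((name, desc, genes))
    return out


def write_gmt(sets: list[tuple[str, str, list[str]]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")
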