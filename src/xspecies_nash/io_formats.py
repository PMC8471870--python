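"""On-disk formats: expression TSV, sample metadata TSV, orthologue TSV, GMT.

All readers validate strictly and raise :class:`FormatError` on malformed
input rather than coercing; every writer/reader pair is a lossless roundtrip
on valid data. TSV is used throughout (gene symbols may not contain tabs),
with the gene column named ``gene``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Platform = Literal["count", "intensity"]


class FormatError(ValueError):
    """Malformed or contract-violating input data."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix with a platform tag.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``platform`` is ``"count"`` (non-negative integer counts) or
    ``"intensity"`` (finite real log-intensities).
    """

    values: pd.DataFrame
    platform: Platform

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise FormatError("empty expression matrix")
        if v.index.duplicated().any():
            dups = sorted(v.index[v.index.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dups[:10]}")
        if v.columns.duplicated().any():
            dups = sorted(v.columns[v.columns.duplicated()].unique())
            raise FormatError(f"duplicate sample ids: {dups[:10]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if np.isnan(arr).any():
            raise FormatError("missing values in expression matrix")
        if not np.isfinite(arr).all():
            raise FormatError("non-finite values in expression matrix")
        if self.platform == "count":
            if (arr < 0).any():
                raise FormatError("negative values in count matrix")
            if not np.allclose(arr, np.round(arr)):
                bad = v.index[np.where(~np.isclose(arr, np.round(arr)))[0][0]]
                raise FormatError(
                    f"non-integer value in count matrix (first offender: gene {bad!r})"
                )
        elif self.platform != "intensity":
            raise FormatError(f"unknown platform {self.platform!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.platform)


def read_expression(path: str | Path, platform: Platform) -> ExpressionMatrix:
    """Read an expression TSV (first column ``gene``, one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expression table needs a gene column and >=1 sample")
    if df.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be named 'gene', got {df.columns[0]!r}")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicated gene rows: {sorted(dup.unique())[:10]}")
    df = df.set_index("gene")
    df.index.name = None
    for c in df.columns:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise FormatError(f"{path}: non-numeric cell in sample column {c!r}")
    if platform == "count":
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"{path}: non-integer count {arr[i, j]} for gene {df.index[i]!r}"
            )
        df = df.astype(np.int64)
    return ExpressionMatrix(df, platform)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered mapping of set name -> member gene symbols."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(members)) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in {name!r} deduplicated")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


GROUP_LEVELS = ("control", "case")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: columns ``sample``, ``group``, ``cohort``,
    optional ``fibrosis_area``. Group labels must already be mapped to
    control/case (cohort-specific labels are mapped by the pipeline config).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "cohort": str})
    for col in ("sample", "group", "cohort"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids")
    unknown = set(df["group"]) - set(GROUP_LEVELS)
    if unknown:
        raise FormatError(f"{path}: unknown group level(s) {sorted(unknown)}; expected {GROUP_LEVELS}")
    if "fibrosis_area" in df.columns:
        if not pd.api.types.is_numeric_dtype(df["fibrosis_area"]):
            raise FormatError(f"{path}: fibrosis_area must be numeric")
        if (df["fibrosis_area"].dropna() <= 0).any():
            raise FormatError(f"{path}: fibrosis_area must be > 0")
    return df.reset_index(drop=True)


def check_samples_covered(matrix: ExpressionMatrix, table: pd.DataFrame) -> None:
    """Every matrix sample must appear exactly once in the sample table."""
    missing = [s for s in matrix.samples if s not in set(table["sample"])]
    if missing:
        raise FormatError(f"samples in matrix but absent from sample table: {missing[:10]}")


def read_orthologue_map(path: str | Path) -> pd.DataFrame:
    """Read an orthologue TSV: ``source_gene``, ``human_symbol``, ``pct_identity``.

    Duplicate source genes (many-to-many mappings) are allowed and resolved
    downstream; identities must lie in (0, 100].
    """
    df = pd.read_csv(path, sep="\t", dtype={"source_gene": str, "human_symbol": str})
    for col in ("source_gene", "human_symbol", "pct_identity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["pct_identity"]):
        raise FormatError(f"{path}: pct_identity must be numeric")
    bad = df[(df["pct_identity"] <= 0) | (df["pct_identity"] > 100)]
    if len(bad):
        raise FormatError(
            f"{path}: pct_identity outside (0,100] for source gene(s) "
            f"{sorted(bad['source_gene'])[:10]}"
        )
    return df.reset_index(drop=True)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_orthologue_map(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
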