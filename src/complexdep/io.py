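"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the in-memory containers produced here:
gene-set collections (:class:`GeneSetCollection`), gene × sample matrices
(:class:`pandas.DataFrame` with genes as rows), and genomic region tables
(:class:`pandas.DataFrame` with ``chrom``/``start``/``end``/``name`` columns,
0-based half-open coordinates).

Supported dialects
------------------
* GMT (MSigDB dialect): one set per line, ``name<TAB>description<TAB>gene...``.
* BED3/BED4, tab-separated, 0-based half-open.
* Delimited matrices: one header row of sample identifiers, first column of
  gene identifiers; comma or tab auto-detected from the header line; empty
  cells are missing values (NaN).
"""

from __future__ import annotations

import io as _stdio
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ParseError",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_bed",
    "write_bed",
    "validate_regions",
    "write_table",
]


class ParseError(ValueError):
    """A file violated the dialect this package supports."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: description plus ordered unique member identifiers."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if any(not g for g in self.genes):
            raise ValueError(f"gene set {self.name!r} contains empty gene identifiers")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered mapping from set name to :class:`GeneSet`.

    Set names are unique; within-set duplicate genes are collapsed on
    construction, preserving first occurrence.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_dict(
        cls, mapping: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None
    ) -> "GeneSetCollection":
        coll = cls()
        for name, genes in mapping.items():
            desc = (descriptions or {}).get(name, "")
            coll.add(name, genes, desc)
        return coll

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        deduped = tuple(dict.fromkeys(g for g in genes if g))
        self.sets[name] = GeneSet(name=name, description=description, genes=deduped)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        out = GeneSetCollection()
        for n in names:
            s = self.sets[n]
            out.add(s.name, s.genes, s.description)
        return out


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file (MSigDB dialect) into a :class:`GeneSetCollection`.

    Each non-blank line must have at least three tab-separated fields:
    set name, description, and one or more gene identifiers. Blank gene
    fields are dropped; within-set duplicates are collapsed, keeping the
    first occurrence.

    Raises
    ------
    ParseError
        If a line has fewer than three fields (the message names the line
        number) or a set name repeats.
    """
    coll = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            try:
                coll.add(name, genes, desc)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return coll


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    """Write a collection as GMT; round trips losslessly through :func:`read_gmt`."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def _sniff_delimiter(header: str) -> str:
    # DepMap exports CSV; local fixtures are TSV. A tab anywhere wins.
    return "\t" if "\t" in header else ","


def read_matrix(path: str | os.PathLike, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a delimited numeric matrix; rows of the result are always genes.

    Parameters
    ----------
    path
        CSV or TSV file with one header row of column identifiers and a
        leading identifier column. The delimiter is auto-detected from the
        header line.
    orientation
        ``"genes_by_samples"`` if file rows are genes, ``"samples_by_genes"``
        if file rows are samples (the result is transposed so rows are genes).

    Empty cells become NaN. Non-numeric non-empty cells and duplicate
    identifiers raise :class:`ParseError` with coordinates.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    sep = _sniff_delimiter(text.splitlines()[0])
    df = pd.read_csv(_stdio.StringIO(text), sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row identifiers {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate column identifiers {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].str.strip(), errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        numeric[col] = converted
    if orientation == "samples_by_genes":
        numeric = numeric.T
    numeric.index.name = "gene"
    return numeric


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike, sep: str = "\t") -> None:
    """Write a genes × samples matrix as delimited text (empty cell = missing)."""
    matrix.to_csv(path, sep=sep, na_rep="")


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Validate a region table (0-based half-open); returns the table itself."""
    required = {"chrom", "start", "end"}
    missing = required - set(regions.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    if (starts < 0).any():
        raise ValueError("region table has negative start coordinates")
    if (starts >= ends).any():
        i = int(np.argmax(starts >= ends))
        r = regions.iloc[i]
        raise ValueError(
            f"empty or inverted interval {r['chrom']}:{r['start']}-{r['end']} (start must be < end)"
        )
    return regions


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3/BED4 into a region table with 0-based half-open coordinates.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end``, ``name``
    (name is empty-string for BED3 records). Validation errors are raised for
    negative coordinates and for ``start >= end``.
    """
    records: list[tuple[str, int, int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            records.append((fields[0], start, end, name))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "name"])
    return validate_regions(df)


def write_bed(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a region table as BED (BED4 when any name is set, else BED3)."""
    validate_regions(regions)
    has_names = "name" in regions.columns and regions["name"].astype(str).str.len().gt(0).any()
    with open(path, "w", encoding="utf-8") as fh:
        for _, r in regions.iterrows():
            cols = [str(r["chrom"]), str(int(r["start"])), str(int(r["end"]))]
            if has_names:
                cols.append(str(r.get("name", "")))
            fh.write("\t".join(cols) + "\n")


def write_table(table: pd.DataFrame, path: str | os.PathLike, columns: list[str] | None = None) -> None:
    """Write a result table as TSV with a stable column order."""
    if columns is not None:
        table = table[columns]
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
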