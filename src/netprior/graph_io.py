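"""Readers for interaction records and association tables.

The interactome is held as an undirected :class:`networkx.Graph` whose nodes
are upper-cased gene symbols. Cleaning reduces raw interaction records (which
may list the same protein pair under several experimental methods, in either
orientation, or as self-interactions) to a set of unique undirected edges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionRecord",
    "GeneScoreTable",
    "PpiParseError",
    "read_ppi_records",
    "clean_interactome",
    "read_gene_pvalues",
    "read_snp_table",
]


class PpiParseError(ValueError):
    """Malformed interaction file (message names the offending line)."""


@dataclass(frozen=True)
class InteractionRecord:
    """One raw interaction row: two protein symbols plus optional metadata."""

    protein_a: str
    protein_b: str
    organism_a: str | None = None
    organism_b: str | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein symbols must be non-empty strings")


# Column-name fragments used to locate fields in a BioGRID TAB header.
_BIOGRID_COLS = {
    "protein_a": ("official symbol interactor a",),
    "protein_b": ("official symbol interactor b",),
    "organism_a": ("organism interactor a", "organism id interactor a", "organism name interactor a"),
    "organism_b": ("organism interactor b", "organism id interactor b", "organism name interactor b"),
    "method": ("experimental system",),
}


def _locate_biogrid_columns(header: Sequence[str]) -> dict[str, int | None]:
    lowered = [h.strip().lower().lstrip("#").strip() for h in header]
    out: dict[str, int | None] = {}
    for key, names in _BIOGRID_COLS.items():
        idx = None
        for name in names:
            if name in lowered:
                idx = lowered.index(name)
                break
        out[key] = idx
    return out


def read_ppi_records(path: str | Path, dialect: str = "simple_tsv") -> list[InteractionRecord]:
    """Parse an interaction file into :class:`InteractionRecord` rows.

    Parameters
    ----------
    path:
        Tab-delimited interaction file.
    dialect:
        ``"simple_tsv"`` — two or more tab-separated symbol columns, ``#``
        comment lines allowed, no header required.
        ``"biogrid_tab"`` — BioGRID TAB export with a header row naming
        official-symbol and organism columns for interactors A and B.
    """
    path = Path(path)
    if dialect not in ("simple_tsv", "biogrid_tab"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    records: list[InteractionRecord] = []
    with path.open() as fh:
        if dialect == "simple_tsv":
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                    raise PpiParseError(
                        f"{path.name}: line {lineno}: expected >=2 tab-separated symbol columns"
                    )
                records.append(InteractionRecord(parts[0].strip(), parts[1].strip()))
        else:
            header: Sequence[str] | None = None
            cols: dict[str, int | None] = {}
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if header is None:
                    if line.lstrip().startswith("#") and "\t" not in line:
                        continue  # pure comment before the header
                    header = line.split("\t")
                    cols = _locate_biogrid_columns(header)
                    if cols["protein_a"] is None or cols["protein_b"] is None:
                        raise PpiParseError(
                            f"{path.name}: line {lineno}: header lacks official-symbol "
                            "columns for interactors A and B"
                        )
                    continue
                parts = line.split("\t")
                if len(parts) != len(header):
                    raise PpiParseError(
                        f"{path.name}: line {lineno}: expected {len(header)} columns, "
                        f"found {len(parts)}"
                    )

                def _get(key: str) -> str | None:
                    idx = cols[key]
                    if idx is None:
                        return None
                    value = parts[idx].strip()
                    return value or None

                a, b = _get("protein_a"), _get("protein_b")
                if not a or not b:
                    raise PpiParseError(
                        f"{path.name}: line {lineno}: empty interactor symbol"
                    )
                records.append(
                    InteractionRecord(a, b, _get("organism_a"), _get("organism_b"), _get("method"))
                )
    return records


def clean_interactome(
    records: Iterable[InteractionRecord], taxon: str | None = None
) -> nx.Graph:
    """Reduce raw records to a clean undirected interactome.

    Symbols are upper-cased; with ``taxon`` given, records where either
    organism label is present and differs from ``taxon`` are dropped;
    self-interactions are removed; duplicate pairs (any orientation, any
    experimental method) collapse to one edge.
    """
    graph = nx.Graph()
    taxon_s = str(taxon) if taxon is not None else None
    for rec in records:
        if taxon_s is not None:
            if (rec.organism_a is not None and rec.organism_a != taxon_s) or (
                rec.organism_b is not None and rec.organism_b != taxon_s
            ):
                continue
        a, b = rec.protein_a.upper(), rec.protein_b.upper()
        if a == b:
            continue
        graph.add_edge(a, b)
    return graph


@dataclass
class GeneScoreTable:
    """Gene-level association p-values plus dataset mean/SD of the p-values.

    ``table`` has columns ``gene`` (upper-cased symbol, unique) and ``p``
    (in (0, 1]). ``mean_p``/``sd_p`` are the dataset-level statistics used to
    standardize p-values to z-scores; ``sd_p`` is the sample (n-1) standard
    deviation.
    """

    table: pd.DataFrame
    mean_p: float = field(init=False)
    sd_p: float = field(init=False)

    def __post_init__(self) -> None:
        df = self.table
        if not {"gene", "p"}.issubset(df.columns):
            raise ValueError("GeneScoreTable requires columns 'gene' and 'p'")
        df = df.loc[:, ["gene", "p"]].copy()
        df["gene"] = df["gene"].astype(str).str.upper()
        df["p"] = df["p"].astype(float)
        if ((df["p"] <= 0) | (df["p"] > 1)).any():
            bad = df.loc[(df["p"] <= 0) | (df["p"] > 1), "gene"].iloc[0]
            raise ValueError(f"p-value outside (0, 1] for gene {bad}")
        dup = df["gene"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate gene rows: {sorted(df.loc[dup, 'gene'].unique())}")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "table", df)
        self.mean_p = float(df["p"].mean())
        self.sd_p = float(df["p"].std(ddof=1)) if len(df) > 1 else 0.0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "GeneScoreTable":
        return cls(pd.DataFrame(list(pairs), columns=["gene", "p"]))

    def pvalues(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["p"]))

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def read_gene_pvalues(path: str | Path) -> GeneScoreTable:
    """Read a gene/p-value TSV (header with Gene and Pvalue columns)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().strip(): c for c in df.columns}
    gene_col = next((cols[k] for k in ("gene", "symbol") if k in cols), df.columns[0])
    p_col = next(
        (cols[k] for k in ("pvalue", "p-value", "p_value", "p") if k in cols),
        df.columns[1],
    )
    return GeneScoreTable(df.rename(columns={gene_col: "gene", p_col: "p"}))


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited SNP association table (SNP, CHR, BP, P).

    Returns a DataFrame with columns ``snp``, ``chrom``, ``pos``, ``p``.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        renames = {
            cols["snp"]: "snp",
            cols["chr"]: "chrom",
            cols["bp"]: "pos",
            cols["p"]: "p",
        }
    except KeyError as exc:
        raise ValueError(f"SNP table {path} lacks required column: {exc}") from exc
    df = df.rename(columns=renames).loc[:, ["snp", "chrom", "pos", "p"]]
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    df["p"] = df["p"].astype(float)
    if (df["pos"] < 1).any():
        raise ValueError("SNP positions must be 1-based (>= 1)")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("SNP p-values must lie in (0, 1]")
    return df
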