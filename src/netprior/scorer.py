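"""Combine gene association p-values with network weights.

Each gene's p-value is standardized against the dataset:

    z_i = (mean_p - p_i) / sd_p,

so genes with small p-values get large positive z. Per network the weighted
(Liptak-Stouffer) combination is

    Z_comb = sum_i w_i z_i / sqrt(sum_i w_i^2),

with w_i the modified-PageRank weight. Z_comb maps to an upper-tail normal
p-value, Bonferroni-corrected by the number of scored genes in the network
times the number of networks. Networks are ranked by corrected p-value
(ascending), ties broken by descending Z_comb then network_id; the network
percentile is 100 * rank / #networks. A gene's network percentile is the
percentile of the best-ranked network containing it.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .graph_io import GeneScoreTable
from .network_builder import SubNetwork
from .ranker import WeightVector

__all__ = [
    "p_to_z",
    "combine_liptak",
    "z_to_p",
    "correct_network_p",
    "rank_networks",
    "score_all_networks",
    "gene_network_percentile",
    "gene_report",
    "snp_to_gene_p",
    "write_network_summary_tsv",
]

logger = logging.getLogger(__name__)


def p_to_z(p, mean_p: float, sd_p: float):
    """Standardize a p-value against the dataset mean/SD (vectorized)."""
    if sd_p <= 0:
        raise ValueError("sd_p must be positive (degenerate p-value distribution)")
    return (mean_p - np.asarray(p, dtype=float)) / sd_p


def combine_liptak(weights: Mapping[str, float], zscores: Mapping[str, float]) -> float:
    """Weighted Stouffer combination over the genes shared by both maps."""
    shared = sorted(set(weights) & set(zscores))
    if not shared:
        raise ValueError("no genes shared between weight and z-score maps")
    w = np.array([weights[g] for g in shared])
    z = np.array([zscores[g] for g in shared])
    return float((w @ z) / np.sqrt((w**2).sum()))


def z_to_p(z_comb: float) -> float:
    """Upper-tail standard normal probability P(Z > z_comb)."""
    return float(norm.sf(z_comb))


def correct_network_p(p: float, n_genes: int, n_networks: int) -> float:
    """Bonferroni: min(1, p * n_genes * n_networks)."""
    if n_genes < 1 or n_networks < 1:
        raise ValueError("n_genes and n_networks must be >= 1")
    return min(1.0, p * n_genes * n_networks)


def rank_networks(
    network_ids: Sequence[str],
    p_corrected: np.ndarray,
    z_comb: np.ndarray,
) -> np.ndarray:
    """1-based ranks: ascending corrected p, ties by descending Z_comb then id.

    The identical ordering is used for the baseline scoring and every
    permutation run, so top-fraction membership is comparable across runs.
    """
    ids = np.asarray(network_ids)
    order = np.lexsort((ids, -np.asarray(z_comb), np.asarray(p_corrected)))
    ranks = np.empty(len(ids), dtype=np.int64)
    ranks[order] = np.arange(1, len(ids) + 1)
    return ranks


def score_all_networks(
    networks: Sequence[SubNetwork],
    weightvectors: Mapping[str, WeightVector] | Iterable[WeightVector],
    gene_table: GeneScoreTable,
    alpha_gene: float = 0.05,
) -> pd.DataFrame:
    """Score and rank every sub-network against the gene p-value table.

    Returns one row per scorable network with columns: network_id, seed,
    n_genes, n_significant, n_nonsignificant, significant_genes,
    nonsignificant_genes (lists of symbols), z_comb, p_network, p_corrected,
    rank, percentile. Genes absent from the gene table are dropped from the
    network's score (total logged); networks with no scored genes are
    excluded and logged.
    """
    if not isinstance(weightvectors, Mapping):
        weightvectors = {wv.network_id: wv for wv in weightvectors}
    pmap = gene_table.pvalues()
    zmap = {
        g: float(z)
        for g, z in zip(
            gene_table.genes, p_to_z(gene_table.table["p"], gene_table.mean_p, gene_table.sd_p)
        )
    }
    rows = []
    n_dropped = 0
    unscored: list[str] = []
    for net in networks:
        wv = weightvectors[net.network_id]
        members = sorted(net.nodes)
        scored = [g for g in members if g in zmap]
        n_dropped += len(members) - len(scored)
        if not scored:
            unscored.append(net.network_id)
            continue
        w = np.array([wv.weights[g] for g in scored])
        z = np.array([zmap[g] for g in scored])
        z_comb = float((w @ z) / np.sqrt((w**2).sum()))
        sig = [g for g in scored if pmap[g] < alpha_gene]
        nonsig = [g for g in scored if pmap[g] >= alpha_gene]
        rows.append(
            {
                "network_id": net.network_id,
                "seed": net.seed,
                "n_genes": len(scored),
                "n_significant": len(sig),
                "n_nonsignificant": len(nonsig),
                "significant_genes": sig,
                "nonsignificant_genes": nonsig,
                "z_comb": z_comb,
            }
        )
    if n_dropped:
        logger.info("dropped %d network member genes absent from the gene table", n_dropped)
    if unscored:
        logger.warning("%d networks had no scored genes and were excluded", len(unscored))
    if not rows:
        raise ValueError("no network could be scored against the gene table")
    df = pd.DataFrame(rows)
    n_networks = len(df)
    df["p_network"] = norm.sf(df["z_comb"].to_numpy())
    df["p_corrected"] = np.minimum(
        1.0, df["p_network"].to_numpy() * df["n_genes"].to_numpy() * n_networks
    )
    df["rank"] = rank_networks(
        df["network_id"].to_numpy(), df["p_corrected"].to_numpy(), df["z_comb"].to_numpy()
    )
    df["percentile"] = 100.0 * df["rank"] / n_networks
    return df.sort_values("rank", ignore_index=True)


def gene_network_percentile(gene: str, table: pd.DataFrame) -> float | None:
    """Percentile of the best-ranked network containing ``gene`` (None if none)."""
    gene = gene.upper()
    best: float | None = None
    for _, row in table.iterrows():
        if gene in row["significant_genes"] or gene in row["nonsignificant_genes"]:
            if best is None or row["percentile"] < best:
                best = float(row["percentile"])
    return best


def gene_report(table: pd.DataFrame, gene_table: GeneScoreTable) -> pd.DataFrame:
    """Per-gene comparison of gene-wise vs network percentile ranks.

    Columns: gene, gene_p, gene_rank, gene_percentile, best_network_id,
    network_percentile. ``gene_rank`` orders genes by ascending p (ties by
    symbol); network columns are NaN/empty for genes in no scored network.
    """
    genes = gene_table.table.sort_values(["p", "gene"], ignore_index=True)
    genes["gene_rank"] = np.arange(1, len(genes) + 1)
    genes["gene_percentile"] = 100.0 * genes["gene_rank"] / len(genes)

    best_pct: dict[str, float] = {}
    best_net: dict[str, str] = {}
    # scan in rank order so the first network seen is the best for its genes
    for _, row in table.sort_values("rank").iterrows():
        for g in row["significant_genes"] + row["nonsignificant_genes"]:
            if g not in best_pct:
                best_pct[g] = float(row["percentile"])
                best_net[g] = row["network_id"]
    genes["best_network_id"] = genes["gene"].map(best_net)
    genes["network_percentile"] = genes["gene"].map(best_pct)
    return genes.rename(columns={"p": "gene_p"}).loc[
        :,
        [
            "gene",
            "gene_p",
            "gene_rank",
            "gene_percentile",
            "best_network_id",
            "network_percentile",
        ],
    ]


def snp_to_gene_p(
    snps: pd.DataFrame, genes: pd.DataFrame, flank: int = 50000
) -> GeneScoreTable:
    """Positional SNP-to-gene assignment with a Sidak min-p gene summary.

    A SNP is assigned to every gene whose span, extended by ``flank`` bases on
    both sides, contains its position on the same chromosome (a SNP may hit
    several genes). The gene-level p-value is 1 - (1 - min_p)^m over its m
    assigned SNPs — a crude stand-in for LD-aware gene-based tests (VEGAS and
    kin), offered only so SNP-level input can flow through the pipeline;
    supplying proper gene-based p-values directly is preferred.

    ``genes`` needs columns gene, chrom, start, end (1-based inclusive).
    """
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene coordinate table needs columns {sorted(required)}")
    out: list[tuple[str, float]] = []
    for chrom, snp_grp in snps.groupby("chrom", sort=True):
        gene_grp = genes[genes["chrom"].astype(str) == str(chrom)]
        if gene_grp.empty:
            continue
        pos = snp_grp["pos"].to_numpy()
        pvals = snp_grp["p"].to_numpy()
        for _, grow in gene_grp.iterrows():
            mask = (pos >= int(grow["start"]) - flank) & (pos <= int(grow["end"]) + flank)
            m = int(mask.sum())
            if m == 0:
                continue
            min_p = float(pvals[mask].min())
            out.append((str(grow["gene"]).upper(), 1.0 - (1.0 - min_p) ** m))
    if not out:
        raise ValueError("no gene received any SNP within the flanking window")
    return GeneScoreTable.from_pairs(sorted(out))


def write_network_summary_tsv(table: pd.DataFrame, path) -> None:
    """Write the per-network summary TSV (member lists comma-joined)."""
    out = table.copy()
    out["significant_genes"] = out["significant_genes"].map(",".join)
    out["nonsignificant_genes"] = out["nonsignificant_genes"].map(",".join)
    out.loc[
        :,
        [
            "network_id",
            "n_genes",
            "n_significant",
            "n_nonsignificant",
            "significant_genes",
            "nonsignificant_genes",
            "z_comb",
            "p_network",
            "p_corrected",
            "rank",
            "percentile",
        ],
    ].to_csv(path, sep="\t", index=False)
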