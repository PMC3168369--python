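"""Permutation null procedures and top-rank recurrence summaries.

Two nulls diagnose "small-world" artifacts — sub-networks that rank highly
regardless of phenotype because they are hub-rich or densely studied:

* node-label permutation of the interactome (degree multiset preserved,
  hubs re-assigned to random labels), after which networks are rebuilt; and
* gene-label permutation of the GWAS table (p-value multiset preserved).

For each permutation run the pipeline is re-scored and a network counts a
top-hit when its percentile is at or below 100 * top_fraction. Networks that
are top-hits in a large fraction of null runs (> 0.5) are flagged
``recurrent`` and deserve skepticism; networks rarely in the null top set
(< 0.05) are flagged ``trait_specific``.

Gene-label permutation cannot change network topology, so that mode reuses
the baseline networks and weights and re-scores only — an exact shortcut.
"""

from __future__ import annotations

import logging
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .graph_io import GeneScoreTable
from .pipeline import RunConfig, build_networks, run_scoring, weight_networks
from .scorer import p_to_z, rank_networks, score_all_networks

__all__ = ["permute_node_labels", "permute_gene_pvalues", "null_frequency", "spawn_seeds"]

logger = logging.getLogger(__name__)

RECURRENT_THRESHOLD = 0.5
TRAIT_SPECIFIC_THRESHOLD = 0.05


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-run child seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def permute_node_labels(interactome: nx.Graph, seed: int) -> nx.Graph:
    """Apply a uniformly random bijection of node labels to the edge list.

    Node and edge counts and the degree multiset are unchanged; which label
    carries which degree is randomized, so hubs do not remain hubs.
    """
    rng = np.random.default_rng(seed)
    labels = sorted(interactome.nodes)
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    mapping = dict(zip(labels, permuted))
    return nx.relabel_nodes(interactome, mapping, copy=True)


def permute_gene_pvalues(table: GeneScoreTable, seed: int) -> GeneScoreTable:
    """Uniformly shuffle the gene -> p assignment (p multiset preserved)."""
    rng = np.random.default_rng(seed)
    df = table.table.copy()
    df["p"] = df["p"].to_numpy()[rng.permutation(len(df))]
    return GeneScoreTable(df)


def _flag(frequency: float) -> str:
    if frequency > RECURRENT_THRESHOLD:
        return "recurrent"
    if frequency < TRAIT_SPECIFIC_THRESHOLD:
        return "trait_specific"
    return "intermediate"


class _GwasNullScorer:
    """Re-scores fixed networks under permuted gene assignments, vectorized."""

    def __init__(self, networks, weights, gene_table: GeneScoreTable):
        self.genes = np.array(gene_table.genes)
        self.z_base = np.asarray(
            p_to_z(gene_table.table["p"].to_numpy(), gene_table.mean_p, gene_table.sd_p)
        )
        pos = {g: i for i, g in enumerate(self.genes)}
        self.ids: list[str] = []
        self.idx: list[np.ndarray] = []
        self.wvec: list[np.ndarray] = []
        self.nrm: list[float] = []
        for net in networks:
            scored = [g for g in sorted(net.nodes) if g in pos]
            if not scored:
                continue
            wv = weights[net.network_id]
            w = np.array([wv.weights[g] for g in scored])
            self.ids.append(net.network_id)
            self.idx.append(np.array([pos[g] for g in scored]))
            self.wvec.append(w)
            self.nrm.append(float(np.sqrt((w**2).sum())))
        self.id_arr = np.array(self.ids)
        self.n_genes = np.array([len(i) for i in self.idx])

    def top_set(self, perm: np.ndarray, top_fraction: float) -> np.ndarray:
        """network_ids in the top fraction under the given gene permutation."""
        z = self.z_base[perm]
        z_comb = np.array(
            [w @ z[ix] / nrm for w, ix, nrm in zip(self.wvec, self.idx, self.nrm)]
        )
        p_net = norm.sf(z_comb)
        p_corr = np.minimum(1.0, p_net * self.n_genes * len(self.ids))
        ranks = rank_networks(self.id_arr, p_corr, z_comb)
        hit = 100.0 * ranks / len(self.ids) <= 100.0 * top_fraction
        return self.id_arr[hit]


def null_frequency(
    interactome: nx.Graph,
    gene_table: GeneScoreTable,
    runs: int,
    mode: Literal["networks", "gwas"],
    seed: int,
    config: RunConfig | None = None,
    top_fraction: float | None = None,
) -> pd.DataFrame:
    """Top-rank recurrence of each sub-network over permutation runs.

    Returns a DataFrame with columns network_id, n_runs, n_top_hits,
    frequency and flag (recurrent / intermediate / trait_specific at the
    0.5 / 0.05 frequency thresholds).
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if mode not in ("networks", "gwas"):
        raise ValueError(f"mode must be 'networks' or 'gwas', got {mode!r}")
    config = config or RunConfig()
    if top_fraction is None:
        top_fraction = config.top_fraction

    networks, _ = build_networks(interactome, config)
    child_seeds = spawn_seeds(seed, runs)
    hits: dict[str, int] = {}

    if mode == "gwas":
        weights = weight_networks(networks, config)
        scorer = _GwasNullScorer(networks, weights, gene_table)
        hits = {nid: 0 for nid in scorer.ids}
        n_genes = len(gene_table)
        for child in child_seeds:
            perm = np.random.default_rng(child).permutation(n_genes)
            for nid in scorer.top_set(perm, top_fraction):
                hits[nid] += 1
    else:
        weights = weight_networks(networks, config)
        baseline = score_all_networks(networks, weights, gene_table, config.alpha_gene)
        hits = {nid: 0 for nid in baseline["network_id"]}
        for child in child_seeds:
            permuted = permute_node_labels(interactome, child)
            table, _ = run_scoring(permuted, gene_table, config)
            top = table.loc[table["percentile"] <= 100.0 * top_fraction, "network_id"]
            for nid in top:
                if nid in hits:
                    hits[nid] += 1

    rows = [
        {
            "network_id": nid,
            "n_runs": runs,
            "n_top_hits": n,
            "frequency": n / runs,
            "flag": _flag(n / runs),
        }
        for nid, n in sorted(hits.items())
    ]
    return pd.DataFrame(rows)
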