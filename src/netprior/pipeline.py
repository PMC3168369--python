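"""End-to-end orchestration: interactome -> sub-networks -> weights -> scores.

Also holds :class:`RunConfig`, the flat, serializable bag of pipeline
parameters, and :class:`StageCounts`, the build-stage accounting (networks
built / retained after subset removal / retained after the size filter).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import networkx as nx
import pandas as pd
import yaml

from .graph_io import GeneScoreTable
from .network_builder import (
    SubNetwork,
    build_all_networks,
    filter_by_size,
    remove_subset_networks,
)
from .ranker import WeightVector, pagerank_weights
from .scorer import score_all_networks

__all__ = ["RunConfig", "StageCounts", "build_networks", "weight_networks", "run_scoring"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters (defaults are the method's standard settings)."""

    flank: int = 50000
    size_min: int = 20
    size_max: int = 200
    top_fraction: float = 0.02
    alpha_gene: float = 0.05
    tol: float = 1e-10
    max_iter: int = 1000
    n_network_randomizations: int = 100
    n_gwas_permutations: int = 10000
    seed: int = 0
    taxon: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class StageCounts:
    """Accounting of the build pipeline, in its fixed stage order."""

    n_nodes: int = 0
    n_edges: int = 0
    n_built: int = 0
    n_after_subset_removal: int = 0
    n_after_size_filter: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def build_networks(
    interactome: nx.Graph, config: RunConfig | None = None
) -> tuple[list[SubNetwork], StageCounts]:
    """build -> subset-removal -> size-filter, with stage accounting."""
    config = config or RunConfig()
    counts = StageCounts(
        n_nodes=interactome.number_of_nodes(), n_edges=interactome.number_of_edges()
    )
    nets = build_all_networks(interactome)
    counts.n_built = len(nets)
    nets = remove_subset_networks(nets)
    counts.n_after_subset_removal = len(nets)
    nets = filter_by_size(nets, config.size_min, config.size_max)
    counts.n_after_size_filter = len(nets)
    logger.info(
        "networks: %d built, %d after subset removal, %d after size filter [%d-%d]",
        counts.n_built,
        counts.n_after_subset_removal,
        counts.n_after_size_filter,
        config.size_min,
        config.size_max,
    )
    return nets, counts


def weight_networks(
    networks: list[SubNetwork], config: RunConfig | None = None
) -> dict[str, WeightVector]:
    """Modified-PageRank weights for every sub-network."""
    config = config or RunConfig()
    return {
        net.network_id: pagerank_weights(net, tol=config.tol, max_iter=config.max_iter)
        for net in networks
    }


def run_scoring(
    interactome: nx.Graph,
    gene_table: GeneScoreTable,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, StageCounts]:
    """Full pipeline from a clean interactome and gene p-values to ranked scores."""
    config = config or RunConfig()
    networks, counts = build_networks(interactome, config)
    weights = weight_networks(networks, config)
    table = score_all_networks(networks, weights, gene_table, alpha_gene=config.alpha_gene)
    return table, counts
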