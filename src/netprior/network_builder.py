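"""Two-step (radius-2) sub-network construction and pruning.

Every interactome protein seeds one sub-network containing all nodes within
graph distance 2 of the seed, with edges induced from the interactome.
Sub-networks whose node set is contained in another retained sub-network's
node set are dropped, then a size filter keeps networks of 20-200 proteins
(both bounds inclusive) — small enough to be interpretable gene sets, large
enough to support a combined network statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "SubNetwork",
    "build_two_step_network",
    "build_all_networks",
    "remove_subset_networks",
    "filter_by_size",
    "write_subnetworks_tsv",
]


@dataclass(eq=False)
class SubNetwork:
    """One seed-centred sub-network with its induced subgraph."""

    seed: str
    graph: nx.Graph
    nodes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.graph.nodes)
        if self.seed not in self.nodes:
            raise ValueError(f"seed {self.seed!r} not among sub-network nodes")

    @property
    def network_id(self) -> str:
        return f"net:{self.seed}"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}


def build_two_step_network(interactome: nx.Graph, seed: str) -> SubNetwork:
    """Sub-network of all nodes within distance 2 of ``seed``, edges induced."""
    if seed not in interactome:
        raise KeyError(f"seed symbol {seed!r} not in interactome")
    reach = nx.single_source_shortest_path_length(interactome, seed, cutoff=2)
    return SubNetwork(seed=seed, graph=interactome.subgraph(reach.keys()).copy())


def build_all_networks(interactome: nx.Graph) -> list[SubNetwork]:
    """One two-step sub-network per interactome node, in sorted seed order."""
    if interactome.number_of_nodes() == 0:
        raise ValueError("interactome has no nodes")
    return [build_two_step_network(interactome, s) for s in sorted(interactome.nodes)]


def remove_subset_networks(networks: Sequence[SubNetwork]) -> list[SubNetwork]:
    """Drop every sub-network whose node set is contained in a retained one.

    Equal node sets collapse to the network with the lexicographically
    smallest seed. Returned networks are sorted by seed.
    """
    order = sorted(networks, key=lambda n: (-n.n_nodes, n.seed))
    kept: list[SubNetwork] = []
    kept_sets: list[frozenset[str]] = []
    for net in order:
        if any(net.nodes <= ks for ks in kept_sets):
            continue
        kept.append(net)
        kept_sets.append(net.nodes)
    return sorted(kept, key=lambda n: n.seed)


def filter_by_size(
    networks: Iterable[SubNetwork], min_n: int = 20, max_n: int = 200
) -> list[SubNetwork]:
    """Keep sub-networks with ``min_n <= |nodes| <= max_n`` (inclusive)."""
    if min_n > max_n:
        raise ValueError(f"min_n ({min_n}) must not exceed max_n ({max_n})")
    return [n for n in networks if min_n <= n.n_nodes <= max_n]


def write_subnetworks_tsv(
    networks: Sequence[SubNetwork], path: str | Path, edges: bool = False
) -> None:
    """Dump sub-networks as TSV: network_id, seed, n_nodes, comma-joined members.

    With ``edges=True`` an adjacent ``<path>.sif`` file receives one
    "a pp b" line per induced edge per network.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("network_id\tseed\tn_nodes\tmembers\n")
        for net in networks:
            fh.write(
                f"{net.network_id}\t{net.seed}\t{net.n_nodes}\t"
                f"{','.join(sorted(net.nodes))}\n"
            )
    if edges:
        with path.with_suffix(path.suffix + ".sif").open("w") as fh:
            for net in networks:
                for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                    fh.write(f"{net.network_id}\t{a} pp {b}\n")
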