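"""Per-node weights by PageRank with a dynamically computed damping factor.

Classical PageRank applies one fixed damping factor (typically 0.85) to every
node. Biological interaction networks are topologically unlike the web graph,
and a fixed damping factor can rank their nodes inconsistently, so here each
node A receives its own damping factor

    d_A = deg(A) / sum of deg(g) over neighbours g of A,

and the weight vector is the fixed point of

    w(A) = (1 - d_A) / (2N) + d_A * sum_H w(H) / deg(H)        (H ~ A),

where N is the number of nodes in the sub-network. The teleport mass uses 2N
rather than N so the total weight of a network stays inside (0, 1); weights
are consumed as-is downstream, without renormalization. Undirected graphs
have no dangling nodes, so every node participates in every iteration.

Solved by synchronous (Jacobi) iteration from the uniform start 1/(2N); for
a k-regular graph d = 1/k for every node and the fixed point is exactly
uniform, w = 1/(2N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_builder import SubNetwork

__all__ = ["WeightVector", "damping_factor", "pagerank_weights"]

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """Modified-PageRank weights for one sub-network."""

    network_id: str
    weights: dict[str, float]
    damping: dict[str, float]
    iterations_used: int
    converged: bool


def damping_factor(subnetwork: SubNetwork, node: str) -> float:
    """d = deg(node) / sum of neighbour degrees; 0 for an isolated node."""
    graph = subnetwork.graph
    if node not in graph:
        raise KeyError(f"node {node!r} not in sub-network {subnetwork.network_id}")
    deg = graph.degree(node)
    if deg == 0:
        return 0.0
    return deg / sum(graph.degree(h) for h in graph.neighbors(node))


def pagerank_weights(
    subnetwork: SubNetwork, tol: float = 1e-10, max_iter: int = 1000
) -> WeightVector:
    """Iterate the damped fixed-point equation to convergence.

    Stops when the max-norm change drops below ``tol`` or after ``max_iter``
    synchronous sweeps; ``converged`` records which. All weights lie strictly
    inside (0, 1).
    """
    graph = subnetwork.graph
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 1:
        # degenerate single-node network: pure teleport mass
        return WeightVector(
            network_id=subnetwork.network_id,
            weights={nodes[0]: 1.0 / (2 * n)},
            damping={nodes[0]: 0.0},
            iterations_used=0,
            converged=True,
        )
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    deg = adj.sum(axis=1)
    neighbor_deg_sum = adj @ deg
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(deg > 0, deg / neighbor_deg_sum, 0.0)
    deg_safe = np.where(deg > 0, deg, 1.0)

    w = np.full(n, 1.0 / (2 * n))
    teleport = (1.0 - d) / (2 * n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        w_new = teleport + d * (adj @ (w / deg_safe))
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        logger.warning(
            "modified PageRank did not converge in %d iterations for %s",
            max_iter,
            subnetwork.network_id,
        )
    return WeightVector(
        network_id=subnetwork.network_id,
        weights=dict(zip(nodes, w.tolist())),
        damping=dict(zip(nodes, d.tolist())),
        iterations_used=iterations,
        converged=converged,
    )
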