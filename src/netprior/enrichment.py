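"""Candidate-gene overlap testing and cross-dataset top-network comparison.

The overlap test asks: drawing ``drawn_n`` genes from a universe of
``universe_n`` that contains ``candidates_k`` trait candidates, how likely is
an overlap at least as large as observed? This is an exact hypergeometric
upper tail. Two tail conventions are exposed: ``"ge"`` (P(X >= k), the
standard at-least-as-extreme test and the default) and ``"gt"``
(P(X > k), the convention some legacy tools report).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Literal

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["OverlapResult", "hypergeom_overlap", "compare_rankings"]


@dataclass(frozen=True)
class OverlapResult:
    universe_n: int
    candidates_k: int
    drawn_n: int
    observed_k: int
    p_upper: float
    tail: str = "ge"


def hypergeom_overlap(
    universe_n: int,
    candidates_k: int,
    drawn_n: int,
    observed_k: int,
    tail: Literal["ge", "gt"] = "ge",
) -> OverlapResult:
    """Exact hypergeometric upper-tail overlap probability.

    ``tail="ge"`` gives P(X >= observed_k); ``tail="gt"`` gives
    P(X > observed_k).
    """
    if not (0 <= candidates_k <= universe_n and 0 <= drawn_n <= universe_n):
        raise ValueError("candidate and drawn counts must lie within the universe")
    if not 0 <= observed_k <= min(candidates_k, drawn_n):
        raise ValueError("observed overlap exceeds min(candidates, drawn)")
    if tail == "ge":
        p = float(hypergeom.sf(observed_k - 1, universe_n, candidates_k, drawn_n))
    elif tail == "gt":
        p = float(hypergeom.sf(observed_k, universe_n, candidates_k, drawn_n))
    else:
        raise ValueError(f"tail must be 'ge' or 'gt', got {tail!r}")
    return OverlapResult(universe_n, candidates_k, drawn_n, observed_k, p, tail)


def compare_rankings(
    tables: Mapping[str, pd.DataFrame], top_fraction: float = 0.02
) -> dict[tuple[str, ...], set[str]]:
    """Inclusion-exclusion partition of top network sets across datasets.

    ``tables`` maps dataset name to a network score table (needs columns
    network_id, percentile). A network is in a dataset's top set when its
    percentile is at or below 100 * top_fraction. Returns every non-empty
    combination of dataset names (as a sorted tuple) mapped to the networks
    in exactly those datasets' top sets (the exclusive Venn region; regions
    may be empty sets).
    """
    if len(tables) < 2:
        raise ValueError("need at least two score tables to compare")
    namespaces = [set(t["network_id"]) for t in tables.values()]
    if not set.intersection(*namespaces):
        raise ValueError("score tables share no network ids (different interactomes?)")
    tops = {
        name: set(t.loc[t["percentile"] <= 100.0 * top_fraction, "network_id"])
        for name, t in tables.items()
    }
    names = sorted(tops)
    partition: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(tops[n] for n in combo))
            outside = set().union(*(tops[n] for n in names if n not in combo))
            partition[combo] = inside - outside
    return partition
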