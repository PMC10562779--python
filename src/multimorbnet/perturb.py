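"""Perturbation analyses: crucial-node removal and random edge deletion.

Node perturbation removes one crucial disease at a time (independently, the
network is restored between removals), drops any nodes the removal isolates,
recomputes the summary metrics, and reports signed percent changes — e.g.
a value of -6.744 for avg_harmonic means a 6.744% reduction in average
harmonic centrality.

Edge perturbation deletes a random 1%/3%/5% of edges (three repetitions per
level by default), recomputes the top-10 PageRank ranking, and counts the
overlap with the unperturbed top 10 — a direct measure of hub-identification
robustness.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .crucial import identify_hub_diseases, PAGERANK_DAMPING_DEFAULT
from .metrics import NetworkSummary, summarize_network

logger = logging.getLogger("multimorbnet")

PCT_FIELDS = (
    "n_nodes",
    "n_edges",
    "density",
    "avg_degree",
    "avg_weighted_degree",
    "avg_closeness",
    "avg_harmonic",
    "avg_harmonic_normalized",
)


@dataclasses.dataclass
class NodeRemovalResult:
    removed_code: str
    before: NetworkSummary
    after: NetworkSummary  # isolated nodes dropped
    after_with_isolates: NetworkSummary
    pct_change: dict[str, float]  # 100 * (after - before) / before, per metric
    error: str | None = None


@dataclasses.dataclass
class EdgeRemovalResult:
    level: float
    rep: int
    seed: tuple[int, ...]
    n_removed: int
    top_k_before: list[str]
    top_k_after: list[str]
    overlap_count: int


def _pct_changes(before: NetworkSummary, after: NetworkSummary) -> dict[str, float]:
    out: dict[str, float] = {}
    for f in PCT_FIELDS:
        b, a = getattr(before, f), getattr(after, f)
        if b is None or a is None or b == 0:
            out[f] = float("nan")
        else:
            out[f] = 100.0 * (a - b) / b
    return out


def node_removal_analysis(
    g: nx.Graph,
    codes_to_remove: Iterable[str],
) -> list[NodeRemovalResult]:
    """Remove each listed node independently and measure the structural impact.

    Nodes left isolated by a removal are dropped before recomputation (the
    networks never carry degree-0 nodes); a summary keeping the isolates is
    also reported. Codes absent from the network yield an error entry and the
    analysis continues.
    """
    before = summarize_network(g)
    results: list[NodeRemovalResult] = []
    for code in codes_to_remove:
        if code not in g:
            logger.warning("node %s not in network; skipped", code)
            results.append(
                NodeRemovalResult(
                    removed_code=code,
                    before=before,
                    after=before,
                    after_with_isolates=before,
                    pct_change={},
                    error="node_not_in_network",
                )
            )
            continue
        h = g.copy()
        h.remove_node(code)
        with_isolates = summarize_network(h)
        h.remove_nodes_from(list(nx.isolates(h)))
        after = summarize_network(h)
        results.append(
            NodeRemovalResult(
                removed_code=code,
                before=before,
                after=after,
                after_with_isolates=with_isolates,
                pct_change=_pct_changes(before, after),
            )
        )
    return results


def edge_removal_analysis(
    g: nx.Graph,
    levels: Sequence[float] = (0.01, 0.03, 0.05),
    reps: int = 3,
    k: int = 10,
    seed: int = 0,
    damping: float = PAGERANK_DAMPING_DEFAULT,
) -> list[EdgeRemovalResult]:
    """Random edge deletion at each level x rep; top-k PageRank overlap.

    The removal count is ``round(level * n_edges)`` edges sampled uniformly
    without replacement; each (level, rep) cell uses an independent RNG stream
    derived deterministically from the master seed. Levels whose removal
    count rounds to zero are skipped with a warning (level 0.0 is reported as
    the identity).
    """
    m = g.number_of_edges()
    top_before = [c for c, _ in identify_hub_diseases(g, k=k, damping=damping)[0]]
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    results: list[EdgeRemovalResult] = []
    for li, level in enumerate(levels):
        n_remove = int(round(level * m))
        if level > 0 and n_remove == 0:
            logger.warning("level %.3f removes 0 of %d edges; skipped", level, m)
            continue
        for rep in range(reps):
            stream = (seed, li, rep)
            rng = np.random.default_rng(stream)
            idx = rng.choice(m, size=n_remove, replace=False) if n_remove else np.array([], dtype=int)
            h = g.copy()
            h.remove_edges_from(edges[i] for i in idx)
            h.remove_nodes_from(list(nx.isolates(h)))
            top_after = [c for c, _ in identify_hub_diseases(h, k=k, damping=damping)[0]]
            results.append(
                EdgeRemovalResult(
                    level=float(level),
                    rep=rep,
                    seed=stream,
                    n_removed=n_remove,
                    top_k_before=top_before,
                    top_k_after=top_after,
                    overlap_count=len(set(top_before) & set(top_after)),
                )
            )
    return results
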