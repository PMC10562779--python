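"""Structural metrics of multimorbidity networks.

Degree, weighted degree (sum of incident SCI weights), density, closeness and
harmonic centrality, plus network-level averages. Harmonic centrality replaces
closeness as the headline proximity measure because the age-stratified
networks are not all connected; it is well defined on disconnected graphs
(unreachable pairs contribute zero). Shortest paths use unweighted hop counts:
the SCI is a similarity, not a distance, and no weight-to-distance transform
is imposed.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import pandas as pd


@dataclasses.dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float | None  # None when n_nodes < 2
    avg_degree: float
    avg_weighted_degree: float
    avg_closeness: float  # averaged over the largest connected component
    avg_harmonic: float  # raw, averaged over all nodes
    avg_harmonic_normalized: float  # raw / (n - 1), comparable across sizes
    connected: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_degrees(g: nx.Graph) -> pd.DataFrame:
    """Integer degree and sum of incident SCI weights per node."""
    rows = [
        {
            "code": v,
            "degree": g.degree(v),
            "weighted_degree": g.degree(v, weight="weight"),
        }
        for v in sorted(g.nodes)
    ]
    return pd.DataFrame(rows, columns=["code", "degree", "weighted_degree"])


def compute_harmonic_centrality(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Harmonic centrality sum_{u != v} 1/d(u, v) on unweighted hop counts.

    Unreachable nodes contribute 0; an isolated node scores 0. With
    ``normalized`` the value is divided by (n - 1).
    """
    raw = nx.harmonic_centrality(g)
    n = g.number_of_nodes()
    if normalized and n > 1:
        return {v: h / (n - 1) for v, h in raw.items()}
    return dict(raw)


def compute_closeness(g: nx.Graph) -> tuple[dict[str, float], float, bool]:
    """Per-node closeness plus the average over the largest connected component.

    On disconnected graphs networkx computes closeness within each node's
    component; the summary average is taken over the largest component only,
    with a disconnectedness flag.
    """
    n = g.number_of_nodes()
    if n == 0:
        return {}, 0.0, True
    closeness = nx.closeness_centrality(g)
    components = list(nx.connected_components(g))
    connected = len(components) == 1
    largest = max(components, key=lambda c: (len(c), sorted(c)[0]))
    avg = sum(closeness[v] for v in largest) / len(largest)
    return closeness, avg, connected


def summarize_network(g: nx.Graph) -> NetworkSummary:
    """All network-level summary metrics; density is undefined below 2 nodes."""
    n, m = g.number_of_nodes(), g.number_of_edges()
    degrees = compute_degrees(g)
    avg_degree = 2 * m / n if n else 0.0
    avg_wdeg = float(degrees["weighted_degree"].mean()) if n else 0.0
    harmonic = compute_harmonic_centrality(g)
    avg_harm = sum(harmonic.values()) / n if n else 0.0
    avg_harm_norm = avg_harm / (n - 1) if n > 1 else 0.0
    _, avg_close, connected = compute_closeness(g)
    density = nx.density(g) if n >= 2 else None
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        density=density,
        avg_degree=avg_degree,
        avg_weighted_degree=avg_wdeg,
        avg_closeness=avg_close,
        avg_harmonic=avg_harm,
        avg_harmonic_normalized=avg_harm_norm,
        connected=connected,
    )


def node_metrics_frame(g: nx.Graph) -> pd.DataFrame:
    """Per-node metric table (degree, weighted degree, harmonic, closeness)."""
    df = compute_degrees(g)
    harmonic = compute_harmonic_centrality(g)
    harmonic_norm = compute_harmonic_centrality(g, normalized=True)
    closeness, _, _ = compute_closeness(g)
    df["harmonic"] = df["code"].map(harmonic)
    df["harmonic_normalized"] = df["code"].map(harmonic_norm)
    df["closeness"] = df["code"].map(closeness)
    return df
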