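"""Crucial-disease identification: hubs, roots, bursts, cores, temporal trends.

Three categories of influential conditions are read off the networks:

* hub diseases — the top 10 nodes by PageRank on the SCI-weighted per-sex
  global network (damping 0.85);
* root diseases — per Louvain community, the member with maximum eigenvector
  centrality on the community's induced weighted subgraph;
* burst diseases — nodes whose degree grows by >= 6 between adjacent
  age-stratum networks of the same sex (absence from a stratum counts as
  degree 0);
* core diseases — the intersection hub ∩ root ∩ burst per sex.

Temporal trends rebuild cumulative yearly networks (baseline 2015 through
2021 by default, i.e. seven networks) from patients indexed in the first
study year with qualifying visits every year, and track node degrees.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ConditionCatalog, ConditionSelection
from .network import StratumNetwork, build_stratum_network, T_CRITICAL_DEFAULT
from .synthetic import AGE_BANDS

logger = logging.getLogger("multimorbnet")

BURST_THRESHOLD_DEFAULT = 6
PAGERANK_DAMPING_DEFAULT = 0.85


@dataclasses.dataclass
class CommunityResult:
    partition: dict[str, int]
    modularity: float
    communities: list[frozenset[str]]


@dataclasses.dataclass(frozen=True)
class BurstRecord:
    code: str
    sex: str
    transition: tuple[str, str]  # adjacent age bands (before, after)
    degree_before: int
    degree_after: int

    @property
    def growth(self) -> int:
        return self.degree_after - self.degree_before


@dataclasses.dataclass
class CrucialDiseaseReport:
    """Hub/root/burst/core sets for one sex, with supporting scores."""

    sex: str
    hubs: list[tuple[str, float]]  # (code, pagerank), ranked
    hub_ties_flagged: bool
    roots: dict[int, str]  # community id -> root code
    root_ties: list[int]  # community ids where the argmax was tied
    communities: CommunityResult
    bursts: list[BurstRecord]
    degree_trajectories: pd.DataFrame  # code x age band
    cores: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "hubs": [{"code": c, "pagerank": p} for c, p in self.hubs],
            "hub_ties_flagged": self.hub_ties_flagged,
            "roots": {str(k): v for k, v in sorted(self.roots.items())},
            "root_ties": self.root_ties,
            "modularity": self.communities.modularity,
            "communities": {
                str(k): sorted(c) for k, c in enumerate(self.communities.communities)
            },
            "bursts": [
                {
                    "code": b.code,
                    "transition": list(b.transition),
                    "degree_before": b.degree_before,
                    "degree_after": b.degree_after,
                    "growth": b.growth,
                }
                for b in self.bursts
            ],
            "cores": sorted(self.cores),
        }


def _weighted_degree(g: nx.Graph, v) -> float:
    return g.degree(v, weight="weight")


def identify_hub_diseases(
    g: nx.Graph,
    k: int = 10,
    damping: float = PAGERANK_DAMPING_DEFAULT,
) -> tuple[list[tuple[str, float]], bool]:
    """Top-k nodes by PageRank on the weighted undirected graph.

    Each undirected edge acts as two directed arcs with transition probability
    proportional to the SCI weight. Ties are broken by higher weighted degree
    then lexicographic code; a tie straddling the k-th rank is flagged.
    Returns ``(ranked list of (code, score), ties_flagged)``.
    """
    if g.number_of_nodes() == 0:
        return [], False
    if k > g.number_of_nodes():
        logger.warning("k=%d exceeds node count %d; returning all nodes", k, g.number_of_nodes())
        k = g.number_of_nodes()
    pr = nx.pagerank(g, alpha=damping, weight="weight", tol=1e-12, max_iter=1000)
    ranked = sorted(pr, key=lambda v: (-pr[v], -_weighted_degree(g, v), str(v)))
    ties = False
    if len(ranked) > k:
        ties = abs(pr[ranked[k - 1]] - pr[ranked[k]]) < 1e-12
    return [(v, pr[v]) for v in ranked[:k]], ties


def detect_communities(
    g: nx.Graph,
    seed: int = 0,
    n_restarts: int = 20,
    resolution: float = 1.0,
) -> CommunityResult:
    """Louvain partition maximizing weighted modularity, best of ``n_restarts``.

    Restart seeds are ``seed, seed+1, ...``; the partition with the highest
    modularity wins (first encountered on ties), so the result is
    reproducible for a fixed seed.
    """
    if g.number_of_nodes() == 0:
        return CommunityResult(partition={}, modularity=0.0, communities=[])
    best, best_q = None, -np.inf
    for s in range(seed, seed + max(1, n_restarts)):
        comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=s)
        q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best, best_q = comms, q
    communities = sorted((frozenset(c) for c in best), key=lambda c: sorted(c)[0])
    partition = {v: cid for cid, comm in enumerate(communities) for v in comm}
    return CommunityResult(partition=partition, modularity=float(best_q), communities=communities)


def eigenvector_centrality_weighted(g: nx.Graph) -> dict[str, float]:
    """Leading-eigenvector scores of the weighted adjacency (non-negative).

    Dense symmetric eigendecomposition; adequate for community-sized
    subgraphs and deterministic. For a connected non-trivial graph the
    Perron-Frobenius vector is strictly positive; the absolute value guards
    against the solver's arbitrary sign choice.
    """
    nodes = sorted(g.nodes)
    if len(nodes) == 1:
        return {nodes[0]: 1.0}
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    w, v = np.linalg.eigh(a)
    lead = np.abs(v[:, np.argmax(w)])
    return {n: float(s) for n, s in zip(nodes, lead)}


def identify_root_diseases(
    communities: CommunityResult,
    g: nx.Graph,
) -> tuple[dict[int, str], list[int]]:
    """Per community, the member with maximum eigenvector centrality.

    Centrality is computed on the community's induced weighted subgraph.
    Ties are broken by higher weighted degree then lexicographic code and the
    community id is recorded in the returned tie list. A single-node
    community's root is that node by convention.
    """
    roots: dict[int, str] = {}
    tied: list[int] = []
    for cid, comm in enumerate(communities.communities):
        sub = g.subgraph(comm)
        if sub.number_of_nodes() == 1:
            roots[cid] = next(iter(comm))
            logger.info("community %d is a single node; root by convention", cid)
            continue
        cent = eigenvector_centrality_weighted(sub)
        best = max(cent.values())
        top = sorted(
            [v for v in cent if cent[v] >= best - 1e-9],
            key=lambda v: (-_weighted_degree(sub, v), str(v)),
        )
        if len(top) > 1:
            tied.append(cid)
        roots[cid] = top[0]
    return roots, tied


def degree_trajectories(
    stratified: Mapping[str, StratumNetwork],
    sex: str,
) -> pd.DataFrame:
    """Degree of every condition across the six age bands for one sex.

    Conditions absent from a band's network have degree 0 there; bands whose
    network was skipped contribute a zero column.
    """
    cols: dict[str, dict[str, int]] = {}
    codes: set[str] = set()
    for band in AGE_BANDS:
        sn = stratified.get(f"{sex}_{band}")
        deg = dict(sn.graph.degree()) if sn is not None else {}
        cols[band] = deg
        codes |= set(deg)
    table = pd.DataFrame(
        {band: [cols[band].get(c, 0) for c in sorted(codes)] for band in AGE_BANDS},
        index=sorted(codes),
    ).astype(int)
    table.index.name = "code"
    return table


def identify_burst_diseases(
    stratified: Mapping[str, StratumNetwork],
    sex: str,
    threshold: int = BURST_THRESHOLD_DEFAULT,
) -> tuple[list[BurstRecord], pd.DataFrame]:
    """Bursts: degree growth >= threshold between adjacent age bands (inclusive)."""
    traj = degree_trajectories(stratified, sex)
    n_bands_present = sum(1 for b in AGE_BANDS if f"{sex}_{b}" in stratified)
    if n_bands_present < 2:
        logger.warning("fewer than 2 non-empty age bands for %s; no burst analysis", sex)
        return [], traj
    records: list[BurstRecord] = []
    for code, row in traj.iterrows():
        for a, b in zip(AGE_BANDS[:-1], AGE_BANDS[1:]):
            growth = int(row[b]) - int(row[a])
            if growth >= threshold:
                records.append(
                    BurstRecord(
                        code=code,
                        sex=sex,
                        transition=(a, b),
                        degree_before=int(row[a]),
                        degree_after=int(row[b]),
                    )
                )
    return records, traj


def identify_core_diseases(
    hubs: Iterable[str],
    roots: Iterable[str],
    bursts: Iterable[str],
) -> frozenset[str]:
    """Core diseases: the intersection of the hub, root, and burst code sets."""
    return frozenset(hubs) & frozenset(roots) & frozenset(bursts)


def crucial_disease_report(
    stratified: Mapping[str, StratumNetwork],
    sex: str,
    k: int = 10,
    damping: float = PAGERANK_DAMPING_DEFAULT,
    burst_threshold: int = BURST_THRESHOLD_DEFAULT,
    louvain_seed: int = 0,
    louvain_restarts: int = 20,
    louvain_resolution: float = 1.0,
) -> CrucialDiseaseReport:
    """Assemble hubs, roots, bursts, and cores for one sex.

    Hubs and communities/roots are computed on the per-sex global network;
    the age-stratified networks feed only the burst analysis.
    """
    global_net = stratified[f"{sex}_global"].graph
    hubs, hub_ties = identify_hub_diseases(global_net, k=k, damping=damping)
    communities = detect_communities(
        global_net, seed=louvain_seed, n_restarts=louvain_restarts, resolution=louvain_resolution
    )
    roots, root_ties = identify_root_diseases(communities, global_net)
    bursts, traj = identify_burst_diseases(stratified, sex, threshold=burst_threshold)
    cores = identify_core_diseases(
        (c for c, _ in hubs), roots.values(), (b.code for b in bursts)
    )
    return CrucialDiseaseReport(
        sex=sex,
        hubs=hubs,
        hub_ties_flagged=hub_ties,
        roots=roots,
        root_ties=root_ties,
        communities=communities,
        bursts=bursts,
        degree_trajectories=traj,
        cores=cores,
    )


def temporal_degree_trends(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    catalog: ConditionCatalog,
    disease_set: Iterable[str],
    universe: Iterable[str],
    start_year: int = 2013,
    baseline_year: int = 2015,
    end_year: int = 2021,
    t_critical: float = T_CRITICAL_DEFAULT,
    pair_eligible: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Degree of each tracked disease on cumulative yearly networks.

    The continuous-record subcohort comprises patients whose index date falls
    in ``start_year`` and who appear in every calendar year through
    ``end_year``. For each year y from ``baseline_year`` to ``end_year`` a
    network is built from all their post-index diagnoses dated on or before
    Dec 31 of y (the baseline network therefore spans start..baseline), and
    the degree of every disease in ``disease_set`` is reported (0 when absent).
    At the defaults this yields seven cumulative networks.
    """
    universe = frozenset(universe)
    idx_year = cohort["index_date"].dt.year
    base = cohort[idx_year == start_year]
    ev = events.merge(base[["patient_id", "index_date"]], on="patient_id", how="inner")
    seen = ev.groupby("patient_id")["visit_date"].agg(lambda s: frozenset(s.dt.year))
    continuous = {
        pid for pid, ys in seen.items() if set(range(start_year, end_year + 1)) <= ys
    }
    ev = ev[ev["patient_id"].isin(continuous)]
    ev = ev[(ev["visit_date"] >= ev["index_date"]) & ev["icd10_code"].isin(universe)]

    diseases = sorted(set(disease_set))
    out = pd.DataFrame(index=diseases, columns=range(baseline_year, end_year + 1), dtype=int)
    out.index.name = "code"
    for y in range(baseline_year, end_year + 1):
        window = ev[ev["visit_date"] <= pd.Timestamp(f"{y}-12-31")]
        sets_df = (
            window[["patient_id", "icd10_code"]]
            .drop_duplicates()
            .rename(columns={"icd10_code": "code"})
        )
        sn = build_stratum_network(
            sets_df,
            n_patients=len(continuous),
            label=f"cumulative_{y}",
            t_critical=t_critical,
            pair_patients=pair_eligible,
        )
        deg = dict(sn.graph.degree())
        out[y] = [int(deg.get(c, 0)) for c in diseases]
    return out
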