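"""Shared fixtures: small synthetic cohorts and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest

import multimorbnet as mm


# ---------------------------------------------------------------------------
# independent brute-force oracles (never call the implementation under test)
# ---------------------------------------------------------------------------

def brute_counts(sets_by_patient: dict, n_patients: int | None = None):
    """Double loop over patients: marginal and pair counts."""
    n = n_patients if n_patients is not None else len(sets_by_patient)
    c: Counter = Counter()
    cij: Counter = Counter()
    for pid in sorted(sets_by_patient):
        s = sorted(set(sets_by_patient[pid]))
        for a in s:
            c[a] += 1
        for a, b in itertools.combinations(s, 2):
            cij[(a, b)] += 1
    return n, dict(c), {k: v for k, v in cij.items() if v > 0}


def brute_pair_stats(n, c, cij):
    """Direct formula evaluation for every pair with positive co-occurrence."""
    out = {}
    for (i, j), v in cij.items():
        ci, cj = c[i], c[j]
        if ci == n or cj == n:
            continue
        sci = v / math.sqrt(ci * cj)
        phi = (v * n - ci * cj) / math.sqrt(ci * cj * (n - ci) * (n - cj))
        if v <= 2:
            t = 0.0
        elif abs(phi) >= 1:
            t = math.inf if phi > 0 else -math.inf
        else:
            t = phi * math.sqrt(v - 2) / math.sqrt(1 - phi * phi)
        out[(i, j)] = (sci, phi, t, v)
    return out


def brute_cutoff(stats: dict, t_critical: float = 2.58):
    """Literal reading of the cut-off steps: sort SCI descending, apply both screens."""
    q = len(stats)
    if q == 0:
        return q, 0, math.inf, set()
    mean_cij = sum(v for (_, _, _, v) in stats.values()) / q
    e = sum(1 for (_, _, t, v) in stats.values() if t > t_critical and v > mean_cij)
    if e == 0:
        return q, 0, math.inf, set()
    sci_desc = sorted((s for (s, _, _, _) in stats.values()), reverse=True)
    cut = sci_desc[e - 1]
    retained = {p for p, (s, _, _, _) in stats.items() if s >= cut}
    return q, e, cut, retained


def harmonic_bfs_oracle(g: nx.Graph) -> dict:
    """All-pairs BFS, summing reciprocal hop distances."""
    out = {}
    for src in g.nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[src] = sum(1.0 / d for v, d in dist.items() if v != src)
    return out


def pagerank_power_oracle(g: nx.Graph, damping: float = 0.85, tol: float = 1e-14) -> dict:
    """Weighted PageRank by dense power iteration (dangling mass spread uniformly)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    out_w = a.sum(axis=1)
    p = np.where(out_w[:, None] > 0, a / np.where(out_w[:, None] > 0, out_w[:, None], 1.0), 1.0 / n)
    x = np.full(n, 1.0 / n)
    for _ in range(100000):
        x_new = (1 - damping) / n + damping * (x @ p)
        if np.abs(x_new - x).sum() < tol:
            break
        x = x_new
    return dict(zip(nodes, x_new))


def eigenvector_power_oracle(g: nx.Graph, tol: float = 1e-15) -> dict:
    """Leading eigenvector by power iteration on A + I (unique for connected graphs)."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight") + np.eye(len(nodes))
    x = np.full(len(nodes), 1.0 / math.sqrt(len(nodes)))
    for _ in range(100000):
        y = a @ x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            break
        x = y
    return dict(zip(nodes, np.abs(y)))


def sets_from_events(events, cohort_like=None):
    """Post-index distinct condition codes per patient, straight from events."""
    ev = events[events["icd10_code"] != "E11"]
    return {pid: frozenset(grp) for pid, grp in ev.groupby("patient_id")["icd10_code"]}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SMALL_SPEC = mm.SyntheticSpec(
    n_patients=800, n_conditions=30, n_clusters=3, cluster_effect=4.0, seed=7
)


@pytest.fixture(scope="session")
def small_dataset():
    return mm.simulate(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    events, patients, catalog_df, truth = small_dataset
    catalog = mm.ConditionCatalog(catalog_df)
    eligible, _ = mm.apply_eligibility(events, patients)
    cohort, _ = mm.compute_index_and_age(
        events[events["patient_id"].isin(eligible["patient_id"])], eligible, ("E11",)
    )
    selection = mm.select_conditions(events, cohort, catalog)
    return events, cohort, catalog, selection, truth


def random_condition_sets(rng: np.random.Generator, n_patients=100, n_codes=20, density=0.15):
    """Random per-patient condition sets (independent of the generator)."""
    codes = [f"C{k:02d}" for k in range(n_codes)]
    sets = {}
    mat = rng.random((n_patients, n_codes)) < density
    for i in range(n_patients):
        sets[f"P{i:04d}"] = frozenset(c for c, hit in zip(codes, mat[i]) if hit)
    return sets


def planted_hub_graph(rng: np.random.Generator, n=40, p=0.12, hub_degree=30):
    """Background G(n, p) plus one hub wired to ``hub_degree`` nodes, weights in (0, 1]."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in range(n)})
    for u, v in g.edges:
        g.edges[u, v]["weight"] = g.edges[u, v]["sci"] = 0.2 + 0.6 * rng.random()
    hub = "HUB"
    targets = rng.choice(n, size=min(hub_degree, n), replace=False)
    for t in targets:
        g.add_edge(hub, f"N{t:02d}", weight=0.9, sci=0.9)
    g.remove_nodes_from(list(nx.isolates(g)))
    return g, hub
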