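"""SCI-weighted multimorbidity network construction.

For each unordered pair of conditions (i, j) in a stratum of N patients, with
c_i / c_j patients carrying each condition and c_ij carrying both:

* Salton cosine index      SCI_ij = c_ij / sqrt(c_i * c_j)
* phi coefficient          phi_ij = (c_ij*N - c_i*c_j)
                                    / sqrt(c_i*c_j*(N - c_i)*(N - c_j))
* t statistic              t_ij   = phi_ij * sqrt(c_ij - 2) / sqrt(1 - phi_ij^2)

The SCI is the edge weight of choice because it is invariant to sample size
(doubling every record leaves it unchanged), but it is positive even for
negatively correlated pairs, so a cut-off is calibrated from the phi screen:

1. compute SCI and phi for every pair;
2. q = number of pairs with c_ij > 0;
3. e = number of pairs with t > t_critical (2.58, two-sided p < 0.01) AND
   c_ij > mean(c_ij) over the q pairs;
4. the SCI cut-off is the e-th largest SCI among the q pairs; the network
   keeps exactly the pairs at or above it (ties included), so the SCI network
   has as many edges as there are significantly positively correlated pairs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import ConditionSelection
from .synthetic import AGE_BANDS

logger = logging.getLogger("multimorbnet")

T_CRITICAL_DEFAULT = 2.58  # two-sided standard normal critical value at p=0.01


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Pair-level 2x2 counts within one stratum."""

    n: int
    c_i: int
    c_j: int
    c_ij: int

    def __post_init__(self):
        if not 0 <= self.c_ij <= min(self.c_i, self.c_j) <= self.n:
            raise ValueError(f"inconsistent contingency counts: {self}")


@dataclasses.dataclass(frozen=True)
class PairStatistics:
    """SCI/phi/t for one unordered pair."""

    pair: tuple[str, str]
    counts: ContingencyTable
    sci: float
    phi: float
    t: float


@dataclasses.dataclass(frozen=True)
class PairError:
    """A pair excluded from the screen, with the reason."""

    pair: tuple[str, str]
    counts: ContingencyTable
    reason: str


@dataclasses.dataclass
class CutoffResult:
    """Outcome of the SCI cut-off calibration (Steps 1-4)."""

    q: int
    e: int
    mean_cij: float
    sci_cutoff: float
    retained_pairs: list[PairStatistics]


@dataclasses.dataclass
class CountsResult:
    """Marginal and pairwise counts for one stratum."""

    n: int
    marginals: dict[str, int]
    pair_counts: dict[tuple[str, str], int]  # keys canonical (i < j), values > 0

    def contingency(self, pair: tuple[str, str]) -> ContingencyTable:
        i, j = sorted(pair)
        return ContingencyTable(
            n=self.n,
            c_i=self.marginals[i],
            c_j=self.marginals[j],
            c_ij=self.pair_counts.get((i, j), 0),
        )


def contingency_counts(
    condition_sets: Mapping[str, Iterable[str]] | pd.DataFrame,
    n_patients: int | None = None,
    pair_patients: Iterable[str] | None = None,
) -> CountsResult:
    """Exact marginal counts c_i and pair counts c_ij from per-patient sets.

    ``condition_sets`` is either a mapping patient -> set of codes or a long
    DataFrame with columns (patient_id, code). ``n_patients`` overrides N when
    the stratum contains patients with empty condition sets that are not in
    the input. ``pair_patients`` optionally restricts which patients
    contribute pairwise counts (the multimorbidity rule); marginals always
    come from all patients.
    """
    if isinstance(condition_sets, pd.DataFrame):
        df = condition_sets[["patient_id", "code"]].drop_duplicates()
    else:
        records = [
            (pid, code) for pid, codes in condition_sets.items() for code in sorted(set(codes))
        ]
        df = pd.DataFrame(records, columns=["patient_id", "code"])

    if n_patients is None:
        if isinstance(condition_sets, pd.DataFrame):
            n_patients = int(df["patient_id"].nunique())
        else:
            n_patients = len(condition_sets)
    if n_patients == 0:
        logger.warning("empty stratum: no patients to count")
        return CountsResult(n=0, marginals={}, pair_counts={})

    codes = np.sort(df["code"].unique())
    code_idx = {c: k for k, c in enumerate(codes)}
    pids = np.sort(df["patient_id"].unique())
    pid_idx = {p: k for k, p in enumerate(pids)}

    rows = df["patient_id"].map(pid_idx).to_numpy()
    cols = df["code"].map(code_idx).to_numpy()
    x = sp.csr_matrix(
        (np.ones(len(df), dtype=np.int64), (rows, cols)), shape=(len(pids), len(codes))
    )
    marginals = {c: int(v) for c, v in zip(codes, np.asarray(x.sum(axis=0)).ravel())}

    if pair_patients is not None:
        keep = np.array([p in set(pair_patients) for p in pids])
        xp = x[keep]
    else:
        xp = x
    co = sp.triu(xp.T @ xp, k=1).tocoo()
    pair_counts = {
        (codes[i], codes[j]): int(v) for i, j, v in zip(co.row, co.col, co.data) if v > 0
    }
    return CountsResult(n=int(n_patients), marginals=marginals, pair_counts=pair_counts)


def pair_statistics(
    counts: ContingencyTable, pair: tuple[str, str] = ("i", "j")
) -> PairStatistics | PairError:
    """Evaluate SCI, phi, and t for one pair; phi is undefined when a marginal
    equals N (zero variance), in which case a :class:`PairError` is returned."""
    return _stats_impl(tuple(sorted(pair)), counts.n, counts.c_i, counts.c_j, counts.c_ij, counts)


def _stats_impl(pair, n, ci, cj, cij, counts) -> PairStatistics | PairError:
    if ci == 0 or cj == 0:
        return PairError(pair=pair, counts=counts, reason="zero_marginal")
    sci = cij / math.sqrt(ci * cj)
    if ci == n or cj == n:
        return PairError(pair=pair, counts=counts, reason="phi_undefined_marginal_equals_n")
    phi = (cij * n - ci * cj) / math.sqrt(ci * cj * (n - ci) * (n - cj))
    if cij <= 2:
        t = 0.0  # t undefined below 3 co-occurrences; fails the screen
    elif abs(phi) >= 1.0:
        t = math.inf if phi > 0 else -math.inf
    else:
        t = phi * math.sqrt(cij - 2) / math.sqrt(1.0 - phi * phi)
    return PairStatistics(pair=pair, counts=counts, sci=sci, phi=phi, t=t)


def compute_pair_statistics(
    counts: CountsResult,
) -> tuple[list[PairStatistics], list[PairError]]:
    """SCI/phi/t for every pair with c_ij > 0, in canonical pair order."""
    stats: list[PairStatistics] = []
    errors: list[PairError] = []
    for (i, j) in sorted(counts.pair_counts):
        ct = counts.contingency((i, j))
        res = _stats_impl((i, j), ct.n, ct.c_i, ct.c_j, ct.c_ij, ct)
        if isinstance(res, PairError):
            errors.append(res)
        else:
            stats.append(res)
    if errors:
        logger.info("excluded %d pairs with undefined statistics", len(errors))
    return stats, errors


def determine_sci_cutoff(
    pair_stats: Iterable[PairStatistics],
    t_critical: float = T_CRITICAL_DEFAULT,
) -> CutoffResult:
    """Calibrate the SCI cut-off from the phi/t screen (Steps 1-4).

    q counts pairs with c_ij > 0; e counts pairs passing both t > t_critical
    and c_ij > mean(c_ij); the cut-off is the e-th largest SCI and every pair
    with SCI >= cut-off is retained (ties included). e == 0 yields an empty
    edge set with a warning, not an exception.
    """
    stats = [s for s in pair_stats if s.counts.c_ij > 0]
    q = len(stats)
    if q == 0:
        logger.warning("no pairs with positive co-occurrence; empty network")
        return CutoffResult(q=0, e=0, mean_cij=float("nan"), sci_cutoff=float("inf"), retained_pairs=[])
    mean_cij = sum(s.counts.c_ij for s in stats) / q
    e = sum(1 for s in stats if s.t > t_critical and s.counts.c_ij > mean_cij)
    if e == 0:
        logger.warning("no pairs pass the dual screen (t > %.2f, c_ij > mean); empty network", t_critical)
        return CutoffResult(q=q, e=0, mean_cij=mean_cij, sci_cutoff=float("inf"), retained_pairs=[])
    sci_sorted = sorted((s.sci for s in stats), reverse=True)
    sci_cutoff = sci_sorted[e - 1]
    retained = [s for s in stats if s.sci >= sci_cutoff]
    return CutoffResult(q=q, e=e, mean_cij=mean_cij, sci_cutoff=sci_cutoff, retained_pairs=retained)


def build_network(
    cutoff: CutoffResult,
    stratum_label: str = "global",
) -> nx.Graph:
    """Assemble the undirected SCI-weighted graph from the retained pairs.

    Nodes are endpoints of retained edges only (no isolated conditions);
    edge weight and attribute ``sci`` both carry the SCI value.
    """
    g = nx.Graph(stratum=stratum_label)
    for s in cutoff.retained_pairs:
        i, j = s.pair
        g.add_edge(i, j, weight=s.sci, sci=s.sci)
    return g


@dataclasses.dataclass
class StratumNetwork:
    """Everything computed for one stratum."""

    label: str
    n_patients: int
    counts: CountsResult
    stats: list[PairStatistics]
    errors: list[PairError]
    cutoff: CutoffResult
    graph: nx.Graph


def build_stratum_network(
    condition_sets: pd.DataFrame | Mapping[str, Iterable[str]],
    n_patients: int | None = None,
    label: str = "global",
    t_critical: float = T_CRITICAL_DEFAULT,
    pair_patients: Iterable[str] | None = None,
) -> StratumNetwork:
    """Run counts -> statistics -> cut-off -> graph for one patient stratum."""
    counts = contingency_counts(condition_sets, n_patients=n_patients, pair_patients=pair_patients)
    stats, errors = compute_pair_statistics(counts)
    cutoff = determine_sci_cutoff(stats, t_critical=t_critical)
    graph = build_network(cutoff, stratum_label=label)
    return StratumNetwork(
        label=label,
        n_patients=counts.n,
        counts=counts,
        stats=stats,
        errors=errors,
        cutoff=cutoff,
        graph=graph,
    )


def build_stratified_networks(
    cohort: pd.DataFrame,
    selection: ConditionSelection,
    t_critical: float = T_CRITICAL_DEFAULT,
    min_stratum_size: int = 30,
    include_global: bool = True,
    require_chronic_anchor: bool = True,
) -> dict[str, StratumNetwork]:
    """One network per non-empty (sex x age band) stratum plus per-sex globals.

    Counts, statistics, and the cut-off are computed *within* each stratum
    (stratum-internal N); the two global networks pool all ages within a sex.
    Strata below ``min_stratum_size`` patients are skipped with a warning.
    """
    sets = selection.condition_sets.merge(
        cohort[["patient_id", "sex", "age_stratum"]], on="patient_id", how="inner"
    )
    pair_ok = selection.pair_eligible if require_chronic_anchor else None
    out: dict[str, StratumNetwork] = {}

    for sex in ("male", "female"):
        in_sex = cohort[cohort["sex"] == sex]
        if include_global:
            label = f"{sex}_global"
            out[label] = build_stratum_network(
                sets.loc[sets["sex"] == sex, ["patient_id", "code"]],
                n_patients=len(in_sex),
                label=label,
                t_critical=t_critical,
                pair_patients=pair_ok,
            )
        for band in AGE_BANDS:
            stratum = in_sex[in_sex["age_stratum"] == band]
            if len(stratum) == 0:
                logger.warning("stratum %s/%s empty; skipped", sex, band)
                continue
            if len(stratum) < min_stratum_size:
                logger.warning(
                    "stratum %s/%s has %d patients (< %d); skipped",
                    sex, band, len(stratum), min_stratum_size,
                )
                continue
            label = f"{sex}_{band}"
            out[label] = build_stratum_network(
                sets.loc[(sets["sex"] == sex) & (sets["age_stratum"] == band), ["patient_id", "code"]],
                n_patients=len(stratum),
                label=label,
                t_critical=t_critical,
                pair_patients=pair_ok,
            )
    return out


def pair_stats_frame(sn: StratumNetwork) -> pd.DataFrame:
    """Tabulate a stratum's pair statistics for export."""
    retained = {s.pair for s in sn.cutoff.retained_pairs}
    rows = [
        {
            "code_i": s.pair[0],
            "code_j": s.pair[1],
            "c_i": s.counts.c_i,
            "c_j": s.counts.c_j,
            "c_ij": s.counts.c_ij,
            "n": s.counts.n,
            "sci": s.sci,
            "phi": s.phi,
            "t": s.t,
            "retained": s.pair in retained,
        }
        for s in sn.stats
    ]
    return pd.DataFrame(rows, columns=["code_i", "code_j", "c_i", "c_j", "c_ij", "n", "sci", "phi", "t", "retained"])
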