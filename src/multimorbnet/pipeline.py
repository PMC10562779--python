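"""End-to-end pipeline and network import/export.

Runs cohort construction -> stratified SCI networks -> metrics -> crucial
diseases -> perturbation -> temporal trends, writing every artifact plus a
run manifest, so a run is fully reproducible from its configuration and
master seed alone. All outputs are deterministic text (CSV/JSON/GraphML/GEXF).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .cohort import (
    ConditionCatalog,
    apply_eligibility,
    compute_index_and_age,
    load_records,
    select_conditions,
)
from .config import PipelineConfig
from .crucial import crucial_disease_report, temporal_degree_trends
from .metrics import node_metrics_frame, summarize_network
from .network import build_stratified_networks, pair_stats_frame
from .perturb import edge_removal_analysis, node_removal_analysis
from .synthetic import write_synthetic_dataset

logger = logging.getLogger("multimorbnet")

EXPORT_FORMATS = ("graphml", "gexf", "edgelist_csv")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def export_network(g: nx.Graph, path, fmt: str) -> None:
    """Write a network to GraphML, GEXF, or an edge-list CSV.

    The SCI weight is stored as edge attribute ``sci`` (and ``weight``); a
    round-trip import reproduces nodes, edges, and weights to full float
    precision.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
        # strip the volatile modification-date stamp for reproducible bytes
        text = path.read_text()
        path.write_text(re.sub(r'\s*lastmodifieddate="[^"]*"', "", text))
    elif fmt == "edgelist_csv":
        # repr() keeps the full shortest-round-trip float representation
        rows = [
            {"source": u, "target": v, "sci": repr(float(d.get("sci", d.get("weight"))))}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "sci"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: {list(EXPORT_FORMATS)}")


def import_network(path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gexf":
        return nx.read_gexf(path)
    if fmt == "edgelist_csv":
        df = pd.read_csv(path, float_precision="round_trip")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["sci"]), sci=float(row["sci"]))
        return g
    raise ValueError(f"unknown format {fmt!r}; supported: {list(EXPORT_FORMATS)}")


def _write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the full analysis; returns a name -> path map of artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("simulate")
        if config.synthetic is not None:
            paths = write_synthetic_dataset(out / "synthetic", config.synthetic)
            config = dataclasses.replace(
                config,
                events_path=paths["events"],
                patients_path=paths["patients"],
                catalog_path=paths["catalog"],
            )
            artifacts.update({f"synthetic_{k}": v for k, v in paths.items()})
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("simulate", exc) from exc

    try:
        _stage("cohort")
        events, patients, catalog = load_records(
            config.events_path, config.patients_path, config.catalog_path
        )
        eligible, excl1 = apply_eligibility(
            events, patients, exempt_partial_years=config.exempt_partial_years
        )
        cohort, excl2 = compute_index_and_age(
            events[events["patient_id"].isin(eligible["patient_id"])],
            eligible,
            config.t2dm_codes,
        )
        selection = select_conditions(
            events,
            cohort,
            catalog,
            min_prevalence=config.min_prevalence,
            require_chronic_anchor=config.require_chronic_anchor,
        )
        cohort_out = cohort.assign(
            index_date=cohort["index_date"].dt.strftime("%Y-%m-%d"),
            last_visit_date=cohort["last_visit_date"].dt.strftime("%Y-%m-%d"),
            birth_date=cohort["birth_date"].dt.strftime("%Y-%m-%d"),
        )
        cohort_out.to_csv(out / "cohort.csv", index=False)
        selection.condition_sets.to_csv(out / "condition_sets.csv", index=False)
        exclusions = pd.concat([excl1, excl2], ignore_index=True)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        artifacts["cohort"] = str(out / "cohort.csv")
        artifacts["condition_sets"] = str(out / "condition_sets.csv")
        artifacts["exclusions"] = str(out / "exclusions.csv")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("cohort", exc) from exc

    try:
        _stage("networks")
        stratified = build_stratified_networks(
            cohort,
            selection,
            t_critical=config.t_critical,
            min_stratum_size=config.min_stratum_size,
            require_chronic_anchor=config.require_chronic_anchor,
        )
        summaries = {}
        for label, sn in stratified.items():
            pair_stats_frame(sn).to_csv(out / f"pair_stats_{label}.csv", index=False)
            _write_json(
                out / f"cutoff_{label}.json",
                {
                    "q": sn.cutoff.q,
                    "e": sn.cutoff.e,
                    "mean_cij": sn.cutoff.mean_cij,
                    "sci_cutoff": sn.cutoff.sci_cutoff,
                    "n_retained": len(sn.cutoff.retained_pairs),
                    "n_patients": sn.n_patients,
                },
            )
            for fmt, suffix in (("graphml", ".graphml"), ("gexf", ".gexf"), ("edgelist_csv", ".edges.csv")):
                export_network(sn.graph, out / f"network_{label}{suffix}", fmt)
            node_metrics_frame(sn.graph).to_csv(out / f"node_metrics_{label}.csv", index=False)
            summaries[label] = summarize_network(sn.graph).to_dict()
        _write_json(out / "network_summaries.json", summaries)
        artifacts["network_summaries"] = str(out / "network_summaries.json")
    except Exception as exc:
        raise PipelineStageError("networks", exc) from exc

    try:
        _stage("crucial")
        reports = {}
        for sex in ("male", "female"):
            if f"{sex}_global" not in stratified:
                logger.warning("no global network for %s; skipping crucial diseases", sex)
                continue
            rep = crucial_disease_report(
                stratified,
                sex,
                k=config.top_k_hubs,
                damping=config.pagerank_damping,
                burst_threshold=config.burst_threshold,
                louvain_seed=config.seed,
                louvain_restarts=config.louvain_restarts,
                louvain_resolution=config.louvain_resolution,
            )
            reports[sex] = rep
            rep.degree_trajectories.to_csv(out / f"degree_trajectories_{sex}.csv")
            comm = pd.DataFrame(
                {
                    "code": sorted(rep.communities.partition),
                    "community": [
                        rep.communities.partition[c] for c in sorted(rep.communities.partition)
                    ],
                }
            )
            comm["is_root"] = comm["code"].isin(set(rep.roots.values()))
            comm.to_csv(out / f"communities_{sex}.csv", index=False)
        _write_json(
            out / "crucial_report.json", {sex: rep.to_dict() for sex, rep in reports.items()}
        )
        artifacts["crucial_report"] = str(out / "crucial_report.json")
    except Exception as exc:
        raise PipelineStageError("crucial", exc) from exc

    try:
        _stage("perturbation")
        perturb_rows = []
        overlap_rows = []
        for sex, rep in reports.items():
            g = stratified[f"{sex}_global"].graph
            crucial_codes = sorted(
                {c for c, _ in rep.hubs} | set(rep.roots.values()) | {b.code for b in rep.bursts}
            )
            crucial_codes = [c for c in crucial_codes if c in g]
            for res in node_removal_analysis(g, crucial_codes):
                row = {"sex": sex, "removed_code": res.removed_code, "error": res.error}
                row.update({f"pct_{k}": v for k, v in res.pct_change.items()})
                perturb_rows.append(row)
            for res in edge_removal_analysis(
                g,
                levels=config.perturb_levels,
                reps=config.perturb_reps,
                k=config.top_k_hubs,
                seed=config.seed,
                damping=config.pagerank_damping,
            ):
                overlap_rows.append(
                    {
                        "sex": sex,
                        "level": res.level,
                        "rep": res.rep,
                        "n_removed": res.n_removed,
                        "overlap_count": res.overlap_count,
                    }
                )
        pd.DataFrame(perturb_rows).to_csv(out / "node_removal.csv", index=False)
        pd.DataFrame(overlap_rows).to_csv(out / "edge_removal.csv", index=False)
        artifacts["node_removal"] = str(out / "node_removal.csv")
        artifacts["edge_removal"] = str(out / "edge_removal.csv")
    except Exception as exc:
        raise PipelineStageError("perturbation", exc) from exc

    try:
        _stage("temporal")
        shared: set[str] = set()
        if len(reports) == 2:
            per_sex = [
                {c for c, _ in rep.hubs} | set(rep.roots.values()) | {b.code for b in rep.bursts}
                for rep in reports.values()
            ]
            shared = per_sex[0] & per_sex[1]
        for sex in reports:
            sub = cohort[cohort["sex"] == sex]
            trends = temporal_degree_trends(
                events,
                sub,
                catalog,
                disease_set=shared or {c for c, _ in reports[sex].hubs},
                universe=selection.universe,
                start_year=config.temporal_start_year,
                baseline_year=config.temporal_baseline_year,
                end_year=config.temporal_end_year,
                t_critical=config.t_critical,
            )
            trends.to_csv(out / f"temporal_degrees_{sex}.csv")
            artifacts[f"temporal_degrees_{sex}"] = str(out / f"temporal_degrees_{sex}.csv")
    except Exception as exc:
        raise PipelineStageError("temporal", exc) from exc

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "artifacts": sorted(artifacts),
    }
    _write_json(out / "manifest.json", manifest)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
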