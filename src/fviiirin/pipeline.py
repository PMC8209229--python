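"""End-to-end orchestration: structure -> RIN -> centralities -> criticality
-> optional binding-interface, classifier and clinical-association stages.

A single :class:`PipelineConfig` drives the run; every stage writes its
table under the output directory and the run report records versions, a
config hash, seeds and per-stage row counts, so identical config + seed
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from . import __version__
from .classifier import (DEFAULT_FLAG_BAND, DEFAULT_FOLDS, build_feature_table,
                         evaluate, median_prediction_frame, read_mutant_csv,
                         train_members)
from .clinical import fisher_association, sanitize_records
from .criticality import criticality_table, domain_closeness_summary
from .interface import comparison_report, neighborhood, read_binding_sites
from .metrics import CENTRALITY_MEASURES, compute_centralities, measure_correlations
from .rin import DEFAULT_CUTOFF, build_rin
from .structure import (DEFAULT_PROBE_RADIUS, DEFAULT_SPHERE_POINTS,
                        compute_surface_area, load_reference_areas,
                        load_structure, relative_exposure)
from .synthetic import GeneratorSpec, generate_structure

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("graphml", "edge_tsv", "node_csv")


@dataclass
class PipelineConfig:
    """Everything a run needs; unset optional stages are skipped."""

    structure_path: Optional[str] = None
    generator: Optional[GeneratorSpec] = None
    chains: Optional[List[str]] = None
    cutoff: float = DEFAULT_CUTOFF
    probe_radius: float = DEFAULT_PROBE_RADIUS
    sphere_points: int = DEFAULT_SPHERE_POINTS
    reference_area_file: Optional[str] = None
    degree_high: float = 0.90
    betweenness_high: float = 0.90
    degree_low: float = 0.50
    betweenness_low: float = 0.50
    seed: int = 0
    folds: int = DEFAULT_FOLDS
    flag_band: Tuple[float, float] = DEFAULT_FLAG_BAND
    features: Optional[List[str]] = None
    full_grid: bool = False
    mutant_table: Optional[str] = None
    clinical_table: Optional[str] = None
    binding_sites: Optional[str] = None
    output_dir: str = "fviii_rin_out"

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _residue_index_to_label(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out.insert(0, "residue", [k.label() if hasattr(k, "label") else str(k)
                              for k in df.index])
    return out.reset_index(drop=True)


def export_network(g: nx.Graph, t: Optional[pd.DataFrame], fmt: str,
                   path: str | Path) -> Path:
    """Write the network as GraphML, an edge TSV, or a node-attribute CSV."""
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {EXPORT_FORMATS}")
    path = Path(path)
    if fmt == "graphml":
        h = nx.relabel_nodes(g, {n: n.label() if hasattr(n, "label") else str(n)
                                 for n in g.nodes})
        for _, _, data in h.edges(data=True):
            if isinstance(data.get("interaction_classes"), list):
                data["interaction_classes"] = ",".join(data["interaction_classes"])
        h.graph.pop("provenance", None)
        nx.write_graphml(h, path)
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tinteraction_classes\n")
            for a, b, data in g.edges(data=True):
                la = a.label() if hasattr(a, "label") else str(a)
                lb = b.label() if hasattr(b, "label") else str(b)
                classes = ",".join(data.get("interaction_classes", []))
                fh.write(f"{la}\t{lb}\t{classes}\n")
    else:  # node_csv
        if t is None:
            raise ValueError("node_csv export needs a centrality table")
        _residue_index_to_label(t).to_csv(path, index=False)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash, "version": __version__,
                    "seed": cfg.seed, "stages": {}}
    current = "setup"
    try:
        # -- structure
        current = "structure"
        if cfg.generator is not None:
            s, _ = generate_structure(cfg.generator, path=out / "structure.pdb")
        elif cfg.structure_path:
            s = load_structure(cfg.structure_path, chains=cfg.chains)
        else:
            raise ValueError("config needs structure_path or generator")
        areas = compute_surface_area(s, probe_radius=cfg.probe_radius,
                                     sphere_points=cfg.sphere_points)
        rel = relative_exposure(areas,
                                load_reference_areas(cfg.reference_area_file))
        report["stages"]["structure"] = {"n_residues": len(s)}

        # -- network
        current = "rin"
        g = build_rin(s, cutoff=cfg.cutoff)
        report["stages"]["rin"] = {"n_nodes": g.number_of_nodes(),
                                   "n_edges": g.number_of_edges()}
        export_network(g, None, "graphml", out / "network.graphml")
        export_network(g, None, "edge_tsv", out / "edges.tsv")

        # -- centralities
        current = "centrality"
        t = compute_centralities(g, relative_exposure=rel,
                                 domain_map=s.domain_map)
        corr = measure_correlations(t)
        _residue_index_to_label(t).to_csv(out / "centrality.csv", index=False)
        corr.to_csv(out / "measure_correlations.csv")
        report["stages"]["centrality"] = {"n_rows": len(t)}

        # -- criticality
        current = "criticality"
        crit = criticality_table(
            t, degree_high=cfg.degree_high, betweenness_high=cfg.betweenness_high,
            degree_low=cfg.degree_low, betweenness_low=cfg.betweenness_low)
        _residue_index_to_label(crit).to_csv(out / "criticality.csv", index=False)
        full = t.join(crit)
        export_network(g, full, "node_csv", out / "nodes.csv")
        report["stages"]["criticality"] = {
            "n_pareto": int(crit["pareto_front"].sum()),
            "groups": crit["group"].value_counts().to_dict()}
        if "domain" in t.columns:
            domain_closeness_summary(t).to_csv(out / "domain_closeness.csv",
                                               index=False)

        # -- binding interface (optional)
        if cfg.binding_sites:
            current = "interface"
            resolve = {(k.chain_id, k.seq_number): k for k in s.residues}
            sites = read_binding_sites(cfg.binding_sites, resolve=resolve)
            site_union = set().union(*(b.residues for b in sites))
            neigh = neighborhood(g, set(site_union))
            rep = comparison_report(t, site_union, neigh,
                                    measures=["degree", "betweenness",
                                              "closeness"])
            rep.to_csv(out / "binding_site_comparison.csv", index=False)
            report["stages"]["interface"] = {"n_sites": len(site_union),
                                             "n_neighbors": len(neigh)}

        # -- classifier (optional)
        if cfg.mutant_table:
            current = "classifier"
            mutants = read_mutant_csv(cfg.mutant_table)
            features = cfg.features or CENTRALITY_MEASURES
            resolve = {(k.chain_id, k.seq_number): k for k in s.residues}
            from dataclasses import replace as _replace
            remapped = []
            for m in mutants:
                key = resolve.get((m.residue_key.chain_id,
                                   m.residue_key.seq_number))
                remapped.append(_replace(m, residue_key=key) if key else m)
            ft = build_feature_table(t, remapped, features)
            ens = train_members(ft, folds=cfg.folds, seed=cfg.seed,
                                full_grid=cfg.full_grid)
            preds = median_prediction_frame(ens.oof_probabilities,
                                            flag_band=cfg.flag_band)
            metrics = evaluate(preds["median_probability"], preds["flagged"],
                               ft.y)
            pd.concat([ens.oof_probabilities, preds], axis=1).pipe(
                _residue_index_to_label).to_csv(out / "predictions.csv",
                                                index=False)
            (out / "classifier_metrics.json").write_text(json.dumps({
                "metrics": metrics, "chosen_params": ens.chosen_params,
                "seed": cfg.seed,
                "fold_metrics": ens.fold_metrics.to_dict("records"),
            }, indent=2, default=float))
            report["stages"]["classifier"] = {"n_instances": len(ft),
                                              **{k: v for k, v in metrics.items()
                                                 if v is not None}}

        # -- clinical association (optional)
        if cfg.clinical_table:
            current = "clinical"
            raw = pd.read_csv(cfg.clinical_table)
            clean, log = sanitize_records(raw)
            clean.to_csv(out / "clinical_sanitized.csv")
            log.to_csv(out / "clinical_exclusion_log.csv", index=False)
            report["stages"]["clinical"] = {
                "n_raw": len(raw), "n_clean": len(clean),
                "n_excluded": int((log["action"] == "excluded").sum())}

        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "FAILED"
        report["failed_stage"] = current
        report["error"] = str(exc)
        (out / "FAILED").write_text(f"stage {current}: {exc}\n")
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=str))
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    logger.info("pipeline complete: %s", report["stages"].keys())
    return report
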