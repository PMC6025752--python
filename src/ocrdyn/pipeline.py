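"""End-to-end orchestration: simulate -> dynamics -> concordance ->
footprints -> TF networks (-> enrichment), with a machine-readable
summary and a run manifest.

One global seed is fanned out to per-step child seeds (seed + step
index, handled inside the simulator), so each module run is
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .concordance import (
    assign_promoter_peak,
    concordance_test,
    fold_change,
    stagewise_correlation,
)
from .dynamics import run_dynamics
from .enrich import enrichment_table, hypergeometric_enrichment
from .footprints import aggregate_tag_density, call_footprints
from .networks import (
    Edge,
    assign_targets,
    build_network,
    detect_autoregulation,
    lag_test,
    master_nodes,
    most_connected_component,
    specificity_table,
    stage_specificity_test,
)
from .simulate import SimulationConfig, run_simulation, write_simulation

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    steps: List[Dict] = field(default_factory=list)
    paths: Dict[str, str] = field(default_factory=dict)

    def record(self, step: str, status: str, seconds: float) -> None:
        self.steps.append(
            {"step": step, "status": status, "wall_time_s": round(seconds, 3)}
        )

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "steps": self.steps,
            "paths": self.paths,
        }


class PipelineError(RuntimeError):
    pass


def run_all(config_path, outdir, gmt_path=None) -> Dict:
    """Run the whole pipeline from a YAML config; returns the summary.

    Writes ``summary.json`` and ``manifest.json`` (plus every per-step
    artifact) under ``outdir``.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(f"config not found: {config_path}")
    raw = config_path.read_bytes()
    config = SimulationConfig.from_dict(gio.read_yaml(config_path))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(raw).hexdigest(),
        seed=config.seed,
        version=__version__,
    )
    summary = run_pipeline(config, outdir=outdir, manifest=manifest, gmt_path=gmt_path)
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest.paths["summary"] = str(summary_path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2) + "\n"
    )
    return summary


def run_pipeline(
    config: SimulationConfig,
    outdir: Optional[Path] = None,
    manifest: Optional[RunManifest] = None,
    gmt_path=None,
) -> Dict:
    """Library entry point: run every stage on a fresh simulation."""
    manifest = manifest or RunManifest(config_hash="", seed=config.seed, version=__version__)
    summary: Dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": list(config.stages),
    }
    stages = list(config.stages)

    def step(name):
        def wrap(fn):
            t0 = time.monotonic()
            logger.info("step %s ...", name)
            try:
                fn()
            except Exception:
                manifest.record(name, "failed", time.monotonic() - t0)
                raise
            manifest.record(name, "ok", time.monotonic() - t0)

        return wrap

    state: Dict = {}

    @step("simulate")
    def _simulate():
        sim = run_simulation(config)
        state["sim"] = sim
        if outdir is not None:
            manifest.paths.update(write_simulation(sim, Path(outdir) / "sim"))

    sim = state["sim"]

    @step("dynamics")
    def _dynamics():
        dyn = run_dynamics(sim.counts, stages=stages)
        state["dyn"] = dyn
        if outdir is not None:
            path = Path(outdir) / "dynamics.tsv"
            dyn.to_csv(path, sep="\t", index_label="peak_id")
            manifest.paths["dynamics"] = str(path)
        counts = dyn["dynamic_class"].value_counts().to_dict()
        summary["dynamic_class_counts"] = {k: int(v) for k, v in sorted(counts.items())}

    @step("concordance")
    def _concordance():
        gene_peak = assign_promoter_peak(sim.peaks, sim.genes)
        from .simulate import promoter_openness

        openness = promoter_openness(sim.counts, gene_peak, stages)
        pearson = {}
        for stage in stages:
            res = stagewise_correlation(
                sim.expression[stage].to_dict(), openness[stage].to_dict()
            )
            pearson[stage] = {"r": res.pearson_r, "p": res.pearson_p, "n": res.n_genes}
        summary["promoter_expression_pearson"] = pearson
        first, last = stages[0], stages[-1]
        shared = sorted(set(openness.index) & set(sim.expression.index))
        fc_expr = {
            g: fold_change(sim.expression.loc[g, last], sim.expression.loc[g, first])
            for g in shared
        }
        fc_ocr = {
            g: fold_change(openness.loc[g, last], openness.loc[g, first]) for g in shared
        }
        table, fisher_p, n_sel = concordance_test(fc_expr, fc_ocr)
        summary["concordance"] = {
            "contrast": f"{last}/{first}",
            "table": table.cells.tolist(),
            "fisher_p": None if np.isnan(fisher_p) else fisher_p,
            "n_selected": n_sel,
        }

    @step("footprints")
    def _footprints():
        fps = call_footprints(sim.genome, sim.coverage, sim.pwms)
        state["fps"] = fps
        tf_names = sorted({tf for tf, _ in fps})
        counts = pd.DataFrame(
            {s: [len(fps[(tf, s)]) for tf in tf_names] for s in stages}, index=tf_names
        )
        state["fp_counts"] = counts
        if outdir is not None:
            path = Path(outdir) / "footprints.bed"
            _write_footprints_bed(path, fps)
            manifest.paths["footprints"] = str(path)
        summary["footprint_counts"] = {
            s: int(counts[s].sum()) for s in stages
        }

    @step("tf_networks")
    def _networks():
        counts = state["fp_counts"]
        fps = state["fps"]
        totals = {s: max(1, int(counts[s].sum())) for s in stages}
        profiles = stage_specificity_test(counts, totals)
        state["profiles"] = profiles
        by_class: Dict[str, int] = {}
        for p in profiles:
            by_class[p.classification] = by_class.get(p.classification, 0) + 1
        summary["tf_specificity_counts"] = dict(sorted(by_class.items()))
        if outdir is not None:
            path = Path(outdir) / "tf_specificity.tsv"
            specificity_table(profiles).to_csv(path, sep="\t", index=False)
            manifest.paths["tf_specificity"] = str(path)

        last = stages[-1]
        lag_tfs = [
            p.tf_name
            for p in profiles
            if p.classification == f"{last}-specific" and p.tf_name in sim.expression.index
        ]
        if lag_tfs:
            lag = lag_test(sim.expression, counts, lag_tfs, stages)
            summary["lag_test"] = {"k": lag.k, "n": lag.n, "p": lag.p_value}
        else:
            summary["lag_test"] = {"k": 0, "n": 0, "p": None}

        all_fps = [fp for fp_list in fps.values() for fp in fp_list]
        edges = assign_targets(all_fps, sim.genes)
        net = build_network(edges, profiles, sim.expression, last, stages[0])
        comp = most_connected_component(net)
        masters = master_nodes(comp)
        summary["network"] = {
            "stage": last,
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "component_nodes": comp.number_of_nodes(),
            "master_nodes": masters,
        }
        genes_by_id = {g.gene_id: g for g in sim.genes}
        auto = {}
        for pwm in sim.pwms:
            flag, dist = detect_autoregulation(pwm.tf_name, edges, genes_by_id)
            if flag:
                auto[pwm.tf_name] = dist
        summary["autoregulation"] = auto
        if outdir is not None:
            gpath = Path(outdir) / f"network_{last}.graphml"
            gio.write_graphml(gpath, net)
            manifest.paths["network"] = str(gpath)
            epath = Path(outdir) / f"network_{last}_edges.tsv"
            gio.write_edge_tsv(epath, net)
            manifest.paths["network_edges"] = str(epath)

    if gmt_path is not None:

        @step("enrichment")
        def _enrich():
            sets = gio.read_gmt(gmt_path)
            universe = [g.gene_id for g in sim.genes]
            last = stages[-1]
            net_targets = [
                t for (tf, t) in {(e.tf, e.gene) for e in assign_targets(
                    [fp for fpl in state["fps"].values() for fp in fpl], sim.genes
                )}
                if t in set(universe)
            ]
            results = hypergeometric_enrichment(sorted(set(net_targets)), sets, universe)
            summary["enrichment"] = [
                {"set": r.set_name, "overlap": r.overlap, "fold": r.fold_enrichment,
                 "p": r.p, "q": r.q}
                for r in results
            ]
            if outdir is not None:
                path = Path(outdir) / "enrichment.tsv"
                enrichment_table(results).to_csv(path, sep="\t", index=False)
                manifest.paths["enrichment"] = str(path)

    return summary


def _write_footprints_bed(path, fps) -> None:
    """Footprints as BED6+ (name=TF, score=purity*1000, extra columns
    stage, purity)."""
    rows = []
    for (tf, stage), fp_list in sorted(fps.items()):
        for fp in fp_list:
            iv = fp.hit.interval
            rows.append(
                (iv.chrom, iv.start, iv.end, tf, int(round(fp.purity * 1000)),
                 iv.strand, stage, f"{fp.purity:.4f}")
            )
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
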