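"""End-to-end orchestration: simulate -> coverage -> SV -> core genes -> methylation.

Runs each stage with configured thresholds, isolates stage failures, and
writes machine-readable summaries plus a provenance record sufficient to
reproduce the run. All outputs are plain text and byte-deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from panelgraph import coverage as cov
from panelgraph import core_genes as cg
from panelgraph import meth_diff as md
from panelgraph import sv_graph as svg
from panelgraph import synthetic_data as sd
from panelgraph.graph_model import graph_stats, parse_rgfa, write_rgfa, export_segments_bed

log = logging.getLogger("panelgraph")

__all__ = ["RunConfig", "run_all", "load_run_config"]


@dataclass
class RunConfig:
    """All thresholds and paths for one pipeline run (fully serialised to provenance)."""

    out_dir: str = "panelgraph_run"
    seed: int = 0
    theta: float = 0.05
    theta_table: float = 0.10
    alt_min_length: int = 10_000
    alt_min_divergence: float = 0.5
    alt_dna_min_samples: int = 2
    alt_dna_depth_frac: float = 0.5
    alt_rna_min_samples: int = 8
    alt_rna_depth_frac: float = 0.1
    del_min_span: int = 10_000
    del_support_frac: float = 0.5
    del_min_samples: int | None = None
    alpha: float = 0.01
    meth_min_reads: int = 5
    meth_min_sites: int = 3
    meth_min_samples: int = 4
    pli_eps: float = 1e-16
    merge_reciprocal: float = 0.8
    merge_max_shift: int = 1_000
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    meth_sim: dict = field(default_factory=dict)  # MethSimConfig overrides


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the summary dict also written to summary.json.

    A stage that raises is recorded as failed in the summary (with the
    error) and later stages that do not depend on it still run; outputs of
    completed stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "counts": {}}
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("graph", _stage_graph),
        ("coverage", _stage_coverage),
        ("sv_graph", _stage_sv),
        ("core_genes", _stage_core_genes),
        ("methylation", _stage_meth),
    ]
    for name, fn in stages:
        try:
            fn(cfg, out, state, summary)
            summary["stages"][name] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log.error("stage %s failed: %s", name, exc)
            summary["stages"][name] = f"failed: {exc}"
            (out / f"{name}.error.log").write_text(traceback.format_exc())

    provenance = {"config": asdict(cfg), "version": __import__("panelgraph").__version__}
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    sim_cfg = sd.SimConfig(seed=cfg.seed, **cfg.sim)
    sim = sd.simulate_graph(sim_cfg)
    write_rgfa(sim.graph, out / "graph.gfa")
    sd.write_gff3(sim.genes, out / "genes.gff3")
    dna, rna = sd.simulate_gaf_lines(sim)
    gaf_dir = out / "gaf"
    gaf_dir.mkdir(exist_ok=True)
    for sample, lines in dna.items():
        (gaf_dir / f"{sample}.dna.gaf").write_text("\n".join(lines) + "\n")
    for sample, lines in rna.items():
        (gaf_dir / f"{sample}.rna.gaf").write_text("\n".join(lines) + "\n")
    div = pd.DataFrame(
        sorted(sim.divergences.items()), columns=["segment", "divergence"]
    )
    _write_tsv(div, out / "divergences.tsv")
    sd.write_truth_json(sim.truth_json(), out / "truth.json")
    state["sim"] = sim
    state["sim_cfg"] = sim_cfg
    summary["counts"]["planted_alt_paths"] = sum(
        1 for t in sim.alt_truth if t["qualifying"]
    )
    summary["counts"]["planted_deletions"] = sum(
        1 for t in sim.del_truth if t["qualifying"]
    )


def _stage_graph(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    g = parse_rgfa(out / "graph.gfa", sd.DEFAULT_PREFIX_MAP)
    state["graph"] = g
    stats = graph_stats(g)
    _write_tsv(stats, out / "graph_stats.tsv")
    bed = export_segments_bed(g)
    _write_tsv(bed, out / "ref_segments.bed")
    summary["counts"]["segments"] = len(g.segments)
    summary["counts"]["links"] = len(g.links)


def _stage_coverage(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    g = state["graph"]
    sim_cfg: sd.SimConfig = state["sim_cfg"]
    dna_profiles, rna_profiles = [], []
    for sample in sim_cfg.samples:
        recs = cov.parse_gaf(out / "gaf" / f"{sample}.dna.gaf")
        dna_profiles.append(cov.compute_profile(recs, g, sample, "DNA"))
    for sample in sim_cfg.rna_samples:
        recs = cov.parse_gaf(out / "gaf" / f"{sample}.rna.gaf")
        rna_profiles.append(cov.compute_profile(recs, g, sample, "RNA"))
    state["dna_profiles"] = dna_profiles
    state["rna_profiles"] = rna_profiles

    usage = cov.usage_matrix(dna_profiles, g, cfg.theta)
    state["usage"] = usage
    _write_tsv(usage, out / f"usage_theta{cfg.theta:g}.tsv", index=True)
    fracs = pd.DataFrame(
        [
            {"sample": p.sample, **{c.value: f for c, f in cov.origin_fractions(p, g).items()}}
            for p in dna_profiles
        ]
    ).fillna(0.0)
    _write_tsv(fracs, out / "origin_fractions.tsv")
    xu = cov.cross_usage(dna_profiles, g, cfg.theta)
    _write_tsv(xu, out / "cross_usage.tsv", index=True)
    depth_rows = []
    for p in dna_profiles:
        for sid in sorted(p.depth):
            depth_rows.append({"sample": p.sample, "segment": sid, "depth": p.depth[sid]})
    _write_tsv(pd.DataFrame(depth_rows), out / "segment_depth.tsv")
    summary["counts"]["dna_samples"] = len(dna_profiles)
    summary["counts"]["rna_samples"] = len(rna_profiles)


def _stage_sv(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    g = state["graph"]
    sim: sd.GraphSim = state["sim"]
    candidates, truncated = svg.enumerate_alt_paths(g)
    alt_params = svg.AltPathParams(
        min_length=cfg.alt_min_length,
        min_divergence=cfg.alt_min_divergence,
        dna_min_samples=cfg.alt_dna_min_samples,
        dna_depth_frac=cfg.alt_dna_depth_frac,
        rna_min_samples=cfg.alt_rna_min_samples,
        rna_depth_frac=cfg.alt_rna_depth_frac,
    )
    alt_calls = svg.call_alt_paths(
        candidates,
        sim.divergences,
        state["dna_profiles"],
        state["rna_profiles"],
        sim.genes,
        g,
        alt_params,
    )
    del_params = svg.DeletionParams(
        min_span=cfg.del_min_span,
        support_frac=cfg.del_support_frac,
        min_samples=cfg.del_min_samples,
    )
    del_calls = svg.call_deletions(g, state["dna_profiles"], sim.genes, del_params)
    relaxed = svg.relaxed_deletion_scan(
        g, state["dna_profiles"], sim.genes, del_params
    )
    alt_df = pd.DataFrame(
        [
            {
                "stable_name": c.stable_name,
                "ref_start": c.ref_span[0],
                "ref_end": c.ref_span[1],
                "left_anchor": c.left_anchor,
                "right_anchor": c.right_anchor,
                "members": ",".join(c.members),
                "cumulative_length": c.cumulative_length,
                "max_divergence": c.max_divergence,
                "dna_support": c.dna_support,
                "rna_support": c.rna_support,
                "exons_overlapped": c.exons_overlapped,
            }
            for c in alt_calls
        ]
    )
    _write_tsv(alt_df, out / "alt_paths.tsv")

    def del_df(calls):
        return pd.DataFrame(
            [
                {
                    "stable_name": c.stable_name,
                    "start": c.start,
                    "end": c.end,
                    "span": c.span,
                    "upstream": c.upstream,
                    "downstream": c.downstream,
                    "support": c.support,
                    "exons_skipped": c.exons_skipped,
                }
                for c in calls
            ]
        )

    _write_tsv(del_df(del_calls), out / "deletions.tsv")
    _write_tsv(del_df(relaxed), out / "deletions_relaxed.tsv")
    summary["counts"]["alt_path_candidates"] = len(candidates)
    summary["counts"]["alt_path_calls"] = len(alt_calls)
    summary["counts"]["deletion_calls"] = len(del_calls)
    summary["counts"]["relaxed_deletion_calls"] = len(relaxed)
    summary["counts"]["enumeration_truncated"] = bool(truncated)


def _stage_core_genes(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    g = state["graph"]
    genes = cg.load_annotation(out / "genes.gff3")
    core = cg.core_segments(state["usage"])
    statuses = cg.classify_genes(genes, core, g)
    df = pd.DataFrame(
        [
            {"gene_id": s.gene_id, "covered_fraction": s.covered_fraction, "class": s.status}
            for s in statuses
        ]
    )
    _write_tsv(df, out / "gene_classes.tsv")
    summary["counts"]["core_gene_summary"] = cg.panel_summary(statuses)


def _stage_meth(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    meth_cfg = sd.MethSimConfig(seed=cfg.seed + 7, **cfg.meth_sim)
    calls, islands, genes, truth = sd.simulate_meth(meth_cfg)
    calls.to_csv(out / "meth_calls.tsv", sep="\t", index=False, float_format="%.6g")
    sd.write_bed(islands, out / "islands.bed")
    sd.write_truth_json(truth, out / "meth_truth.json")
    sites = md.aggregate_sites(calls, min_reads=cfg.meth_min_reads)
    tests = md.test_islands(
        islands, sites, min_sites=cfg.meth_min_sites, min_samples=cfg.meth_min_samples
    )
    md.apply_fdr(tests, alpha=cfg.alpha)
    table, matrix = md.dmr_report(tests, alpha=cfg.alpha)
    _write_tsv(table, out / "dmr_significant.tsv")
    _write_tsv(matrix, out / "dmr_matrix.tsv", index=True)
    tss = md.tss_distance_summary(tests, genes)
    _write_tsv(tss, out / "tss_distances.tsv")
    summary["counts"]["islands_tested"] = sum(1 for t in tests if t.tested)
    summary["counts"]["dmr_significant"] = len(table)
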