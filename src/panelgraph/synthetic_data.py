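"""Synthetic inputs with recorded ground truth for every pipeline stage.

Generates an rGFA backbone with planted divergent alternative paths and
deletion links, per-sample DNA/RNA GAF alignments at Poisson depth, GFF3
annotation, repeat/island BEDs, pLI tables, per-sample SV call sets and
per-read CpG LLR tables drawn from a two-component mixture. Every output is
a deterministic function of the seed; decoy events are labelled with the
single criterion they violate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from panelgraph.core_genes import GeneModel
from panelgraph.graph_model import (
    OriginClass,
    PanGraph,
    Segment,
    canonical_link,
    segment_identity,
)
from panelgraph.sv_annotation import SvRecord

__all__ = [
    "EventSpec",
    "SimConfig",
    "MethSimConfig",
    "SvSimConfig",
    "GraphSim",
    "DEFAULT_PREFIX_MAP",
    "simulate_graph",
    "simulate_gaf_lines",
    "mutate_to_divergence",
    "simulate_core_gene_panel",
    "simulate_svs",
    "simulate_meth",
    "simulate_null_meth",
    "write_gff3",
    "write_bed",
    "write_truth_json",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_PREFIX_MAP = {
    "refA": OriginClass.REF_PRIMARY,
    "refB": OriginClass.REF_ALT_1,
    "refC": OriginClass.REF_ALT_2,
    "panel": OriginClass.PANEL,
}

ALT_VIOLATIONS = ("length", "divergence", "dna", "rna", "exon")
DEL_VIOLATIONS = ("span", "support", "exon")


@dataclass(frozen=True)
class EventSpec:
    kind: str  # "alt" | "deletion"
    violation: str | None = None  # None => qualifying

    def __post_init__(self) -> None:
        if self.kind not in ("alt", "deletion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        allowed = ALT_VIOLATIONS if self.kind == "alt" else DEL_VIOLATIONS
        if self.violation is not None and self.violation not in allowed:
            raise ValueError(f"{self.kind} event cannot violate {self.violation!r}")


def _default_events() -> tuple[EventSpec, ...]:
    return (
        EventSpec("alt"),
        EventSpec("alt"),
        EventSpec("alt"),
        EventSpec("deletion"),
        EventSpec("deletion"),
        EventSpec("deletion"),
        EventSpec("alt", "length"),
        EventSpec("alt", "divergence"),
        EventSpec("deletion", "span"),
        EventSpec("deletion", "exon"),
    )


@dataclass
class SimConfig:
    """Shape parameters for the graph/alignment simulation.

    Defaults mirror the panel design the pipeline targets: 12 DNA samples at
    ~20x depth with 3 sibling pairs, long-read lengths around 7 kb.
    """

    seed: int = 0
    n_samples: int = 12
    n_rna_samples: int = 12
    depth: float = 20.0
    rna_depth: float = 20.0
    read_length: int = 7_000
    rna_read_length: int = 150
    contig_name: str = "refA_1"
    spacing: int = 20_000
    backbone_segment: int = 3_000
    exon_length: int = 400
    # alternative-path design
    alt_ref_span: int = 2_000
    alt_cum_length: int = 12_000
    alt_divergent_length: int = 240
    alt_divergence: float = 0.60
    decoy_divergence: float = 0.30
    decoy_cum_length: int = 9_000
    dna_carriers: int = 3
    decoy_dna_carriers: int = 1
    rna_supporters: int = 9
    decoy_rna_supporters: int = 5
    # deletion design
    del_span: int = 15_000
    decoy_del_span: int = 3_000
    del_carriers: int = 10
    decoy_del_carriers: int = 3
    filler_divergence: float = 0.20
    events: tuple[EventSpec, ...] = field(default_factory=_default_events)
    extra_origin_bubbles: bool = True  # small refB/refC bubbles used by all samples

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def rna_samples(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_rna_samples)]


@dataclass
class GraphSim:
    """Simulation result: the graph plus everything needed to score detectors."""

    config: SimConfig
    graph: PanGraph
    genes: list[GeneModel]
    divergences: dict[str, float]  # per non-reference segment, vs primary reference
    alt_truth: list[dict]
    del_truth: list[dict]
    backbone: list[str]  # REF_PRIMARY segment ids in stable order
    alt_routes: list[dict]  # internal routing info for read simulation

    def truth_json(self) -> dict:
        return {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "alt_paths": self.alt_truth,
            "deletions": self.del_truth,
            "genes": [
                {"id": g.gene_id, "chrom": g.stable_name, "exons": list(map(list, g.exons))}
                for g in self.genes
            ],
        }


# ---------------------------------------------------------------------------
# sequence helpers


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_to_divergence(
    ref: str, target: float, rng: np.random.Generator, tol: float = 0.02
) -> tuple[str, float]:
    """Derive a sequence whose global-alignment divergence from ``ref`` hits ``target``.

    A suffix of length ``r`` is replaced by a triple-length random sequence;
    realised divergence is monotone in ``r`` (substitution-only mutation
    saturates near 0.5 under min-cost/max-match identity, whereas the length
    mismatch drives divergence towards ~0.7). A binary search on ``r``
    returns the sequence and its realised divergence, within ``tol`` where
    attainable.
    """
    length = len(ref)
    tail = random_sequence(rng, 3 * length)

    def realise(r: int) -> tuple[str, float]:
        seq = ref[: length - r] + tail[: 3 * r]
        rec = segment_identity(seq, ref)
        return seq, rec.divergence

    lo, hi = 0, length
    best_seq, best_div = realise(min(length, int(round(target * length))))
    if abs(best_div - target) <= tol:
        return best_seq, best_div
    for _ in range(14):
        mid = (lo + hi) // 2
        seq, div = realise(mid)
        if abs(div - target) < abs(best_div - target):
            best_seq, best_div = seq, div
        if abs(div - target) <= tol:
            break
        if div < target:
            lo = mid + 1
        else:
            hi = mid - 1
        if lo > hi:
            break
    return best_seq, best_div


# ---------------------------------------------------------------------------
# graph simulation


def simulate_graph(cfg: SimConfig) -> GraphSim:
    """Plant the configured events on a single reference contig."""
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.samples
    rna_samples = cfg.rna_samples

    # --- lay out event windows left to right
    cursor = cfg.spacing
    layout: list[dict] = []  # per event: interval [a, b) on the contig
    genes: list[GeneModel] = []
    gene_n = 0

    def add_gene(exon_start: int, strand: str = "+") -> GeneModel:
        nonlocal gene_n
        gene_n += 1
        exons = ((exon_start, exon_start + cfg.exon_length),)
        gene = GeneModel(
            gene_id=f"gene{gene_n:04d}",
            stable_name=cfg.contig_name,
            strand=strand,
            tss=exon_start if strand == "+" else exon_start + cfg.exon_length - 1,
            exons=exons,
        )
        genes.append(gene)
        return gene

    for idx, ev in enumerate(cfg.events):
        # background gene in the spacer ahead of the event
        add_gene(cursor - cfg.spacing // 2, "+" if idx % 2 == 0 else "-")
        if ev.kind == "alt":
            a, b = cursor, cursor + cfg.alt_ref_span
            if ev.violation != "exon":
                add_gene(a + cfg.alt_ref_span // 4)
        else:
            span = cfg.decoy_del_span if ev.violation == "span" else cfg.del_span
            a, b = cursor, cursor + span
            if ev.violation != "exon":
                add_gene(a + span // 3)
        layout.append({"event": ev, "a": a, "b": b, "index": idx})
        cursor = b + cfg.spacing
    extra_windows: list[tuple[int, int, str]] = []
    if cfg.extra_origin_bubbles:
        for prefix in ("refB", "refC"):
            extra_windows.append((cursor, cursor + 500, prefix))
            cursor += 500 + cfg.spacing
    contig_len = cursor

    contig_seq = random_sequence(rng, contig_len)

    # --- breakpoints: event boundaries plus regular backbone splits
    special = {0, contig_len}
    for item in layout:
        special.update((item["a"], item["b"]))
    for lo, hi, _ in extra_windows:
        special.update((lo, hi))
    breaks = sorted(special)
    points: list[int] = []
    for lo, hi in zip(breaks, breaks[1:]):
        points.append(lo)
        n_cuts = (hi - lo) // cfg.backbone_segment
        for k in range(1, n_cuts):
            points.append(lo + k * cfg.backbone_segment)
    points.append(contig_len)

    segments: dict[str, Segment] = {}
    backbone: list[str] = []
    start_of: dict[int, str] = {}
    end_of: dict[int, str] = {}
    for i, (lo, hi) in enumerate(zip(points, points[1:])):
        sid = f"s{i + 1:06d}"
        segments[sid] = Segment(
            id=sid,
            length=hi - lo,
            stable_name=cfg.contig_name,
            stable_offset=lo,
            rank=0,
            origin_class=OriginClass.REF_PRIMARY,
            sequence=contig_seq[lo:hi],
        )
        backbone.append(sid)
        start_of[lo] = sid
        end_of[hi] = sid
    links = {
        canonical_link(a, "+", b, "+") for a, b in zip(backbone, backbone[1:])
    }

    divergences: dict[str, float] = {}
    alt_truth: list[dict] = []
    del_truth: list[dict] = []
    alt_routes: list[dict] = []
    alt_n = 0

    def new_alt_segment(length: int, sequence: str, prefix: str = "panel") -> str:
        nonlocal alt_n
        alt_n += 1
        sid = f"a{alt_n:06d}"
        origin = DEFAULT_PREFIX_MAP[prefix]
        segments[sid] = Segment(
            id=sid,
            length=length,
            stable_name=f"{prefix}_alt{alt_n}",
            stable_offset=0,
            rank=1,
            origin_class=origin,
            sequence=sequence,
        )
        return sid

    for item in layout:
        ev: EventSpec = item["event"]
        a, b = item["a"], item["b"]
        left, right = end_of[a], start_of[b]
        if ev.kind == "alt":
            cum = cfg.decoy_cum_length if ev.violation == "length" else cfg.alt_cum_length
            target_div = (
                cfg.decoy_divergence if ev.violation == "divergence" else cfg.alt_divergence
            )
            div_seq, realised = mutate_to_divergence(
                contig_seq[a : a + cfg.alt_divergent_length], target_div, rng
            )
            m1 = new_alt_segment(len(div_seq), div_seq)
            filler_len = cum - len(div_seq)
            m2 = new_alt_segment(filler_len, random_sequence(rng, filler_len))
            divergences[m1] = realised
            divergences[m2] = cfg.filler_divergence
            links.add(canonical_link(left, "+", m1, "+"))
            links.add(canonical_link(m1, "+", m2, "+"))
            links.add(canonical_link(m2, "+", right, "+"))
            n_dna = cfg.decoy_dna_carriers if ev.violation == "dna" else cfg.dna_carriers
            n_rna = (
                cfg.decoy_rna_supporters if ev.violation == "rna" else cfg.rna_supporters
            )
            n_dna = min(n_dna, len(samples))
            n_rna = min(n_rna, len(rna_samples))
            carriers = sorted(rng.choice(samples, size=n_dna, replace=False))
            supporters = sorted(rng.choice(rna_samples, size=n_rna, replace=False))
            alt_truth.append(
                {
                    "left_anchor": left,
                    "right_anchor": right,
                    "members": [m1, m2],
                    "cumulative_length": cum,
                    "divergence": realised,
                    "target_divergence": target_div,
                    "dna_carriers": carriers,
                    "rna_supporters": supporters,
                    "ref_span": [a, b],
                    "qualifying": ev.violation is None,
                    "violation": ev.violation,
                }
            )
            alt_routes.append(
                {
                    "kind": "alt",
                    "a": a,
                    "b": b,
                    "members": [m1, m2],
                    "dna_carriers": set(carriers),
                    "rna_supporters": set(supporters),
                    "divergent_member": m1,
                }
            )
        else:
            n_car = min(
                cfg.decoy_del_carriers if ev.violation == "support" else cfg.del_carriers,
                len(samples),
            )
            carriers = sorted(rng.choice(samples, size=n_car, replace=False))
            links.add(canonical_link(left, "+", right, "+"))
            del_truth.append(
                {
                    "upstream": left,
                    "downstream": right,
                    "start": a,
                    "end": b,
                    "span": b - a,
                    "carriers": carriers,
                    "qualifying": ev.violation is None,
                    "violation": ev.violation,
                }
            )
            alt_routes.append(
                {"kind": "deletion", "a": a, "b": b, "dna_carriers": set(carriers)}
            )

    for lo, hi, prefix in extra_windows:
        left, right = end_of[lo], start_of[hi]
        seq, realised = mutate_to_divergence(
            contig_seq[lo:hi], cfg.decoy_divergence, rng
        )
        sid = new_alt_segment(len(seq), seq, prefix=prefix)
        divergences[sid] = realised
        links.add(canonical_link(left, "+", sid, "+"))
        links.add(canonical_link(sid, "+", right, "+"))
        alt_routes.append(
            {
                "kind": "alt",
                "a": lo,
                "b": hi,
                "members": [sid],
                "dna_carriers": set(samples),  # used by everyone
                "rna_supporters": set(),
                "divergent_member": sid,
            }
        )

    graph = PanGraph(segments=segments, links=links)
    return GraphSim(
        config=cfg,
        graph=graph,
        genes=genes,
        divergences=divergences,
        alt_truth=alt_truth,
        del_truth=del_truth,
        backbone=backbone,
        alt_routes=alt_routes,
    )


# ---------------------------------------------------------------------------
# GAF simulation


def _haplotype(sim: GraphSim, sample: str) -> list[str]:
    """Ordered segment path for one sample's DNA haplotype."""
    g = sim.graph
    events = {
        r["a"]: r for r in sim.alt_routes if sample in r["dna_carriers"]
    }
    path: list[str] = []
    skip_until = -1
    for sid in sim.backbone:
        seg = g.segments[sid]
        if seg.stable_offset < skip_until:
            continue
        route = events.get(seg.stable_offset)
        if route is not None:
            if route["kind"] == "alt":
                path.extend(route["members"])
            skip_until = route["b"]
            continue
        path.append(sid)
    return path


def _reads_to_gaf(
    g: PanGraph,
    path: list[str],
    starts: np.ndarray,
    read_len: int,
    name_prefix: str,
) -> list[str]:
    lengths = np.array([g.segments[s].length for s in path])
    cum = np.concatenate([[0], np.cumsum(lengths)])
    lines = []
    for i, start in enumerate(np.sort(starts)):
        end = start + read_len
        first = int(np.searchsorted(cum, start, side="right") - 1)
        last = int(np.searchsorted(cum, end, side="left") - 1)
        members = path[first : last + 1]
        plen = int(cum[last + 1] - cum[first])
        pstart = int(start - cum[first])
        pend = int(end - cum[first])
        path_str = "".join(">" + s for s in members)
        lines.append(
            "\t".join(
                map(
                    str,
                    [
                        f"{name_prefix}_r{i:06d}",
                        read_len,
                        0,
                        read_len,
                        "+",
                        path_str,
                        plen,
                        pstart,
                        pend,
                        read_len,
                        read_len,
                        60,
                    ],
                )
            )
        )
    return lines


def simulate_gaf_lines(sim: GraphSim) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per-sample DNA and RNA GAF lines at Poisson depth over true haplotypes."""
    cfg = sim.config
    g = sim.graph
    rng = np.random.default_rng(cfg.seed + 1)
    dna: dict[str, list[str]] = {}
    for sample in cfg.samples:
        path = _haplotype(sim, sample)
        total = sum(g.segments[s].length for s in path)
        n_reads = int(rng.poisson(cfg.depth * total / cfg.read_length))
        starts = rng.integers(0, total - cfg.read_length + 1, size=n_reads)
        dna[sample] = _reads_to_gaf(g, path, starts, cfg.read_length, sample)

    rna: dict[str, list[str]] = {}
    exons = sorted(e for gene in sim.genes for e in gene.exons)
    for sample in cfg.rna_samples:
        lines: list[str] = []
        counter = 0
        for es, ee in exons:
            exon_len = ee - es
            n = int(rng.poisson(cfg.rna_depth * exon_len / cfg.rna_read_length))
            if n == 0:
                continue
            hi = max(es + 1, ee - cfg.rna_read_length)
            starts = rng.integers(es, hi, size=n)
            lines.extend(
                _reads_to_gaf(
                    g, sim.backbone, starts, cfg.rna_read_length, f"{sample}_x{counter}"
                )
            )
            counter += 1
        for route in sim.alt_routes:
            if route["kind"] != "alt" or sample not in route["rna_supporters"]:
                continue
            member = route["divergent_member"]
            mlen = g.segments[member].length
            n = max(1, int(rng.poisson(cfg.rna_depth * mlen / cfg.rna_read_length)))
            starts = rng.integers(0, max(1, mlen - cfg.rna_read_length + 1), size=n)
            lines.extend(
                _reads_to_gaf(
                    g, [member], starts, cfg.rna_read_length, f"{sample}_alt{counter}"
                )
            )
            counter += 1
        rna[sample] = lines
    return dna, rna


# ---------------------------------------------------------------------------
# core-gene panel with planted coverage fractions


def simulate_core_gene_panel(
    n_genes: int = 100,
    n_samples: int = 12,
    seed: int = 0,
    exon_length: int = 1_000,
) -> tuple[PanGraph, pd.DataFrame, list[GeneModel], list[dict]]:
    """Graph + usage matrix + genes with exactly planted covered fractions.

    Each gene has one ``exon_length`` exon split at a planted point; the left
    part lies in a segment used by all samples, the right part in a segment
    one sample misses. Returns (graph, usage, genes, truth) where truth
    records the exact fraction and expected class per gene.
    """
    rng = np.random.default_rng(seed)
    chrom = "refA_1"
    pitch = exon_length * 3
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    choices = np.array([0.0, 0.2, 0.5, 0.9, 0.95, 0.96, 0.98, 1.0])
    fractions = rng.choice(choices, size=n_genes)

    segments: dict[str, Segment] = {}
    usage_rows: dict[str, list[bool]] = {}
    genes: list[GeneModel] = []
    truth: list[dict] = []
    seg_n = 0

    def add_segment(lo: int, hi: int, core: bool) -> None:
        nonlocal seg_n
        seg_n += 1
        sid = f"c{seg_n:06d}"
        segments[sid] = Segment(
            id=sid,
            length=hi - lo,
            stable_name=chrom,
            stable_offset=lo,
            rank=0,
            origin_class=OriginClass.REF_PRIMARY,
        )
        miss = int(rng.integers(0, n_samples))
        usage_rows[sid] = [True] * n_samples if core else [
            i != miss for i in range(n_samples)
        ]

    for i, frac in enumerate(fractions):
        base = i * pitch
        covered = int(round(frac * exon_length))
        exon = (base, base + exon_length)
        if covered > 0:
            add_segment(base, base + covered, core=True)
        if covered < exon_length:
            add_segment(base + covered, base + exon_length, core=False)
        add_segment(base + exon_length, base + pitch, core=True)  # spacer
        gene = GeneModel(
            gene_id=f"gene{i + 1:04d}",
            stable_name=chrom,
            strand="+",
            tss=exon[0],
            exons=(exon,),
        )
        genes.append(gene)
        exact = covered / exon_length
        if exact > 0.95:
            expected = "core"
        elif covered == 0:
            expected = "absent"
        else:
            expected = "fragmented"
        truth.append(
            {"gene_id": gene.gene_id, "fraction": exact, "expected_class": expected}
        )

    graph = PanGraph(segments=segments, links=set())
    usage = pd.DataFrame(usage_rows, index=samples).T
    usage.index.name = "segment"
    return graph, usage, genes, truth


# ---------------------------------------------------------------------------
# reference-anchored SV simulation


@dataclass
class SvSimConfig:
    seed: int = 0
    n_samples: int = 9
    chrom: str = "refA_1"
    genome_length: int = 1_000_000
    repeat_fraction: float = 0.16
    repeat_length: int = 400
    counts: dict = field(
        default_factory=lambda: {"DEL": 40, "INS": 30, "DUP": 16, "INV": 10, "TRA": 10}
    )
    overlap_fraction: dict = field(
        default_factory=lambda: {
            "DEL": 0.72,
            "INS": 0.21,
            "DUP": 0.63,
            "INV": 0.81,
            "TRA": 0.35,
        }
    )
    jitter: int = 40  # per-sample breakpoint jitter, well under merge max_shift

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def simulate_svs(
    cfg: SvSimConfig,
) -> tuple[dict[str, list[SvRecord]], list[tuple[int, int]], dict]:
    """Per-sample SV call sets with planted carrier sets and repeat overlap.

    Repeats are evenly spaced ``repeat_length`` intervals realising
    ``repeat_fraction`` of the genome; each distinct SV is placed either
    inside a repeat or centred in a repeat-free gap according to the
    per-type planted overlap fraction. Per-sample calls jitter breakpoints
    within the merge tolerance. Returns (per-sample call sets, repeat
    intervals, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    period = int(cfg.repeat_length / cfg.repeat_fraction)
    n_repeats = cfg.genome_length // period
    repeats = [
        (k * period, k * period + cfg.repeat_length) for k in range(n_repeats)
    ]
    gap = period - cfg.repeat_length

    distinct: list[dict] = []
    slot = 0
    for svtype in ("DEL", "INS", "DUP", "INV", "TRA"):
        n = cfg.counts.get(svtype, 0)
        n_hit = int(round(cfg.overlap_fraction.get(svtype, 0.0) * n))
        for i in range(n):
            overlapping = i < n_hit
            rep_start = (slot % n_repeats) * period
            slot += 3
            if svtype in ("INS", "TRA"):
                if overlapping:
                    pos = rep_start + cfg.repeat_length // 2
                else:
                    # gap centre, > pad away from repeat edges
                    pos = rep_start + cfg.repeat_length + gap // 2
                start, end = pos, pos + 1
                length = int(rng.integers(100, 1_500))
            else:
                length = int(rng.integers(300, min(1_200, gap - 300)))
                if overlapping:
                    start = rep_start + cfg.repeat_length // 4
                else:
                    start = rep_start + cfg.repeat_length + 200
                end = start + length
            n_carriers = int(rng.integers(1, cfg.n_samples + 1))
            carriers = sorted(
                rng.choice(cfg.samples, size=n_carriers, replace=False)
            )
            distinct.append(
                {
                    "type": svtype,
                    "start": start,
                    "end": end,
                    "length": length,
                    "carriers": carriers,
                    "overlaps_repeat": overlapping,
                }
            )

    call_sets: dict[str, list[SvRecord]] = {s: [] for s in cfg.samples}
    for sv in distinct:
        for sample in sv["carriers"]:
            j1 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
            j2 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
            if sv["type"] in ("INS", "TRA"):
                start = max(0, sv["start"] + j1)
                end = start + 1
            else:
                start = max(0, sv["start"] + j1)
                end = max(start + 1, sv["end"] + j2)
            call_sets[sample].append(
                SvRecord(
                    chrom=cfg.chrom,
                    start=start,
                    end=end,
                    type=sv["type"],
                    length=sv["length"],
                    carriers=frozenset([sample]),
                    chrom2=cfg.chrom if sv["type"] == "TRA" else None,
                    pos2=sv["start"] if sv["type"] == "TRA" else None,
                )
            )
    truth = {
        "distinct": distinct,
        "n_distinct": len(distinct),
        "overlap_fraction": {
            t: sum(1 for d in distinct if d["type"] == t and d["overlaps_repeat"])
            / max(1, sum(1 for d in distinct if d["type"] == t))
            for t in cfg.counts
        },
    }
    return call_sets, repeats, truth


# ---------------------------------------------------------------------------
# methylation simulation


@dataclass
class MethSimConfig:
    seed: int = 0
    n_samples: int = 12
    n_islands: int = 60
    n_dmr: int = 12
    sites_per_island: int = 10
    reads_per_site: int = 20
    mu: float = 2.5
    sigma: float = 1.0
    base_rate: float = 0.5
    delta: float = 0.8
    sib_pairs: bool = True  # samples (0,1), (2,3), ... share rate profiles
    sib_noise: float = 0.02
    balanced_groups: bool = False  # DMR split: first half of families low, rest high
    chrom: str = "refA_1"
    island_length: int = 600
    island_pitch: int = 10_000
    site_step: int = 30

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def _llr_draws(
    rng: np.random.Generator, rates: np.ndarray, reads: int, mu: float, sigma: float
) -> np.ndarray:
    """LLRs for ``reads`` reads at sites with the given methylation rates.

    rates has shape (...,); output (..., reads): mixture of N(+mu, sigma)
    with probability rate, else N(-mu, sigma).
    """
    shape = rates.shape + (reads,)
    methylated = rng.random(shape) < rates[..., None]
    noise = rng.normal(0.0, sigma, size=shape)
    return np.where(methylated, mu, -mu) + noise


def simulate_meth(
    cfg: MethSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneModel], dict]:
    """Per-read LLR calls, island BED, TSS-bearing genes and DMR truth.

    The first ``n_dmr`` islands are differentially methylated: sample groups
    (split by sibling family when ``sib_pairs``) receive rates differing by
    ``delta``; non-DMR islands share one rate across samples. DMR islands get
    a gene TSS inside the island, non-DMR islands are gene-distal.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.samples
    n = cfg.n_samples
    islands = []
    genes: list[GeneModel] = []
    frames = []
    truth_rows = []
    family = np.arange(n) // 2 if cfg.sib_pairs else np.arange(n)
    n_fam = int(family.max()) + 1

    for i in range(cfg.n_islands):
        start = 1_000 + i * cfg.island_pitch
        end = start + cfg.island_length
        islands.append({"chrom": cfg.chrom, "start": start, "end": end})
        is_dmr = i < cfg.n_dmr
        if is_dmr:
            lo = (1.0 - cfg.delta) / 2.0
            hi = lo + cfg.delta
            if cfg.balanced_groups:
                fam_rates = np.where(np.arange(n_fam) < n_fam // 2, lo, hi)
            else:
                fam_rates = np.where(rng.random(n_fam) < 0.5, lo, hi)
                if np.all(fam_rates == fam_rates[0]):  # force a real difference
                    fam_rates[0] = hi if fam_rates[0] == lo else lo
            rates = fam_rates[family] + rng.normal(0.0, cfg.sib_noise, size=n)
            rates = np.clip(rates, 0.0, 1.0)
            genes.append(
                GeneModel(
                    gene_id=f"mgene{i + 1:04d}",
                    stable_name=cfg.chrom,
                    strand="+",
                    tss=start + cfg.island_length // 2,
                    exons=((start, end),),
                )
            )
        else:
            rates = np.full(n, cfg.base_rate)
        truth_rows.append(
            {
                "chrom": cfg.chrom,
                "start": start,
                "end": end,
                "is_dmr": bool(is_dmr),
                "rates": rates.tolist(),
            }
        )
        positions = start + np.arange(cfg.sites_per_island) * cfg.site_step
        for s_idx, sample in enumerate(samples):
            site_rates = np.full(cfg.sites_per_island, rates[s_idx])
            llrs = _llr_draws(rng, site_rates, cfg.reads_per_site, cfg.mu, cfg.sigma)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": cfg.chrom,
                        "position": np.repeat(positions, cfg.reads_per_site),
                        "read": [
                            f"{sample}_i{i}_p{p}_k{k}"
                            for p in range(cfg.sites_per_island)
                            for k in range(cfg.reads_per_site)
                        ],
                        "log_lik_ratio": llrs.ravel(),
                        "sample": sample,
                    }
                )
            )

    calls = pd.concat(frames, ignore_index=True)
    islands_df = pd.DataFrame(islands)
    truth = {"islands": truth_rows, "n_dmr": cfg.n_dmr, "family": family.tolist()}
    return calls, islands_df, genes, truth


def simulate_null_meth(
    n_islands: int,
    n_samples: int = 12,
    sites_per_island: int = 8,
    reads_per_site: int = 5,
    mu: float = 2.5,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null islands (every sample drawn from one site-wise distribution).

    Vectorised for large island counts; returns (calls, islands).
    """
    rng = np.random.default_rng(seed)
    chrom = "null1"
    pitch = sites_per_island * 10 + 100
    rates = rng.random(n_islands)  # shared by all samples within an island
    site_rates = np.repeat(rates, sites_per_island * n_samples)
    llrs = _llr_draws(rng, site_rates, reads_per_site, mu, sigma)

    island_idx = np.repeat(np.arange(n_islands), sites_per_island * n_samples)
    within = np.tile(
        np.repeat(np.arange(sites_per_island), n_samples), n_islands
    )
    sample_idx = np.tile(np.arange(n_samples), n_islands * sites_per_island)
    positions = island_idx * pitch + within * 10
    n_rows = positions.size
    calls = pd.DataFrame(
        {
            "chrom": chrom,
            "position": np.repeat(positions, reads_per_site),
            "read": np.char.add(
                "r", np.arange(n_rows * reads_per_site).astype(str)
            ),
            "log_lik_ratio": llrs.ravel(),
            "sample": np.char.add(
                "S", np.repeat(sample_idx, reads_per_site).astype(str)
            ),
        }
    )
    islands = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_islands) * pitch,
            "end": np.arange(n_islands) * pitch + sites_per_island * 10,
        }
    )
    return calls, islands


# ---------------------------------------------------------------------------
# writers


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            lo = min(s for s, _ in gene.exons)
            hi = max(e for _, e in gene.exons)
            attrs = f"ID={gene.gene_id}"
            fh.write(
                f"{gene.stable_name}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            mrna = f"{gene.gene_id}.t1"
            fh.write(
                f"{gene.stable_name}\tsim\tmRNA\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t"
                f"ID={mrna};Parent={gene.gene_id}\n"
            )
            for k, (s, e) in enumerate(gene.exons):
                fh.write(
                    f"{gene.stable_name}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={mrna}.exon{k};Parent={mrna}\n"
                )
                fh.write(
                    f"{gene.stable_name}\tsim\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t"
                    f"ID={mrna}.cds{k};Parent={mrna}\n"
                )


def write_bed(intervals, path: str | Path, chrom: str | None = None) -> None:
    """Write (chrom, start, end) rows; ``intervals`` may be a DataFrame or tuples."""
    with open(path, "w") as fh:
        if isinstance(intervals, pd.DataFrame):
            for row in intervals.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
        else:
            for lo, hi in intervals:
                fh.write(f"{chrom}\t{lo}\t{hi}\n")


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
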