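"""Core / fragmented / absent gene classification.

A gene is *core* when more than 95% of its coding-exon bases fall in stable
intervals of REF_PRIMARY segments used by every sample, *absent* when none
do, and *fragmented* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from panelgraph.graph_model import OriginClass, PanGraph

__all__ = [
    "GeneModel",
    "GeneStatus",
    "load_annotation",
    "core_segments",
    "classify_genes",
    "panel_summary",
]

CORE_FRACTION = 0.95


@dataclass(frozen=True)
class GeneModel:
    """A gene with merged coding-exon intervals on stable coordinates.

    Exons are 0-based half-open, sorted and disjoint. The TSS is the
    leftmost coordinate on the + strand and the rightmost on the - strand.
    """

    gene_id: str
    stable_name: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    @property
    def exonic_bases(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneStatus:
    gene_id: str
    covered_fraction: float
    status: str  # core | fragmented | absent


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    if not ivs:
        return ()
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def load_annotation(path: str | Path, feature: str = "CDS") -> list[GeneModel]:
    """Load gene models from GFF3, merging coding intervals across transcripts.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    ``feature`` selects which child feature defines the intervals
    (``CDS`` by default; ``exon`` to count all exonic bases).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    orphans = 0
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        intervals: list[tuple[int, int]] = []
        for child in db.children(gene, featuretype=feature):
            intervals.append((child.start - 1, child.end))
        if not intervals:
            continue
        strand = gene.strand if gene.strand in "+-" else "+"
        tss = gene.start - 1 if strand == "+" else gene.end - 1
        genes.append(
            GeneModel(
                gene_id=gene.id,
                stable_name=gene.seqid,
                strand=strand,
                tss=tss,
                exons=_merge_intervals(intervals),
            )
        )
    # features with no gene ancestor are silently unusable; surface them
    for feat in db.features_of_type(feature):
        if not any(True for _ in db.parents(feat)):
            orphans += 1
    if orphans:
        warnings.warn(f"{orphans} {feature} feature(s) without a parent gene skipped")
    return genes


def core_segments(usage: pd.DataFrame) -> set[str]:
    """Segment ids used by every sample in a boolean segments x samples table."""
    if usage.empty:
        return set()
    return set(usage.index[usage.all(axis=1)])


def _covered_bases(
    gene: GeneModel,
    core_ivs: list[tuple[int, int]],
    fully_contained: bool,
) -> int:
    covered = 0
    for es, ee in gene.exons:
        for ss, se in core_ivs:
            lo, hi = max(es, ss), min(ee, se)
            if hi <= lo:
                continue
            if fully_contained:
                if ss <= es and ee <= se:
                    covered += ee - es
            else:
                covered += hi - lo
    return covered


def classify_genes(
    genes: list[GeneModel],
    core: set[str],
    g: PanGraph,
    fully_contained: bool = False,
) -> list[GeneStatus]:
    """Classify genes from coding-exon overlap with core REF_PRIMARY segments.

    ``fully_contained`` counts an exon's bases only when the whole exon lies
    inside a single core segment (instead of base-level intersection).
    """
    core_ivs_by_stable: dict[str, list[tuple[int, int]]] = {}
    for stable_name, segs in g.ref_by_stable.items():
        core_ivs_by_stable[stable_name] = [
            (s.stable_offset, s.stable_end) for s in segs if s.id in core
        ]
    known_ref_names = set(g.ref_by_stable)
    out: list[GeneStatus] = []
    for gene in genes:
        if gene.stable_name not in known_ref_names:
            raise ValueError(
                f"gene {gene.gene_id} on unknown stable name {gene.stable_name!r}"
            )
        total = gene.exonic_bases
        covered = _covered_bases(
            gene, core_ivs_by_stable[gene.stable_name], fully_contained
        )
        frac = covered / total if total else 0.0
        if frac > CORE_FRACTION:
            status = "core"
        elif covered == 0:
            status = "absent"
        else:
            status = "fragmented"
        out.append(GeneStatus(gene_id=gene.gene_id, covered_fraction=frac, status=status))
    return out


def panel_summary(statuses: list[GeneStatus]) -> dict[str, float]:
    """Three-way panel summary: fractions of core / fragmented / absent genes."""
    n = len(statuses)
    counts = {"core": 0, "fragmented": 0, "absent": 0}
    for st in statuses:
        counts[st.status] += 1
    out: dict[str, float] = {f"n_{k}": v for k, v in counts.items()}
    out["n_genes"] = n
    for k, v in counts.items():
        out[f"frac_{k}"] = v / n if n else 0.0
    return out
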