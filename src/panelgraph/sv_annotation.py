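"""Annotation of reference-anchored structural-variant call sets.

Provides pLI log10-odds (LOD) scoring over overlapping genes, per-type
repeat-overlap fractions, cross-sample merging of per-sample calls into
distinct SVs with carrier sets, and total/singleton counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from panelgraph.core_genes import GeneModel

__all__ = [
    "SvRecord",
    "load_pli_table",
    "read_sv_vcf",
    "read_sv_tsv",
    "pli_lod",
    "repeat_overlap",
    "merge_distinct",
    "singleton_counts",
]

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")
TRA_PAD = 100  # bp of padding around each TRA breakend when testing overlap


@dataclass(frozen=True)
class SvRecord:
    """One SV call; ``start``/``end`` are 0-based half-open.

    Insertions use ``end = start + 1`` with the inserted length in
    ``length``. TRA records carry the partner locus in ``chrom2``/``pos2``.
    """

    chrom: str
    start: int
    end: int
    type: str
    length: int
    carriers: frozenset[str] = frozenset()
    chrom2: str | None = None
    pos2: int | None = None

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")
        if self.length <= 0:
            raise ValueError("SV length must be positive")
        if self.type == "TRA" and (self.chrom2 is None or self.pos2 is None):
            raise ValueError("TRA record requires a paired locus (chrom2/pos2)")


# ---------------------------------------------------------------------------
# input plumbing


def load_pli_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene id, pLI in [0,1]) -> dict, validated."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "pli"], comment="#")
    table: dict[str, float] = {}
    for gene, pli in zip(df["gene"], df["pli"].astype(float)):
        if not 0.0 <= pli <= 1.0:
            raise ValueError(f"pLI for {gene} out of [0,1]: {pli}")
        table[str(gene)] = pli
    return table


def read_sv_vcf(path: str | Path, sample: str | None = None) -> list[SvRecord]:
    """Read SVs from a VCF using SVTYPE / SVLEN / END (and CHR2 for TRA)."""
    out: list[SvRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            svtype = str(svtype)
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            start = rec.start  # pysam: 0-based
            if svtype == "INS":
                end = start + 1
                length = abs(int(svlen)) if svlen is not None else 1
            elif svtype == "TRA":
                end = start + 1
                length = 1
            elif svlen is not None:
                # htslib folds SVLEN into rlen (including the anchor base);
                # recompute the half-open end directly for consistency
                length = abs(int(svlen))
                end = start + length
            else:
                end = int(rec.stop)
                length = end - start
            carriers = frozenset([sample]) if sample else frozenset()

            def info_get(key):
                try:  # pysam raises on keys absent from the header
                    return rec.info.get(key)
                except (KeyError, ValueError):
                    return None

            chrom2 = info_get("CHR2")
            pos2 = info_get("POS2")
            if svtype == "TRA" and pos2 is None:
                pos2 = int(rec.stop)
            out.append(
                SvRecord(
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    type=svtype,
                    length=length,
                    carriers=carriers,
                    chrom2=str(chrom2) if chrom2 is not None else None,
                    pos2=int(pos2) if pos2 is not None else None,
                )
            )
    return out


def read_sv_tsv(path: str | Path) -> list[SvRecord]:
    """TSV with columns chrom, start, end, type, length[, sample, chrom2, pos2]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        carriers = (
            frozenset(str(row.sample).split(",")) if hasattr(row, "sample") else frozenset()
        )
        chrom2 = getattr(row, "chrom2", None)
        pos2 = getattr(row, "pos2", None)
        out.append(
            SvRecord(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                type=str(row.type),
                length=int(row.length),
                carriers=carriers,
                chrom2=None if pd.isna(chrom2) else str(chrom2),
                pos2=None if pd.isna(pos2) else int(pos2),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pLI LOD


def pli_lod(
    sv: SvRecord,
    genes: Sequence[GeneModel] | Sequence[tuple[str, str, int, int]],
    pli: Mapping[str, float],
    eps: float = 1e-16,
) -> float | None:
    """Sum of log10 odds of pLI over genes overlapping the SV interval.

    pLI values are clamped to ``[eps, 1 - eps]`` so scores stay finite for
    pLI in {0, 1}. Returns ``None`` (not 0) when no scored gene overlaps.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    lod = 0.0
    hit = False
    for gene in genes:
        if isinstance(gene, GeneModel):
            gid, chrom = gene.gene_id, gene.stable_name
            gs, ge = gene.exons[0][0], gene.exons[-1][1]
        else:
            gid, chrom, gs, ge = gene
        if chrom != sv.chrom or min(ge, sv.end) <= max(gs, sv.start):
            continue
        p = pli.get(gid)
        if p is None:
            continue
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"pLI for {gid} out of [0,1]: {p}")
        # clamp numerator and complement independently: 1 - (1 - eps) is not
        # exactly eps in floating point, which would distort extreme scores
        num = min(max(p, eps), 1.0 - eps)
        den = min(max(1.0 - p, eps), 1.0 - eps)
        lod += math.log10(num) - math.log10(den)
        hit = True
    return lod if hit else None


# ---------------------------------------------------------------------------
# repeat overlap


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _overlaps_any(ivs: list[tuple[int, int]], lo: int, hi: int) -> bool:
    import bisect

    if not ivs:
        return False
    i = bisect.bisect_right([s for s, _ in ivs], lo)
    for s, e in ivs[max(0, i - 1):]:
        if s >= hi:
            break
        if min(e, hi) > max(s, lo):
            return True
    return False


def repeat_overlap(
    svs: Sequence[SvRecord],
    repeats: Mapping[str, Iterable[tuple[int, int]]],
) -> dict[str, float]:
    """Fraction of distinct SVs per type overlapping >= 1 repeat base.

    Repeats are merged per chromosome, strand-ignored. TRA variants test
    both breakends padded by +/-100 bp; other types test their interval.
    An SV counts once regardless of how many repeats it touches.
    """
    merged = {chrom: _merge(list(ivs)) for chrom, ivs in repeats.items()}
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for sv in svs:
        totals[sv.type] = totals.get(sv.type, 0) + 1
        if sv.type == "TRA":
            loci = [
                (sv.chrom, sv.start - TRA_PAD, sv.start + 1 + TRA_PAD),
                (sv.chrom2, sv.pos2 - TRA_PAD, sv.pos2 + 1 + TRA_PAD),
            ]
        else:
            loci = [(sv.chrom, sv.start, sv.end)]
        if any(
            _overlaps_any(merged.get(chrom, []), max(lo, 0), hi) for chrom, lo, hi in loci
        ):
            hits[sv.type] = hits.get(sv.type, 0) + 1
    return {t: hits.get(t, 0) / n for t, n in sorted(totals.items())}


# ---------------------------------------------------------------------------
# merging and singleton counts


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _mergeable(a: SvRecord, b: SvRecord, reciprocal: float, max_shift: int) -> bool:
    if a.type != b.type or a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) > max_shift or abs(a.end - b.end) > max_shift:
        return False
    if a.type in ("INS", "TRA"):
        # point-like: compare lengths reciprocally instead of intervals
        lo, hi = sorted((a.length, b.length))
        return hi == 0 or lo / hi >= reciprocal
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov / (a.end - a.start) >= reciprocal and ov / (b.end - b.start) >= reciprocal


def merge_distinct(
    call_sets: Sequence[Sequence[SvRecord]],
    reciprocal: float = 0.8,
    max_shift: int = 1_000,
) -> list[SvRecord]:
    """Merge per-sample call sets into distinct SVs with carrier sets.

    Two same-type calls merge when their reciprocal overlap reaches
    ``reciprocal`` and neither breakpoint shifts by more than ``max_shift``
    bp; merging is the transitive closure of that relation, so the result is
    independent of input order. Each cluster is represented by its
    coordinate-smallest member carrying the union of carrier sets.
    """
    records = sorted(
        (r for cs in call_sets for r in cs),
        key=lambda r: (r.chrom, r.type, r.start, r.end, sorted(r.carriers)),
    )
    n = len(records)
    dsu = _DSU(n)
    for i in range(n):
        a = records[i]
        for j in range(i + 1, n):
            b = records[j]
            if b.chrom != a.chrom or b.type != a.type:
                break
            if b.start - a.start > max_shift:
                break
            if _mergeable(a, b, reciprocal, max_shift):
                dsu.union(i, j)
    clusters: dict[int, list[SvRecord]] = {}
    for i in range(n):
        clusters.setdefault(dsu.find(i), []).append(records[i])
    out = []
    for root in sorted(clusters):
        members = clusters[root]
        carriers = frozenset().union(*(m.carriers for m in members))
        out.append(replace(members[0], carriers=carriers))
    return out


def singleton_counts(distinct: Sequence[SvRecord], samples: Sequence[str]) -> pd.DataFrame:
    """Per-sample, per-type total and singleton counts (singleton = 1 carrier)."""
    rows = []
    for sample in samples:
        for svtype in SV_TYPES:
            carried = [
                sv for sv in distinct if sv.type == svtype and sample in sv.carriers
            ]
            rows.append(
                {
                    "sample": sample,
                    "type": svtype,
                    "total": len(carried),
                    "singletons": sum(1 for sv in carried if len(sv.carriers) == 1),
                }
            )
    return pd.DataFrame(rows)
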