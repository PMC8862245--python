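"""Graph-derived structural variants.

Two procedures over a parsed pangenome graph plus per-sample coverage:

* divergent alternative paths — bubbles leaving and rejoining the primary
  reference through non-reference segments, filtered on cumulative length,
  member divergence, DNA/RNA sample support and exon overlap;
* large-scale deletions — links joining two distant primary-reference
  segments on one stable sequence, filtered on gap size, junction support
  across samples and skipped exons. A relaxed scan drops the exon criterion
  and lowers the gap threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from panelgraph.coverage import CoverageProfile
from panelgraph.core_genes import GeneModel
from panelgraph.graph_model import Link, OriginClass, PanGraph, canonical_link

__all__ = [
    "AltPathCandidate",
    "AltPathCall",
    "DeletionCall",
    "AltPathParams",
    "DeletionParams",
    "enumerate_alt_paths",
    "call_alt_paths",
    "call_deletions",
    "relaxed_deletion_scan",
]


@dataclass(frozen=True)
class AltPathCandidate:
    """A simple reference-to-reference path through non-reference segments."""

    left_anchor: str
    right_anchor: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class AltPathCall:
    left_anchor: str
    right_anchor: str
    members: tuple[str, ...]
    cumulative_length: int
    max_divergence: float
    dna_support: int
    rna_support: int
    exons_overlapped: int
    stable_name: str
    ref_span: tuple[int, int]


@dataclass(frozen=True)
class DeletionCall:
    link: Link
    upstream: str
    downstream: str
    stable_name: str
    start: int  # end of upstream segment (0-based)
    end: int  # start of downstream segment
    support: int
    exons_skipped: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AltPathParams:
    min_length: int = 10_000
    min_divergence: float = 0.5
    dna_min_samples: int = 2
    dna_depth_frac: float = 0.5
    rna_min_samples: int = 8
    rna_depth_frac: float = 0.1
    min_exons: int = 1
    divergence_mode: str = "any"  # any | all member segments above min_divergence
    dna_mode: str = "all"  # sample supports iff all | any members above depth cut
    rna_mode: str = "any"


@dataclass(frozen=True)
class DeletionParams:
    min_span: int = 10_000
    support_frac: float = 0.5
    min_samples: int | None = None  # default: ceil(n_samples / 2)
    require_exon: bool = True
    min_exons: int = 1


# ---------------------------------------------------------------------------
# bubble enumeration


def enumerate_alt_paths(
    g: PanGraph,
    max_depth: int = 50,
    max_paths: int = 10_000,
) -> tuple[list[AltPathCandidate], bool]:
    """Enumerate simple ref->alt*->ref paths, deterministically.

    Returns the candidate list in lexicographic order and a flag set when
    the per-anchor ``max_paths`` bound truncated the enumeration. Paths are
    deduplicated against their reversals (each bubble is reported once).
    """
    ref_ids = set(g.by_class[OriginClass.REF_PRIMARY])
    seen: set[tuple[str, tuple[str, ...], str]] = set()
    out: list[AltPathCandidate] = []
    truncated = False

    for start in sorted(ref_ids):
        found_here = 0
        # stack of (current segment, members so far, link used to enter the bubble)
        stack: list[tuple[str, tuple[str, ...], Link]] = []
        for nb, entry in sorted(g.neighbours(start)):
            if nb not in ref_ids:
                stack.append((nb, (nb,), entry))
        while stack:
            node, members, entry = stack.pop()
            if found_here >= max_paths:
                truncated = True
                break
            for nb, link in sorted(g.neighbours(node), reverse=True):
                if nb in ref_ids:
                    if link == entry:  # would re-use the entry junction to exit
                        continue
                    key = min(
                        (start, members, nb),
                        (nb, tuple(reversed(members)), start),
                    )
                    if key not in seen:
                        seen.add(key)
                        out.append(AltPathCandidate(key[0], key[2], key[1]))
                        found_here += 1
                elif nb not in members and len(members) < max_depth:
                    stack.append((nb, members + (nb,), entry))
    out.sort(key=lambda c: (c.left_anchor, c.members, c.right_anchor))
    return out, truncated


# ---------------------------------------------------------------------------
# alt-path calling


def _ref_span(
    g: PanGraph, left: str, right: str
) -> tuple[str, int, int] | None:
    """Stable interval between the two anchors, or None when undefined."""
    a, b = g.segments[left], g.segments[right]
    if a.stable_name != b.stable_name:
        return None
    if a.stable_offset > b.stable_offset:
        a, b = b, a
    if b.stable_offset < a.stable_end:
        return None
    return a.stable_name, a.stable_end, b.stable_offset


def _exons_on(genes: Sequence[GeneModel], stable_name: str) -> list[tuple[int, int]]:
    out = []
    for gene in genes:
        if gene.stable_name == stable_name:
            out.extend(gene.exons)
    return sorted(out)


def _count_overlapping(exons: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(1 for s, e in exons if min(e, hi) > max(s, lo))


def _count_contained(exons: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(1 for s, e in exons if s >= lo and e <= hi)


def call_alt_paths(
    candidates: Sequence[AltPathCandidate],
    divergences: Mapping[str, float],
    dna_profiles: Sequence[CoverageProfile],
    rna_profiles: Sequence[CoverageProfile],
    genes: Sequence[GeneModel],
    g: PanGraph,
    params: AltPathParams = AltPathParams(),
) -> list[AltPathCall]:
    """Apply the five alt-path criteria to enumerated candidates.

    A candidate is called iff (a) cumulative member length exceeds
    ``min_length``, (b) member divergence exceeds ``min_divergence``
    (any-member by default), (c) at least ``dna_min_samples`` DNA samples
    have every member at depth >= ``dna_depth_frac`` x that sample's
    ref_mean, (d) at least ``rna_min_samples`` RNA samples have >= 1 member
    at ``rna_depth_frac`` x RNA ref_mean, and (e) the reference span between
    the anchors overlaps at least ``min_exons`` annotated exons.
    """
    missing = sorted(
        {m for c in candidates for m in c.members if m not in divergences}
    )
    if missing:
        raise ValueError(f"no divergence available for segments: {', '.join(missing)}")

    exon_cache: dict[str, list[tuple[int, int]]] = {}
    calls: list[AltPathCall] = []
    for cand in candidates:
        cum_len = sum(g.segments[m].length for m in cand.members)
        if cum_len <= params.min_length:
            continue
        divs = [divergences[m] for m in cand.members]
        if params.divergence_mode == "any":
            div_ok = max(divs) > params.min_divergence
        else:
            div_ok = min(divs) > params.min_divergence
        if not div_ok:
            continue
        dna = _support(cand.members, dna_profiles, params.dna_depth_frac, params.dna_mode, g)
        if dna < params.dna_min_samples:
            continue
        rna = _support(cand.members, rna_profiles, params.rna_depth_frac, params.rna_mode, g)
        if rna < params.rna_min_samples:
            continue
        span = _ref_span(g, cand.left_anchor, cand.right_anchor)
        if span is None:
            continue
        stable_name, lo, hi = span
        if stable_name not in exon_cache:
            exon_cache[stable_name] = _exons_on(genes, stable_name)
        n_exons = _count_overlapping(exon_cache[stable_name], lo, hi)
        if n_exons < params.min_exons:
            continue
        calls.append(
            AltPathCall(
                left_anchor=cand.left_anchor,
                right_anchor=cand.right_anchor,
                members=cand.members,
                cumulative_length=cum_len,
                max_divergence=max(divs),
                dna_support=dna,
                rna_support=rna,
                exons_overlapped=n_exons,
                stable_name=stable_name,
                ref_span=(lo, hi),
            )
        )
    return calls


def _support(
    members: tuple[str, ...],
    profiles: Sequence[CoverageProfile],
    depth_frac: float,
    mode: str,
    g: PanGraph,
) -> int:
    n = 0
    for p in profiles:
        cut = depth_frac * p.ref_mean
        covered = [p.depth_of(m) >= cut for m in members]
        ok = all(covered) if mode == "all" else any(covered)
        if ok and p.ref_mean > 0:
            n += 1
    return n


# ---------------------------------------------------------------------------
# deletion calling


def call_deletions(
    g: PanGraph,
    dna_profiles: Sequence[CoverageProfile],
    genes: Sequence[GeneModel],
    params: DeletionParams = DeletionParams(),
    counters: dict[str, int] | None = None,
) -> list[DeletionCall]:
    """Call large-scale deletions from junction usage between distant reference segments.

    A link is called iff both endpoints are REF_PRIMARY on one stable name
    with a positive gap > ``min_span``, its traversal count is
    >= ``support_frac`` x ref_mean in at least ``min_samples`` samples
    (default: half the panel, rounded up), and — unless ``require_exon`` is
    off — the deleted interval fully contains >= ``min_exons`` exons.
    Inversion-like links (inconsistent orientations) are excluded and, when
    ``counters`` is given, tallied under ``inversion_like``.
    """
    q = params.min_samples
    if q is None:
        q = math.ceil(len(dna_profiles) / 2)
    exon_cache: dict[str, list[tuple[int, int]]] = {}
    calls: list[DeletionCall] = []
    for link in sorted(g.links):
        a = g.segments[link.from_id]
        b = g.segments[link.to_id]
        if (
            a.origin_class is not OriginClass.REF_PRIMARY
            or b.origin_class is not OriginClass.REF_PRIMARY
            or a.stable_name != b.stable_name
        ):
            continue
        u, v = (a, b) if a.stable_offset <= b.stable_offset else (b, a)
        gap = v.stable_offset - u.stable_end
        if gap <= 0:
            continue
        if link != canonical_link(u.id, "+", v.id, "+"):
            if counters is not None:
                counters["inversion_like"] = counters.get("inversion_like", 0) + 1
            continue
        if gap <= params.min_span:
            continue
        support = sum(
            1
            for p in dna_profiles
            if p.ref_mean > 0 and p.junctions_of(link) >= params.support_frac * p.ref_mean
        )
        if support < q:
            continue
        if u.stable_name not in exon_cache:
            exon_cache[u.stable_name] = _exons_on(genes, u.stable_name)
        n_exons = _count_contained(exon_cache[u.stable_name], u.stable_end, v.stable_offset)
        if params.require_exon and n_exons < params.min_exons:
            continue
        calls.append(
            DeletionCall(
                link=link,
                upstream=u.id,
                downstream=v.id,
                stable_name=u.stable_name,
                start=u.stable_end,
                end=v.stable_offset,
                support=support,
                exons_skipped=n_exons,
            )
        )
    calls.sort(key=lambda c: (c.stable_name, c.start, c.end))
    return calls


def relaxed_deletion_scan(
    g: PanGraph,
    dna_profiles: Sequence[CoverageProfile],
    genes: Sequence[GeneModel] = (),
    params: DeletionParams = DeletionParams(),
) -> list[DeletionCall]:
    """Deletion scan at a 1 kb gap threshold with the exon criterion disabled.

    Genes may still be supplied so skipped-exon counts are annotated on the
    relaxed calls; they do not gate the call.
    """
    relaxed = DeletionParams(
        min_span=1_000,
        support_frac=params.support_frac,
        min_samples=params.min_samples,
        require_exon=False,
        min_exons=params.min_exons,
    )
    return call_deletions(g, dna_profiles, genes=genes, params=relaxed)
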