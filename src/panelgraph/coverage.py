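"""Per-sample segment/junction coverage from GAF alignments.

Aligned bases are attributed to segments by intersecting the record's
``[path_start, path_end)`` interval with each member segment's span on the
concatenated path; a junction between consecutive path members is counted
when the record covers at least one base on both sides. Depths are
length-normalised (bases / segment length); ``ref_mean`` is the
length-weighted mean depth over all REF_PRIMARY segments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from panelgraph.graph_model import Link, OriginClass, PanGraph, canonical_link

__all__ = [
    "GafRecord",
    "GafError",
    "CoverageProfile",
    "parse_gaf",
    "compute_profile",
    "usage_call",
    "usage_matrix",
    "origin_fractions",
    "cross_usage",
]

_PATH_STEP = re.compile(r"([><])([^><\s]+)")
_ORIENT = {">": "+", "<": "-"}


class GafError(ValueError):
    """Raised for malformed GAF input."""


@dataclass(frozen=True)
class GafRecord:
    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    path: tuple[tuple[str, str], ...]  # (segment id, +/-)
    path_length: int
    path_start: int
    path_end: int
    residue_matches: int
    block_length: int
    mapping_quality: int
    tags: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.path_start < self.path_end <= self.path_length:
            raise GafError(
                f"record {self.query_name}: path interval "
                f"[{self.path_start},{self.path_end}) outside [0,{self.path_length})"
            )


def _parse_path(raw: str, lineno: int) -> tuple[tuple[str, str], ...]:
    if not raw or raw[0] not in "><":
        raise GafError(f"line {lineno}: path column {raw!r} is not an oriented path")
    steps = _PATH_STEP.findall(raw)
    consumed = sum(1 + len(s) for _, s in steps)
    if consumed != len(raw):
        raise GafError(f"line {lineno}: malformed path column {raw!r}")
    return tuple((sid, _ORIENT[o]) for o, sid in steps)


def parse_gaf(
    path: str | Path,
    min_mapq: int = 0,
    counters: dict[str, int] | None = None,
) -> Iterator[GafRecord]:
    """Stream validated :class:`GafRecord` objects from a GAF file.

    Records below ``min_mapq`` are dropped; when ``counters`` is given it
    receives ``kept`` / ``dropped_mapq`` totals.
    """
    if counters is not None:
        counters.setdefault("kept", 0)
        counters.setdefault("dropped_mapq", 0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GafError(f"line {lineno}: expected >= 12 columns, got {len(fields)}")
            try:
                rec = GafRecord(
                    query_name=fields[0],
                    query_length=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    path=_parse_path(fields[5], lineno),
                    path_length=int(fields[6]),
                    path_start=int(fields[7]),
                    path_end=int(fields[8]),
                    residue_matches=int(fields[9]),
                    block_length=int(fields[10]),
                    mapping_quality=int(fields[11]),
                    tags={f.split(":", 2)[0]: f.split(":", 2)[2] for f in fields[12:]},
                )
            except GafError:
                raise
            except ValueError as exc:
                raise GafError(f"line {lineno}: {exc}") from exc
            if rec.mapping_quality < min_mapq:
                if counters is not None:
                    counters["dropped_mapq"] += 1
                continue
            if counters is not None:
                counters["kept"] += 1
            yield rec


@dataclass
class CoverageProfile:
    """Length-normalised segment depths and junction traversal counts for one sample."""

    sample: str
    kind: str  # "DNA" or "RNA"
    depth: dict[str, float]
    aligned_bases: dict[str, int]
    junction_counts: dict[Link, int]
    ref_mean: float

    def depth_of(self, sid: str) -> float:
        return self.depth.get(sid, 0.0)

    def junctions_of(self, link: Link) -> int:
        return self.junction_counts.get(link, 0)


def compute_profile(
    records: Iterable[GafRecord],
    g: PanGraph,
    sample: str,
    kind: str = "DNA",
    ref_mean_mode: str = "weighted",
) -> CoverageProfile:
    """Accumulate segment depths and junction counts from GAF records.

    ``ref_mean_mode`` is ``"weighted"`` (total REF_PRIMARY bases / total
    REF_PRIMARY length, the default) or ``"simple"`` (unweighted mean of
    per-segment depths over all REF_PRIMARY segments).
    """
    bases: dict[str, int] = {}
    junctions: dict[Link, int] = {}
    for rec in records:
        offset = 0
        prev: tuple[str, str] | None = None
        for sid, orient in rec.path:
            seg = g.segments.get(sid)
            if seg is None:
                raise GafError(
                    f"record {rec.query_name}: path references unknown segment {sid}"
                )
            if prev is not None:
                # junction at `offset`; traversed iff >=1 base on both sides
                if rec.path_start < offset < rec.path_end:
                    link = canonical_link(prev[0], prev[1], sid, orient)
                    junctions[link] = junctions.get(link, 0) + 1
            lo = max(rec.path_start, offset)
            hi = min(rec.path_end, offset + seg.length)
            if hi > lo:
                bases[sid] = bases.get(sid, 0) + (hi - lo)
            offset += seg.length
            prev = (sid, orient)
        if offset != rec.path_length:
            raise GafError(
                f"record {rec.query_name}: path length {rec.path_length} != "
                f"sum of segment lengths {offset}"
            )
    depth = {sid: b / g.segments[sid].length for sid, b in bases.items()}
    ref_ids = g.by_class[OriginClass.REF_PRIMARY]
    if ref_mean_mode == "weighted":
        ref_len = sum(g.segments[s].length for s in ref_ids)
        ref_mean = (
            sum(bases.get(s, 0) for s in ref_ids) / ref_len if ref_len else 0.0
        )
    elif ref_mean_mode == "simple":
        ref_mean = (
            sum(depth.get(s, 0.0) for s in ref_ids) / len(ref_ids) if ref_ids else 0.0
        )
    else:
        raise ValueError(f"unknown ref_mean_mode {ref_mean_mode!r}")
    return CoverageProfile(
        sample=sample,
        kind=kind,
        depth=depth,
        aligned_bases=bases,
        junction_counts=junctions,
        ref_mean=ref_mean,
    )


def usage_call(profile: CoverageProfile, g: PanGraph, theta: float) -> dict[str, bool]:
    """Per-segment usage: depth >= theta * sample ref_mean (inclusive)."""
    if profile.ref_mean <= 0:
        raise ValueError(
            f"sample {profile.sample}: ref_mean is 0 (no reference-aligned reads)"
        )
    cut = theta * profile.ref_mean
    return {sid: profile.depth_of(sid) >= cut for sid in g.segments}

def usage_matrix(
    profiles: Sequence[CoverageProfile], g: PanGraph, theta: float
) -> pd.DataFrame:
    """Boolean segments x samples table at threshold ``theta``."""
    cols = {p.sample: usage_call(p, g, theta) for p in profiles}
    df = pd.DataFrame(cols, index=sorted(g.segments))
    df.index.name = "segment"
    return df


def origin_fractions(profile: CoverageProfile, g: PanGraph) -> dict[OriginClass, float]:
    """Fraction of this sample's aligned bases on each origin class (sums to 1)."""
    totals: dict[OriginClass, int] = {}
    for sid, b in profile.aligned_bases.items():
        cls = g.segments[sid].origin_class
        totals[cls] = totals.get(cls, 0) + b
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError(f"sample {profile.sample}: no aligned bases")
    return {cls: b / grand for cls, b in sorted(totals.items(), key=lambda kv: kv[0].value)}


def cross_usage(
    profiles: Sequence[CoverageProfile], g: PanGraph, theta: float
) -> pd.DataFrame:
    """Aligned bases on non-REF_PRIMARY segments stratified by cross-sample usage.

    For every sample, bases on each alternative segment are binned by the
    number of samples using that segment at threshold ``theta`` (0..n).
    Row sums equal each sample's total non-REF_PRIMARY aligned bases.
    """
    if len(profiles) < 2:
        raise ValueError("cross_usage requires at least 2 samples")
    usage = usage_matrix(profiles, g, theta)
    n_users = usage.sum(axis=1)
    n = len(profiles)
    out = pd.DataFrame(
        0,
        index=[p.sample for p in profiles],
        columns=range(n + 1),
        dtype="int64",
    )
    for p in profiles:
        for sid, b in p.aligned_bases.items():
            if g.segments[sid].origin_class is OriginClass.REF_PRIMARY:
                continue
            out.loc[p.sample, int(n_users[sid])] += b
    out.index.name = "sample"
    out.columns.name = "n_samples_using"
    return out
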