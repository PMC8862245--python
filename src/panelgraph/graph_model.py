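"""Reference-GFA (rGFA) graph model.

Parses GFA1 files whose S-lines carry the rGFA ``SN`` (stable name), ``SO``
(stable offset) and ``SR`` (assembly rank) tags, assigns every segment to an
origin class via a configurable stable-name-prefix map, and provides summary
statistics, global-alignment identity and BED export on stable coordinates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OriginClass",
    "Segment",
    "Link",
    "PanGraph",
    "DivergenceRecord",
    "RgfaError",
    "parse_rgfa",
    "write_rgfa",
    "graph_stats",
    "segment_identity",
    "export_segments_bed",
    "canonical_link",
]


class RgfaError(ValueError):
    """Raised for malformed or inconsistent rGFA input."""


class OriginClass(str, enum.Enum):
    """Assembly of origin for a graph segment, derived from the stable-name prefix."""

    REF_PRIMARY = "REF_PRIMARY"
    REF_ALT_1 = "REF_ALT_1"
    REF_ALT_2 = "REF_ALT_2"
    PANEL = "PANEL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_FLIP = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class Segment:
    """A graph segment with rGFA provenance.

    ``stable_offset`` is 0-based; the segment covers
    ``[stable_offset, stable_offset + length)`` on ``stable_name``.
    """

    id: str
    length: int
    stable_name: str
    stable_offset: int
    rank: int
    origin_class: OriginClass
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise RgfaError(f"segment {self.id}: length must be >= 1, got {self.length}")
        if self.stable_offset < 0:
            raise RgfaError(f"segment {self.id}: negative stable offset")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise RgfaError(
                f"segment {self.id}: sequence length {len(self.sequence)} != LN {self.length}"
            )
        if (self.rank == 0) != (self.origin_class is OriginClass.REF_PRIMARY):
            raise RgfaError(
                f"segment {self.id}: rank {self.rank} inconsistent with "
                f"origin class {self.origin_class}"
            )

    @property
    def stable_end(self) -> int:
        return self.stable_offset + self.length


@dataclass(frozen=True, order=True)
class Link:
    """A canonical oriented edge between two segments.

    Stored once per junction: of the two equivalent traversals
    ``(a, oa) -> (b, ob)`` and ``(b, !ob) -> (a, !oa)`` the lexicographically
    smaller ``(id, orient)`` endpoint comes first, so a traversal in either
    direction maps to the same object.
    """

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str


def canonical_link(from_id: str, from_orient: str, to_id: str, to_orient: str) -> Link:
    fwd = (from_id, from_orient, to_id, to_orient)
    rev = (to_id, _FLIP[to_orient], from_id, _FLIP[from_orient])
    return Link(*min(fwd, rev))


@dataclass(frozen=True)
class DivergenceRecord:
    """Identity of a segment against the primary reference; divergence = 1 - identity."""

    segment_id: str
    identity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of [0,1]: {self.identity}")

    @property
    def divergence(self) -> float:
        return 1.0 - self.identity


@dataclass
class PanGraph:
    """Segment table, canonical link set and the derived indexes."""

    segments: dict[str, Segment] = field(default_factory=dict)
    links: set[Link] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._adjacency: dict[str, list[Link]] | None = None
        self._by_class: dict[OriginClass, list[str]] | None = None
        self._ref_by_stable: dict[str, list[Segment]] | None = None

    # -- indexes ------------------------------------------------------------

    @property
    def adjacency(self) -> dict[str, list[Link]]:
        if self._adjacency is None:
            adj: dict[str, list[Link]] = {sid: [] for sid in self.segments}
            for link in sorted(self.links):
                adj[link.from_id].append(link)
                if link.to_id != link.from_id:
                    adj[link.to_id].append(link)
            self._adjacency = adj
        return self._adjacency

    @property
    def by_class(self) -> dict[OriginClass, list[str]]:
        if self._by_class is None:
            idx: dict[OriginClass, list[str]] = {c: [] for c in OriginClass}
            for sid, seg in self.segments.items():
                idx[seg.origin_class].append(sid)
            self._by_class = idx
        return self._by_class

    @property
    def ref_by_stable(self) -> dict[str, list[Segment]]:
        """REF_PRIMARY segments per stable_name, ordered by stable_offset."""
        if self._ref_by_stable is None:
            idx: dict[str, list[Segment]] = {}
            for seg in self.segments.values():
                if seg.origin_class is OriginClass.REF_PRIMARY:
                    idx.setdefault(seg.stable_name, []).append(seg)
            for segs in idx.values():
                segs.sort(key=lambda s: s.stable_offset)
                for a, b in zip(segs, segs[1:]):
                    if b.stable_offset < a.stable_end:
                        raise RgfaError(
                            f"REF_PRIMARY segments {a.id} and {b.id} overlap on "
                            f"{a.stable_name}"
                        )
            self._ref_by_stable = idx
        return self._ref_by_stable

    def neighbours(self, sid: str) -> list[tuple[str, Link]]:
        """Adjacent segment ids (undirected view) with the shared link."""
        out = []
        for link in self.adjacency[sid]:
            other = link.to_id if link.from_id == sid else link.from_id
            out.append((other, link))
        return out

    def ref_length(self) -> int:
        return sum(
            self.segments[sid].length for sid in self.by_class[OriginClass.REF_PRIMARY]
        )


# ---------------------------------------------------------------------------
# parsing / writing


def _parse_tags(fields: Iterable[str], lineno: int) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise RgfaError(f"line {lineno}: malformed tag field {f!r}")
        tags[parts[0]] = parts[2]
    return tags


def assign_origin_class(stable_name: str, prefix_map: Mapping[str, OriginClass | str]) -> OriginClass:
    """Map a stable name onto an origin class by longest matching prefix."""
    best: tuple[int, OriginClass] | None = None
    for prefix, cls in prefix_map.items():
        if stable_name.startswith(prefix):
            cls = OriginClass(cls)
            if best is None or len(prefix) > best[0]:
                best = (len(prefix), cls)
    if best is None:
        raise RgfaError(
            f"stable name {stable_name!r} matches no prefix in the origin-class map"
        )
    return best[1]


def parse_rgfa(path: str | Path, prefix_map: Mapping[str, OriginClass | str]) -> PanGraph:
    """Parse an rGFA file into a :class:`PanGraph`.

    Parameters
    ----------
    path
        rGFA file. S-lines must carry SN/SO/SR tags; sequence may be ``*``
        if an ``LN`` tag gives the length.
    prefix_map
        Mapping of stable-name prefix to :class:`OriginClass` (or its name).
    """
    segments: dict[str, Segment] = {}
    raw_links: list[tuple[int, str, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            rec_type = fields[0]
            if rec_type == "S":
                if len(fields) < 3:
                    raise RgfaError(f"line {lineno}: S-line with fewer than 3 fields")
                sid, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:], lineno)
                for required in ("SN", "SO", "SR"):
                    if required not in tags:
                        raise RgfaError(f"line {lineno}: S-line missing {required} tag")
                if seq == "*":
                    if "LN" not in tags:
                        raise RgfaError(
                            f"line {lineno}: sequence-less S-line without LN tag"
                        )
                    sequence, length = None, int(tags["LN"])
                else:
                    sequence, length = seq.upper(), len(seq)
                try:
                    stable_offset = int(tags["SO"])
                    rank = int(tags["SR"])
                except ValueError as exc:
                    raise RgfaError(f"line {lineno}: non-integer SO/SR tag") from exc
                if sid in segments:
                    raise RgfaError(f"line {lineno}: duplicate segment id {sid}")
                stable_name = tags["SN"]
                origin = assign_origin_class(stable_name, prefix_map)
                try:
                    segments[sid] = Segment(
                        id=sid,
                        length=length,
                        stable_name=stable_name,
                        stable_offset=stable_offset,
                        rank=rank,
                        origin_class=origin,
                        sequence=sequence,
                    )
                except RgfaError as exc:
                    raise RgfaError(f"line {lineno}: {exc}") from exc
            elif rec_type == "L":
                if len(fields) < 6:
                    raise RgfaError(f"line {lineno}: L-line with fewer than 6 fields")
                fid, fo, tid, to = fields[1], fields[2], fields[3], fields[4]
                if fo not in _FLIP or to not in _FLIP:
                    raise RgfaError(f"line {lineno}: bad orientation in L-line")
                raw_links.append((lineno, fid, fo, tid, to))
            # H-lines and other record types are ignored
    links: set[Link] = set()
    for lineno, fid, fo, tid, to in raw_links:
        if fid not in segments:
            raise RgfaError(f"line {lineno}: L-line references unknown segment {fid}")
        if tid not in segments:
            raise RgfaError(f"line {lineno}: L-line references unknown segment {tid}")
        links.add(canonical_link(fid, fo, tid, to))
    return PanGraph(segments=segments, links=links)


def write_rgfa(g: PanGraph, path: str | Path) -> None:
    """Write a graph back out as rGFA (deterministic ordering)."""
    with open(path, "w") as fh:
        for sid in sorted(g.segments):
            seg = g.segments[sid]
            seq = seg.sequence if seg.sequence is not None else "*"
            fields = [
                "S",
                seg.id,
                seq,
                f"LN:i:{seg.length}",
                f"SN:Z:{seg.stable_name}",
                f"SO:i:{seg.stable_offset}",
                f"SR:i:{seg.rank}",
            ]
            fh.write("\t".join(fields) + "\n")
        for link in sorted(g.links):
            fh.write(
                f"L\t{link.from_id}\t{link.from_orient}\t{link.to_id}\t"
                f"{link.to_orient}\t0M\n"
            )


# ---------------------------------------------------------------------------
# statistics


def _n50(lengths: np.ndarray) -> int:
    lengths = np.sort(lengths)[::-1]
    half = lengths.sum() / 2.0
    cum = np.cumsum(lengths)
    return int(lengths[np.searchsorted(cum, half)])


def graph_stats(g: PanGraph) -> pd.DataFrame:
    """Per-origin-class summary: segment count, total/median/longest length, N50.

    Includes an ``All`` row whose totals are the sum over classes.
    """
    if not g.segments:
        raise ValueError("graph has no segments")
    rows = []
    all_lengths = []
    for cls in OriginClass:
        sids = g.by_class[cls]
        if not sids:
            continue
        lengths = np.array([g.segments[s].length for s in sids], dtype=np.int64)
        all_lengths.append(lengths)
        rows.append(
            {
                "origin_class": cls.value,
                "n_segments": len(lengths),
                "total_length": int(lengths.sum()),
                "median_length": float(np.median(lengths)),
                "longest": int(lengths.max()),
                "n50": _n50(lengths),
            }
        )
    lengths = np.concatenate(all_lengths)
    rows.append(
        {
            "origin_class": "All",
            "n_segments": len(lengths),
            "total_length": int(lengths.sum()),
            "median_length": float(np.median(lengths)),
            "longest": int(lengths.max()),
            "n50": _n50(lengths),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# identity


def _edit_distance_max_matches(a: str, b: str) -> tuple[int, int]:
    """Unit-cost edit distance and the max match count over min-cost alignments.

    Encodes the lexicographic pair (cost, -matches) in a single integer
    ``cost * big - matches`` so the DP vectorises row-wise.
    """
    n, m = len(a), len(b)
    big = n + m + 2
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    idx = np.arange(m + 1, dtype=np.int64)
    prev = idx * big
    for i in range(1, n + 1):
        diag_add = np.where(bb == aa[i - 1], -1, big)
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = i * big
        cand[1:] = np.minimum(prev[:-1] + diag_add, prev[1:] + big)
        # row[j] = min(cand[j], row[j-1] + big) via prefix-min with slope -big
        shifted = np.minimum.accumulate(cand - idx * big)
        prev = shifted + idx * big
    val = int(prev[m])
    q, r = divmod(-val, big)
    return -q, r


def segment_identity(seq_a: str, ref_window: str, segment_id: str = "") -> DivergenceRecord:
    """Global-alignment identity between a segment sequence and a reference window.

    Identity is ``matches / alignment_columns`` for a unit-cost (mismatch and
    indel each cost 1) global alignment that first minimises cost and then
    maximises matches; every column is either a match or a unit-cost
    operation, so columns = matches + cost. This is symmetric and
    deterministic without a traceback.
    """
    if not seq_a or not ref_window:
        raise ValueError(
            "segment_identity requires both sequences; supply segment sequences "
            "or inject precomputed DivergenceRecords"
        )
    cost, matches = _edit_distance_max_matches(seq_a.upper(), ref_window.upper())
    columns = matches + cost
    identity = matches / columns if columns else 1.0
    return DivergenceRecord(segment_id=segment_id, identity=identity, aligned_length=columns)


# ---------------------------------------------------------------------------
# export


def export_segments_bed(g: PanGraph) -> pd.DataFrame:
    """BED6 records of REF_PRIMARY segments on stable coordinates (0-based half-open)."""
    rows = []
    for stable_name in sorted(g.ref_by_stable):
        for seg in g.ref_by_stable[stable_name]:
            rows.append(
                {
                    "chrom": stable_name,
                    "start": seg.stable_offset,
                    "end": seg.stable_end,
                    "name": seg.id,
                    "score": 0,
                    "strand": "+",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
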