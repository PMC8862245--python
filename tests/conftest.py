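"""Shared fixtures and independent oracles used across the test suite.

The oracles here deliberately recompute quantities from first principles
(exhaustive enumeration, per-base counting, closed forms) so the package
implementations are checked against an independent route.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import chi2

from panelgraph.coverage import GafRecord
from panelgraph.graph_model import (
    OriginClass,
    PanGraph,
    Segment,
    canonical_link,
)


# ---------------------------------------------------------------------------
# small graphs


def make_segment(
    sid: str,
    length: int,
    offset: int = 0,
    stable: str = "refA_1",
    rank: int = 0,
    seq: str | None = None,
) -> Segment:
    origin = OriginClass.REF_PRIMARY if rank == 0 else OriginClass.PANEL
    return Segment(
        id=sid,
        length=length,
        stable_name=stable if rank == 0 else f"panel_{sid}",
        stable_offset=offset,
        rank=rank,
        origin_class=origin,
        sequence=seq,
    )


@pytest.fixture
def two_segment_graph() -> PanGraph:
    """s1 (100 bp ref) -> s2 (50 bp panel)."""
    segs = {
        "s1": make_segment("s1", 100, 0),
        "s2": make_segment("s2", 50, rank=1),
    }
    links = {canonical_link("s1", "+", "s2", "+")}
    return PanGraph(segments=segs, links=links)


def make_gaf_record(path, path_start, path_end, g: PanGraph, name="q") -> GafRecord:
    plen = sum(g.segments[s].length for s, _ in path)
    span = path_end - path_start
    return GafRecord(
        query_name=name,
        query_length=span,
        query_start=0,
        query_end=span,
        strand="+",
        path=tuple(path),
        path_length=plen,
        path_start=path_start,
        path_end=path_end,
        residue_matches=span,
        block_length=span,
        mapping_quality=60,
    )


# ---------------------------------------------------------------------------
# brute-force coverage oracle


def brute_force_profile(records, g: PanGraph):
    """Per-base depth counter and per-traversal junction counter."""
    per_base = {sid: np.zeros(seg.length, dtype=np.int64) for sid, seg in g.segments.items()}
    junctions: dict = {}
    for rec in records:
        offset = 0
        prev = None
        for sid, orient in rec.path:
            seg = g.segments[sid]
            if prev is not None and rec.path_start < offset < rec.path_end:
                link = canonical_link(prev[0], prev[1], sid, orient)
                junctions[link] = junctions.get(link, 0) + 1
            for p in range(seg.length):
                if rec.path_start <= offset + p < rec.path_end:
                    per_base[sid][p] += 1
            offset += seg.length
            prev = (sid, orient)
    depth = {
        sid: arr.sum() / len(arr) for sid, arr in per_base.items() if arr.sum() > 0
    }
    return depth, junctions


def random_graph_and_records(rng: np.random.Generator, max_segments=50, max_records=200):
    """A random small graph plus GAF records over random oriented paths."""
    n_seg = int(rng.integers(2, max_segments + 1))
    segs = {}
    offset = 0
    for i in range(n_seg):
        length = int(rng.integers(1, 51))
        rank = 0 if rng.random() < 0.6 else 1
        sid = f"g{i:03d}"
        segs[sid] = make_segment(sid, length, offset=offset if rank == 0 else 0, rank=rank)
        if rank == 0:
            offset += length
    ids = sorted(segs)
    g = PanGraph(segments=segs, links=set())
    n_rec = int(rng.integers(0, max_records + 1))
    records = []
    for r in range(n_rec):
        k = int(rng.integers(1, 5))
        path = [
            (ids[int(rng.integers(0, len(ids)))], "+-"[int(rng.integers(0, 2))])
            for _ in range(k)
        ]
        plen = sum(segs[s].length for s, _ in path)
        ps = int(rng.integers(0, plen))
        pe = int(rng.integers(ps + 1, plen + 1))
        records.append(make_gaf_record(path, ps, pe, g, name=f"r{r}"))
    return g, records


# ---------------------------------------------------------------------------
# alignment-identity oracle (exhaustive, for short sequences)


def identity_oracle(a: str, b: str) -> float:
    """Enumerate all global alignments; min cost first, then max matches.

    identity = matches / (matches + cost) for the selected alignment.
    """
    best: dict[tuple[int, int], set[tuple[int, int]]] = {}

    def rec(i, j, cost, matches):
        if i == len(a) and j == len(b):
            best.setdefault((cost, matches), set()).add((cost, matches))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cost + (a[i] != b[j]), matches + (a[i] == b[j]))
        if i < len(a):
            rec(i + 1, j, cost + 1, matches)
        if j < len(b):
            rec(i, j + 1, cost + 1, matches)

    rec(0, 0, 0, 0)
    min_cost = min(c for c, _ in best)
    max_match = max(m for c, m in best if c == min_cost)
    denom = max_match + min_cost
    return max_match / denom if denom else 1.0


# ---------------------------------------------------------------------------
# rank-statistic oracles


def ranks_with_ties(values: np.ndarray) -> np.ndarray:
    """Average ranks, computed directly from sorted positions."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """H statistic with tie correction plus chi-squared p-value, from the formula."""
    values = np.concatenate(groups)
    n_total = len(values)
    ranks = ranks_with_ties(values)
    h = 0.0
    pos = 0
    for grp in groups:
        r = ranks[pos : pos + len(grp)]
        h += len(grp) * (r.mean() - (n_total + 1) / 2.0) ** 2
        pos += len(grp)
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(values, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    if tie_term == 0:
        return 0.0, 1.0
    h /= tie_term
    p = float(chi2.sf(h, len(groups) - 1))
    return float(h), p


def bh_oracle(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH by the literal definition: q_i = min over p_(j) >= p_i of m p_(j)/j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rank_of = np.empty(m, dtype=int)
    rank_of[order] = np.arange(1, m + 1)
    q = np.empty(m, dtype=float)
    for i in range(m):
        candidates = [
            m * p[j] / rank_of[j] for j in range(m) if rank_of[j] >= rank_of[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


def compositions(n: int, min_parts: int = 2):
    """All ordered splits of n observations into >= min_parts non-empty groups."""
    for k in range(min_parts, n + 1):
        for cut in itertools.combinations(range(1, n), k - 1):
            bounds = (0, *cut, n)
            yield [bounds[i + 1] - bounds[i] for i in range(k)]
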