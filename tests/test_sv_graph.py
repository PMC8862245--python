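import numpy as np
import pytest

from panelgraph.coverage import CoverageProfile, compute_profile, parse_gaf
from panelgraph.graph_model import PanGraph, canonical_link, parse_rgfa
from panelgraph.sv_graph import (
    AltPathParams,
    DeletionParams,
    call_alt_paths,
    call_deletions,
    enumerate_alt_paths,
    relaxed_deletion_scan,
)
from panelgraph.synthetic_data import (
    DEFAULT_PREFIX_MAP,
    EventSpec,
    SimConfig,
    simulate_gaf_lines,
    simulate_graph,
)

from conftest import make_segment


def diamond(n_branches=1, cyclic=False):
    """ref1 -> (alt_i)* -> ref2 bubble graph."""
    segs = {
        "ref1": make_segment("ref1", 100, 0),
        "ref2": make_segment("ref2", 100, 5_000),
    }
    links = set()
    for i in range(n_branches):
        aid = f"alt{i}"
        segs[aid] = make_segment(aid, 50, rank=1)
        links.add(canonical_link("ref1", "+", aid, "+"))
        links.add(canonical_link(aid, "+", "ref2", "+"))
    if cyclic:
        segs["altx"] = make_segment("altx", 10, rank=1)
        links.add(canonical_link("alt0", "+", "altx", "+"))
        links.add(canonical_link("altx", "+", "alt0", "+"))
    return PanGraph(segments=segs, links=links)


class TestEnumerateAltPaths:
    def test_diamond_single_path(self):
        cands, truncated = enumerate_alt_paths(diamond())
        assert not truncated
        assert len(cands) == 1
        assert cands[0].members == ("alt0",)

    def test_nested_two_branches(self):
        cands, _ = enumerate_alt_paths(diamond(n_branches=2))
        assert {c.members for c in cands} == {("alt0",), ("alt1",)}

    def test_exhaustive_against_dfs_oracle(self):
        # 7-segment toy: two anchors, chains alt0-alt1 and alt2, plus a spur
        segs = {
            "r1": make_segment("r1", 10, 0),
            "r2": make_segment("r2", 10, 100),
            "a0": make_segment("a0", 5, rank=1),
            "a1": make_segment("a1", 5, rank=1),
            "a2": make_segment("a2", 5, rank=1),
            "a3": make_segment("a3", 5, rank=1),  # dead-end spur
        }
        links = {
            canonical_link("r1", "+", "a0", "+"),
            canonical_link("a0", "+", "a1", "+"),
            canonical_link("a1", "+", "r2", "+"),
            canonical_link("r1", "+", "a2", "+"),
            canonical_link("a2", "+", "r2", "+"),
            canonical_link("a0", "+", "a3", "+"),
        }
        g = PanGraph(segments=segs, links=links)
        cands, _ = enumerate_alt_paths(g)
        assert {c.members for c in cands} == {("a0", "a1"), ("a2",)}

    def test_cycle_terminates_with_simple_paths(self):
        cands, truncated = enumerate_alt_paths(diamond(cyclic=True))
        assert not truncated
        members = {c.members for c in cands}
        assert ("alt0",) in members
        for m in members:
            assert len(set(m)) == len(m)

    def test_deterministic_order(self):
        g = diamond(n_branches=3)
        first, _ = enumerate_alt_paths(g)
        second, _ = enumerate_alt_paths(g)
        assert first == second

    def test_truncation_flagged(self):
        cands, truncated = enumerate_alt_paths(diamond(n_branches=5), max_paths=2)
        assert truncated
        assert len(cands) >= 2


def _mock_profile(sample, depths, ref_mean=20.0, junctions=None, kind="DNA"):
    return CoverageProfile(
        sample=sample,
        kind=kind,
        depth=depths,
        aligned_bases={},
        junction_counts=junctions or {},
        ref_mean=ref_mean,
    )


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(
        seed=21,
        events=(
            EventSpec("alt"),
            EventSpec("alt", "length"),
            EventSpec("alt", "divergence"),
            EventSpec("alt", "dna"),
            EventSpec("alt", "rna"),
            EventSpec("alt", "exon"),
            EventSpec("deletion"),
            EventSpec("deletion", "span"),
            EventSpec("deletion", "support"),
            EventSpec("deletion", "exon"),
        ),
    )
    sim = simulate_graph(cfg)
    dna_lines, rna_lines = simulate_gaf_lines(sim)

    def profiles(lines_by_sample, kind, tmp):
        out = []
        for sample, lines in lines_by_sample.items():
            p = tmp / f"{sample}.{kind}.gaf"
            p.write_text("\n".join(lines) + "\n")
            out.append(compute_profile(parse_gaf(p), sim.graph, sample, kind))
        return out

    import tempfile
    from pathlib import Path

    tmp = Path(tempfile.mkdtemp())
    dna = profiles(dna_lines, "DNA", tmp)
    rna = profiles(rna_lines, "RNA", tmp)
    return sim, dna, rna


class TestCallAltPaths:
    def test_planted_recovery(self, planted):
        sim, dna, rna = planted
        cands, _ = enumerate_alt_paths(sim.graph)
        calls = call_alt_paths(cands, sim.divergences, dna, rna, sim.genes, sim.graph)
        got = {(c.left_anchor, c.members, c.right_anchor) for c in calls}
        want = {
            (t["left_anchor"], tuple(t["members"]), t["right_anchor"])
            for t in sim.alt_truth
            if t["qualifying"]
        }
        assert got == want

    def test_length_threshold_excludes(self, planted):
        sim, dna, rna = planted
        decoy = next(t for t in sim.alt_truth if t["violation"] == "length")
        cands, _ = enumerate_alt_paths(sim.graph)
        calls = call_alt_paths(cands, sim.divergences, dna, rna, sim.genes, sim.graph)
        assert all(c.members != tuple(decoy["members"]) for c in calls)
        # ...but passes when the length threshold is relaxed below its size
        relaxed = call_alt_paths(
            cands, sim.divergences, dna, rna, sim.genes, sim.graph,
            AltPathParams(min_length=5_000),
        )
        assert any(c.members == tuple(decoy["members"]) for c in relaxed)

    def test_divergence_threshold_excludes(self, planted):
        sim, dna, rna = planted
        decoy = next(t for t in sim.alt_truth if t["violation"] == "divergence")
        cands, _ = enumerate_alt_paths(sim.graph)
        calls = call_alt_paths(cands, sim.divergences, dna, rna, sim.genes, sim.graph)
        assert all(c.members != tuple(decoy["members"]) for c in calls)

    def test_missing_divergence_errors(self, planted):
        sim, dna, rna = planted
        cands, _ = enumerate_alt_paths(sim.graph)
        divs = dict(sim.divergences)
        dropped = next(iter(divs))
        del divs[dropped]
        with pytest.raises(ValueError, match=dropped):
            call_alt_paths(cands, divs, dna, rna, sim.genes, sim.graph)

    def test_threshold_monotonicity(self, planted):
        sim, dna, rna = planted
        cands, _ = enumerate_alt_paths(sim.graph)
        strict = call_alt_paths(cands, sim.divergences, dna, rna, sim.genes, sim.graph)
        loose = call_alt_paths(
            cands, sim.divergences, dna, rna, sim.genes, sim.graph,
            AltPathParams(min_length=8_000, min_divergence=0.25, dna_min_samples=1,
                          rna_min_samples=4),
        )
        strict_keys = {(c.left_anchor, c.members) for c in strict}
        loose_keys = {(c.left_anchor, c.members) for c in loose}
        assert strict_keys <= loose_keys

    def test_sample_order_invariance(self, planted):
        sim, dna, rna = planted
        cands, _ = enumerate_alt_paths(sim.graph)
        a = call_alt_paths(cands, sim.divergences, dna, rna, sim.genes, sim.graph)
        b = call_alt_paths(
            cands, sim.divergences, dna[::-1], rna[::-1], sim.genes, sim.graph
        )
        assert a == b


class TestCallDeletions:
    def test_gap_arithmetic(self):
        segs = {
            "u": make_segment("u", 500, 1_000),
            "v": make_segment("v", 100, 20_000),
        }
        links = {canonical_link("u", "+", "v", "+")}
        g = PanGraph(segments=segs, links=links)
        profiles = [
            _mock_profile(f"S{i}", {}, junctions={canonical_link("u", "+", "v", "+"): 15})
            for i in range(12)
        ]
        calls = call_deletions(g, profiles, genes=(), params=DeletionParams(require_exon=False))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end, calls[0].span) == (1_500, 20_000, 18_500)

    def test_planted_recovery_with_exon_count(self, planted):
        sim, dna, _ = planted
        calls = call_deletions(sim.graph, dna, sim.genes)
        got = {(c.start, c.end) for c in calls}
        want = {(t["start"], t["end"]) for t in sim.del_truth if t["qualifying"]}
        assert got == want
        assert all(c.exons_skipped >= 1 for c in calls)

    def test_low_support_excluded(self, planted):
        sim, dna, _ = planted
        decoy = next(t for t in sim.del_truth if t["violation"] == "support")
        calls = call_deletions(sim.graph, dna, sim.genes)
        assert (decoy["start"], decoy["end"]) not in {(c.start, c.end) for c in calls}

    def test_inversion_like_links_counted_separately(self):
        segs = {
            "u": make_segment("u", 500, 1_000),
            "v": make_segment("v", 100, 20_000),
        }
        links = {canonical_link("u", "+", "v", "-")}
        g = PanGraph(segments=segs, links=links)
        counters = {}
        calls = call_deletions(
            g, [_mock_profile("S", {})], genes=(),
            params=DeletionParams(require_exon=False), counters=counters,
        )
        assert calls == []
        assert counters["inversion_like"] == 1


class TestRelaxedScan:
    def test_strict_subset_of_filtered_relaxed(self, planted):
        sim, dna, _ = planted
        strict = call_deletions(sim.graph, dna, sim.genes)
        relaxed = relaxed_deletion_scan(sim.graph, dna, sim.genes)
        filtered = {
            (c.start, c.end)
            for c in relaxed
            if c.span > 10_000 and c.exons_skipped >= 1
        }
        assert {(c.start, c.end) for c in strict} <= filtered

    def test_short_exonless_deletion_only_in_relaxed(self, planted):
        sim, dna, _ = planted
        span_decoy = next(t for t in sim.del_truth if t["violation"] == "span")
        strict = {(c.start, c.end) for c in call_deletions(sim.graph, dna, sim.genes)}
        relaxed = {
            (c.start, c.end) for c in relaxed_deletion_scan(sim.graph, dna, sim.genes)
        }
        key = (span_decoy["start"], span_decoy["end"])
        assert key in relaxed and key not in strict

    def test_empty_profiles_empty_calls(self, planted):
        sim, _, _ = planted
        empty = [_mock_profile(f"S{i}", {}, ref_mean=10.0) for i in range(12)]
        assert relaxed_deletion_scan(sim.graph, empty) == []
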