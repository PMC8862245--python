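import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelgraph.coverage import (
    GafError,
    compute_profile,
    cross_usage,
    origin_fractions,
    parse_gaf,
    usage_call,
    usage_matrix,
)
from panelgraph.graph_model import OriginClass, PanGraph, canonical_link

from conftest import (
    brute_force_profile,
    make_gaf_record,
    make_segment,
    random_graph_and_records,
)


def write_gaf(tmp_path, rows):
    path = tmp_path / "t.gaf"
    path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + ("\n" if rows else ""))
    return path


GAF_ROW = ["q1", 100, 0, 100, "+", ">s1<s2", 150, 0, 100, 100, 100, 60]


class TestParseGaf:
    def test_path_orientation_syntax(self, tmp_path):
        recs = list(parse_gaf(write_gaf(tmp_path, [GAF_ROW])))
        assert recs[0].path == (("s1", "+"), ("s2", "-"))

    def test_empty_file(self, tmp_path):
        counters = {}
        recs = list(parse_gaf(write_gaf(tmp_path, []), counters=counters))
        assert recs == []
        assert counters == {"kept": 0, "dropped_mapq": 0}

    def test_mapq_filter_counted(self, tmp_path):
        low = list(GAF_ROW)
        low[11] = 3
        counters = {}
        recs = list(parse_gaf(write_gaf(tmp_path, [GAF_ROW, low]), min_mapq=10, counters=counters))
        assert len(recs) == 1
        assert counters == {"kept": 1, "dropped_mapq": 1}

    def test_malformed_path_names_line(self, tmp_path):
        bad = list(GAF_ROW)
        bad[5] = "s1s2"
        with pytest.raises(GafError, match="line 1"):
            list(parse_gaf(write_gaf(tmp_path, [bad])))

    def test_interval_validation(self, tmp_path):
        bad = list(GAF_ROW)
        bad[8] = 400  # path_end beyond path_length
        with pytest.raises(GafError):
            list(parse_gaf(write_gaf(tmp_path, [bad])))


class TestComputeProfile:
    def test_full_span(self, two_segment_graph):
        rec = make_gaf_record([("s1", "+"), ("s2", "+")], 0, 150, two_segment_graph)
        prof = compute_profile([rec], two_segment_graph, "S", "DNA")
        assert prof.depth_of("s1") == pytest.approx(1.0)
        assert prof.depth_of("s2") == pytest.approx(1.0)
        assert prof.junctions_of(canonical_link("s1", "+", "s2", "+")) == 1

    def test_partial_span(self, two_segment_graph):
        rec = make_gaf_record([("s1", "+"), ("s2", "+")], 50, 150, two_segment_graph)
        prof = compute_profile([rec], two_segment_graph, "S", "DNA")
        assert prof.depth_of("s1") == pytest.approx(0.5)
        assert prof.depth_of("s2") == pytest.approx(1.0)

    def test_linearity(self, two_segment_graph):
        recs = [
            make_gaf_record([("s1", "+"), ("s2", "+")], 0, 150, two_segment_graph, name=f"q{i}")
            for i in range(10)
        ]
        prof = compute_profile(recs, two_segment_graph, "S", "DNA")
        assert prof.depth_of("s1") == pytest.approx(10.0)
        assert prof.junctions_of(canonical_link("s1", "+", "s2", "+")) == 10

    def test_junction_requires_base_on_both_sides(self, two_segment_graph):
        rec = make_gaf_record([("s1", "+"), ("s2", "+")], 0, 100, two_segment_graph)
        prof = compute_profile([rec], two_segment_graph, "S", "DNA")
        assert prof.junction_counts == {}

    def test_unknown_segment_errors(self, two_segment_graph):
        rec = make_gaf_record([("s1", "+")], 0, 50, two_segment_graph)
        object.__setattr__(rec, "path", (("zz", "+"),))
        with pytest.raises(GafError, match="zz"):
            compute_profile([rec], two_segment_graph, "S", "DNA")

    def test_ref_mean_is_length_weighted(self):
        segs = {
            "r1": make_segment("r1", 100, 0),
            "r2": make_segment("r2", 300, 100),
        }
        g = PanGraph(segments=segs)
        rec = make_gaf_record([("r1", "+")], 0, 100, g)
        prof = compute_profile([rec], g, "S", "DNA")
        assert prof.ref_mean == pytest.approx(100 / 400)
        simple = compute_profile([rec], g, "S", "DNA", ref_mean_mode="simple")
        assert simple.ref_mean == pytest.approx((1.0 + 0.0) / 2)

    def test_oracle_equivalence_small(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g, records = random_graph_and_records(rng, max_segments=12, max_records=40)
            prof = compute_profile(records, g, "S", "DNA")
            odepth, ojunc = brute_force_profile(records, g)
            assert set(prof.depth) == set(odepth)
            for sid, d in odepth.items():
                assert prof.depth[sid] == pytest.approx(d, abs=1e-9)
            assert prof.junction_counts == ojunc

    def test_conservation(self):
        rng = np.random.default_rng(6)
        g, records = random_graph_and_records(rng, max_segments=20, max_records=60)
        prof = compute_profile(records, g, "S", "DNA")
        lhs = sum(prof.depth[s] * g.segments[s].length for s in prof.depth)
        rhs = sum(r.path_end - r.path_start for r in records)
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_junctions_invariant_under_path_reversal(self):
        rng = np.random.default_rng(7)
        g, records = random_graph_and_records(rng, max_segments=10, max_records=30)
        flip = {"+": "-", "-": "+"}
        reversed_records = [
            make_gaf_record(
                [(s, flip[o]) for s, o in reversed(r.path)],
                r.path_length - r.path_end,
                r.path_length - r.path_start,
                g,
                name=r.query_name,
            )
            for r in records
        ]
        fwd = compute_profile(records, g, "S", "DNA")
        rev = compute_profile(reversed_records, g, "S", "DNA")
        assert fwd.junction_counts == rev.junction_counts


class TestUsage:
    def _profile(self, g, depth_s2):
        rec_ref = make_gaf_record([("s1", "+")], 0, 100, g)
        recs = [rec_ref]
        span = int(depth_s2 * 50)
        if span:
            recs.append(make_gaf_record([("s2", "+")], 0, span, g, name="alt"))
        return compute_profile(recs, g, "S", "DNA")

    def test_threshold_5pct(self, two_segment_graph):
        prof = self._profile(two_segment_graph, 0.06)
        used = usage_call(prof, two_segment_graph, 0.05)
        assert used["s2"]

    def test_threshold_10pct(self, two_segment_graph):
        prof = self._profile(two_segment_graph, 0.06)
        used = usage_call(prof, two_segment_graph, 0.10)
        assert not used["s2"]

    def test_boundary_inclusive(self, two_segment_graph):
        prof = self._profile(two_segment_graph, 0.0)
        prof.depth["s2"] = 0.05 * prof.ref_mean
        assert usage_call(prof, two_segment_graph, 0.05)["s2"]

    def test_zero_ref_mean_errors(self, two_segment_graph):
        rec = make_gaf_record([("s2", "+")], 0, 50, two_segment_graph)
        prof = compute_profile([rec], two_segment_graph, "S", "DNA")
        with pytest.raises(ValueError, match="ref_mean"):
            usage_call(prof, two_segment_graph, 0.05)

    @given(st.lists(st.floats(0.01, 0.5), min_size=2, max_size=6, unique=True))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_theta(self, thetas):
        g = PanGraph(
            segments={
                "s1": make_segment("s1", 100, 0),
                "s2": make_segment("s2", 50, rank=1),
            }
        )
        recs = [
            make_gaf_record([("s1", "+")], 0, 100, g),
            make_gaf_record([("s2", "+")], 0, 10, g, name="b"),
        ]
        prof = compute_profile(recs, g, "S", "DNA")
        prev_used = None
        for theta in sorted(thetas):
            used = {s for s, u in usage_call(prof, g, theta).items() if u}
            if prev_used is not None:
                assert used <= prev_used
            prev_used = used


class TestOriginFractions:
    def test_all_ref(self, two_segment_graph):
        rec = make_gaf_record([("s1", "+")], 0, 100, two_segment_graph)
        prof = compute_profile([rec], two_segment_graph, "S", "DNA")
        assert origin_fractions(prof, two_segment_graph) == {OriginClass.REF_PRIMARY: 1.0}

    def test_85_15_split(self, two_segment_graph):
        recs = [
            make_gaf_record([("s1", "+")], 0, 85, two_segment_graph),
            make_gaf_record([("s2", "+")], 0, 15, two_segment_graph, name="b"),
        ]
        prof = compute_profile(recs, two_segment_graph, "S", "DNA")
        fr = origin_fractions(prof, two_segment_graph)
        assert fr[OriginClass.REF_PRIMARY] == pytest.approx(0.85)
        assert fr[OriginClass.PANEL] == pytest.approx(0.15)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        g, records = random_graph_and_records(rng, max_segments=15, max_records=50)
        prof = compute_profile(records, g, "S", "DNA")
        if prof.aligned_bases:
            assert sum(origin_fractions(prof, g).values()) == pytest.approx(1.0)


class TestCrossUsage:
    def _panel(self):
        g = PanGraph(
            segments={
                "r": make_segment("r", 100, 0),
                "shared": make_segment("shared", 50, rank=1),
                "private": make_segment("private", 50, rank=1),
            }
        )
        profiles = []
        for i in range(3):
            recs = [make_gaf_record([("r", "+")], 0, 100, g, name="ref")]
            recs.append(make_gaf_record([("shared", "+")], 0, 50, g, name="sh"))
            if i == 0:
                recs.append(make_gaf_record([("private", "+")], 0, 50, g, name="pv"))
            profiles.append(compute_profile(recs, g, f"S{i}", "DNA"))
        return g, profiles

    def test_shared_segment_stratum(self):
        g, profiles = self._panel()
        xu = cross_usage(profiles, g, 0.05)
        for p in profiles:
            assert xu.loc[p.sample, 3] == 50

    def test_private_segment_stratum(self):
        g, profiles = self._panel()
        xu = cross_usage(profiles, g, 0.05)
        assert xu.loc["S0", 1] == 50
        assert xu.loc["S1", 1] == 0

    def test_row_sums_match_non_ref_bases(self):
        g, profiles = self._panel()
        xu = cross_usage(profiles, g, 0.05)
        for p in profiles:
            non_ref = sum(
                b
                for sid, b in p.aligned_bases.items()
                if g.segments[sid].origin_class is not OriginClass.REF_PRIMARY
            )
            assert xu.loc[p.sample].sum() == non_ref

    def test_requires_two_samples(self, two_segment_graph):
        rec = make_gaf_record([("s1", "+")], 0, 100, two_segment_graph)
        prof = compute_profile([rec], two_segment_graph, "S", "DNA")
        with pytest.raises(ValueError):
            cross_usage([prof], two_segment_graph, 0.05)
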