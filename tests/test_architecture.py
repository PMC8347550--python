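import pytest

from forktrap.architecture import (
    OrientedSite,
    TrapUndefinedError,
    arithmetic_midpoint,
    blocking_direction,
    compare_to_reference,
    dif_in_trap,
    find_innermost_trap,
    inner_span_percent,
    replichore_percent,
)
from forktrap.genome_io import CircularGenome
from forktrap.motif_scan import MotifHit
from forktrap.pipeline import analyze_genome
from forktrap.synthetic_data import build_template

from oracle_utils import fork_walk_expected


def geom(length, oric=0):
    return CircularGenome(name="geom", sequence="A" * length, oric_position=oric)


def site(name, start, blocks, functional="active"):
    return OrientedSite(name=name, start=start,
                        strand="+" if blocks == "cw" else "-",
                        blocks=blocks, functional=functional)


def dif_hit(start, strand="-"):
    return MotifHit(query_name="dif", start=start, strand=strand, mismatch_count=0,
                    mismatch_positions=frozenset(), matched_sequence="A" * 27, span=27)


class TestMidpointAndReplichores:
    @pytest.mark.parametrize("length,oric,expected", [(100, 0, 50), (100, 80, 30), (101, 0, 50)])
    def test_arithmetic_midpoint(self, length, oric, expected):
        assert arithmetic_midpoint(geom(length, oric)) == expected

    def test_oric_is_100_percent(self):
        _, pct = replichore_percent(30, geom(1000, oric=30))
        assert pct == 100.0

    def test_midpoint_is_0_percent(self):
        g = geom(1000, oric=30)
        _, pct = replichore_percent(arithmetic_midpoint(g), g)
        assert pct == 0.0

    def test_quarter_point(self):
        repl, pct = replichore_percent(250, geom(1000, oric=0))
        assert (repl, pct) == ("cw", 50.0)

    def test_ccw_side(self):
        repl, pct = replichore_percent(750, geom(1000, oric=0))
        assert (repl, pct) == ("ccw", 50.0)


class TestBlockingDirection:
    def test_default_convention(self):
        assert blocking_direction("+") == "cw"
        assert blocking_direction("-") == "ccw"

    def test_flipped_convention(self):
        assert blocking_direction("+", "plus-blocks-ccw") == "ccw"
        assert blocking_direction("-", "plus-blocks-ccw") == "cw"

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            blocking_direction("+", "nonsense")


class TestForkWalk:
    def test_simple_construction(self):
        g = geom(1000, oric=0)
        sites = [site("x", 600, "cw"), site("y", 400, "ccw")]
        trap = find_innermost_trap(sites, g, dif=dif_hit(500))
        assert trap.cw_boundary.name == "x" and trap.ccw_boundary.name == "y"
        assert trap.trap_intact and trap.inner_span_bp == 200
        assert trap.dif_in_trap is True

    def test_no_cw_blocker(self):
        g = geom(1000, oric=0)
        trap = find_innermost_trap([site("y", 400, "ccw")], g)
        assert not trap.trap_intact and trap.cw_boundary is None
        assert trap.inner_span_bp is None

    def test_empty_site_list(self):
        trap = find_innermost_trap([], geom(1000))
        assert not trap.trap_intact

    def test_likely_inactive_excluded_from_walk(self):
        g = geom(1000, oric=0)
        sites = [site("dead", 550, "cw", functional="likely_inactive"), site("x", 600, "cw"),
                 site("y", 400, "ccw")]
        trap = find_innermost_trap(sites, g)
        assert trap.cw_boundary.name == "x"

    def test_secondary_sites_excluded_by_default(self):
        g = geom(1000, oric=0)
        sites = [site("terY", 950, "ccw"), site("x", 600, "cw"), site("y", 400, "ccw")]
        trap = find_innermost_trap(sites, g)
        assert trap.ccw_boundary.name == "y"

    def test_template_matches_independent_fork_walk(self, mg_like, queries):
        genome, manifest = mg_like
        analysis = analyze_genome(genome, queries)
        expected = fork_walk_expected(manifest)
        assert analysis.trap.cw_boundary.name == expected["cw_boundary"]
        assert analysis.trap.ccw_boundary.name == expected["ccw_boundary"]
        assert analysis.trap.trap_intact == expected["trap_intact"]
        # every non-boundary primary site lies behind its boundary
        L = genome.length
        oric = genome.oric_position
        cw_d = (analysis.trap.cw_boundary.start - oric) % L
        for s in analysis.trap.sites:
            if s.blocks == "cw" and s.name not in ("terK", "terL", "terY", "terZ"):
                assert (s.start - oric) % L >= cw_d


class TestDifInTrap:
    def test_between_boundaries(self):
        g = geom(1000, oric=0)
        trap = find_innermost_trap([site("x", 600, "cw"), site("y", 400, "ccw")], g)
        assert dif_in_trap(trap, dif_hit(500), g) is True

    def test_outside_boundaries(self):
        g = geom(1000, oric=0)
        trap = find_innermost_trap([site("x", 600, "cw"), site("y", 400, "ccw")], g)
        assert dif_in_trap(trap, dif_hit(700), g) is False

    def test_undefined_without_trap(self):
        g = geom(1000, oric=0)
        trap = find_innermost_trap([site("y", 400, "ccw")], g)
        with pytest.raises(TrapUndefinedError):
            dif_in_trap(trap, dif_hit(500), g)

    def test_flipped_terc_template(self, queries):
        genome, manifest = build_template("flipped_terC", length=120_000, seed=4)
        analysis = analyze_genome(genome, queries)
        trap = analysis.trap
        assert trap.trap_intact
        assert {trap.cw_boundary.name, trap.ccw_boundary.name} == {"terB", "terC"}
        assert trap.dif_in_trap is True


class TestInnerSpanPercent:
    def test_table_row_arithmetic(self):
        assert round(inner_span_percent(238_000, 5_528_000), 2) == 4.31

    def test_half_genome(self):
        assert inner_span_percent(500, 1000) == 50.0

    def test_rounded_kb_inputs(self):
        assert round(inner_span_percent(267_000, 4_641_000), 2) == 5.75

    def test_trap_report_form(self):
        g = geom(1000, oric=0)
        trap = find_innermost_trap([site("x", 600, "cw"), site("y", 400, "ccw")], g)
        assert inner_span_percent(trap) == 20.0

    def test_not_intact_raises(self):
        trap = find_innermost_trap([], geom(1000))
        with pytest.raises(TrapUndefinedError):
            inner_span_percent(trap)


class TestCompareToReference:
    def test_identical_reports_empty_diff(self, mg_like, queries):
        genome, _ = mg_like
        trap = analyze_genome(genome, queries).trap
        diff = compare_to_reference(trap, trap)
        assert diff.is_empty

    def test_flipped_terc_signature(self, queries):
        ref_g, _ = build_template("mg1655_like", length=120_000, seed=4)
        tgt_g, _ = build_template("flipped_terC", length=120_000, seed=4)
        ref = analyze_genome(ref_g, queries).trap
        tgt = analyze_genome(tgt_g, queries).trap
        diff = compare_to_reference(tgt, ref)
        flipped = {d.name for d in diff.site_diffs if d.orientation_flipped}
        assert flipped == {"terC"}
        assert diff.dif_neighbours_changed is True
        assert set(diff.dif_neighbours_reference) == {"terA", "terC"}
        assert set(diff.dif_neighbours_target) == {"terC", "terB"}
        # dif keeps its strand: the terC + dif "same strand" signature
        assert diff.dif_strand_changed is False

    def test_inner_inversion_detected_as_block(self, queries):
        ref_g, _ = build_template("mg1655_like", length=120_000, seed=4)
        inv_g, _ = build_template("inner_inverted", length=120_000, seed=4)
        ref = analyze_genome(ref_g, queries).trap
        tgt = analyze_genome(inv_g, queries).trap
        assert ref.trap_intact and tgt.trap_intact
        diff = compare_to_reference(tgt, ref)
        assert ["terA", "terC"] in diff.block_inversions

    def test_no_shared_sites(self, mg_like, queries):
        genome, _ = mg_like
        trap = analyze_genome(genome, queries).trap
        import dataclasses

        empty = dataclasses.replace(trap, sites=[])
        with pytest.raises(ValueError):
            compare_to_reference(trap, empty)
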