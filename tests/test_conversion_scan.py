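import itertools

import numpy as np
import pytest

from xyconv.alignio import Interval, read_species_tree
from xyconv.distances import WindowSpec
from xyconv.njphylo import (
    MIXED,
    RECIPROCAL_MONOPHYLY,
    SPECIES_PAIRING,
    UNRESOLVED,
    TopologyCall,
)
from xyconv.conversion_scan import (
    ConversionEvent,
    X_TO_Y,
    Y_TO_X,
    _minimal_branch_cover,
    infer_direction,
    locate_breakpoint,
    map_events,
    scan_topologies,
    segment_subregions,
)
from xyconv.synthsim import ConversionSpec, SimConfig, make_paper_fixture, simulate
from conftest import make_alignment


def call(kind, *groups):
    return TopologyCall(kind, tuple(frozenset(g) for g in groups))


def with_intervals(calls, width=500, step=400):
    return [
        (Interval(i * step, i * step + width), c) for i, c in enumerate(calls)
    ]


class TestScanTopologies:
    def test_null_region_all_reciprocal_monophyly(self, null_fixture):
        aln, _ = null_fixture
        calls = scan_topologies(aln, WindowSpec.from_overlap(500, 100), n_reps=100, seed=3)
        assert all(c.call == RECIPROCAL_MONOPHYLY for _, c in calls)

    def test_single_tract_pairs_only_overlapping_windows(self):
        cfg = SimConfig(
            seq_length=9000,
            sample_plan={
                "nwm": {"X": 1},
                "rhesus": {"X": 1, "Y": 1},
                "human": {"X": 1, "Y": 1},
                "chimp": {"X": 1, "Y": 1},
            },
            conversions=[ConversionSpec(frozenset(["rhesus"]), 12.0, 3000, 6000, Y_TO_X)],
        )
        aln, truth = simulate(cfg, seed=21)
        spec = WindowSpec.from_overlap(500, 100)
        calls = scan_topologies(aln, spec, n_reps=100, seed=4)
        paired = [iv for iv, c in calls if "rhesus" in c.paired_species]
        overlapping = [iv for iv, _ in calls if iv.overlaps(Interval(3000, 6000))]
        # paired windows are exactly the tract-overlapping ones, +-1 window
        assert paired
        assert set(paired) <= set(overlapping)
        inner = [iv for iv in overlapping[1:-1]]
        missed = [iv for iv in inner if iv not in paired]
        assert len(missed) <= 1

    def test_scan_requires_two_xy_species(self):
        aln = make_alignment([("h_X", "ACGT" * 200), ("h_Y", "AGGT" * 200)])
        with pytest.raises(ValueError):
            scan_topologies(aln, WindowSpec(200, 200))


class TestSegmentSubregions:
    def test_runs_merge_into_three_subregions(self):
        calls = with_intervals(
            [
                call(RECIPROCAL_MONOPHYLY),
                call(RECIPROCAL_MONOPHYLY),
                call(MIXED, {"h"}),
                call(MIXED, {"h"}),
                call(RECIPROCAL_MONOPHYLY),
            ]
        )
        srs = segment_subregions(calls)
        assert [s.signature.call for s in srs] == [RECIPROCAL_MONOPHYLY, MIXED, RECIPROCAL_MONOPHYLY]
        assert [s.n_windows for s in srs] == [2, 2, 1]
        # boundary at the midpoint of the overlap of windows 1 and 2
        assert srs[0].interval.end == srs[1].interval.start == (800 + 900) // 2

    def test_no_smoothing_of_alternating_signatures(self):
        calls = with_intervals(
            [call(MIXED, {"h"}), call(MIXED, {"c"}), call(MIXED, {"h"})]
        )
        assert len(segment_subregions(calls)) == 3

    def test_unresolved_absorbed_and_flanks_merged(self):
        calls = with_intervals(
            [
                call(MIXED, {"h"}),
                call(UNRESOLVED),
                call(MIXED, {"h"}),
                call(UNRESOLVED),
                call(MIXED, {"c"}),
            ]
        )
        srs = segment_subregions(calls)
        assert len(srs) == 2
        assert srs[0].n_windows == 4  # ties absorb to the left
        assert srs[0].signature.paired_species == frozenset({"h"})

    def test_all_unresolved_yields_nothing(self):
        assert segment_subregions(with_intervals([call(UNRESOLVED)] * 4)) == []

    def test_subregions_partition_classified_extent(self, fig3_run):
        _, _, calls, subregions, _ = fig3_run
        assert subregions[0].interval.start == calls[0][0].start
        assert subregions[-1].interval.end == calls[-1][0].end
        for a, b in zip(subregions, subregions[1:]):
            assert a.interval.end == b.interval.start


@pytest.fixture(scope="module")
def tree():
    return read_species_tree(
        "(rhesus:30,(gibbon:18,(gorilla:8,(human:6,chimp:6):2):10):12);"
    )


class TestMapEvents:

    def test_clade_group_maps_to_single_stem_event(self, tree):
        sr_calls = with_intervals([call(MIXED, {"human", "chimp", "gorilla"})])
        evs = map_events(segment_subregions(sr_calls), tree)
        assert len(evs) == 1
        assert evs[0].branch == frozenset({"human", "chimp", "gorilla"})
        # undated bounds are the branch's existence window
        assert (evs[0].t_low, evs[0].t_high) == (8.0, 18.0)

    def test_non_clade_group_needs_two_events(self, tree):
        sr_calls = with_intervals([call(MIXED, {"gibbon", "human"})])
        evs = map_events(segment_subregions(sr_calls), tree)
        assert sorted(ev.branch_name() for ev in evs) == ["gibbon", "human"]

    def test_unknown_species_rejected(self, tree):
        sr_calls = with_intervals([call(MIXED, {"lemur"})])
        with pytest.raises(ValueError, match="lemur"):
            map_events(segment_subregions(sr_calls), tree)

    def test_minimal_cover_matches_bruteforce(self, tree):
        # laminar-maximal cover equals the exhaustive minimum over all
        # branch subsets, for every coverable species set
        branches = tree.branches()
        species = tree.species
        for r in range(1, len(species) + 1):
            for combo in itertools.combinations(species, r):
                group = frozenset(combo)
                got = _minimal_branch_cover(group, tree)
                best = None
                for k in range(1, len(branches) + 1):
                    for sub in itertools.combinations(branches, k):
                        if all(b <= group for b in sub) and frozenset().union(*sub) == group:
                            best = k
                            break
                    if best:
                        break
                assert len(got) == best

    def test_events_recovered_on_true_branches(self, fig3_run, primate_tree):
        aln, truth, calls, subregions, events = fig3_run
        assert len(subregions) == 7
        assert len(events) == 10
        remaining = list(truth.events)
        for ev in events:
            hit = [
                t
                for t in remaining
                if frozenset(t.lineage) == ev.branch
                and ev.interval.overlaps(Interval(t.start, t.end))
            ]
            assert hit, f"no truth event for {ev.branch_name()} @ {ev.interval}"
            remaining.remove(hit[0])
        assert not remaining


class TestInferDirection:
    def hand_toy(self, pair_state):
        """6-taxon toy: ref species r and s, outgroup o, converted species v.

        Five diagnostic columns where refs' X (A) and Y (T) differ and the
        outgroup carries the X state; the converted pair carries
        ``pair_state`` at those columns.
        """
        backbone = "ACGTACGTAC"
        diag_x, diag_y = "A" * 5, "T" * 5
        rows = [
            ("o_KAL", backbone + diag_x),
            ("r_X", backbone + diag_x),
            ("s_X", backbone + diag_x),
            ("r_Y", backbone + diag_y),
            ("s_Y", backbone + diag_y),
            ("v_X", backbone + pair_state * 5),
            ("v_Y", backbone + pair_state * 5),
        ]
        return make_alignment(rows)

    def test_shared_y_derived_states_vote_y_to_x(self):
        aln = self.hand_toy("T")
        ev = ConversionEvent(branch=frozenset({"v"}), interval=Interval(0, 15))
        dc = infer_direction(aln, ev)
        assert dc.direction == Y_TO_X and (dc.n_y_to_x, dc.n_x_to_y) == (5, 0)

    def test_mirrored_toy_votes_x_to_y(self):
        # same sites, but the outgroup carries the Y state: the X state is
        # derived, and the pair carrying it votes X->Y
        aln = self.hand_toy("A")
        rows = list(zip([t.format() for t in aln.taxa], aln.rows))
        rows[0] = ("o_KAL", rows[0][1][:10] + "T" * 5)
        aln2 = make_alignment(rows)
        ev = ConversionEvent(branch=frozenset({"v"}), interval=Interval(0, 15))
        dc = infer_direction(aln2, ev)
        assert dc.direction == X_TO_Y and (dc.n_y_to_x, dc.n_x_to_y) == (0, 5)

    def test_no_informative_sites_is_unknown(self):
        aln = make_alignment(
            [
                ("o_KAL", "ACGT" * 5),
                ("r_X", "ACGT" * 5),
                ("r_Y", "ACGT" * 5),
                ("v_X", "ACGT" * 5),
                ("v_Y", "ACGT" * 5),
            ]
        )
        ev = ConversionEvent(branch=frozenset({"v"}), interval=Interval(0, 20))
        dc = infer_direction(aln, ev)
        assert dc.direction == "UNKNOWN" and dc.n_y_to_x + dc.n_x_to_y == 0

    def test_below_min_votes_is_unknown(self):
        aln = self.hand_toy("T")
        ev = ConversionEvent(branch=frozenset({"v"}), interval=Interval(0, 15))
        dc = infer_direction(aln, ev, min_votes=6)
        assert dc.direction == "UNKNOWN"

    def test_outgroup_required(self):
        aln = self.hand_toy("T")
        sub = aln.subalignment([t for t in aln.taxa if t.species != "o"])
        ev = ConversionEvent(branch=frozenset({"v"}), interval=Interval(0, 15))
        with pytest.raises(ValueError, match="outgroup"):
            infer_direction(sub, ev)


class TestLocateBreakpoint:
    def test_planted_switch_recovered(self):
        aln, _ = make_paper_fixture("fig5_breakpoint", seed=2)
        bp = locate_breakpoint(aln, Interval(0, 3000), candidate_step=20, n_boot=40, seed=5)
        assert not bp.no_switch
        assert abs(bp.column - 1500) <= 150
        assert bp.left_call.call == RECIPROCAL_MONOPHYLY
        assert bp.right_call.call == SPECIES_PAIRING

    def test_no_switch_flagged_on_uniform_region(self, null_fixture):
        aln, _ = null_fixture
        bp = locate_breakpoint(aln, Interval(0, 3000), candidate_step=100, n_boot=30, seed=5)
        assert bp.no_switch and bp.score == 0.0

    def test_fully_converted_interval_points_at_start(self):
        cfg = SimConfig(
            species_newick="(rhesus:30,(human:6,chimp:6):24);",
            seq_length=2000,
            conversions=[
                ConversionSpec(frozenset(["human"]), 3.0, 0, 2000, Y_TO_X),
                ConversionSpec(frozenset(["chimp"]), 4.0, 0, 2000, X_TO_Y),
                ConversionSpec(frozenset(["rhesus"]), 15.0, 0, 2000, Y_TO_X),
            ],
        )
        aln, _ = simulate(cfg, seed=9)
        bp = locate_breakpoint(aln, Interval(0, 2000), candidate_step=100, n_boot=30, seed=6)
        assert bp.column == 0
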