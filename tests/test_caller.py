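"""Octad caller: genotype calling, segregation, tracts, events, lengths."""

import numpy as np
import pytest

from conftest import build_octad, mendelian_octad

from meiorec.caller import (
    CallerParams,
    call_genotypes,
    call_octad,
    call_spore_tracts,
    classify_event_co_nco,
    classify_marker_segregation,
    group_events,
    segment_strand,
    tract_boundaries,
)
from meiorec.errors import FormatError, ParameterError
from meiorec.simulate import (
    NA,
    P1,
    P2,
    SimParams,
    make_marker_map,
    simulate_octad,
)


class TestCallGenotypes:
    @pytest.mark.parametrize(
        "n1,n2,purity,expected",
        [
            (10, 0, 0.9, P1),
            (0, 10, 0.9, P2),
            (3, 3, 0.9, NA),
            (9, 1, 0.9, P1),
            (9, 1, 0.95, NA),
            (2, 0, 0.9, NA),  # below min_depth=5
        ],
    )
    def test_purity_and_depth_thresholds(self, n1, n2, purity, expected):
        mm = make_marker_map(1000, 400, seed=1)
        m = len(mm)
        d1 = np.full((8, m), float(n1))
        d2 = np.full((8, m), float(n2))
        octad = call_genotypes(d1, d2, mm, CallerParams(min_purity=purity))
        assert (octad.calls == expected).all()

    def test_wrong_shape_rejected(self):
        mm = make_marker_map(1000, 400, seed=1)
        with pytest.raises(FormatError):
            call_genotypes(np.zeros((7, len(mm))), np.zeros((7, len(mm))), mm)


class TestMarkerSegregation:
    def test_classes_from_counts(self):
        # one column per marker: 4:4, 5:3, 3:5, 6:2, incomplete
        columns = [
            [P1, P1, P1, P1, P2, P2, P2, P2],
            [P1, P1, P1, P1, P1, P2, P2, P2],
            [P1, P1, P1, P2, P2, P2, P2, P2],
            [P1, P1, P1, P1, P1, P1, P2, P2],
            [P1, P1, P1, P1, P2, P2, P2, NA],
        ]
        octad = build_octad(np.array(columns, dtype=np.int8).T)
        seg = classify_marker_segregation(octad)
        assert list(seg["class"]) == ["4:4", "5:3", "3:5", "6:2", "incomplete"]
        assert (seg["n_p1"] + seg["n_p2"] + seg["n_na"] == 8).all()

    def test_aberrant_pattern(self):
        calls = np.full((8, 1), P1, dtype=np.int8)
        calls[7, 0] = P2  # 7:1
        seg = classify_marker_segregation(build_octad(calls))
        assert seg["class"].iloc[0] == "aberrant"


class TestSegmentStrand:
    def test_single_run(self):
        octad = build_octad(np.full((8, 10), P1, dtype=np.int8))
        assert segment_strand(octad, 0) == [(P1, 0, 9)]

    def test_changepoint(self):
        calls = np.full((8, 10), P1, dtype=np.int8)
        calls[0, 5:] = P2
        assert segment_strand(build_octad(calls), 0) == [(P1, 0, 4), (P2, 5, 9)]

    def test_na_carried_over(self):
        calls = np.full((8, 5), P1, dtype=np.int8)
        calls[0] = [P1, P1, NA, P1, P2]
        assert segment_strand(build_octad(calls), 0) == [(P1, 0, 3), (P2, 4, 4)]

    def test_all_na_warns_and_empty(self):
        calls = np.full((8, 4), P1, dtype=np.int8)
        calls[0] = NA
        with pytest.warns(UserWarning):
            assert segment_strand(build_octad(calls), 0) == []


def _plant_hdna(octad, spore, first, last):
    """Flip one daughter of a spore over marker indices [first, last]."""
    octad.calls[2 * spore, first : last + 1] = 1 - octad.calls[2 * spore, first : last + 1]


class TestSporeTracts:
    def test_no_events_no_tracts(self):
        mm = make_marker_map(50_000, 160, seed=1)
        octad, _ = simulate_octad(mm, SimParams(chrom_length=50_000, events_per_chrom=0, seed=2))
        assert call_spore_tracts(octad) == []

    def test_planted_range_recovered_exactly(self):
        octad = mendelian_octad(30)
        _plant_hdna(octad, 1, 10, 14)
        tracts = call_spore_tracts(octad)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.spore, t.first_marker, t.last_marker) == (1, 10, 14)
        assert set(t.categories) == {"hDNA"}

    def test_missing_call_inside_tract_is_neutral(self):
        octad = mendelian_octad(30)
        _plant_hdna(octad, 2, 10, 16)
        octad.calls[2 * 2, 13] = NA  # one daughter missing mid-tract
        tracts = call_spore_tracts(octad)
        assert len(tracts) == 1
        assert (tracts[0].first_marker, tracts[0].last_marker) == (10, 16)

    def test_full_conversion_6_2_detected(self):
        octad = mendelian_octad(30)
        # both daughters of spore 0 converted over markers 12-15 -> 2:6
        octad.calls[0, 12:16] = P2
        octad.calls[1, 12:16] = P2
        seg = classify_marker_segregation(octad)
        assert set(seg["class"].iloc[12:16]) == {"2:6"}
        tracts = call_spore_tracts(octad)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.spore, t.first_marker, t.last_marker) == (0, 12, 15)
        assert set(t.categories) == {"full"}

    def test_isolated_single_marker_flagged_low_confidence(self):
        octad = mendelian_octad(30)
        _plant_hdna(octad, 3, 15, 15)
        tracts = call_spore_tracts(octad)
        assert len(tracts) == 1
        assert tracts[0].low_confidence
        # multi-marker tracts are never flagged
        octad2 = mendelian_octad(30)
        _plant_hdna(octad2, 3, 15, 17)
        assert not call_spore_tracts(octad2)[0].low_confidence

    def test_mendelian_gap_splits_tract_by_default(self):
        octad = mendelian_octad(30)
        _plant_hdna(octad, 0, 8, 10)
        _plant_hdna(octad, 0, 12, 14)  # marker 11 Mendelian in between
        assert len(call_spore_tracts(octad)) == 2
        merged = call_spore_tracts(octad, CallerParams(merge_gap_markers=1))
        assert len(merged) == 1
        assert (merged[0].first_marker, merged[0].last_marker) == (8, 14)

    def test_brute_force_oracle_equivalence(self):
        """Called tract markers equal the per-spore discordant-marker scan on
        NCO-only octads (full conversions absent, so non-Mendelian means
        daughter-discordant)."""
        for s in range(25):
            mm = make_marker_map(8000, 160, seed=400 + s)
            if len(mm) > 50:
                continue
            octad, _ = simulate_octad(
                mm,
                SimParams(
                    chrom_length=8000,
                    events_per_chrom=1.5,
                    p_co=0.0,
                    tract_mean=600,
                    min_event_sep=1000,
                    seed=s,
                ),
            )
            tracts = call_spore_tracts(octad)
            for spore in range(4):
                a, b = octad.spore_strands(spore)
                brute = set(np.flatnonzero((a != NA) & (b != NA) & (a != b)).tolist())
                called = {
                    i for t in tracts if t.spore == spore for i in t.marker_indices
                }
                assert called == brute


class TestTractBoundaries:
    def test_midpoint_convention(self):
        # converted markers at 1000..2000, flanks at 900 and 2100
        positions = [900, 1000, 1500, 2000, 2100]
        octad = mendelian_octad(5, positions)
        start, end = tract_boundaries(1, 3, octad.map)
        assert (start, end) == (950.0, 2050.0)
        assert end - start == 1100.0

    def test_single_marker(self):
        positions = [900, 1000, 1100]
        octad = mendelian_octad(3, positions)
        start, end = tract_boundaries(1, 1, octad.map)
        assert (start, end) == (950.0, 1050.0)
        assert end - start == 100.0

    def test_chromosome_start_edge(self):
        positions = [500, 800, 1200]
        octad = mendelian_octad(3, positions)
        start, end = tract_boundaries(0, 1, octad.map)
        assert start == 500.0  # terminal converted marker itself
        assert end == 1000.0

    def test_empty_tract_rejected(self):
        octad = mendelian_octad(3)
        with pytest.raises(ParameterError):
            tract_boundaries(2, 1, octad.map)


class TestEvents:
    def test_distant_tracts_two_events(self):
        octad = mendelian_octad(600)
        _plant_hdna(octad, 0, 10, 12)
        _plant_hdna(octad, 1, 500, 504)  # 50 kb away at 100 bp spacing
        events = group_events(call_spore_tracts(octad))
        assert len(events) == 2

    def test_chained_tracts_single_linkage(self):
        octad = mendelian_octad(200)
        for spore, first in ((0, 10), (1, 50), (2, 90)):  # 4 kb gaps
            _plant_hdna(octad, spore, first, first + 2)
        events = group_events(call_spore_tracts(octad), CallerParams(event_merge_bp=5000))
        assert len(events) == 1
        assert events[0].chromatids == (0, 1, 2)

    def test_co_round_trip_groups_and_classifies(self):
        for s in range(30):
            mm = make_marker_map(200_000, 160, seed=600 + s)
            octad, truth = simulate_octad(mm, SimParams(events_per_chrom=1, p_co=1.0, seed=s))
            if len(truth) != 1:
                continue
            tracts, events = call_octad(octad)
            with_markers = [
                t for t in truth.tracts
                if ((mm.positions >= t.start) & (mm.positions <= t.end)).any()
            ]
            if not with_markers:
                continue
            assert len(events) == 1
            assert events[0].classification == "CO"
            assert set(truth.co_spores[0]) <= set(events[0].chromatids)

    def test_nco_round_trip_classifies(self):
        for s in range(30):
            mm = make_marker_map(200_000, 160, seed=900 + s)
            octad, truth = simulate_octad(mm, SimParams(events_per_chrom=1, p_co=0.0, seed=s))
            tracts, events = call_octad(octad)
            for ev in events:
                assert ev.classification == "NCO"

    def test_event_at_chromosome_end_unclassified(self):
        octad = mendelian_octad(20)
        _plant_hdna(octad, 0, 0, 2)  # fewer than flank_k markers on the left
        tracts = call_spore_tracts(octad)
        events = group_events(tracts)
        assert classify_event_co_nco(events[0], octad) == "unclassified"

    def test_complex_three_recombinant_chromatids(self):
        octad = mendelian_octad(60)
        # three chromatids switch background at marker 30: not a simple CO
        octad.calls[0:2, 30:] = P2
        octad.calls[2:4, 30:] = P2
        octad.calls[4:6, 30:] = P1
        _plant_hdna(octad, 0, 28, 29)
        tracts = call_spore_tracts(octad)
        events = group_events(tracts)
        assert classify_event_co_nco(events[0], octad) == "complex"
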