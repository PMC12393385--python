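"""The three-zone crossing detector and its derived sequences."""

import dataclasses

import numpy as np
import pytest

import permkit as pk
from permkit.event_detection import BT, TB, CoarseSamplingWarning
from conftest import make_trace

GEOM = pk.ChannelGeometry(z_top=20.0, z_bottom=-20.0, cylinder_radius=17.3)


def bundle_of(traces, duration=None, geometry=GEOM):
    if duration is None:
        duration = max(t.times[-1] for t in traces)
    md = pk.SystemMetadata(box_height=120.0, duration=duration, membrane_voltage=-102.0)
    return pk.TrajectoryBundle(traces=list(traces), geometry=geometry, metadata=md)


class TestStateMachine:
    def test_single_axial_tb_crossing(self):
        led = pk.detect_crossings(bundle_of([make_trace([30, 5, -30])]))
        assert len(led) == 1
        ev = led.events[0]
        assert ev.direction == TB and ev.species == "K+"
        # linear interpolation: crosses z=20 at t=0.04, z=-20 at t=0.17
        assert ev.t_start == pytest.approx(0.04)
        assert ev.t_end == pytest.approx(0.1 + 0.1 * (5 - (-20)) / (5 - (-30)))

    def test_bt_crossing_is_negative_direction(self):
        led = pk.detect_crossings(bundle_of([make_trace([-30, 0, 30])]))
        assert [e.direction for e in led.events] == [BT]

    def test_residency_open_at_start_is_disregarded(self):
        led = pk.detect_crossings(bundle_of([make_trace([0, -10, -30])]))
        assert len(led) == 0

    def test_residency_open_at_end_is_disregarded(self):
        led = pk.detect_crossings(bundle_of([make_trace([30, 10, 0])]))
        assert len(led) == 0

    def test_backing_out_through_entry_ring_is_no_event(self):
        led = pk.detect_crossings(bundle_of([make_trace([30, 5, 30, 5, 30])]))
        assert len(led) == 0

    def test_second_traversal_after_reentry_counts(self):
        zs = [30, 0, -30, 0, 30, 0, -30]
        led = pk.detect_crossings(bundle_of([make_trace(zs)]))
        assert [e.direction for e in led.events] == [TB, BT, TB]

    def test_radial_escape_resets_the_traversal(self):
        # enters from top on-axis, slides out beyond the radial gate while
        # inside, and leaves below: the traversal was broken, no event
        t = np.arange(5) * 0.1
        pos = np.array(
            [[0, 0, 30], [0, 0, 5], [25, 0, 5], [25, 0, -5], [25, 0, -30]], dtype=float
        )
        tr = pk.IonTrace("r1", "K+", t, pos)
        led = pk.detect_crossings(bundle_of([tr]))
        assert len(led) == 0

    def test_radial_gate_monotonicity(self, small_run):
        _, bundle, _ = small_run
        counts = []
        for radius in (4.0, 8.0, 17.3):
            geo = dataclasses.replace(bundle.geometry, cylinder_radius=radius)
            b = pk.TrajectoryBundle(bundle.traces, geo, bundle.metadata)
            counts.append(len(pk.detect_crossings(b)))
        assert counts == sorted(counts)

    def test_region_skip_is_flagged_not_dropped(self):
        tr = make_trace([30, -30], dt=1.0)
        with pytest.warns(CoarseSamplingWarning):
            led = pk.detect_crossings(bundle_of([tr], duration=1.0))
        assert len(led) == 1 and led.events[0].direction == TB

    def test_missing_geometry_errors(self, small_run):
        _, bundle, _ = small_run
        broken = pk.TrajectoryBundle(bundle.traces, None, bundle.metadata)
        with pytest.raises(ValueError, match="geometry"):
            pk.detect_crossings(broken)

    def test_frame_snapped_times_when_interpolation_off(self):
        led = pk.detect_crossings(bundle_of([make_trace([30, 5, -30])]), interpolate=False)
        assert led.events[0].t_start == pytest.approx(0.1)
        assert led.events[0].t_end == pytest.approx(0.2)


class TestGroundTruthEquivalence:
    def test_counts_directions_and_pathways_match_exactly(self, small_run):
        _, bundle, truth = small_run
        led = pk.detect_crossings(bundle)
        assert led.counts() == truth.counts()
        detected = {e.ion_id: e for e in led.events}
        for ev in truth.events:
            assert ev.ion_id in detected
            assert detected[ev.ion_id].direction == ev.direction
            # event times agree to the frame spacing
            assert abs(detected[ev.ion_id].t_start - ev.t_start) < 0.011

    def test_time_reversal_maps_tb_to_bt(self, small_run):
        _, bundle, _ = small_run
        fwd = pk.detect_crossings(bundle)
        T = bundle.traces[0].times[-1]
        reversed_traces = [
            pk.IonTrace(t.ion_id, t.species, T - t.times[::-1], t.positions[::-1])
            for t in bundle.traces
        ]
        rev = pk.detect_crossings(
            pk.TrajectoryBundle(reversed_traces, bundle.geometry, bundle.metadata)
        )
        for species in ("K+", "Cl-"):
            assert fwd.count(species, TB) == rev.count(species, BT)
            assert fwd.count(species, BT) == rev.count(species, TB)


class TestDerivedSequences:
    def test_waiting_times_are_start_differences(self):
        events = [
            pk.CrossingEvent("a", "K+", TB, t, t + 0.5) for t in (1.0, 3.0, 8.0)
        ]
        led = pk.EventLedger(events=events, dt=20.0)
        np.testing.assert_allclose(pk.waiting_times(led, TB), [2.0, 5.0])

    def test_no_interval_spans_a_segment_boundary(self):
        events = [
            pk.CrossingEvent("a", "K+", TB, 1.0, 1.5, segment="s1"),
            pk.CrossingEvent("b", "K+", TB, 3.0, 3.5, segment="s1"),
            pk.CrossingEvent("c", "K+", TB, 11.0, 11.5, segment="s2"),
            pk.CrossingEvent("d", "K+", TB, 14.0, 14.5, segment="s2"),
        ]
        led = pk.EventLedger(events=events, dt=10.0)
        np.testing.assert_allclose(sorted(pk.waiting_times(led, TB)), [2.0, 3.0])

    def test_fewer_than_two_events_gives_empty_not_error(self):
        led = pk.EventLedger(events=[pk.CrossingEvent("a", "K+", TB, 1.0, 2.0)], dt=5.0)
        assert pk.waiting_times(led, TB).size == 0
        assert pk.waiting_times(led, BT).size == 0

    def test_event_durations(self):
        led = pk.EventLedger(
            events=[pk.CrossingEvent("a", "K+", TB, 1.0, 2.2)], dt=5.0
        )
        np.testing.assert_allclose(pk.event_durations(led), [1.2])
        assert pk.event_durations(pk.EventLedger(events=[], dt=5.0)).size == 0

    def test_synthetic_poisson_run_recovers_rate(self):
        # single-Poisson TB entries at 0.5/ns: sample mean waiting ~ 2 ns
        spec = pk.SyntheticSpec(
            duration=150.0,
            seed=5,
            n_bulk=0,
            entry_models={("K+", TB): pk.PoissonModel(0.5)},
        )
        bundle, _ = pk.generate_run(spec)
        led = pk.detect_crossings(bundle)
        w = pk.waiting_times(led, TB)
        assert len(w) > 30
        assert abs(w.mean() - 2.0) < 3 * 2.0 / np.sqrt(len(w))

    def test_mean_transit_duration_matches_generator(self):
        spec = pk.SyntheticSpec(duration=200.0, seed=9, n_bulk=0)
        bundle, _ = pk.generate_run(spec)
        durs = pk.event_durations(pk.detect_crossings(bundle))
        assert len(durs) > 40
        # heavy-tailed log-normal: bound with the theoretical sd, not the
        # (tail-starved) sample sd
        sd = spec.transit_mean * np.sqrt(np.exp(spec.transit_sigma**2) - 1)
        assert abs(durs.mean() - spec.transit_mean) < 3 * sd / np.sqrt(len(durs)) + 0.05
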