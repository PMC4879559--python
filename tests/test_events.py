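"""Trace-analysis chain: baseline, ΔF/F, detection, scaling, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinedyn.events import (
    BaselineError,
    DendriteClass,
    DetectionParams,
    FluorescenceTrace,
    RoiTraceSet,
    classification_percentages,
    classify_dendrite,
    classify_spine,
    compute_dff,
    detect_shaft_events,
    estimate_mode_baseline,
    fit_shaft_scale,
    is_active_shaft,
    robust_sd,
    summarize_classification,
)
from spinedyn.simulate import SimParams, simulate_trace_set

from conftest import make_dff_trace, pulse_trace


class TestModeBaseline:
    def test_constant_trace_returns_its_value(self):
        assert estimate_mode_baseline(np.full(100, 100.0)) == 100.0

    def test_sparse_transients_do_not_shift_mode(self, rng):
        # baseline 100, 3% of frames elevated to 200, noise SD 2
        values = rng.normal(100.0, 2.0, size=2000)
        values[:60] = rng.normal(200.0, 2.0, size=60)
        f0 = estimate_mode_baseline(values)
        lo, hi = values.min(), values.max()
        n_bins = max(20, int(np.ceil((hi - lo) / (2 * (np.percentile(values, 75) - np.percentile(values, 25)) * 2000 ** (-1 / 3)))))
        bin_width = (hi - lo) / n_bins
        assert abs(f0 - 100.0) <= bin_width
        assert lo <= f0 <= hi

    def test_bimodal_trace_picks_majority_mode(self, rng):
        values = np.concatenate(
            [rng.normal(50.0, 1.0, 600), rng.normal(150.0, 1.0, 400)]
        )
        f0 = estimate_mode_baseline(values)
        assert abs(f0 - 50.0) < 5.0

    def test_tie_breaks_toward_lower_bin(self):
        # two exactly equally populated well-separated clusters
        values = np.concatenate([np.full(50, 10.0), np.full(50, 20.0)])
        f0 = estimate_mode_baseline(values)
        assert f0 < 15.0


class TestComputeDff:
    def test_constant_trace_gives_zero_dff(self):
        tr = FluorescenceTrace(np.full(100, 100.0), 12.0, "raw")
        dff = compute_dff(tr)
        assert dff.kind == "dff"
        np.testing.assert_array_equal(dff.values, 0.0)

    def test_doubling_frame_gives_unit_dff(self, rng):
        values = rng.normal(100.0, 0.5, size=500)
        values[100] = 2 * 100.0
        tr = FluorescenceTrace(values, 12.0, "raw")
        dff = compute_dff(tr)
        f0 = estimate_mode_baseline(values)
        assert dff.values[100] == pytest.approx((values[100] - f0) / f0)
        assert dff.values[100] == pytest.approx(1.0, abs=0.05)

    def test_background_subtraction_precedes_baseline(self):
        tr = FluorescenceTrace(np.full(100, 150.0), 12.0, "raw")
        dff = compute_dff(tr, background=50.0)
        np.testing.assert_array_equal(dff.values, 0.0)

    def test_nonpositive_baseline_is_an_error(self):
        tr = FluorescenceTrace(np.full(100, -5.0), 12.0, "raw")
        with pytest.raises(BaselineError):
            compute_dff(tr)

    def test_recovers_simulated_clean_dff(self):
        params = SimParams(seed=21, n_spines_per_dendrite=1, noise_sd=0.05)
        traces, _ = simulate_trace_set(params)
        dff = compute_dff(traces.shaft)
        clean = traces.shaft.values / params.baseline_f0 - 1.0
        # agreement up to noise and the mode-bin width
        assert np.median(np.abs(dff.values - clean)) < 0.1


class TestDetection:
    def test_flat_trace_has_no_events(self):
        assert detect_shaft_events(make_dff_trace(np.zeros(100))) == []

    @pytest.mark.parametrize("run_len,n_expected", [(2, 0), (3, 1), (5, 1)])
    def test_run_length_boundary(self, run_len, n_expected):
        # excursions lasting exactly 2 frames are rejected; 3 frames accepted
        values = pulse_trace(600, [(100, run_len, 1.0)], noise_sd=0.01, seed=1)
        events = detect_shaft_events(make_dff_trace(values))
        assert len(events) == n_expected
        if events:
            assert events[0].onset_frame == 100
            assert events[0].n_frames >= run_len

    def test_injected_events_recovered_with_onset_accuracy(self):
        onsets = [50, 300, 700, 1200, 2000]
        values = pulse_trace(2880, [(o, 6, 0.8) for o in onsets], noise_sd=0.1, seed=2)
        events = detect_shaft_events(make_dff_trace(values))
        assert len(events) == 5
        for ev, onset in zip(events, onsets):
            assert abs(ev.onset_frame - onset) <= 2

    def test_events_disjoint_sorted_min_length(self, rng):
        values = pulse_trace(
            2000,
            [(int(o), 4, 1.0) for o in rng.integers(10, 1900, size=8)],
            noise_sd=0.05,
            seed=3,
        )
        events = detect_shaft_events(make_dff_trace(values))
        for prev, cur in zip(events, events[1:]):
            assert prev.offset_frame <= cur.onset_frame
        for ev in events:
            assert ev.n_frames >= 3
            assert ev.peak_dff > 0

    @given(mult=st.floats(min_value=1.0, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_raising_threshold_never_adds_events(self, mult):
        values = pulse_trace(
            1000, [(100, 5, 0.6), (400, 4, 1.2), (800, 6, 0.3)], noise_sd=0.05, seed=4
        )
        trace = make_dff_trace(values)
        base = len(detect_shaft_events(trace, DetectionParams(sd_multiplier=mult)))
        higher = len(
            detect_shaft_events(trace, DetectionParams(sd_multiplier=mult + 1.0))
        )
        assert higher <= base

    def test_active_shaft_is_any_event(self):
        values = pulse_trace(600, [(100, 4, 1.0)], seed=5)
        events = detect_shaft_events(make_dff_trace(values))
        assert is_active_shaft(events)
        assert not is_active_shaft([])


class TestShaftScaling:
    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0])
    def test_exact_proportionality_recovered(self, k):
        shaft = pulse_trace(1000, [(100, 5, 1.0), (600, 5, 1.5)], noise_sd=0.0, seed=0)
        shaft_tr = make_dff_trace(shaft)
        spine_tr = make_dff_trace(k * shaft)
        events = detect_shaft_events(shaft_tr)
        a, residual = fit_shaft_scale(spine_tr, shaft_tr, events)
        assert a == pytest.approx(k, abs=1e-9)
        assert np.max(np.abs(residual)) < 1e-9

    def test_zero_shaft_gives_zero_scale_and_full_residual(self):
        spine = pulse_trace(500, [(100, 5, 1.0)], seed=1)
        a, residual = fit_shaft_scale(
            make_dff_trace(spine), make_dff_trace(np.zeros(500)), []
        )
        assert a == 0.0
        np.testing.assert_array_equal(residual, spine)

    def test_scale_near_one_with_extra_spine_events(self):
        # spine = shaft + independent events: fit over shaft-event frames only
        shaft = pulse_trace(2000, [(200, 6, 1.0), (1500, 6, 1.0)], noise_sd=0.05, seed=2)
        spine = shaft + pulse_trace(2000, [(800, 6, 1.0)], noise_sd=0.05, seed=3)
        shaft_tr, spine_tr = make_dff_trace(shaft), make_dff_trace(spine)
        events = detect_shaft_events(shaft_tr)
        a, residual = fit_shaft_scale(spine_tr, shaft_tr, events)
        assert a == pytest.approx(1.0, abs=0.1)
        # the spine-only event survives in the residual
        assert residual[800:806].mean() > 0.5

    def test_anticorrelated_spine_clamps_to_zero(self):
        shaft = pulse_trace(500, [(100, 5, 1.0)], noise_sd=0.0, seed=0)
        a, _ = fit_shaft_scale(
            make_dff_trace(-shaft), make_dff_trace(shaft),
            detect_shaft_events(make_dff_trace(shaft)),
        )
        assert a == 0.0


class TestSpineClassification:
    def test_pure_scaled_shaft_is_inactive(self):
        shaft = pulse_trace(2000, [(i, 5, 1.0) for i in (100, 600, 1200)], noise_sd=0.02, seed=6)
        shaft_tr = make_dff_trace(shaft)
        for k in (0.3, 1.0, 3.0):
            active, events = classify_spine(make_dff_trace(k * shaft), shaft_tr)
            assert not active
            assert events == []

    @pytest.mark.parametrize("n_events,expect_active", [(3, False), (4, True)])
    def test_exceedance_boundary_three_vs_four(self, n_events, expect_active):
        onsets = [100, 500, 900, 1300][:n_events]
        spine = pulse_trace(2000, [(o, 5, 1.0) for o in onsets], noise_sd=0.01, seed=7)
        shaft_tr = make_dff_trace(np.zeros(2000))
        active, events = classify_spine(make_dff_trace(spine), shaft_tr)
        assert len(events) == n_events
        assert active is expect_active
        assert all(ev.source == "spine_specific" for ev in events)

    def test_scale_invariance_of_decision(self):
        params = SimParams(seed=13, n_spines_per_dendrite=2, spine_specific_rate_hz=0.05)
        traces, _ = simulate_trace_set(params)
        shaft = compute_dff(traces.shaft)
        for tr in traces.spines.values():
            spine = compute_dff(tr)
            base, _ = classify_spine(spine, shaft)
            for c in (0.1, 10.0):
                scaled_spine = make_dff_trace(c * spine.values)
                scaled_shaft = make_dff_trace(c * shaft.values)
                assert classify_spine(scaled_spine, scaled_shaft)[0] == base

    def test_additive_offset_of_raw_trace_preserves_event_calls(self, rng):
        values = 100.0 * (1 + pulse_trace(2000, [(300, 6, 1.0), (900, 6, 1.0)], noise_sd=0.05, seed=8))
        tr = FluorescenceTrace(values, 12.0, "raw")
        tr_shifted = FluorescenceTrace(values + 25.0, 12.0, "raw")
        ev1 = detect_shaft_events(compute_dff(tr))
        ev2 = detect_shaft_events(compute_dff(tr_shifted))
        assert [(e.onset_frame, e.offset_frame) for e in ev1] == [
            (e.onset_frame, e.offset_frame) for e in ev2
        ]


class TestDendriteClassification:
    def _trace_set(self, shaft_values, spine_values_list):
        shaft = make_dff_trace(shaft_values)
        spines = {
            f"spine_{i + 1:03d}": make_dff_trace(v)
            for i, v in enumerate(spine_values_list)
        }
        return RoiTraceSet(shaft, spines)

    def test_all_flat_is_none(self):
        ts = self._trace_set(np.zeros(500), [np.zeros(500)])
        assert classify_dendrite(ts) is DendriteClass.NONE

    def test_shaft_only_is_dendritic_only(self):
        shaft = pulse_trace(2000, [(200, 5, 1.0)], noise_sd=0.02, seed=9)
        # spine follows the shaft exactly: no spine-specific events
        ts = self._trace_set(shaft, [shaft.copy()])
        assert classify_dendrite(ts) is DendriteClass.DENDRITIC_ONLY

    def test_active_spine_makes_dendritic_plus_synaptic(self):
        shaft = pulse_trace(2000, [(200, 5, 1.0)], noise_sd=0.02, seed=10)
        spine = shaft + pulse_trace(
            2000, [(o, 5, 1.0) for o in (500, 900, 1300, 1700)], noise_sd=0.02, seed=11
        )
        ts = self._trace_set(shaft, [spine])
        assert classify_dendrite(ts) is DendriteClass.DENDRITIC_PLUS_SYNAPTIC

    def test_classification_from_raw_traces(self, quiet_sim_params):
        traces, _ = simulate_trace_set(quiet_sim_params.with_(noise_sd=0.05))
        assert classify_dendrite(traces) is DendriteClass.NONE


class TestSummary:
    def test_single_condition_counts_and_percentages(self):
        table = summarize_classification(
            [DendriteClass.NONE, DendriteClass.NONE], ["ctrl", "ctrl"]
        )
        assert list(table["ctrl"]) == [0, 0, 2]
        pct = classification_percentages(table)
        assert list(pct["ctrl"]) == [0.0, 0.0, 100.0]
        assert pct["ctrl"].sum() == pytest.approx(100.0)

    def test_table_equals_direct_tally_and_is_order_invariant(self, rng):
        classes = list(rng.choice(list(DendriteClass), size=30))
        conds = list(rng.choice(["a", "b"], size=30))
        table = summarize_classification(classes, conds)
        for cond in ("a", "b"):
            for cls in DendriteClass:
                direct = sum(
                    1 for k, c in zip(classes, conds) if c == cond and k == cls
                )
                assert table.loc[cls.value, cond] == direct
        perm = rng.permutation(30)
        table2 = summarize_classification(
            [classes[i] for i in perm], [conds[i] for i in perm]
        )
        assert table.equals(table2[table.columns])

    def test_empty_condition_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            summarize_classification([DendriteClass.NONE], ["a", "b"])


def test_robust_sd_matches_noise_scale(rng):
    x = rng.normal(0, 0.1, size=5000)
    assert robust_sd(x) == pytest.approx(0.1, rel=0.1)
    x[:200] += 5.0  # sparse events barely move the robust estimate
    assert robust_sd(x) == pytest.approx(0.1, rel=0.15)
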