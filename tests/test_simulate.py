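"""Generator correctness: determinism, degenerate limits, and distributions."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from spinedyn.io import write_trace_set
from spinedyn.simulate import (
    SimParams,
    simulate_morphology_profiles,
    simulate_spine_population,
    simulate_trace_set,
)
from spinedyn.turnover import filter_spines


class TestTraceSet:
    def test_degenerate_rates_give_constant_baseline(self, quiet_sim_params):
        traces, truth = simulate_trace_set(quiet_sim_params)
        assert np.all(traces.shaft.values == quiet_sim_params.baseline_f0)
        for tr in traces.spines.values():
            assert np.all(tr.values == quiet_sim_params.baseline_f0)
        assert truth.shaft_event_times.size == 0
        assert all(v.size == 0 for v in truth.spine_specific_event_times.values())

    def test_frame_count_is_rate_times_duration(self):
        traces, _ = simulate_trace_set(SimParams(frame_rate_hz=12, duration_s=240))
        assert traces.n_frames == 2880
        assert all(tr.n_frames == 2880 for tr in traces.spines.values())

    def test_shaft_events_invade_spines_scaled_by_gain(self):
        params = SimParams(
            shaft_event_rate_hz=0.05,
            spine_specific_rate_hz=0.0,
            noise_sd=0.0,
            invasion_gain=0.6,
            n_spines_per_dendrite=2,
            seed=11,
        )
        traces, truth = simulate_trace_set(params)
        assert truth.shaft_event_times.size > 0
        shaft_dff = traces.shaft.values / params.baseline_f0 - 1.0
        for tr in traces.spines.values():
            spine_dff = tr.values / params.baseline_f0 - 1.0
            np.testing.assert_allclose(spine_dff, 0.6 * shaft_dff, atol=1e-12)

    def test_spine_specific_events_stay_in_their_spine(self):
        params = SimParams(
            shaft_event_rate_hz=0.0,
            spine_specific_rate_hz=0.05,
            noise_sd=0.0,
            n_spines_per_dendrite=3,
            seed=5,
        )
        traces, truth = simulate_trace_set(params)
        for name, tr in traces.spines.items():
            own = truth.spine_specific_event_times[name]
            flat = np.all(tr.values == params.baseline_f0)
            assert flat == (own.size == 0)
        assert np.all(traces.shaft.values == params.baseline_f0)

    def test_event_count_matches_poisson_mean(self):
        # lambda = 0.02 Hz x 240 s = 4.8 expected events per session
        lam = 0.02 * 240
        counts = []
        for seed in range(500):
            _, truth = simulate_trace_set(
                SimParams(
                    shaft_event_rate_hz=0.02,
                    spine_specific_rate_hz=0.0,
                    n_spines_per_dendrite=1,
                    noise_sd=0.0,
                    seed=seed,
                )
            )
            counts.append(truth.shaft_event_times.size)
        counts = np.array(counts)
        se = np.sqrt(lam / counts.size)
        assert abs(counts.mean() - lam) < 3 * se

    def test_event_counts_pass_poisson_goodness_of_fit(self):
        lam = 0.05 * 240
        counts = np.array(
            [
                simulate_trace_set(
                    SimParams(
                        shaft_event_rate_hz=0.05,
                        spine_specific_rate_hz=0.0,
                        n_spines_per_dendrite=1,
                        noise_sd=0.0,
                        seed=1000 + s,
                    )
                )[1].shaft_event_times.size
                for s in range(500)
            ]
        )
        # bin tail so every expected count is >= 5
        kmax = int(sps.poisson.ppf(0.995, lam))
        kmin = int(sps.poisson.ppf(0.005, lam))
        edges = list(range(kmin, kmax + 1))
        observed = np.array(
            [np.sum(counts <= kmin)]
            + [np.sum(counts == k) for k in range(kmin + 1, kmax)]
            + [np.sum(counts >= kmax)]
        )
        expected = np.array(
            [sps.poisson.cdf(kmin, lam)]
            + [sps.poisson.pmf(k, lam) for k in range(kmin + 1, kmax)]
            + [sps.poisson.sf(kmax - 1, lam)]
        ) * counts.size
        stat = np.sum((observed - expected) ** 2 / expected)
        p = sps.chi2.sf(stat, len(observed) - 1)
        assert p > 0.01

    def test_event_times_within_session(self):
        _, truth = simulate_trace_set(SimParams(shaft_event_rate_hz=0.1, seed=3))
        assert np.all(truth.shaft_event_times >= 0)
        assert np.all(truth.shaft_event_times < 240.0)

    def test_determinism_bitwise(self, tmp_path):
        params = SimParams(seed=42, n_spines_per_dendrite=4)
        files = []
        for run in range(2):
            traces, truth = simulate_trace_set(params)
            path = tmp_path / f"run{run}.csv"
            write_trace_set(traces, path, params.to_dict(), truth.to_dict())
            files.append((path.read_bytes(), path.with_suffix(".meta.json").read_bytes()))
        assert files[0] == files[1]

    @pytest.mark.parametrize(
        "bad",
        [
            {"noise_sd": -0.1},
            {"frame_rate_hz": float("nan")},
            {"p_gen": 1.5},
            {"shaft_event_rate_hz": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimParams(**bad)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            simulate_trace_set(SimParams(frame_rate_hz=1.0, duration_s=5.0))


class TestSpinePopulation:
    def test_frozen_population_when_no_turnover(self):
        params = SimParams(p_gen=0.0, p_elim=0.0, n_spines_per_dendrite=20, seed=2)
        sessions, truth = simulate_spine_population(params)
        ids0 = [o.spine_id for o in sessions[0]]
        for prev, sess in zip(sessions, sessions[1:]):
            assert [o.spine_id for o in sess] == ids0
            # between successive sessions survivors move strictly less than
            # the 1-um matching tolerance (jitter truncated at 0.5 um)
            step = np.abs(
                np.array([o.position_um for o in sess])
                - np.array([o.position_um for o in prev])
            )
            assert step.max() <= 0.5
        for fate in truth.spine_fates:
            assert fate["eliminated"] == [] and fate["generated"] == []

    def test_requires_two_sessions(self):
        with pytest.raises(ValueError, match="n_sessions"):
            simulate_spine_population(SimParams(n_sessions=1))

    def test_fates_are_conserved_and_ids_never_resurrect(self):
        params = SimParams(
            p_gen=0.2, p_elim=0.2, n_spines_per_dendrite=30, n_sessions=6, seed=9
        )
        sessions, truth = simulate_spine_population(params)
        gone: set[int] = set()
        for k, fate in enumerate(truth.spine_fates):
            before = {o.spine_id for o in sessions[k]}
            after = {o.spine_id for o in sessions[k + 1]}
            assert set(fate["persist"]) | set(fate["eliminated"]) == before
            assert set(fate["persist"]) | set(fate["generated"]) == after
            assert gone.isdisjoint(after)
            gone |= set(fate["eliminated"])

    def test_elimination_fraction_matches_binomial(self):
        # 500 intervals of ~100 spines at p_elim = 0.1
        elim, total = 0, 0
        for seed in range(100):
            sessions, truth = simulate_spine_population(
                SimParams(
                    p_gen=0.1,
                    p_elim=0.1,
                    n_spines_per_dendrite=100,
                    n_sessions=6,
                    seed=seed,
                )
            )
            for k, fate in enumerate(truth.spine_fates):
                elim += len(fate["eliminated"])
                total += len(sessions[k])
        assert abs(elim / total - 0.1) < 0.01

    def test_balanced_birth_death_keeps_population_stable(self):
        # mean population size drifts < 5% over 5 sessions when p_gen = p_elim
        sizes = np.zeros(5)
        reps = 500
        for seed in range(reps):
            sessions, _ = simulate_spine_population(
                SimParams(
                    p_gen=0.05, p_elim=0.05, n_spines_per_dendrite=20, seed=seed
                )
            )
            sizes += [len(s) for s in sessions]
        sizes /= reps
        assert abs(sizes[-1] - sizes[0]) / sizes[0] < 0.05

    def test_generated_spines_respect_exclusion_zone(self):
        sessions, truth = simulate_spine_population(
            SimParams(p_gen=0.3, p_elim=0.0, n_spines_per_dendrite=20, seed=4)
        )
        for k, fate in enumerate(truth.spine_fates):
            new = set(fate["generated"])
            if not new:
                continue
            pos = {o.spine_id: o.position_um for o in sessions[k + 1]}
            for nid in new:
                others = [p for sid, p in pos.items() if sid != nid]
                assert min(abs(pos[nid] - p) for p in others) >= 1.0


class TestMorphologyProfiles:
    def test_all_spines_pass_filter_when_no_filopodia(self):
        obs, _ = simulate_morphology_profiles(SimParams(seed=1), 0.0)
        assert len(filter_spines(obs)) == len(obs)

    def test_no_records_pass_when_all_filopodia(self):
        obs, _ = simulate_morphology_profiles(SimParams(seed=1), 1.0)
        assert filter_spines(obs) == []

    def test_acceptance_fraction_tracks_filopodium_fraction(self):
        params = SimParams(n_spines_per_dendrite=1000, seed=8)
        obs, truth = simulate_morphology_profiles(params, 0.3)
        accepted = filter_spines(obs)
        n_spine_label = sum(
            1 for v in truth.morphology_labels.values() if v == "spine"
        )
        # the filter recovers the labels exactly by construction
        assert len(accepted) == n_spine_label
        # and the label fraction is binomial around 0.7
        se = np.sqrt(0.3 * 0.7 / 1000)
        assert abs(n_spine_label / 1000 - 0.7) < 4 * se

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_morphology_profiles(SimParams(), 1.2)
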