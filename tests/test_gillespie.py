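"""Stochastic-simulation tests: exactness, bookkeeping, determinism."""

import numpy as np
import pandas as pd
import pytest

from myodwell import (Condition, ForceModel, RateConstants, build_unicycle,
                      extract_dwells, histogram, simulate, velocity)
from myodwell.gillespie import DwellSample, Trajectory
from myodwell.histogram import HistogramError

SAT = Condition(atp=1000.0)


class TestSimulate:
    def test_seed_determinism(self, unicycle, fm):
        a = simulate(unicycle, SAT, fm, {"n_events": 2000}, seed=5)
        b = simulate(unicycle, SAT, fm, {"n_events": 2000}, seed=5)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.transition_ids, b.transition_ids)
        c = simulate(unicycle, SAT, fm, {"n_events": 2000}, seed=6)
        assert not np.array_equal(a.times, c.times)

    def test_waiting_times_exponential(self, unicycle, fm):
        # DD's only exit at [ADP]=0 is ADP release at 12/s; waiting times
        # in DD are exponential with mean 1/12
        traj = simulate(unicycle, SAT, fm, {"n_events": 60000}, seed=3)
        t = np.concatenate([[0.0], traj.times])
        # reconstruct per-event source states from the transition list
        src = [unicycle.transitions[k].source for k in traj.transition_ids]
        waits = np.diff(t)[np.array(src) == "DD"]
        se = waits.std() / np.sqrt(len(waits))
        assert abs(waits.mean() - 1.0 / 12) < 3 * se

    def test_equal_rate_branching_is_symmetric(self, fm):
        # DT with step_bwd == p_release: both exits equally likely
        rc = RateConstants(step_bwd=250.0)
        net = build_unicycle(rc)
        traj = simulate(net, SAT, fm, {"n_events": 50000}, seed=9)
        srcs = np.array([net.transitions[k].source
                         for k in traj.transition_ids])
        offs = traj.offsets[srcs == "DT"]
        frac_bwd = np.mean(offs == -1)
        n = len(offs)
        se = 0.5 / np.sqrt(n)
        assert abs(frac_bwd - 0.5) < 3 * se

    def test_backstep_fraction_matches_splitting_probability(self, unicycle,
                                                             fm):
        traj = simulate(unicycle, SAT, fm, {"n_steps": 100000}, seed=17,
                        record="mechanical")
        _, offs = traj.mechanical_events()
        frac = np.mean(offs == -1)
        p = 0.65 / 250.65 / (1 + 0.65 / 250.65)   # stationary backstep rate
        se = np.sqrt(p * (1 - p) / len(offs))
        assert abs(frac - p) < 3 * se

    def test_stop_criteria(self, unicycle, fm):
        by_events = simulate(unicycle, SAT, fm, {"n_events": 500}, seed=1)
        assert by_events.n_events == 500
        by_steps = simulate(unicycle, SAT, fm, {"n_steps": 50}, seed=1)
        assert np.sum(by_steps.offsets != 0) == 50
        by_time = simulate(unicycle, SAT, fm, {"t_max": 0.5}, seed=1)
        assert by_time.times[-1] <= 0.5
        with pytest.raises(ValueError):
            simulate(unicycle, SAT, fm, {}, seed=1)

    def test_mechanical_recording_matches_full_recording(self, unicycle, fm):
        full = simulate(unicycle, SAT, fm, {"n_steps": 200}, seed=8)
        mech = simulate(unicycle, SAT, fm, {"n_steps": 200}, seed=8,
                        record="mechanical")
        t_full, off_full = full.mechanical_events()
        assert np.array_equal(mech.times, t_full)
        assert np.array_equal(mech.offsets, off_full)


class TestPositionBookkeeping:
    def test_displacement_per_forward_step_is_step_size(self, unicycle, fm):
        traj = simulate(unicycle, SAT, fm, {"n_events": 10000}, seed=2)
        trace = traj.position_trace()
        dpos = np.diff(np.concatenate([[0.0],
                                       trace["position_nm"].to_numpy()]))
        fwd = dpos[traj.offsets == 1]
        assert len(fwd) > 0
        assert np.all(fwd == fm.step_size)
        assert np.all(dpos[traj.offsets == 0] == 0.0)

    def test_long_run_velocity_matches_steady_state(self, unicycle, fm):
        traj = simulate(unicycle, SAT, fm, {"n_steps": 20000}, seed=4,
                        record="mechanical")
        t, off = traj.mechanical_events()
        v_sim = off.sum() * fm.step_size / t[-1]
        v_theory = velocity(unicycle, SAT, fm)
        # s.e. of the renewal velocity estimate from dwell variability
        dwells = np.diff(t)
        se = v_theory * dwells.std() / dwells.mean() / np.sqrt(len(dwells))
        assert abs(v_sim - v_theory) < 3 * se


class TestExtractDwells:
    def test_adjacent_step_pairs(self, unicycle, fm):
        traj = Trajectory(unicycle, SAT, ForceModel(), 0,
                          np.array([1.0, 2.5, 3.0]),
                          np.array([4, 4, 5]), np.array([1, 1, -1]), "DD")
        sample = extract_dwells(traj)
        assert sample.records.to_dict("list") == {
            "dwell_s": [1.5, 0.5], "prev": ["f", "f"], "next": ["f", "b"]}

    def test_single_step_gives_empty_sample(self, unicycle, fm):
        traj = Trajectory(unicycle, SAT, ForceModel(), 0,
                          np.array([1.0]), np.array([4]), np.array([1]), "DD")
        with pytest.warns(UserWarning):
            sample = extract_dwells(traj)
        assert sample.n == 0

    def test_dwell_count_is_steps_minus_one(self, unicycle, fm):
        traj = simulate(unicycle, SAT, fm, {"n_steps": 321}, seed=12,
                        record="mechanical")
        assert extract_dwells(traj).n == 320


class TestHistogramOp:
    def test_area_is_one(self, unicycle, fm):
        traj = simulate(unicycle, SAT, fm, {"n_steps": 500}, seed=13,
                        record="mechanical")
        h = histogram(extract_dwells(traj), bin_width=0.02)
        assert h.area == pytest.approx(1.0)

    def test_dead_time_filters_short_dwells(self, unicycle, fm):
        sample = DwellSample(
            pd.DataFrame({"dwell_s": [0.005, 0.2, 0.4],
                          "prev": ["f"] * 3, "next": ["f"] * 3}),
            SAT, 0)
        h = histogram(sample, bin_width=0.1, dead_time=0.01)
        assert h.n_samples == 2
        with pytest.raises(HistogramError):
            histogram(sample, bin_width=0.1, dead_time=1.0)
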