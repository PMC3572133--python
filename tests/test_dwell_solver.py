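"""Dwell-solver tests: occupancies, splitting probabilities, densities,
spectra, moments — each checked against closed forms or first-step
analysis done by hand on the packaged rate table."""

import numpy as np
import pytest
from scipy import integrate

from myodwell import (Condition, build_absorbing_chain, mean_dwell,
                      absorption_probabilities, conditional_density,
                      decay_spectrum, solve_occupancies, step_densities)
from myodwell.dwell import DwellSolverError, step_statistics

from conftest import random_conditions


class TestOccupancies:
    def test_initial_condition_is_indicator(self, sat_chain):
        traj = solve_occupancies(sat_chain, "DD", np.linspace(0, 0.5, 20))
        assert traj.transient["DD"][0] == pytest.approx(1.0)
        for s in ("ED", "TD", "DT"):
            assert traj.transient[s][0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_exit_state_decays_exponentially(self, sat_chain):
        # DT at saturating ATP, no ADP/P: occupancy e^{-250.65 t}
        grid = np.array([0.0, 0.005, 0.01])
        traj = solve_occupancies(sat_chain, "DT", grid)
        assert traj.transient["DT"][-1] == pytest.approx(
            np.exp(-250.65 * 0.01), rel=1e-8)

    def test_probability_conserved_and_transients_vanish(self, sat_chain):
        grid = np.linspace(0, 2.0, 50)
        traj = solve_occupancies(sat_chain, "DT", grid)
        total = sum(traj.transient.values()) + sum(traj.absorbed.values())
        assert np.max(np.abs(total - 1.0)) < 1e-9
        assert sum(v[-1] for v in traj.transient.values()) < 1e-9

    def test_bad_grid_rejected(self, sat_chain):
        with pytest.raises(ValueError):
            solve_occupancies(sat_chain, "DD", np.array([0.1, 0.2]))


class TestAbsorption:
    def test_backstep_probability_from_post_forward_state(self, sat_chain):
        # from DT the only competing exits are the backstep (0.65) and P
        # release (250); every downstream path absorbs forward
        result = absorption_probabilities(sat_chain)
        assert result.pi("backward", "DT") == pytest.approx(
            0.65 / 250.65, rel=1e-12)
        assert result.pi("forward", "TD") == pytest.approx(1.0)

    def test_splitting_probabilities_normalize(self, sat_chain):
        result = absorption_probabilities(sat_chain)
        for s in sat_chain.states:
            assert result.by_state[s]["forward"] + \
                result.by_state[s]["backward"] == pytest.approx(1.0, abs=1e-12)


class TestConditionalDensities:
    def test_backward_conditional_is_memoryless_exit_law(self, sat_chain):
        # backward absorption happens only directly out of DT, so the
        # conditional dwell is DT's exponential exit-time law
        rho = conditional_density(sat_chain, "DT", "backward")
        t = np.linspace(0.0, 0.02, 7)
        assert rho(t) == pytest.approx(250.65 * np.exp(-250.65 * t), rel=1e-8)

    def test_density_vanishes_for_negative_times(self, sat_chain):
        rho = conditional_density(sat_chain, "DT", "forward")
        assert rho(np.array([-1.0, -0.1])) == pytest.approx([0.0, 0.0])

    def test_undefined_conditional_raises(self, unicycle, fm):
        chain = build_absorbing_chain(unicycle, Condition(atp=1000.0), fm)
        # forward absorption from TD is certain, so backward conditional
        # from TD is undefined
        with pytest.raises(DwellSolverError):
            conditional_density(chain, "TD", "backward")

    def test_normalization_and_mean_match_linear_solve(self, sat_chain):
        rho = conditional_density(sat_chain, "DT", "forward")
        integral, _ = integrate.quad(rho, 0, np.inf, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-8)


class TestStepDensities:
    def test_stationary_backstep_frequency(self, sat_chain):
        # two-state step chain built from the splitting probabilities:
        # p_b = pi_b / (1 + pi_b) with pi_b = 0.65/250.65
        stats = step_statistics(sat_chain)
        pi_b = 0.65 / 250.65
        assert stats.p_bwd == pytest.approx(pi_b / (1 + pi_b), rel=1e-10)
        assert stats.p_fwd + stats.p_bwd == pytest.approx(1.0)

    def test_total_density_is_step_type_mixture(self, sat_chain):
        dists = step_densities(sat_chain)
        stats = step_statistics(sat_chain)
        t = np.linspace(0.0, 0.3, 11)
        mixed = stats.p_fwd * dists["rho_f"](t) + \
            stats.p_bwd * dists["rho_b"](t)
        assert dists["rho_total"](t) == pytest.approx(mixed, rel=1e-9)

    def test_all_step_densities_normalized(self, sat_chain):
        for rho in step_densities(sat_chain).values():
            assert rho.mixture.integral == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("net_name", ["unicycle", "branched"])
    def test_normalization_over_random_conditions(self, net_name, unicycle,
                                                  branched, fm):
        net = {"unicycle": unicycle, "branched": branched}[net_name]
        for cond in random_conditions(10, seed=99, adp=(0.1, 500.0)):
            chain = build_absorbing_chain(net, cond, fm)
            rho = step_densities(chain)["rho_total"]
            assert rho.mixture.integral == pytest.approx(1.0, abs=1e-6)


class TestSpectrum:
    def test_acyclic_spectrum_equals_exit_rates(self, sat_chain):
        # no ADP/P rebinding: the transient graph is acyclic and the
        # eigenvalues are exactly the per-state exit rates
        spec = decay_spectrum(sat_chain)
        assert spec.rates == pytest.approx([12.0, 250.65, 900.0, 7000.0])
        assert not spec.complex_pairs

    def test_smallest_rate_at_limiting_atp_is_atp_binding(self, unicycle, fm):
        chain = build_absorbing_chain(unicycle, Condition(atp=2.0), fm)
        assert decay_spectrum(chain).smallest == pytest.approx(1.8)

    def test_two_slowest_rates_in_small_adp_limit(self, unicycle, fm):
        # as [ADP] -> 0 the two slowest modes converge to the ATP binding
        # and ADP release rates (1.8 and 12 /s at 2 µM ATP)
        for adp, rtol in [(1.0, 0.5), (0.1, 0.05), (0.001, 1e-3)]:
            chain = build_absorbing_chain(
                unicycle, Condition(atp=2.0, adp=adp), fm)
            lo = np.sort(decay_spectrum(chain).rates)[:2]
            assert lo == pytest.approx([1.8, 12.0], rel=rtol)

    def test_tail_slope_matches_smallest_eigenvalue(self, sat_chain):
        rho = step_densities(sat_chain)["rho_total"]
        lam = decay_spectrum(sat_chain).smallest
        t = np.linspace(5.0 / lam, 10.0 / lam, 40)
        slope = np.polyfit(t, np.log(rho(t)), 1)[0]
        assert slope == pytest.approx(-lam, rel=0.01)


class TestMeanDwell:
    def test_first_step_analysis_value(self, sat_chain):
        # 1/250.65 + (250/250.65) * (1/12 + 1/900 + 1/7000), by hand
        want = 1 / 250.65 + (250 / 250.65) * (1 / 12 + 1 / 900 + 1 / 7000)
        assert mean_dwell(sat_chain, "DT") == pytest.approx(want, rel=1e-10)

    def test_mean_matches_density_first_moment(self, sat_chain):
        rho = conditional_density(sat_chain, "DT", "forward")
        pi_f = absorption_probabilities(sat_chain).pi("forward", "DT")
        rho_b = conditional_density(sat_chain, "DT", "backward")
        mixed_mean = pi_f * rho.mixture.mean + (1 - pi_f) * rho_b.mixture.mean
        assert mean_dwell(sat_chain, "DT") == pytest.approx(
            mixed_mean, rel=1e-8)

    def test_uniform_rate_rescaling(self, unicycle, fm):
        from myodwell import RateConstants, build_unicycle
        c = 3.7
        rc2 = RateConstants(atp_bind=0.9 * c, adp_bind=4.5 * c,
                            adp_release_trail=12 * c, p_release=250 * c,
                            step_fwd=7000 * c, step_bwd=0.65 * c)
        chain2 = build_absorbing_chain(build_unicycle(rc2),
                                       Condition(atp=1000.0), fm)
        base = build_absorbing_chain(unicycle, Condition(atp=1000.0), fm)
        assert mean_dwell(chain2, "DT") == pytest.approx(
            mean_dwell(base, "DT") / c, rel=1e-10)
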