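"""Network structure and absorbing-chain construction tests."""

import numpy as np
import pytest

from myodwell import (Condition, ForceModel, RateConstants,
                      build_absorbing_chain, build_branched, build_unicycle,
                      bundled_network, load_network, save_network)
from myodwell.dwell import absorption_probabilities
from myodwell.network import NetworkError

from conftest import random_conditions


class TestUnicycle:
    def test_four_states_eight_transitions_two_mechanical(self, unicycle):
        assert len(unicycle.states) == 4
        assert set(unicycle.states) == {"DD", "ED", "TD", "DT"}
        assert len(unicycle.transitions) == 8
        assert len(unicycle.mechanical_transitions) == 2

    def test_forward_step_swaps_head_roles(self, unicycle):
        fwd = [t for t in unicycle.transitions if t.offset == 1]
        assert [(t.source, t.target) for t in fwd] == [("TD", "DT")]
        bwd = [t for t in unicycle.transitions if t.offset == -1]
        assert [(t.source, t.target) for t in bwd] == [("DT", "TD")]

    def test_all_transitions_in_cycle_f(self, unicycle):
        assert all(t.cycles == ("F",) for t in unicycle.transitions)

    def test_reverse_cycle_rates_default_to_zero(self, rc):
        assert rc.atp_dissoc == 0.0 and rc.p_bind == 0.0


class TestBranched:
    def test_six_states(self, branched):
        assert len(branched.states) == 6
        assert set(branched.states) == {"DD", "ED", "TD", "DT", "DE", "EE"}

    def test_gating_sets_leading_release(self):
        net = build_branched(RateConstants(gating_g=10.0))
        lead = [t for t in net.transitions if t.rate == "adp_release_lead"]
        assert lead and net.rates.value("adp_release_lead") == \
            pytest.approx(1.2)
        # g = 1 means both heads release equally fast
        assert RateConstants(gating_g=1.0).adp_release_lead == \
            pytest.approx(12.0)

    def test_slip_steps_tagged_mechanical_cycle(self, branched):
        slips = [t for t in branched.transitions
                 if t.source == "EE" and t.target == "EE"]
        assert sorted(t.offset for t in slips) == [-1, 1]
        assert all(t.cycles == ("M",) for t in slips)

    def test_missing_slip_rates_rejected(self):
        rc = RateConstants(slip_fwd=0.0, slip_bwd=0.0)
        with pytest.raises(NetworkError):
            build_branched(rc)
        assert len(build_branched(rc, include_slip=False).states) == 6

    def test_optional_wiring_toggles(self):
        rc = RateConstants(gating_g=10.0)
        extra = build_branched(rc, leading_release_from_dd=True,
                               futile_hydrolysis=True)
        base = build_branched(rc)
        assert len(extra.transitions) == len(base.transitions) + 2


class TestAbsorbingChain:
    def test_unicycle_has_four_transient_two_channels(self, sat_chain):
        assert sat_chain.n == 4
        assert len(sat_chain.channels) == 2
        assert {ch.direction for ch in sat_chain.channels} == \
            {"forward", "backward"}
        assert sat_chain.init_states == {"post_forward": "DT",
                                         "post_backward": "TD"}

    def test_exit_rates_at_saturating_atp(self, sat_chain):
        # per-state totals summed from the packaged rate table by hand
        expected = {"DD": 12.0, "ED": 900.0, "TD": 7000.0, "DT": 250.65}
        exit_rates = -np.diag(sat_chain.generator)
        for s, want in expected.items():
            assert exit_rates[sat_chain.index(s)] == pytest.approx(want)

    def test_extended_generator_conserves_probability(self, sat_chain):
        cols = sat_chain.generator.sum(axis=0) + \
            sat_chain.channel_rates.sum(axis=0)
        assert np.max(np.abs(cols)) < 1e-12

    @pytest.mark.parametrize("net_name", ["unicycle", "branched"])
    def test_conservation_and_certain_absorption_random_conditions(
            self, net_name, unicycle, branched, fm):
        net = {"unicycle": unicycle, "branched": branched}[net_name]
        for cond in random_conditions(25, seed=734):
            chain = build_absorbing_chain(net, cond, fm)
            cols = chain.generator.sum(axis=0) + \
                chain.channel_rates.sum(axis=0)
            assert np.max(np.abs(cols)) < 1e-12 * max(
                1.0, np.max(np.abs(chain.generator)))
            result = absorption_probabilities(chain)
            for s in chain.states:
                total = result.by_state[s]["forward"] + \
                    result.by_state[s]["backward"]
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_exit_state_rejected(self, fm):
        net = build_unicycle()
        # without ATP, ADP and P binding, ED has no exit at all
        with pytest.raises(NetworkError):
            build_absorbing_chain(net, Condition(), fm)


class TestNetworkIO:
    def test_bundled_unicycle_round_trip(self, tmp_path, rc):
        net = bundled_network("unicycle", rc)
        path = tmp_path / "net.json"
        save_network(net, path)
        again = load_network(path, rc)
        assert again.states == net.states
        assert again.transitions == net.transitions

    def test_bundled_files_match_builders(self):
        assert bundled_network("unicycle").transitions == \
            build_unicycle().transitions
        assert bundled_network("branched").transitions == \
            build_branched().transitions

    def test_malformed_network_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(NetworkError):
            load_network(bad)
        bad.write_text('{"states": ["DD"], "transitions": [{"from": "DD"}]}')
        with pytest.raises(NetworkError):
            load_network(bad)
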