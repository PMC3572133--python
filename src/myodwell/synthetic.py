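"""Synthetic pseudo-experimental dwell datasets with known ground truth.

Single-molecule dwell histograms exist in the literature only as
figures, so validation here is self-consistent parameter recovery:
datasets are drawn from the network dynamics at stated conditions,
binned at a fixed width with area normalization, with optional
detection dead time and the multinomial sampling noise of finite N.
Every bundle stores the parameters that generated it; those, never the
data, are the ground truth for recovery tests.

The fixture suite mirrors the experimental conditions the model is
meant to confront: saturating ATP with and without added 400 µM ADP,
limiting ATP (10 and 2 µM), and one substall- and one superstall-load
case on the branched network.  Defaults: N = 2000 dwells per condition,
gating parameter g = 10, zero dead time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gillespie
from .histogram import Histogram
from .network import NetworkSpec, build_branched, build_unicycle
from .rates import Condition, ForceModel, RateConstants

__all__ = ["SyntheticBundle", "generate", "make_fixture_suite",
           "FIXTURE_MANIFEST", "simulate_dwells"]

_BUILDERS = {"unicycle": build_unicycle, "branched": build_branched}


@dataclass(frozen=True)
class SyntheticBundle:
    name: str
    histogram: Histogram
    sample: gillespie.DwellSample
    network_id: str
    rate_constants: RateConstants
    condition: Condition
    force_model: ForceModel
    n_dwells: int
    bin_width: float
    dead_time: float
    seed: int

    def manifest_entry(self) -> dict:
        return {
            "name": self.name,
            "network": self.network_id,
            "gating_g": self.rate_constants.gating_g,
            "atp_uM": self.condition.atp,
            "adp_uM": self.condition.adp,
            "p_uM": self.condition.p,
            "force_pN": self.condition.force,
            "n_dwells": self.n_dwells,
            "bin_width_s": self.bin_width,
            "dead_time_s": self.dead_time,
            "seed": self.seed,
            "theta": self.force_model.theta,
            "chem_force_mode": self.force_model.chem_force_mode,
            "chem_force_threshold": self.force_model.chem_force_threshold,
            "chem_force_scale": self.force_model.chem_force_scale,
        }


def simulate_dwells(net: NetworkSpec, cond: Condition, fm: ForceModel,
                    n_dwells: int, seed: int) -> gillespie.DwellSample:
    """Run the SSA until ``n_dwells`` dwell records are collected."""
    traj = gillespie.simulate(net, cond, fm, {"n_steps": n_dwells + 1}, seed,
                              record="mechanical")
    sample = gillespie.extract_dwells(traj)
    if sample.n < n_dwells:
        raise gillespie.SimulationError(
            f"collected only {sample.n}/{n_dwells} dwells "
            "(trajectory absorbed?)")
    return sample


def generate(network_id: str, rc: RateConstants, cond: Condition,
             fm: ForceModel, n_dwells: int, bin_width: float,
             dead_time: float = 0.0, seed: int = 0,
             name: str | None = None) -> SyntheticBundle:
    """One synthetic 'experiment': N dwells, binned and area-normalized."""
    if n_dwells < 100:
        raise ValueError("n_dwells must be >= 100 for a stable histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    net = _BUILDERS[network_id](rc)
    sample = simulate_dwells(net, cond, fm, n_dwells, seed)
    hist = Histogram.from_dwells(sample.dwells, bin_width=bin_width,
                                 dead_time=dead_time)
    return SyntheticBundle(name or network_id, hist, sample, network_id,
                           rc, cond, fm, n_dwells, bin_width, dead_time, seed)


#: Study conditions of the fixture suite.  All branched-network draws use
#: gating g = 10 and the packaged rate constants; [ADP] = 0.1 µM stands in
#: for the experiments' nominally ADP-free buffers.
FIXTURE_MANIFEST: tuple[dict, ...] = (
    dict(name="saturating_atp", network="branched", atp=1000.0, adp=0.1,
         p=0.0, force=0.0, gating_g=10.0, n_dwells=2000, bin_width=0.02),
    dict(name="added_adp_400", network="branched", atp=1000.0, adp=400.0,
         p=0.0, force=0.0, gating_g=10.0, n_dwells=2000, bin_width=0.05),
    dict(name="limiting_atp_10", network="branched", atp=10.0, adp=0.1,
         p=0.0, force=0.0, gating_g=10.0, n_dwells=2000, bin_width=0.05),
    dict(name="limiting_atp_2", network="branched", atp=2.0, adp=0.1,
         p=0.0, force=0.0, gating_g=10.0, n_dwells=2000, bin_width=0.1),
    dict(name="substall_load", network="branched", atp=1000.0, adp=0.1,
         p=0.0, force=1.0, gating_g=10.0, n_dwells=2000, bin_width=0.02),
    dict(name="superstall_load", network="branched", atp=2.0, adp=0.1,
         p=0.0, force=3.0, gating_g=10.0, n_dwells=2000, bin_width=0.005,
         chem_force_mode="threshold", chem_force_threshold=1.9,
         chem_force_scale=1.0),
)


def make_fixture_suite(seed: int, fm: ForceModel | None = None
                       ) -> dict[str, SyntheticBundle]:
    """Deterministic fixture bundles, one per manifest entry.

    Per-fixture seeds derive from (seed, entry index) so the whole suite
    is reproducible from a single integer.
    """
    base = fm if fm is not None else ForceModel()
    out: dict[str, SyntheticBundle] = {}
    for i, entry in enumerate(FIXTURE_MANIFEST):
        rc = RateConstants(gating_g=entry["gating_g"])
        cond = Condition(atp=entry["atp"], adp=entry["adp"], p=entry["p"],
                         force=entry["force"])
        fm = ForceModel(
            theta=base.theta, step_size=base.step_size, kBT=base.kBT,
            chem_force_mode=entry.get("chem_force_mode", "none"),
            chem_force_threshold=entry.get("chem_force_threshold", 0.0),
            chem_force_scale=entry.get("chem_force_scale", 0.0))
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                       % (2**31))
        out[entry["name"]] = generate(
            entry["network"], rc, cond, fm, entry["n_dwells"],
            entry["bin_width"], dead_time=0.0, seed=sub_seed,
            name=entry["name"])
    return out
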