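# myodwell

Chemomechanical network analysis of myosin V stepping: exact dwell-time
distributions, force–velocity relations, stochastic trajectory
simulation, and inference of the head-gating parameter from dwell
histograms.

## The problem

Myosin V is a two-headed processive motor that walks along actin in
36 nm center-of-mass steps, fueled by ATP hydrolysis. In single-molecule
experiments the observable between steps is the **dwell time** — the
interval the motor sojourns at one filament site — and its distribution
is distinctly non-exponential, encoding the motor's chemical kinetics.

The package models the motor as a continuous-time Markov chain on a
small network of chemomechanical states. Each state is the nucleotide
occupancy of the trailing and leading head (T = ATP, D = ADP,
E = empty); chemical transitions (nucleotide binding/release) keep the
motor at its site, mechanical transitions step it by ±36 nm. Two
networks are bundled:

* the **uni-cycle network** (4 states DD → ED → TD → DT → DD, single
  chemomechanical cycle F), valid below the stall force;
* a **branched 6-state network** adding ADP release from the *leading*
  head (states DE, EE; enzymatic cycle E) and load-driven slip steps
  EE → EE (mechanical cycle M) that carry forced backward stepping
  above stall.

A dwell is the first-passage time of this chain started in a post-step
state and absorbed by the next mechanical transition. With transient
generator **Q** and absorption rate vector **r**, the dwell density is
the phase-type mixture

ρ(t) = **r**·exp(**Q**t)·**p**(0) / π,  π = **r**·(−**Q**)⁻¹·**p**(0),

so densities, splitting probabilities π(forward/backward), moments and
the decay spectrum all follow from one small linear-algebra problem.
The periodic (non-absorbing) network gives the stationary state and the
velocity v = ℓ·ΔJ through the stepping transitions. Transition rates
follow ω = κ·[X] for binding, ω = κ for release, and load-balanced
step rates ω_f = κ_f·e^(−θFℓ/k_BT), ω_b = κ_b·e^((1−θ)Fℓ/k_BT) with
ω_f/ω_b ∝ e^(−Fℓ/k_BT).

**Gating** — the coordination of the two heads — is quantified by the
ratio g ≥ 1 of trailing- to leading-head ADP release rates. At limiting
[ATP], ADP release from the leading head competes with ATP binding, so
dwell histograms discriminate g; the package scans the branched model
against an observed histogram with an RMSD objective and reports the
saturation onset ĝ (a lower bound on g).

Intended users: single-molecule biophysicists comparing kinetic schemes
against dwell statistics, and modelers of motor-protein chemomechanics.

## Worked example

```python
from myodwell import (Condition, ForceModel, build_unicycle,
                      build_absorbing_chain, decay_spectrum,
                      step_densities, mean_dwell, velocity)

cond = Condition(atp=1000.0)          # µM; [ADP] = [P] = 0, no load
chain = build_absorbing_chain(build_unicycle(), cond, ForceModel())

decay_spectrum(chain).rates           # [12.0, 250.65, 900.0, 7000.0]
mean_dwell(chain, "DT")               # 0.0884 s
step_densities(chain)["rho_total"](0.05)   # 6.99 1/s
velocity(build_unicycle(), cond, ForceModel())  # 406.4 nm/s
```

The four decay rates are the per-state exit rates (the chain is acyclic
at these concentrations); the slowest, 12/s, is trailing-head ADP
release and governs the distribution's tail. The mean dwell of 88 ms
and velocity of 406 nm/s follow from the same rate table. Running
`python examples/04_gating_fit.py` prints an RMSD scan over
g ∈ {1, 2, 5, 10, 20, 50} against a synthetic histogram generated at
g = 10 and 2 µM ATP — the RMSD falls from 0.081 to 0.018 1/s and
saturates with onset ĝ = 5, a lower bound consistent with the
generating value.

The `examples/` scripts cover each capability (dwell distributions,
force–velocity and stall, trajectory simulation, gating fit, superstall
ratcheting). A thin CLI mirrors them:
`myodwell dwell|spectrum|velocity|fv-curve|simulate|synth|fit-gating`.

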