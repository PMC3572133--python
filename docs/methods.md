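# Methods

## Model

The motor is a continuous-time Markov chain on a network of
chemomechanical states. A state labels the nucleotide occupancy of the
(trailing, leading) head pair over {D, T, E}; the filament position is
an integer site index with physical position = index × 36 nm. Chemical
transitions (site offset 0) bind or release ATP, ADP or P; mechanical
transitions (offset ±1) step the motor and swap head roles (forward:
TD at x → DT at x+1; backward: DT at x → TD at x−1).

Transition rates have the form ω = κ·Φ(F), with κ a bare rate constant
and Φ the load factor:

* binding: ω = κ·[X] (concentrations in µM, dilute-solution mass
  action), times a chemical load factor (below);
* release: ω = κ, load-independent under every policy;
* mechanical: Φ_f = exp(−θFℓ/k_BT), Φ_b = exp((1−θ)Fℓ/k_BT), which
  satisfy the thermodynamic balance Φ_f/Φ_b = exp(−Fℓ/k_BT) for any
  load-sharing factor θ.

Sign convention: F > 0 resists forward motion.

### Rate constants (packaged defaults)

| name | value | units | meaning |
|---|---|---|---|
| atp_bind | 0.9 | 1/(µM·s) | ATP binding to the trailing head |
| adp_bind | 4.5 | 1/(µM·s) | ADP binding (either empty head) |
| adp_release_trail | 12 | 1/s | trailing-head ADP release |
| p_release | 250 | 1/s | lumped hydrolysis + P release (DT→DD) |
| step_fwd | 7000 | 1/s | forward step out of TD |
| step_bwd | 0.65 | 1/s | backward step out of DT |
| gating_g | 1 | – | trailing/leading ADP-release ratio (≥ 1) |
| atp_dissoc, p_bind | 0 | | reverse-cycle rates, off by default |
| slip_fwd, slip_bwd | 1e−4 | 1/s | slip steps out of EE (branched) |

The six uni-cycle values are the experimentally established myosin V
kinetics this model family is built on. The leading-head release rate
is derived as adp_release_trail / g, so g = 1 means no gating and
larger g means stronger suppression of the leading head. (Gating is
sometimes written as the inverse ratio; this package standardizes on
g ≥ 1 growing with gating strength, so RMSD curves saturate toward
large g and the fit reports a lower bound.)

### Force-model parameters

* θ = 0.5 (symmetric load sharing) by default. No consensus value is
  established for myosin V; θ only reshapes the force–velocity curve
  between the F = 0 limit and the balance-fixed ratio, and is exposed
  in `ForceModel`.
* ℓ = 36 nm, k_BT = 4.114 pN·nm (25 °C), both configurable.
* Chemical load policy: default "none" (chemical rates are
  force-independent). The alternative "threshold" policy multiplies
  only the two nucleotide *binding* rates by
  exp(−s·(F−F_thr)·ℓ/k_BT) for F > F_thr. This is the minimal
  parametrization under which superstall ratcheting becomes
  ATP-independent; the superstall fixture uses F_thr = 1.9 pN (just
  below the computed stall force) and s = 1, chosen so that at 3 pN
  binding is suppressed by ~4 decades and the EE state empties only
  through slip steps. Without it, residual ATP binding at superstall
  routes the chain into TD whose forward exit is exponentially
  suppressed, producing unphysical ~70 s trap dwells.

### Branched-network wiring

The six states are {DD, ED, TD, DT, DE, EE}. The bundled default adds
to the uni-cycle: leading-head ADP release ED→EE at rate
adp_release_trail/g; trailing-head release DE→EE; ADP rebinding
EE→ED, EE→DE and DE→DD (cycle E); and slip steps EE→EE at offsets ±1
(cycle M). Two further transitions are builder toggles, off by
default:

* DD→DE (leading-head release from DD). Excluded because it is an
  ATP-independent leak: with it, the g = 1 distribution at saturating
  ATP acquires a multi-second tail (mean dwell 1.2 s vs 0.088 s) and
  the four- and six-state descriptions no longer agree at high [ATP],
  contrary to the established behaviour of this model family. With the
  leak confined to ED→EE it competes with ATP binding, which is
  exactly the mechanism that makes gating detectable at limiting [ATP]
  and invisible at saturating [ATP].
* TD→DD futile hydrolysis (cycle E closure through chemistry only).

Topology is data-driven (JSON); variant wirings can be supplied
without code changes.

The slip rates are not fixed by the dwell data this package targets;
slip_fwd = slip_bwd = 1e−4 /s was calibrated once so that, with θ = 0.5
force factors, the branched stall force at 2 µM ATP computes to
≈ 2.0 pN (the experimentally reported stall range is 1.6–2.5 pN) and
slips are negligible (2×10⁻⁴ /s total) at zero load.

## Dwell-time machinery

The absorbing chain keeps all states at one site as transients; every
mechanical transition becomes an absorption channel recording its
direction and its post-step state. The transient generator Q (column
convention, dP/dt = QP) yields:

* splitting probabilities π[channel | start] = r_c·(−Q)⁻¹·e_i by
  linear solve (first-step analysis, no time integration);
* conditional densities ρ(t) = r_c·e^{Qt}·e_i / π as exponential
  mixtures over the spectrum of −Q (phase-type densities);
* mean first-passage times by one more linear solve, used as an
  independent cross-check on the first moment of the mixtures.

Step-resolved statistics use the embedded renewal chain over post-step
states: the next dwell starts in the state the step delivered the
motor to (DT after a forward F-cycle step, TD after a backstep, EE
after a slip). Its stationary distribution gives the step-type
frequencies (p̂_f, p̂_b); the forward/backward densities ρ_f, ρ_b mix
the conditionals accordingly, and ρ_total = p̂_f·ρ_f + p̂_b·ρ_b. This
weighting is the unique choice consistent with long-trajectory dwell
statistics and is validated against simulation (Kolmogorov–Smirnov
distance < 0.01 at 10⁵ dwells) and through the Markov-renewal identity
v = ℓ·(p̂_f − p̂_b)/⟨τ⟩, which must match the flux-based velocity to
10⁻⁶ relative.

Numerical choices: spectral decomposition is the primary evaluator; a
matrix-exponential propagator is the fallback for defective generators
(reported in the result's `method` field). Linear solves use LAPACK at
machine precision; normalization is asserted to 10⁻⁸. Complex
eigenvalue pairs (possible with strong rebinding cycles) are kept in
conjugate pairs and densities evaluated as real parts, with a flag.

The periodic steady state solves the site-collapsed generator with a
normalization-row linear system in extended (long-double) precision:
at superstall the rates span ~20 decades and the net mechanical flux
is a tiny difference of large opposing fluxes, where a float64 null
space solve loses the sign of the velocity.

## Stochastic simulation

Direct-method SSA, justified by the small state count: exponential
waiting with the state's total exit rate, next transition proportional
to rates. The inner loop is numba-JIT-compiled (pure-Python fallback);
recording can be restricted to mechanical events so that dwell
collection at strong ADP rebinding (10³ chemical events per step)
stays O(steps) in memory. Dwells are the intervals between successive
mechanical events, classified by the bracketing step directions; the
leading and trailing partial intervals are discarded. Every simulation
is seeded and reproducible.

## Synthetic data

Synthetic "experiments" are drawn from the same model family used for
fitting, because the published single-molecule histograms exist only as
figures; validation is therefore self-consistent parameter recovery,
not data reproduction. Each bundle stores its generating parameters
(network, rate constants including g, condition, N, bin width, dead
time, seed) alongside the data; only those parameters are ever treated
as ground truth. Histograms are area-normalized densities on uniform
bins anchored at t = 0, matching how experimental dwell histograms are
published; an optional dead time discards dwells below the detection
resolution (default 0).

The fixture suite (N = 2000 dwells per condition, g = 10, seed-derived
sub-seeds) covers: saturating ATP (1000 µM), saturating ATP + 400 µM
ADP, limiting ATP (10 and 2 µM), a substall load (1 pN) and a
superstall load (3 pN with the threshold chemical policy). [ADP] =
0.1 µM stands in for nominally ADP-free buffers; at exactly zero ADP
the branched network's EE state would empty only through slips, which
is an artifact of truncating the network rather than motor physics.

What the generator does *not* emulate: bead–trap elasticity and
filtering noise, step-detection errors, substeps of the 36 nm stride,
and drift. Passing recovery tests therefore show that the inference
machinery is consistent and identifiable at realistic N — not that
these instrumental effects are negligible in real data.

## Gating fit

RMSD between observed and model histograms on identical bin edges
(no silent rebinning), in density units 1/s. Model histograms come
from simulation at the observed sample size, so the objective carries
matched sampling noise — the RMSD floor is then the seed-to-seed noise
level rather than zero. The reported ĝ is the saturation onset: the
plateau is estimated as the mean RMSD over the top half of the grid,
and ĝ is the smallest g within one plateau standard deviation of it.
The onset is a *lower bound* on g: beyond it, ATP binding dominates
the leading-head leak and the data cannot distinguish stronger gating.
The ATP-binding co-fit is a plain grid argmin at fixed g, returned
with the full RMSD curve; on a 17-point log grid over
[0.3, 3] /(µM·s) the recovery of the generating 0.9 /(µM·s) is within
one to two grid intervals (≤ 15 %).

## Problem sizes

Analytic operations are O(n³) in the handful of states and effectively
instant. The validation suite uses 10⁵ dwells for the
solver–simulator KS oracle, 10⁴ dwells for superstall exponentiality,
2000-dwell fixtures for recovery scans (5 seeds × 6 gating values),
and 10⁴-event trajectories for bookkeeping checks; these sizes put
sampling noise well below each test's decision threshold while keeping
the whole suite at around ten seconds of CPU.

## Known limitations

* The near-stall regime (≈ 1.8–2.2 pN) is not quantitatively described:
  a single load-sharing parameter θ on the step rates cannot reproduce
  the slow experimental velocity decrease near stall, and no power
  stroke or substep structure is modeled.
* Cycle-occupation weights for shared states are apportioned by
  outgoing flux — one defensible convention, isolated in a single
  function; crossover forces depend on it only weakly.
* The enzymatic cycle's exact wiring is a documented reconstruction
  (see above); alternative wirings can be supplied as network JSON.
* Dead-time distortion is modeled as a hard cutoff, not as missed-event
  merging of adjacent dwells.
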