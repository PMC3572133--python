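"""Exact dwell-time analysis of the absorbing-boundary chain.

The dwell of the motor between two mechanical steps is the first-passage
time of a continuous-time Markov chain started in a post-step state and
absorbed by the next mechanical transition.  With transient generator Q
(column convention, dP/dt = Q P) and absorption-rate vector r for a
target channel, the occupancy obeys P(t) = exp(Qt) P(0), the absorption
probability is pi = r . (-Q)^{-1} P(0), and the conditional dwell
density is

    rho(t) = r . exp(Qt) P(0) / pi,

a mixture of exponentials over the spectrum of -Q (a phase-type
density).  All quantities below are computed from a single
eigendecomposition of Q; linear solves provide the zeroth and first
moments independently of the spectral path, which the tests use as
internal cross-checks.

Step-resolved statistics mix the conditional densities over the
embedded renewal chain of post-step states: after each mechanical event
the motor restarts the dwell clock in the state the step delivered it
to, so the stationary frequencies of the post-step states (and hence of
forward/backward step types) follow from the absorption probabilities
alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .network import AbsorbingChain

__all__ = [
    "ExponentialMixture",
    "OccupancyTrajectory",
    "AbsorptionResult",
    "DwellDistribution",
    "DecaySpectrum",
    "StepStatistics",
    "DwellSolverError",
    "solve_occupancies",
    "absorption_probabilities",
    "conditional_density",
    "step_densities",
    "decay_spectrum",
    "mean_dwell",
]

_LINALG_TOL = 1e-10


class DwellSolverError(RuntimeError):
    """Degenerate chain or undefined conditional."""


@dataclass(frozen=True)
class ExponentialMixture:
    """Density rho(t) = Re sum_k c_k exp(-lambda_k t) on t >= 0.

    Coefficients may be negative or complex (in conjugate pairs); the
    density itself is real and non-negative for valid chains.
    """

    coefficients: np.ndarray
    decay_rates: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tt = np.clip(t[..., None], 0.0, None)
        vals = (self.coefficients * np.exp(-self.decay_rates * tt)).sum(axis=-1)
        return np.where(t >= 0, np.real(vals), 0.0)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        tt = np.clip(t[..., None], 0.0, None)
        terms = (self.coefficients / self.decay_rates
                 * (1.0 - np.exp(-self.decay_rates * tt)))
        return np.real(terms.sum(axis=-1))

    @property
    def integral(self) -> float:
        return float(np.real(np.sum(self.coefficients / self.decay_rates)))

    @property
    def mean(self) -> float:
        return float(np.real(np.sum(self.coefficients / self.decay_rates**2)))

    @property
    def slowest_rate(self) -> float:
        return float(np.min(np.real(self.decay_rates)))

    def scaled(self, factor: float) -> "ExponentialMixture":
        return ExponentialMixture(self.coefficients * factor, self.decay_rates)


@dataclass(frozen=True)
class OccupancyTrajectory:
    init: str
    times: np.ndarray
    transient: dict[str, np.ndarray]
    absorbed: dict[str, np.ndarray]      # keyed by direction "forward"/"backward"
    method: str = "spectral"


@dataclass(frozen=True)
class AbsorptionResult:
    """Splitting probabilities pi[direction | initial state].

    ``by_state`` maps initial transient state -> {"forward": p, "backward": q}
    with p + q = 1; ``by_channel`` resolves individual mechanical
    transitions (relevant for the branched network's slip steps).
    """

    by_state: dict[str, dict[str, float]]
    by_channel: dict[str, tuple[float, ...]]

    def pi(self, direction: str, init: str) -> float:
        return self.by_state[init][direction]


@dataclass(frozen=True)
class DwellDistribution:
    kind: str
    mixture: ExponentialMixture
    absorption: AbsorptionResult | None = None
    complex_spectrum: bool = False

    def __call__(self, t):
        return self.mixture(t)

    def cdf(self, t):
        return self.mixture.cdf(t)

    @property
    def mean(self) -> float:
        return self.mixture.mean

    def grid(self, t_max: float, n: int = 400):
        """(t, density) arrays on a uniform grid from 0 to t_max."""
        t = np.linspace(0.0, t_max, n)
        return t, self(t)


@dataclass(frozen=True)
class DecaySpectrum:
    """Eigenvalue magnitudes of -Q, ascending; the smallest rules the tail."""

    rates: np.ndarray
    complex_pairs: bool = False

    @property
    def smallest(self) -> float:
        return float(self.rates[0])


@dataclass(frozen=True)
class StepStatistics:
    """Embedded renewal chain over post-step states.

    p_fwd/p_bwd are the stationary step-type frequencies; psi the
    stationary distribution over post-step initial states; mean_dwell
    the stationary mean dwell between steps.
    """

    post_states: tuple[str, ...]
    psi: np.ndarray
    p_fwd: float
    p_bwd: float
    mean_dwell: float


def _eig(chain: AbsorbingChain):
    evals, vecs = linalg.eig(chain.generator)
    if np.any(np.real(evals) >= _LINALG_TOL):
        raise DwellSolverError("transient generator has a non-decaying mode; "
                               "absorption is not certain")
    cond = np.linalg.cond(vecs)
    if not np.isfinite(cond) or cond > 1e12:
        raise DwellSolverError("defective spectrum")
    return evals, vecs, linalg.inv(vecs)


def solve_occupancies(chain: AbsorbingChain, init: str,
                      grid: np.ndarray) -> OccupancyTrajectory:
    """Solve the absorbing master equation for one initial state.

    Spectral expansion by default; falls back to a matrix-exponential
    propagator if the generator is defective (reported in ``method``).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing from 0")
    i0 = chain.index(init)
    p0 = np.zeros(chain.n)
    p0[i0] = 1.0
    q = chain.generator
    try:
        evals, v, vinv = _eig(chain)
        amps = v * (vinv @ p0)          # column k: v_k * (vinv p0)_k
        pt = np.real(amps @ np.exp(np.outer(evals, grid)))
        method = "spectral"
    except DwellSolverError:
        pt = np.column_stack([linalg.expm(q * t) @ p0 for t in grid])
        method = "expm"
    transient = {s: pt[i] for i, s in enumerate(chain.states)}
    absorbed: dict[str, np.ndarray] = {}
    for direction in ("forward", "backward"):
        r = chain.absorb_rates(direction)
        # A(t) = r . Q^{-1} (exp(Qt) - I) p0
        if method == "spectral":
            acc = np.real((r @ (amps / evals))
                          @ (np.exp(np.outer(evals, grid)) - 1.0))
        else:
            acc = np.array([r @ np.linalg.solve(q, pt[:, k] - p0)
                            for k in range(len(grid))])
        absorbed[direction] = acc
    return OccupancyTrajectory(init, grid, transient, absorbed, method)


def absorption_probabilities(chain: AbsorbingChain,
                             init: str | None = None) -> AbsorptionResult:
    """Splitting probabilities by a linear solve (first-step analysis).

    Computed for every transient state; ``init`` is accepted for
    symmetry with the other operations but does not restrict the result.
    """
    q = chain.generator
    try:
        green = np.linalg.solve(-q, np.eye(chain.n))   # (-Q)^{-1}
    except np.linalg.LinAlgError:
        raise DwellSolverError("singular transient generator") from None
    by_channel: dict[str, tuple[float, ...]] = {}
    per_dir = {d: np.zeros(chain.n) for d in ("forward", "backward")}
    for k, (ch, r) in enumerate(zip(chain.channels, chain.channel_rates)):
        pis = r @ green
        key = f"{ch.source}->{ch.post_state}:{ch.direction}[{k}]"
        by_channel[key] = tuple(float(x) for x in pis)
        per_dir[ch.direction] += pis
    by_state = {
        s: {d: float(per_dir[d][i]) for d in ("forward", "backward")}
        for i, s in enumerate(chain.states)
    }
    for s, d in by_state.items():
        total = d["forward"] + d["backward"]
        if abs(total - 1.0) > 1e-9:
            raise DwellSolverError(
                f"absorption from {s} sums to {total}, not 1")
    return AbsorptionResult(by_state, by_channel)


def _conditional_mixture(chain: AbsorbingChain, init: str,
                         r: np.ndarray) -> tuple[ExponentialMixture, float, bool]:
    """Unnormalized flux density r.exp(Qt)p0 as a mixture, with pi."""
    i0 = chain.index(init)
    p0 = np.zeros(chain.n)
    p0[i0] = 1.0
    evals, v, vinv = _eig(chain)
    coeff = (r @ v) * (vinv @ p0)
    lam = -evals
    pi = float(np.real(np.sum(coeff / lam)))
    is_complex = bool(np.max(np.abs(np.imag(evals))) > _LINALG_TOL)
    return ExponentialMixture(coeff, lam), pi, is_complex


def conditional_density(chain: AbsorbingChain, init: str,
                        target: str) -> DwellDistribution:
    """Dwell density conditioned on the next step direction.

    target: "forward" or "backward" (the FWD/BWD absorbing state).
    """
    if target not in ("forward", "backward"):
        raise ValueError("target must be 'forward' or 'backward'")
    r = chain.absorb_rates(target)
    mix, pi, cplx = _conditional_mixture(chain, init, r)
    if pi <= 1e-14:
        raise DwellSolverError(
            f"absorption into {target} from {init} has probability 0; "
            "conditional density undefined")
    return DwellDistribution(f"conditional({init}->{target})",
                             mix.scaled(1.0 / pi), None, cplx)


def decay_spectrum(chain: AbsorbingChain) -> DecaySpectrum:
    evals = linalg.eigvals(chain.generator)
    lam = -evals
    cplx = bool(np.max(np.abs(np.imag(lam))) > 1e-9 * np.max(np.abs(lam)))
    if cplx:
        warnings.warn("complex eigenvalue pairs; reporting magnitudes",
                      stacklevel=2)
        vals = np.sort(np.abs(lam))
    else:
        vals = np.sort(np.real(lam))
    return DecaySpectrum(vals, cplx)


def mean_dwell(chain: AbsorbingChain, init: str) -> float:
    """Mean first-passage time to the absorbing set, by linear solve."""
    i0 = chain.index(init)
    p0 = np.zeros(chain.n)
    p0[i0] = 1.0
    try:
        y = np.linalg.solve(-chain.generator, p0)
    except np.linalg.LinAlgError:
        raise DwellSolverError("singular transient generator") from None
    return float(np.sum(y))


def step_statistics(chain: AbsorbingChain) -> StepStatistics:
    """Stationary statistics of the embedded chain of post-step states."""
    absorption = absorption_probabilities(chain)
    post_states: list[str] = []
    for ch in chain.channels:
        if ch.post_state not in post_states:
            post_states.append(ch.post_state)
    m = len(post_states)
    pmat = np.zeros((m, m))              # pmat[a, b] = P(next post-state b | a)
    for a, s in enumerate(post_states):
        for ch, key in zip(chain.channels, absorption.by_channel):
            b = post_states.index(ch.post_state)
            pmat[a, b] += absorption.by_channel[key][chain.index(s)]
    evals, vecs = linalg.eig(pmat.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    psi = np.real(vecs[:, k])
    psi = psi / psi.sum()
    p_fwd = float(sum(psi[a] * absorption.by_state[s]["forward"]
                      for a, s in enumerate(post_states)))
    tau = float(sum(psi[a] * mean_dwell(chain, s)
                    for a, s in enumerate(post_states)))
    return StepStatistics(tuple(post_states), psi, p_fwd, 1.0 - p_fwd, tau)


def step_densities(chain: AbsorbingChain) -> dict[str, DwellDistribution]:
    """Forward-step, backward-step and total dwell densities.

    rho_f and rho_b mix the conditional densities over the stationary
    post-step state distribution; rho_total = p_fwd*rho_f + p_bwd*rho_b
    with the stationary step-type frequencies as weights.  If one step
    direction is unreachable from every initial state, the total equals
    the reachable side and the missing density is flagged by a warning.
    """
    stats = step_statistics(chain)
    absorption = absorption_probabilities(chain)
    rates_ref: np.ndarray | None = None
    cplx = False
    sums = {"forward": None, "backward": None}
    weights = {"forward": stats.p_fwd, "backward": stats.p_bwd}
    for direction in ("forward", "backward"):
        r = chain.absorb_rates(direction)
        coeff_sum = None
        for a, s in enumerate(stats.post_states):
            mix, pi, c = _conditional_mixture(chain, s, r)
            cplx = cplx or c
            contrib = mix.coefficients * stats.psi[a]
            coeff_sum = contrib if coeff_sum is None else coeff_sum + contrib
            rates_ref = mix.decay_rates
        sums[direction] = coeff_sum
    out: dict[str, DwellDistribution] = {}
    total_coeff = np.zeros_like(rates_ref, dtype=complex)
    for direction, label in (("forward", "rho_f"), ("backward", "rho_b")):
        w = weights[direction]
        if w <= 1e-14:
            warnings.warn(
                f"{direction} steps unreachable; omitting {label}",
                stacklevel=2)
            continue
        mix = ExponentialMixture(sums[direction] / w, rates_ref)
        out[label] = DwellDistribution(label, mix, absorption, cplx)
        total_coeff = total_coeff + sums[direction]
    out["rho_total"] = DwellDistribution(
        "rho_total", ExponentialMixture(total_coeff, rates_ref),
        absorption, cplx)
    return out
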