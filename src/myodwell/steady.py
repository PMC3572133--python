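"""Periodic steady state of the network: fluxes, velocity, stall force.

Because every lattice site carries the same chemical state set, the
periodic network collapses onto a single site: mechanical transitions
wrap onto the same states while contributing their site offset to the
displacement bookkeeping.  The stationary distribution is the null
space of the collapsed generator; the motor velocity is the step size
times the net (excess) flux through the mechanical transitions,

    v = l * sum_mech offset * omega_m * P(source_m).

The module also exposes the Markov-renewal route to the velocity,
v = l * (p_fwd - p_bwd) / <tau>, computed entirely from the
absorbing-chain machinery — an independent identity that must agree
with the flux route and serves as a cross-module consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .dwell import step_statistics
from .network import NetworkError, NetworkSpec, build_absorbing_chain
from .rates import Condition, ForceModel, transition_rate

__all__ = [
    "SteadyStateResult",
    "periodic_steady_state",
    "velocity",
    "renewal_velocity",
    "force_velocity_curve",
    "stall_force",
    "cycle_occupation",
]


@dataclass(frozen=True)
class SteadyStateResult:
    probabilities: dict[str, float]
    fluxes: tuple[float, ...]            # one per transition, omega * P(source)
    excess_fluxes: dict[str, float]      # net flux per source->target pair
    velocity: float                      # nm/s
    cycle_weights: dict[str, float]


def _solve_longdouble(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gaussian elimination with partial pivoting in long-double precision.

    LAPACK has no extended-precision path; the collapsed generators here
    are at most a handful of states, so a direct elimination is cheap.
    """
    a = a.copy()
    b = b.copy()
    n = len(b)
    for col in range(n):
        piv = col + int(np.argmax(np.abs(a[col:, col])))
        if a[piv, col] == 0:
            raise NetworkError(
                "collapsed generator is singular; no unique steady state "
                "(disconnected network?)")
        if piv != col:
            a[[col, piv]] = a[[piv, col]]
            b[[col, piv]] = b[[piv, col]]
        for row in range(col + 1, n):
            f = a[row, col] / a[col, col]
            a[row, col:] -= f * a[col, col:]
            b[row] -= f * b[col]
    x = np.zeros(n, dtype=np.longdouble)
    for row in range(n - 1, -1, -1):
        x[row] = (b[row] - a[row, row + 1:] @ x[row + 1:]) / a[row, row]
    return x


def _collapsed_generator(net: NetworkSpec, cond: Condition,
                         fm: ForceModel) -> tuple[np.ndarray, np.ndarray]:
    idx = {s: i for i, s in enumerate(net.states)}
    n = len(net.states)
    w = np.zeros((n, n))
    omegas = np.zeros(len(net.transitions))
    for k, t in enumerate(net.transitions):
        omega = transition_rate(net.rates.value(t.rate), t.law, cond, fm)
        omegas[k] = omega
        j, i = idx[t.source], idx[t.target]
        if i != j:
            w[i, j] += omega
            w[j, j] -= omega
        # self-loops (slip steps) carry displacement but no probability flow
    return w, omegas


def periodic_steady_state(net: NetworkSpec, cond: Condition,
                          fm: ForceModel) -> SteadyStateResult:
    """Stationary distribution and fluxes of the site-collapsed network."""
    w, omegas = _collapsed_generator(net, cond, fm)
    n = w.shape[0]
    # replace one (dependent) balance row with the normalization sum(p) = 1;
    # solved in extended precision because strongly loaded networks mix
    # rates spanning ~10 decades and the net mechanical flux can be a
    # tiny difference of large reciprocal fluxes
    a = w.astype(np.longdouble)
    a[-1, :] = 1.0
    b = np.zeros(n, dtype=np.longdouble)
    b[-1] = 1.0
    p = _solve_longdouble(a, b)
    resid = float(np.max(np.abs((w.astype(np.longdouble) @ p)[:-1])))
    scale = max(float(np.max(np.abs(w))), 1.0)
    if resid > 1e-8 * scale:
        raise NetworkError(
            f"steady-state solve failed (residual {resid:.2e})")
    if np.any(p < -1e-10):
        raise NetworkError("negative stationary probability")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    idx = {s: i for i, s in enumerate(net.states)}
    fluxes_ld = [np.longdouble(omegas[k]) * p[idx[t.source]]
                 for k, t in enumerate(net.transitions)]
    fluxes = tuple(float(f) for f in fluxes_ld)
    # net flux per reciprocal pair: forward minus backward over same edge
    net_excess: dict[str, float] = {}
    for k, t in enumerate(net.transitions):
        a, b = sorted((t.source, t.target))
        key = f"{a}<->{b}" if t.offset == 0 else f"{a}<->{b}:mech"
        sign = 1.0
        if t.offset != 0:
            sign = float(t.offset)
        elif (t.source, t.target) != (a, b):
            sign = -1.0
        net_excess[key] = net_excess.get(key, 0.0) + sign * fluxes[k]
    v = fm.step_size * float(sum(
        np.longdouble(t.offset) * fluxes_ld[k]
        for k, t in enumerate(net.transitions) if t.offset != 0))
    weights = _cycle_weights(net, p, omegas, idx)
    probs = {s: float(p[idx[s]]) for s in net.states}
    return SteadyStateResult(probs, fluxes, net_excess, v, weights)


def _cycle_weights(net: NetworkSpec, p: np.ndarray, omegas: np.ndarray,
                   idx: dict[str, int]) -> dict[str, float]:
    cycles = net.cycle_names()
    if not cycles:
        raise NetworkError("network has untagged transitions (no cycles)")
    weights = {c: 0.0 for c in cycles}
    for s in net.states:
        out_flux = {c: 0.0 for c in cycles}
        for k, t in enumerate(net.transitions):
            if t.source != s:
                continue
            share = omegas[k] * p[idx[s]] / len(t.cycles)
            for c in t.cycles:
                out_flux[c] += share
        total = sum(out_flux.values())
        if total <= 0:
            # trapped state: apportion by membership of incident transitions
            incident = [c for t in net.transitions if s in (t.source, t.target)
                        for c in t.cycles]
            for c in set(incident):
                weights[c] += p[idx[s]] / len(set(incident))
            continue
        for c in cycles:
            weights[c] += p[idx[s]] * out_flux[c] / total
    return {c: float(w) for c, w in weights.items()}


def velocity(net: NetworkSpec, cond: Condition, fm: ForceModel) -> float:
    """Steady-state motor velocity in nm/s (positive = toward barbed end)."""
    return periodic_steady_state(net, cond, fm).velocity


def renewal_velocity(net: NetworkSpec, cond: Condition,
                     fm: ForceModel) -> float:
    """Velocity via the renewal identity l*(p_fwd - p_bwd)/<tau>.

    Computed from the absorbing-boundary chain only; must match
    :func:`velocity` (flux route) for any valid network.
    """
    stats = step_statistics(build_absorbing_chain(net, cond, fm))
    return fm.step_size * (stats.p_fwd - stats.p_bwd) / stats.mean_dwell


def force_velocity_curve(net: NetworkSpec, cond: Condition, fm: ForceModel,
                         forces) -> list[tuple[float, float]]:
    """Evaluate (F, v) pointwise over a force grid at fixed concentrations."""
    out = []
    for f in np.asarray(forces, dtype=float):
        out.append((float(f), velocity(net, cond.with_(force=float(f)), fm)))
    return out


def stall_force(net: NetworkSpec, cond: Condition, fm: ForceModel,
                bracket: tuple[float, float] = (0.1, 5.0),
                tol: float = 1e-3) -> float | None:
    """Root of v(F) in the bracket, or None if v does not change sign.

    The uni-cycle with blocked reverse chemistry has strictly positive
    velocity at every load, so stalling requires the branched network's
    slip cycle; None is returned (with the endpoint velocities in the
    diagnostic) rather than a spurious root.
    """
    f_lo, f_hi = bracket
    v_lo = velocity(net, cond.with_(force=f_lo), fm)
    v_hi = velocity(net, cond.with_(force=f_hi), fm)
    if v_lo * v_hi > 0:
        return None
    root = optimize.brentq(
        lambda f: velocity(net, cond.with_(force=float(f)), fm),
        f_lo, f_hi, xtol=tol)
    return float(root)


def cycle_occupation(net: NetworkSpec, cond: Condition,
                     fm: ForceModel) -> dict[str, float]:
    """Stationary weight of each tagged cycle (F, E, M).

    States exclusive to one cycle contribute their full probability;
    shared states are apportioned in proportion to their outgoing flux
    into each cycle's transitions.  Weights sum to 1.
    """
    return periodic_steady_state(net, cond, fm).cycle_weights
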