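"""Exact stochastic simulation of motor trajectories (direct-method SSA).

Realizes the continuous-time Markov dynamics of a chemomechanical
network: exponentially distributed waiting in each state, next
transition drawn proportional to its rate.  Mechanical transitions move
the motor by one lattice site (±36 nm by default); dwell times are the
intervals between successive mechanical events, classified by the
directions of the bracketing steps so that each conditional dwell
distribution can be validated against the analytic solver.

The inner event loop is JIT-compiled with numba when available (strong
ADP rebinding produces thousands of chemical events per mechanical
step, so long dwell collections run through 10^8 events); a pure-Python
loop with identical logic serves as fallback.  Recording can be
restricted to mechanical events (``record="mechanical"``) so that dwell
collection stays O(number of steps) in memory.

Reproducibility: every simulation takes an explicit seed and identical
(network, condition, seed, record mode) runs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .histogram import Histogram
from .network import NetworkSpec
from .rates import Condition, ForceModel, transition_rate

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba present in practice
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(fn):
            return fn
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = ["Trajectory", "DwellSample", "simulate", "extract_dwells",
           "histogram", "SimulationError"]

_CHUNK = 1 << 20


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Trajectory:
    """Recorded events of one stochastic realization.

    times: event times (s), strictly increasing; transition_ids index
    into ``network.transitions``; offsets are per-event site offsets (0
    for chemical events).  With ``record="mechanical"`` only stepping
    events are kept (chemical events still advance the clock and the
    hidden state).  ``n_events_total`` counts every event either way.
    ``absorbed`` flags a run that stopped in a state with zero exit
    rate.
    """

    network: NetworkSpec
    condition: Condition
    force_model: ForceModel
    seed: int
    times: np.ndarray
    transition_ids: np.ndarray
    offsets: np.ndarray
    initial_state: str
    record: str = "all"
    n_events_total: int = 0
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return len(self.times)

    def position_trace(self) -> pd.DataFrame:
        """(t_s, position_nm) at recorded events; position changes only
        at mechanical events, by exactly one step size."""
        pos = np.cumsum(self.offsets) * self.force_model.step_size
        return pd.DataFrame({"t_s": self.times, "position_nm": pos})

    def mechanical_events(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, offsets) of the mechanical events only."""
        mask = self.offsets != 0
        return self.times[mask], self.offsets[mask]


@dataclass(frozen=True)
class DwellSample:
    """Raw dwell records: (dwell_s, prev, next) step directions."""

    records: pd.DataFrame
    condition: Condition
    seed: int

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def dwells(self) -> np.ndarray:
        return self.records["dwell_s"].to_numpy()

    def subset(self, prev: str | None = None,
               next_: str | None = None) -> np.ndarray:
        """Dwells filtered by bracketing step directions ('f'/'b')."""
        df = self.records
        if prev is not None:
            df = df[df["prev"] == prev]
        if next_ is not None:
            df = df[df["next"] == next_]
        return df["dwell_s"].to_numpy()


def _compile(net: NetworkSpec, cond: Condition, fm: ForceModel):
    """Flatten the network into per-state arrays for the kernel."""
    idx = {s: i for i, s in enumerate(net.states)}
    n = len(net.states)
    per_state: list[list[tuple[float, int, int, int]]] = [[] for _ in range(n)]
    for k, t in enumerate(net.transitions):
        omega = transition_rate(net.rates.value(t.rate), t.law, cond, fm)
        if omega <= 0:
            continue
        per_state[idx[t.source]].append((omega, idx[t.target], t.offset, k))
    width = max((len(p) for p in per_state), default=1) or 1
    rates = np.zeros((n, width))
    targets = np.zeros((n, width), dtype=np.int64)
    offs = np.zeros((n, width), dtype=np.int64)
    tids = np.zeros((n, width), dtype=np.int64)
    n_out = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(per_state):
        n_out[i] = len(p)
        for j, (omega, tgt, off, k) in enumerate(p):
            rates[i, j] = omega
            targets[i, j] = tgt
            offs[i, j] = off
            tids[i, j] = k
    total = rates.sum(axis=1)
    return idx, rates, targets, offs, tids, n_out, total


@njit(cache=False)
def _seed_kernel(seed):          # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=False)
def _ssa_chunk(rates, targets, offs, tids, n_out, total,
               state, t, cap, max_events, t_max, max_steps,
               mech_only, out_t, out_id, out_off):
    """Simulate until ``cap`` events are recorded or a stop limit hits.

    Returns (n_recorded, n_events, n_steps, state, t, status) with
    status 0 = cap reached (continue), 1 = stop limit met, 2 = absorbed.
    """
    n_rec = 0
    n_ev = 0
    n_st = 0
    while n_rec < cap:
        if n_ev >= max_events or n_st >= max_steps:
            return n_rec, n_ev, n_st, state, t, 1
        tot = total[state]
        if tot <= 0.0:
            return n_rec, n_ev, n_st, state, t, 2
        t = t + np.random.exponential(1.0 / tot)
        if t > t_max:
            return n_rec, n_ev, n_st, state, t, 1
        u = np.random.random() * tot
        acc = 0.0
        k = 0
        for j in range(n_out[state]):
            acc += rates[state, j]
            k = j
            if u <= acc:
                break
        off = offs[state, k]
        n_ev += 1
        if off != 0:
            n_st += 1
        if (not mech_only) or off != 0:
            out_t[n_rec] = t
            out_id[n_rec] = tids[state, k]
            out_off[n_rec] = off
            n_rec += 1
        state = targets[state, k]
    return n_rec, n_ev, n_st, state, t, 0


if not _HAVE_NUMBA:              # pragma: no cover - numba present in practice
    _PY_RNG: dict = {"state": None}

    def _seed_kernel(seed):
        _PY_RNG["state"] = np.random.RandomState(seed)

    def _ssa_chunk(rates, targets, offs, tids, n_out, total, state, t, cap,
                   max_events, t_max, max_steps, mech_only,
                   out_t, out_id, out_off):
        rng = _PY_RNG["state"]
        n_rec = n_ev = n_st = 0
        while n_rec < cap:
            if n_ev >= max_events or n_st >= max_steps:
                return n_rec, n_ev, n_st, state, t, 1
            tot = total[state]
            if tot <= 0.0:
                return n_rec, n_ev, n_st, state, t, 2
            t = t + rng.exponential(1.0 / tot)
            if t > t_max:
                return n_rec, n_ev, n_st, state, t, 1
            u = rng.random() * tot
            acc = 0.0
            k = 0
            for j in range(n_out[state]):
                acc += rates[state, j]
                k = j
                if u <= acc:
                    break
            off = offs[state, k]
            n_ev += 1
            if off != 0:
                n_st += 1
            if (not mech_only) or off != 0:
                out_t[n_rec] = t
                out_id[n_rec] = tids[state, k]
                out_off[n_rec] = off
                n_rec += 1
            state = targets[state, k]
        return n_rec, n_ev, n_st, state, t, 0


def simulate(net: NetworkSpec, cond: Condition, fm: ForceModel,
             stop: dict, seed: int, initial_state: str | None = None,
             record: str = "all") -> Trajectory:
    """Run the SSA until a stop criterion is met.

    stop: one of {"n_events": int} (total events), {"t_max": float}, or
    {"n_steps": int} (mechanical events).  ``record`` is "all" or
    "mechanical".  A state with zero total exit rate terminates the run
    with ``absorbed=True``.
    """
    keys = set(stop) & {"n_events", "t_max", "n_steps"}
    if len(keys) != 1:
        raise ValueError("stop must specify exactly one of "
                         "n_events, t_max, n_steps")
    if record not in ("all", "mechanical"):
        raise ValueError("record must be 'all' or 'mechanical'")
    idx, rates, targets, offs, tids, n_out, total = _compile(net, cond, fm)
    if initial_state is None:
        initial_state = net.states[0]
    state = idx[initial_state]
    max_events = int(stop.get("n_events", np.iinfo(np.int64).max // 2))
    t_max = float(stop.get("t_max", np.inf))
    max_steps = int(stop.get("n_steps", np.iinfo(np.int64).max // 2))
    mech_only = record == "mechanical"
    _seed_kernel(seed % (2**32))
    t = 0.0
    n_ev_done = 0
    n_st_done = 0
    parts_t, parts_id, parts_off = [], [], []
    absorbed = False
    while True:
        cap = min(_CHUNK,
                  max_steps - n_st_done if mech_only
                  else max_events - n_ev_done)
        cap = max(int(cap), 1)
        out_t = np.empty(cap)
        out_id = np.empty(cap, dtype=np.int64)
        out_off = np.empty(cap, dtype=np.int64)
        n_rec, n_ev, n_st, state, t, status = _ssa_chunk(
            rates, targets, offs, tids, n_out, total, state, t, cap,
            max_events - n_ev_done, t_max, max_steps - n_st_done,
            mech_only, out_t, out_id, out_off)
        n_ev_done += n_ev
        n_st_done += n_st
        if n_rec:
            parts_t.append(out_t[:n_rec].copy())
            parts_id.append(out_id[:n_rec].copy())
            parts_off.append(out_off[:n_rec].copy())
        if status == 2:
            absorbed = True
            break
        if status == 1:
            break
        if n_ev_done >= max_events or n_st_done >= max_steps:
            break
    times = np.concatenate(parts_t) if parts_t else np.empty(0)
    ids = np.concatenate(parts_id) if parts_id else np.empty(0, dtype=np.int64)
    offsets = (np.concatenate(parts_off) if parts_off
               else np.empty(0, dtype=np.int64))
    return Trajectory(net, cond, fm, seed, times, ids, offsets,
                      initial_state, record, n_ev_done, absorbed)


def extract_dwells(traj: Trajectory) -> DwellSample:
    """Dwells between successive mechanical events, with step directions.

    The leading interval (before the first step) and the trailing
    partial interval are discarded; each record's ``prev``/``next`` are
    the directions ('f'/'b') of the steps bracketing the dwell.
    """
    t_mech, off_mech = traj.mechanical_events()
    if len(t_mech) < 2:
        import warnings
        warnings.warn("fewer than 2 mechanical events; empty dwell sample",
                      stacklevel=2)
        empty = pd.DataFrame({"dwell_s": [], "prev": [], "next": []})
        return DwellSample(empty, traj.condition, traj.seed)
    dwell = np.diff(t_mech)
    dirs = np.where(off_mech > 0, "f", "b")
    df = pd.DataFrame({"dwell_s": dwell,
                       "prev": dirs[:-1], "next": dirs[1:]})
    return DwellSample(df, traj.condition, traj.seed)


def histogram(sample: DwellSample, bin_width: float,
              dead_time: float = 0.0) -> Histogram:
    """Area-normalized dwell histogram with uniform bins from 0.

    Dwells shorter than ``dead_time`` are discarded first (finite
    detection resolution); an empty post-filter sample is an error.
    """
    return Histogram.from_dwells(sample.dwells, bin_width=bin_width,
                                 dead_time=dead_time)
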