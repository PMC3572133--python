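"""Chemomechanical networks and their absorbing-boundary Markov chains.

A network state is the nucleotide composition of the two bound motor
heads, written as a two-letter label (trailing, leading) with letters
D (ADP), T (ATP), E (empty).  Chemical transitions keep the motor at its
filament site (site-offset 0); mechanical transitions step it by one
lattice constant (offset +1 forward, -1 backward) and swap the head
roles, e.g. the forward step takes TD at site x into DT at site x+1.

Two networks are bundled:

* the uni-cycle network (4 states DD, ED, TD, DT; single chemomechanical
  cycle F), valid for substall loads, and
* a branched 6-state network adding leading-head ADP release (states DE,
  EE; enzymatic cycle E) and load-driven slip steps out of EE (purely
  mechanical cycle M), which carries forced backward stepping above
  stall.

Topology is data-driven: networks round-trip through a small JSON format
so variant wirings can be explored without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np

from .rates import (Condition, ForceModel, Law, RateConstants, binding,
                    mechanical, release, transition_rate)

__all__ = [
    "Transition",
    "NetworkSpec",
    "AbsorptionChannel",
    "AbsorbingChain",
    "NetworkError",
    "build_unicycle",
    "build_branched",
    "build_absorbing_chain",
    "load_network",
    "save_network",
    "bundled_network",
]

_HEADS = frozenset("DTE")


class NetworkError(ValueError):
    """Structural problem in a network description."""


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate: str                       # rate-constant name, resolved via RateConstants
    law: Law
    offset: int = 0                 # lattice-site offset: 0 chemical, ±1 mechanical
    cycles: tuple[str, ...] = ("F",)

    def __post_init__(self) -> None:
        if self.law.kind == "mechanical":
            if self.offset not in (-1, 1):
                raise NetworkError(
                    f"mechanical transition {self.source}->{self.target} "
                    f"must have offset ±1, got {self.offset}")
            want = "forward" if self.offset == 1 else "backward"
            if self.law.direction != want:
                raise NetworkError(
                    f"offset {self.offset:+d} requires direction {want!r}")
        elif self.offset != 0:
            raise NetworkError(
                f"chemical transition {self.source}->{self.target} "
                "must have offset 0")


@dataclass(frozen=True)
class NetworkSpec:
    """States, transitions and cycle tags of one chemomechanical network.

    Carries its RateConstants so that downstream solvers only need the
    network, the experimental Condition and a ForceModel.
    """

    name: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    rates: RateConstants = field(default_factory=RateConstants)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set(self.states)
        if len(seen) != len(self.states):
            raise NetworkError("duplicate state labels")
        for s in self.states:
            if len(s) != 2 or not set(s) <= _HEADS:
                raise NetworkError(
                    f"state {s!r} is not a (trailing, leading) pair over D/T/E")
        for t in self.transitions:
            if t.source not in seen or t.target not in seen:
                raise NetworkError(
                    f"transition {t.source}->{t.target} references unknown state")
            self.rates.value(t.rate)  # raises KeyError if unresolvable
        g = nx.Graph()
        g.add_nodes_from(self.states)
        g.add_edges_from((t.source, t.target)
                         for t in self.transitions if t.offset == 0)
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise NetworkError(
                f"chemical-transition graph is disconnected: {comps}")

    @property
    def mechanical_transitions(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if t.offset != 0)

    def with_rates(self, rc: RateConstants) -> "NetworkSpec":
        return replace(self, rates=rc)

    def cycle_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for t in self.transitions:
            for c in t.cycles:
                if c not in names:
                    names.append(c)
        return tuple(names)


@dataclass(frozen=True)
class AbsorptionChannel:
    """One mechanical exit of the absorbing chain.

    A channel records which transient state it leaves, the step direction,
    and the state the motor occupies at the new site directly after the
    step (the initial state of the next dwell).
    """

    transition: Transition

    @property
    def source(self) -> str:
        return self.transition.source

    @property
    def direction(self) -> str:
        return "forward" if self.transition.offset == 1 else "backward"

    @property
    def post_state(self) -> str:
        return self.transition.target


@dataclass(frozen=True)
class AbsorbingChain:
    """Transient generator + absorption channels for one lattice site.

    ``generator`` is the transient block Q in column convention
    (dP/dt = Q P): Q[i, j] >= 0 for i != j is the rate from state j to
    state i, and the diagonal carries minus the total exit rate of each
    state *including* flow into the absorbing channels, so that every
    column of the generator extended by the absorbing rows sums to zero.
    """

    states: tuple[str, ...]
    generator: np.ndarray
    channels: tuple[AbsorptionChannel, ...]
    channel_rates: np.ndarray       # shape (n_channels, n_states)
    network: NetworkSpec
    condition: Condition
    force_model: ForceModel

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise NetworkError(f"unknown state {state!r}") from None

    @property
    def n(self) -> int:
        return len(self.states)

    def absorb_rates(self, direction: str) -> np.ndarray:
        """Total rate into the FWD or BWD absorbing state, per source state."""
        rows = [r for ch, r in zip(self.channels, self.channel_rates)
                if ch.direction == direction]
        if not rows:
            return np.zeros(self.n)
        return np.sum(rows, axis=0)

    @property
    def init_states(self) -> dict[str, str]:
        """Designated post-step initial states, one per step direction.

        For the uni-cycle these are post-forward = DT and
        post-backward = TD.  When several mechanical transitions share a
        direction (branched network with slips) the channel with the
        largest absorption flux is not privileged; this map just exposes
        the cycle-F convention and the full per-channel structure lives
        in ``channels``.
        """
        out: dict[str, str] = {}
        for ch in self.channels:
            key = f"post_{ch.direction}"
            out.setdefault(key, ch.post_state)
        return out


def build_unicycle(rc: RateConstants | None = None) -> NetworkSpec:
    """The 4-state uni-cycle network (single chemomechanical cycle F).

    DD --adp_release_trail--> ED --atp_bind[ATP]--> TD --step_fwd--> DT(+1)
    --p_release--> DD, with the reverse transitions ED->DD (ADP binding),
    TD->ED (ATP dissociation, 0 by default), DT->TD (backstep, -1) and
    DD->DT (P binding, 0 by default).
    """
    rc = rc if rc is not None else RateConstants()
    trans = (
        Transition("DD", "ED", "adp_release_trail", release("ADP")),
        Transition("ED", "DD", "adp_bind", binding("ADP")),
        Transition("ED", "TD", "atp_bind", binding("ATP")),
        Transition("TD", "ED", "atp_dissoc", release("ATP")),
        Transition("TD", "DT", "step_fwd", mechanical("forward"), offset=1),
        Transition("DT", "TD", "step_bwd", mechanical("backward"), offset=-1),
        Transition("DT", "DD", "p_release", release("P")),
        Transition("DD", "DT", "p_bind", binding("P")),
    )
    return NetworkSpec("unicycle", ("DD", "ED", "TD", "DT"), trans, rc)


def build_branched(rc: RateConstants | None = None, *,
                   include_slip: bool = True,
                   leading_release_from_dd: bool = False,
                   futile_hydrolysis: bool = False) -> NetworkSpec:
    """The 6-state branched network with gating and slip cycle.

    Adds to the uni-cycle: leading-head ADP release ED->EE at rate
    adp_release_trail/gating_g — the transition that competes with ATP
    binding and carries the gating signal at limiting [ATP] — plus the
    enzymatic closure through state DE (trailing-head release DE->EE,
    ADP rebinding EE->ED, EE->DE and DE->DD; cycle E) and, when
    ``include_slip``, forced slip steps EE->EE at offsets ±1 (mechanical
    cycle M).

    ``leading_release_from_dd`` adds the second leading-head release
    DD->DE.  It is off by default: an ATP-independent leak out of DD
    broadens the dwell distribution at saturating [ATP] even without
    gating, whereas branched and uni-cycle distributions are known to
    coincide there for every g; with the leak confined to ED the escape
    competes with ATP binding and that agreement holds.
    ``futile_hydrolysis`` toggles an optional chemistry-only TD->DD
    transition (rate p_release, cycle E), off by default.
    """
    rc = rc if rc is not None else RateConstants()
    uni = build_unicycle(rc)
    trans = list(uni.transitions)
    trans += [
        Transition("ED", "EE", "adp_release_lead", release("ADP"), cycles=("E",)),
        Transition("DE", "EE", "adp_release_trail", release("ADP"), cycles=("E",)),
        Transition("EE", "ED", "adp_bind", binding("ADP"), cycles=("E",)),
        Transition("EE", "DE", "adp_bind", binding("ADP"), cycles=("E",)),
        Transition("DE", "DD", "adp_bind", binding("ADP"), cycles=("E",)),
    ]
    if leading_release_from_dd:
        trans.append(
            Transition("DD", "DE", "adp_release_lead", release("ADP"),
                       cycles=("E",)))
    if include_slip:
        if rc.slip_fwd == 0.0 and rc.slip_bwd == 0.0:
            raise NetworkError(
                "slip cycle requested but slip_fwd and slip_bwd are both 0; "
                "set rates or pass include_slip=False")
        trans += [
            Transition("EE", "EE", "slip_fwd", mechanical("forward"),
                       offset=1, cycles=("M",)),
            Transition("EE", "EE", "slip_bwd", mechanical("backward"),
                       offset=-1, cycles=("M",)),
        ]
    if futile_hydrolysis:
        trans.append(
            Transition("TD", "DD", "p_release", release("P"), cycles=("E",)))
    states = ("DD", "ED", "TD", "DT", "DE", "EE")
    return NetworkSpec("branched", states, tuple(trans), rc)


def build_absorbing_chain(net: NetworkSpec, cond: Condition,
                          fm: ForceModel) -> AbsorbingChain:
    """Evaluate rates at ``cond`` and split the site network into the
    transient generator plus absorption channels (one per mechanical
    transition)."""
    idx = {s: i for i, s in enumerate(net.states)}
    n = len(net.states)
    q = np.zeros((n, n))
    channels: list[AbsorptionChannel] = []
    channel_rates: list[np.ndarray] = []
    for t in net.transitions:
        omega = transition_rate(net.rates.value(t.rate), t.law, cond, fm)
        j = idx[t.source]
        if t.offset == 0:
            q[idx[t.target], j] += omega
            q[j, j] -= omega
        else:
            row = np.zeros(n)
            row[j] = omega
            channels.append(AbsorptionChannel(t))
            channel_rates.append(row)
            q[j, j] -= omega
    chain = AbsorbingChain(net.states, q, tuple(channels),
                           np.array(channel_rates), net, cond, fm)
    exit_rates = -np.diag(q)
    if np.any(exit_rates <= 0):
        dead = [s for s, r in zip(net.states, exit_rates) if r <= 0]
        raise NetworkError(
            f"states {dead} have zero exit rate; absorption is not certain")
    return chain


# -- JSON round-trip ---------------------------------------------------------

def _law_to_dict(law: Law) -> dict:
    d = {"type": law.kind}
    if law.species is not None:
        d["species"] = law.species
    if law.direction is not None:
        d["direction"] = law.direction
    return d


def save_network(net: NetworkSpec, path: str | Path) -> None:
    doc = {
        "name": net.name,
        "states": list(net.states),
        "transitions": [
            {
                "from": t.source,
                "to": t.target,
                "rate": t.rate,
                "law": _law_to_dict(t.law),
                "offset": t.offset,
                "cycles": list(t.cycles),
            }
            for t in net.transitions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _network_from_doc(doc: dict, rc: RateConstants) -> NetworkSpec:
    try:
        states = tuple(doc["states"])
        trans = tuple(
            Transition(
                e["from"], e["to"], e["rate"],
                Law(e["law"]["type"], e["law"].get("species"),
                    e["law"].get("direction")),
                e.get("offset", 0),
                tuple(e.get("cycles", ["F"])),
            )
            for e in doc["transitions"]
        )
    except KeyError as exc:
        raise NetworkError(f"network file missing key {exc}") from None
    return NetworkSpec(doc.get("name", "network"), states, trans, rc)


def load_network(path: str | Path, rc: RateConstants | None = None) -> NetworkSpec:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkError(f"malformed network file {path}: {exc}") from None
    return _network_from_doc(doc, rc if rc is not None else RateConstants())


def bundled_network(name: str, rc: RateConstants | None = None) -> NetworkSpec:
    """Load a packaged network by id ('unicycle' or 'branched')."""
    fname = {"unicycle": "unicycle.json",
             "branched": "branched_default.json"}.get(name)
    if fname is None:
        raise NetworkError(f"no bundled network named {name!r}")
    text = resources.files("myodwell.data").joinpath(fname).read_text()
    return _network_from_doc(json.loads(text),
                             rc if rc is not None else RateConstants())
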