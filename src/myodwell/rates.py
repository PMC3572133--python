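"""Transition-rate laws for chemomechanical motor networks.

Every transition rate of the network has the form omega = kappa * Phi(F),
where kappa is a bare rate constant and Phi accounts for external load.
Chemical binding rates additionally carry the nucleotide concentration,
omega = kappa * [X] * Phi_chem(F), as appropriate for dilute solutions.
Mechanical (stepping) rates obey the thermodynamic balance condition

    Phi_fwd(F) / Phi_bwd(F) = exp(-F * l / kBT)

for the step size l, which any load-sharing split must respect.  The
implemented split is Phi_fwd = exp(-theta*F*l/kBT) and
Phi_bwd = exp((1-theta)*F*l/kBT) with load-sharing factor theta in [0, 1].

Units: concentrations in µM, forces in pN, lengths in nm, energies in
pN·nm, rates in 1/s, second-order rate constants in 1/(µM·s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "RateConstants",
    "ForceModel",
    "Condition",
    "Law",
    "binding",
    "release",
    "mechanical",
    "transition_rate",
    "RateLawError",
]


class RateLawError(ValueError):
    """Invalid input to a rate law (negative concentration, bad species...)."""


@dataclass(frozen=True)
class RateConstants:
    """Bare rate constants of the myosin V network.

    Defaults are the experimentally determined uni-cycle values:
    ATP binding 0.9 /(µM·s), ADP binding 4.5 /(µM·s), trailing-head ADP
    release 12 /s, lumped hydrolysis + P release 250 /s, forward step
    7000 /s, backward step 0.65 /s.

    ``gating_g`` is the trailing-to-leading ADP release ratio (>= 1, with
    g = 1 meaning no gating); the leading-head release rate is derived as
    ``adp_release_trail / gating_g``.  ``slip_fwd``/``slip_bwd`` are the
    bare rates of the purely mechanical slip cycle of the branched
    network, active under forced stepping.
    """

    atp_bind: float = 0.9
    adp_bind: float = 4.5
    adp_release_trail: float = 12.0
    p_release: float = 250.0
    step_fwd: float = 7000.0
    step_bwd: float = 0.65
    gating_g: float = 1.0
    atp_dissoc: float = 0.0
    p_bind: float = 0.0
    slip_fwd: float = 1e-4
    slip_bwd: float = 1e-4

    def __post_init__(self) -> None:
        for name in (
            "atp_bind", "adp_bind", "adp_release_trail", "p_release",
            "step_fwd", "step_bwd", "atp_dissoc", "p_bind",
            "slip_fwd", "slip_bwd",
        ):
            if getattr(self, name) < 0:
                raise RateLawError(f"rate constant {name} must be >= 0")
        if self.gating_g < 1:
            raise RateLawError("gating_g must be >= 1 (g = 1 means no gating)")

    @property
    def adp_release_lead(self) -> float:
        """ADP release rate from the leading head (1/s)."""
        return self.adp_release_trail / self.gating_g

    def value(self, name: str) -> float:
        """Resolve a rate-constant reference by name (incl. derived names)."""
        if name == "adp_release_lead":
            return self.adp_release_lead
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown rate constant {name!r}") from None

    def with_(self, **kw) -> "RateConstants":
        return replace(self, **kw)


#: Names binding against which a chemical force factor may act
#: (the two nucleotide binding rates; P binding is left untouched).
_FORCE_SENSITIVE_BINDING = frozenset({"ATP", "ADP"})


@dataclass(frozen=True)
class ForceModel:
    """Load dependence of the transition rates.

    theta: load-sharing factor of the mechanical step, in [0, 1].
    step_size: motor step size l in nm (36 nm for myosin V).
    kBT: thermal energy in pN·nm (4.114 at 25 °C).
    chem_force_mode: "none" (chemical rates force-independent, default) or
        "threshold" (the two nucleotide *binding* rates are exponentially
        suppressed above chem_force_threshold with dimensionless strength
        chem_force_scale).
    """

    theta: float = 0.5
    step_size: float = 36.0
    kBT: float = 4.114
    chem_force_mode: str = "none"
    chem_force_threshold: float = 0.0
    chem_force_scale: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise RateLawError("theta must lie in [0, 1]")
        if self.step_size <= 0 or self.kBT <= 0:
            raise RateLawError("step_size and kBT must be > 0")
        if self.chem_force_mode not in ("none", "threshold"):
            raise RateLawError(
                f"unknown chem_force_mode {self.chem_force_mode!r}")

    def _exponent(self, force: float) -> float:
        x = force * self.step_size / self.kBT
        if not math.isfinite(x):
            raise RateLawError("non-finite force exponent F*l/kBT")
        return x

    def forward_factor(self, force: float) -> float:
        """Load factor of a forward mechanical step, exp(-theta*F*l/kBT)."""
        return math.exp(-self.theta * self._exponent(force))

    def backward_factor(self, force: float) -> float:
        """Load factor of a backward step, exp((1-theta)*F*l/kBT)."""
        return math.exp((1.0 - self.theta) * self._exponent(force))

    def chemical_factor(self, force: float, species: str | None) -> float:
        if self.chem_force_mode == "none":
            return 1.0
        if species not in _FORCE_SENSITIVE_BINDING:
            return 1.0
        if force <= self.chem_force_threshold:
            return 1.0
        excess = force - self.chem_force_threshold
        return math.exp(-self.chem_force_scale * excess
                        * self.step_size / self.kBT)


@dataclass(frozen=True)
class Condition:
    """Experimental condition: nucleotide concentrations (µM) and load (pN).

    Positive force resists forward motion; assisting loads are negative.
    """

    atp: float = 0.0
    adp: float = 0.0
    p: float = 0.0
    force: float = 0.0

    def __post_init__(self) -> None:
        for name in ("atp", "adp", "p"):
            if getattr(self, name) < 0:
                raise RateLawError(f"concentration [{name.upper()}] must be >= 0")

    def concentration(self, species: str) -> float:
        try:
            return {"ATP": self.atp, "ADP": self.adp, "P": self.p}[species]
        except KeyError:
            raise RateLawError(f"undefined species {species!r}") from None

    def with_(self, **kw) -> "Condition":
        return replace(self, **kw)


@dataclass(frozen=True)
class Law:
    """Kinetic law of a transition.

    kind: "binding" (chemical, needs species), "release" (chemical),
    or "mechanical" (needs direction "forward"/"backward").
    """

    kind: str
    species: str | None = None
    direction: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "binding" and self.species is None:
            raise RateLawError("binding law requires a species")
        if self.kind == "mechanical" and self.direction not in (
                "forward", "backward"):
            raise RateLawError("mechanical law requires direction "
                               "'forward' or 'backward'")
        if self.kind not in ("binding", "release", "mechanical"):
            raise RateLawError(f"unknown law kind {self.kind!r}")


def binding(species: str) -> Law:
    return Law("binding", species=species)


def release(species: str | None = None) -> Law:
    return Law("release", species=species)


def mechanical(direction: str) -> Law:
    return Law("mechanical", direction=direction)


def transition_rate(kappa: float, law: Law, cond: Condition,
                    fm: ForceModel) -> float:
    """Effective transition rate omega (1/s) for one transition.

    binding:    kappa * [X] * Phi_chem(F)
    release:    kappa * Phi_chem(F)        (Phi_chem = 1 by default)
    mechanical: kappa * exp(-theta*F*l/kBT)        (forward)
                kappa * exp((1-theta)*F*l/kBT)     (backward)
    """
    if kappa < 0:
        raise RateLawError("rate constant must be >= 0")
    if law.kind == "binding":
        conc = cond.concentration(law.species)
        rate = kappa * conc * fm.chemical_factor(cond.force, law.species)
    elif law.kind == "release":
        # release rates are load-independent under every policy; only the
        # nucleotide *binding* rates are suppressed in threshold mode
        rate = kappa * 1.0
    else:  # mechanical
        if law.direction == "forward":
            rate = kappa * fm.forward_factor(cond.force)
        else:
            rate = kappa * fm.backward_factor(cond.force)
    if not math.isfinite(rate):
        raise RateLawError("non-finite transition rate (force exponent overflow)")
    return rate
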