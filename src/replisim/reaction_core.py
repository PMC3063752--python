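"""Molecules, kinetic parameters and stochastic reaction rules.

The model world contains two chemical forms of the same information-carrying
polymer: RNA-form molecules, which can act both as templates and as
template-directed polymerases (catalysts), and DNA-form molecules, which can
act only as templates.  A catalyst is either an RNA polymerase (Rp, its
products are RNA-form) or a DNA polymerase (Dp, products are DNA-form), and
carries two recognition rate constants, ``rrec`` for RNA templates and
``drec`` for DNA templates, both confined to [0, 1].

Replication is a two-step reaction: a free RNA-form catalyst binds a free
template into a complex (rate = the matching recognition constant, times a
constant advantage factor ``k_p`` if the template is a parasite), the complex
dissociates at one minus that recognition constant, or replicates at rate
``k`` into an available resource unit, producing a copy of the template whose
form is set by the catalyst's polymerase type.  Molecules decay back into
resource at a form-dependent rate; decay of one complex member frees the
other.

This module is the single source of truth for those rules at the level of
individual molecules.  The lattice engines re-express the same rules over
flat arrays for speed; the well-mixed-lattice versus mass-action-ODE
calibration test pins the two representations to each other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Role",
    "Form",
    "Bond",
    "Label",
    "ReplicatorState",
    "KineticParams",
    "complex_formation_rate",
    "complex_dissociation_rate",
    "mutate_offspring",
    "replicate",
    "decay_rates",
]


class Role(enum.IntEnum):
    """Catalytic identity of a molecule."""

    Rp = 1          # RNA polymerase: products are RNA-form
    Dp = 2          # DNA polymerase: products are DNA-form
    parasite = 3    # no catalytic activity; favoured template


class Form(enum.IntEnum):
    """Chemical form the information is currently held in."""

    RNA = 0
    DNA = 1


class Bond(enum.IntEnum):
    free = 0
    catalyst_in_complex = 1
    template_in_complex = 2


class Label(enum.IntEnum):
    """Lineage label propagated template-side (see :mod:`replisim.lineage`)."""

    none = 0
    RNA_origin = 1
    DNA_origin = 2


@dataclass
class ReplicatorState:
    """One molecule.

    Parasites carry inert ``rrec``/``drec`` fields so that the parasite
    mutation channel is a plain role flip; the values are never read for a
    parasite.
    """

    role: Role
    form: Form
    rrec: float
    drec: float
    bond: Bond = Bond.free
    partner: Optional["ReplicatorState"] = field(default=None, repr=False)
    lineage_label: Label = Label.none

    def is_catalyst(self) -> bool:
        """Only free-standing chemistry decides this: RNA-form, non-parasite."""
        return self.form == Form.RNA and self.role != Role.parasite

    def validate(self) -> None:
        if not (0.0 <= self.rrec <= 1.0 and 0.0 <= self.drec <= 1.0):
            raise ValueError("recognition parameters must lie in [0, 1]")
        if self.bond == Bond.catalyst_in_complex and not self.is_catalyst():
            raise ValueError(
                "DNA-form molecules and parasites cannot occupy the catalyst "
                "side of a complex"
            )
        if (self.bond != Bond.free) != (self.partner is not None):
            raise ValueError("bond state and partner reference disagree")
        if self.partner is not None and self.partner.partner is not self:
            raise ValueError("partner back-reference broken")


class ConfigurationError(ValueError):
    """Raised for parameter sets that violate model invariants."""


class InvalidEventError(ValueError):
    """Raised when a reaction is requested between incompatible molecules."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and mutation probabilities.

    ``d_rna`` and ``d_dna`` are equal in the baseline model; setting
    ``d_dna < d_rna`` implements the differential-stability variant used with
    the instantaneous-replication control.  The five mutation probabilities
    are mutually exclusive alternatives per replication and must sum to at
    most one.
    """

    k: float = 1.0              # replication rate constant of a formed complex
    d_rna: float = 0.05         # decay rate, RNA-form
    d_dna: float = 0.05         # decay rate, DNA-form
    diff: float = 0.01          # diffusion (neighbour-swap) rate
    k_p: float = 2.0            # parasite complex-formation advantage, >= 1
    mu_r: float = 0.0           # P(mutate rrec) per replication
    mu_d: float = 0.0           # P(mutate drec)
    mu_rp_to_dp: float = 0.0    # P(Rp -> Dp role flip)
    mu_dp_to_rp: float = 0.0    # P(Dp -> Rp), zero by default
    mu_par: float = 0.0         # P(catalyst -> parasite)
    delta: float = 0.05         # half-width of the uniform mutation step
    complex_formation_enabled: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError("k must be positive")
        if self.d_rna < 0 or self.d_dna < 0 or self.diff < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.k_p < 1:
            raise ConfigurationError("k_p must be >= 1")
        if self.delta <= 0:
            raise ConfigurationError("delta must be positive")
        mu_sum = (self.mu_r + self.mu_d + self.mu_rp_to_dp
                  + self.mu_dp_to_rp + self.mu_par)
        probs = (self.mu_r, self.mu_d, self.mu_rp_to_dp,
                 self.mu_dp_to_rp, self.mu_par)
        if any(p < 0 or p > 1 for p in probs) or mu_sum > 1.0 + 1e-12:
            raise ConfigurationError(
                "mutation probabilities must be in [0,1] and sum to <= 1"
            )

    def decay_rate(self, form: Form) -> float:
        return self.d_rna if form == Form.RNA else self.d_dna

    def max_event_rate(self) -> float:
        """Largest per-molecule total event rate, for time-step selection.

        A free catalyst can decay, bind (recognition <= 1, times ``k_p`` for a
        parasite template) or diffuse; a complexed catalyst can decay,
        dissociate (<= 1) or replicate at ``k``, plus diffuse.
        """
        d = max(self.d_rna, self.d_dna)
        free = d + self.k_p + self.diff
        bound = d + 1.0 + self.k + self.diff
        return max(free, bound)


def complex_formation_rate(catalyst: ReplicatorState,
                           template: ReplicatorState,
                           params: KineticParams) -> float:
    """Rate constant at which ``catalyst`` binds ``template``.

    The catalyst's RNA-recognition constant applies to RNA-form templates and
    its DNA-recognition constant to DNA-form templates; parasite templates of
    either form receive the constant factor ``k_p``.
    """
    if not catalyst.is_catalyst():
        raise InvalidEventError("catalyst side must be an RNA-form Rp or Dp")
    a = catalyst.rrec if template.form == Form.RNA else catalyst.drec
    if template.role == Role.parasite:
        a *= params.k_p
    return a


def complex_dissociation_rate(template_form: Form,
                              catalyst: ReplicatorState) -> float:
    """One minus the matching recognition constant (parasite factor excluded:
    the advantage acts on binding only)."""
    a = catalyst.rrec if template_form == Form.RNA else catalyst.drec
    return 1.0 - a


def mutate_offspring(role: Role, rrec: float, drec: float,
                     params: KineticParams,
                     rng: np.random.Generator) -> tuple[Role, float, float]:
    """Apply at most one mutation channel to an offspring's heritable state.

    Exactly one of the four channels fires, or none: a uniform step of
    half-width ``delta`` on ``rrec`` (clamped to [0,1]), the same on ``drec``,
    a polymerase-type flip, or conversion into a parasite.  Channel choice is
    a single uniform draw against cumulative probabilities, which enforces
    mutual exclusivity by construction.  Parasite templates breed true.
    """
    if role == Role.parasite:
        return role, rrec, drec
    u = rng.random()
    c = params.mu_r
    if u < c:
        rrec = float(np.clip(rrec + rng.uniform(-params.delta, params.delta),
                             0.0, 1.0))
        return role, rrec, drec
    c += params.mu_d
    if u < c:
        drec = float(np.clip(drec + rng.uniform(-params.delta, params.delta),
                             0.0, 1.0))
        return role, rrec, drec
    c += params.mu_rp_to_dp
    if u < c:
        if role == Role.Rp:
            role = Role.Dp
        return role, rrec, drec
    c += params.mu_dp_to_rp
    if u < c:
        if role == Role.Dp:
            role = Role.Rp
        return role, rrec, drec
    c += params.mu_par
    if u < c:
        role = Role.parasite
    return role, rrec, drec


def replicate(catalyst: ReplicatorState, template: ReplicatorState,
              params: KineticParams,
              rng: np.random.Generator) -> ReplicatorState:
    """Produce a copy of ``template`` and dissolve the complex.

    The product inherits the template's role and recognition parameters
    (subject to :func:`mutate_offspring`) and its lineage label; its form is
    RNA if the catalyst is an Rp, DNA if it is a Dp.  Both complex partners
    return to the free state — the two-step reaction scheme lists all three
    molecules as free products.
    """
    if not catalyst.is_catalyst():
        raise InvalidEventError("only RNA-form Rp/Dp molecules catalyse")
    role, rrec, drec = mutate_offspring(template.role, template.rrec,
                                        template.drec, params, rng)
    product_form = Form.RNA if catalyst.role == Role.Rp else Form.DNA
    if catalyst.bond != Bond.free:
        catalyst.bond = Bond.free
        catalyst.partner = None
    if template.bond != Bond.free:
        template.bond = Bond.free
        template.partner = None
    return ReplicatorState(role=role, form=product_form, rrec=rrec, drec=drec,
                           lineage_label=template.lineage_label)


def decay_rates(molecule: ReplicatorState,
                params: KineticParams) -> float:
    """Per-molecule decay rate; complex members decay independently, and the
    surviving partner is freed (handled by the engines)."""
    return params.decay_rate(molecule.form)


def form_complex(catalyst: ReplicatorState, template: ReplicatorState) -> None:
    """Bind two free molecules into a catalyst/template complex."""
    if catalyst.bond != Bond.free or template.bond != Bond.free:
        raise InvalidEventError("both molecules must be free")
    if not catalyst.is_catalyst():
        raise InvalidEventError("catalyst side must be an RNA-form Rp or Dp")
    catalyst.bond = Bond.catalyst_in_complex
    template.bond = Bond.template_in_complex
    catalyst.partner = template
    template.partner = catalyst


def dissolve_complex(member: ReplicatorState) -> None:
    """Return both partners of a complex to the free state."""
    other = member.partner
    member.bond = Bond.free
    member.partner = None
    if other is not None:
        other.bond = Bond.free
        other.partner = None
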