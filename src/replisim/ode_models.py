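"""Deterministic mass-action companions of the lattice models.

The state tracks, per replicator species and chemical form, the
concentration of free molecules, plus one concentration per complex type
(catalyst species x template species x template form).  The resource is not
integrated separately: it is the capacity minus all molecules, complexes
counting their two members — exactly the empty-square bookkeeping of the
lattice, so mass conservation holds identically.

Reactions follow the two-step scheme: complex formation at the catalyst's
matching recognition constant (times ``k_p`` for parasite templates),
dissociation at one minus the base constant, replication at ``k`` times the
resource, producing a template copy whose form is set by the catalyst's
polymerase type and freeing both partners, and first-order decay of every
molecule with partner release from complexes.  Mutation terms are omitted:
this model isolates the deterministic population dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .reaction_core import ConfigurationError, Form, KineticParams, Role

__all__ = [
    "Species",
    "ODESystem",
    "build_derivatives",
    "integrate",
    "ODEResult",
    "steady_state_ratio_scan",
    "invasion_experiment",
    "free_supply_ratio_for_equal_complex_production",
    "selfrep_system",
    "transcription_system",
    "transcription_like_system",
    "transcription_rt_system",
]

EXTINCTION_FRACTION = 1e-6  # of capacity; integrator-noise floor


@dataclass(frozen=True)
class Species:
    name: str
    role: Role
    rrec: float
    drec: float

    def __post_init__(self) -> None:
        if not (0 <= self.rrec <= 1 and 0 <= self.drec <= 1):
            raise ConfigurationError("recognition constants must be in [0,1]")


class ODESystem:
    """Index bookkeeping for the species/complex state vector."""

    def __init__(self, species: Sequence[Species], capacity: float = 1.0):
        if capacity <= 0:
            raise ConfigurationError("capacity must be positive")
        self.species = list(species)
        self.capacity = capacity
        self.free_index: dict[tuple[str, Form], int] = {}
        for s in self.species:
            for f in (Form.RNA, Form.DNA):
                self.free_index[(s.name, f)] = len(self.free_index)
        self.n_free = len(self.free_index)
        # complex types: RNA-form non-parasite catalyst x any template form
        self.complexes: list[tuple[Species, Species, Form]] = []
        for cat in self.species:
            if cat.role == Role.parasite:
                continue
            for tmpl in self.species:
                for f in (Form.RNA, Form.DNA):
                    a = cat.rrec if f == Form.RNA else cat.drec
                    if a > 0:
                        self.complexes.append((cat, tmpl, f))
        self.n_complex = len(self.complexes)
        self.n_state = self.n_free + self.n_complex

    def zero_state(self) -> np.ndarray:
        return np.zeros(self.n_state)

    def set_free(self, y: np.ndarray, name: str, form: Form,
                 value: float) -> None:
        y[self.free_index[(name, form)]] = value

    def get_free(self, y: np.ndarray, name: str, form: Form) -> float:
        return float(y[self.free_index[(name, form)]])

    def resource(self, y: np.ndarray) -> float:
        return self.capacity - float(y[:self.n_free].sum()) \
            - 2.0 * float(y[self.n_free:].sum())

    def total_of(self, y: np.ndarray, name: str,
                 form: Optional[Form] = None) -> float:
        """Total concentration of a species (free plus complexed)."""
        total = 0.0
        for f in (Form.RNA, Form.DNA):
            if form is not None and f != form:
                continue
            total += self.get_free(y, name, f)
        for idx, (cat, tmpl, f) in enumerate(self.complexes):
            c = float(y[self.n_free + idx])
            if cat.name == name and (form is None or form == Form.RNA):
                total += c
            if tmpl.name == name and (form is None or form == f):
                total += c
        return total

    def catalyst_mass(self, y: np.ndarray) -> float:
        """Total RNA-form, non-parasite concentration (free + complexed)."""
        return sum(self.total_of(y, s.name, Form.RNA) for s in self.species
                   if s.role != Role.parasite)


def build_derivatives(system: ODESystem,
                      params: KineticParams) -> Callable[[float, np.ndarray],
                                                         np.ndarray]:
    """Compile the mass-action right-hand side for ``system``."""
    nf = system.n_free
    k = params.k
    d_form = {Form.RNA: params.d_rna, Form.DNA: params.d_dna}
    i_cat = np.empty(system.n_complex, dtype=np.intp)
    i_tmpl = np.empty(system.n_complex, dtype=np.intp)
    i_prod = np.empty(system.n_complex, dtype=np.intp)
    a_base = np.empty(system.n_complex)
    a_eff = np.empty(system.n_complex)
    d_t = np.empty(system.n_complex)
    for idx, (cat, tmpl, f) in enumerate(system.complexes):
        i_cat[idx] = system.free_index[(cat.name, Form.RNA)]
        i_tmpl[idx] = system.free_index[(tmpl.name, f)]
        prod_form = Form.RNA if cat.role == Role.Rp else Form.DNA
        i_prod[idx] = system.free_index[(tmpl.name, prod_form)]
        a = cat.rrec if f == Form.RNA else cat.drec
        a_base[idx] = a
        a_eff[idx] = a * (params.k_p if tmpl.role == Role.parasite else 1.0)
        d_t[idx] = d_form[f]
    d_free = np.empty(nf)
    for (name, f), i in system.free_index.items():
        d_free[i] = d_form[f]
    d_cat = params.d_rna  # catalyst side is always RNA-form

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        x = y[:nf]
        c = y[nf:]
        r = system.capacity - x.sum() - 2.0 * c.sum()
        dy = np.zeros_like(y)
        dx = dy[:nf]
        dx -= d_free * x
        if system.n_complex:
            F = a_eff * x[i_cat] * x[i_tmpl]
            D = (1.0 - a_base) * c
            R = k * c * r
            dy[nf:] = F - D - R - (d_cat + d_t) * c
            np.add.at(dx, i_cat, -F + D + R + d_t * c)
            np.add.at(dx, i_tmpl, -F + D + R + d_cat * c)
            np.add.at(dx, i_prod, R)
        return dy

    return rhs


@dataclass
class ODEResult:
    t: np.ndarray
    y: np.ndarray
    system: ODESystem
    outcome: str            # "survival" | "extinction"

    def final(self) -> np.ndarray:
        return self.y[:, -1]

    def final_total(self, name: str, form: Optional[Form] = None) -> float:
        return self.system.total_of(self.final(), name, form)


def integrate(system: ODESystem, params: KineticParams, y0: np.ndarray,
              t_end: float, t_eval: Optional[np.ndarray] = None,
              rtol: float = 1e-8, atol: float = 1e-12) -> ODEResult:
    """Integrate to ``t_end`` and classify survival vs extinction.

    Extinction means the total catalyst concentration falls below
    ``EXTINCTION_FRACTION`` of the capacity.  On solver failure the
    integration is retried once with tighter tolerances before aborting.
    """
    if t_end <= 0:
        raise ConfigurationError("t_end must be positive")
    rhs = build_derivatives(system, params)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="Radau",
                        t_eval=t_eval, rtol=rtol * 1e-2, atol=atol * 1e-2)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    mass = system.catalyst_mass(y[:, -1])
    outcome = ("extinction"
               if mass < EXTINCTION_FRACTION * system.capacity
               else "survival")
    return ODEResult(t=sol.t, y=y, system=system, outcome=outcome)


# ---------------------------------------------------------------------------
# canonical systems
# ---------------------------------------------------------------------------

def selfrep_system(rrec: float = 0.4, drec: float = 0.0) -> ODESystem:
    """Pure self-replication: a single RNA replicase species."""
    return ODESystem([Species("Rp", Role.Rp, rrec, drec)])


def transcription_system() -> ODESystem:
    """Idealized transcription: DNA-specialist Rp and Dp (both rrec=0,
    drec=1)."""
    return ODESystem([Species("Rp", Role.Rp, 0.0, 1.0),
                      Species("Dp", Role.Dp, 0.0, 1.0)])


def transcription_like_system(rp_rrec: float = 1.0) -> ODESystem:
    """Dual-specificity Rp plus DNA replicase — the compartment-evolved
    configuration."""
    return ODESystem([Species("Rp", Role.Rp, rp_rrec, 1.0),
                      Species("Dp", Role.Dp, 0.0, 1.0)])


def transcription_rt_system(rt_rrec: float = 0.01) -> ODESystem:
    """Transcription plus reverse transcription (Dp recognises RNA at
    ``rt_rrec``)."""
    return ODESystem([Species("Rp", Role.Rp, 0.0, 1.0),
                      Species("Dp", Role.Dp, rt_rrec, 1.0)])


def symmetric_start(system: ODESystem, total: float = 0.4) -> np.ndarray:
    """Equal free concentrations of every species x form pair."""
    y0 = system.zero_state()
    per = total / system.n_free
    for key in system.free_index:
        system.set_free(y0, key[0], key[1], per)
    return y0


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def steady_state_ratio_scan(ratios: Sequence[float],
                            params: Optional[KineticParams] = None,
                            dna_total: float = 0.2, rna_each: float = 0.1,
                            t_end: float = 5e3) -> list[dict]:
    """Outcome of the pure transcription system across initial Rp^DNA:Dp^DNA
    ratios.

    The system is symmetric under exchange of Rp and Dp, so the equilibrium
    composition varies continuously with the initial DNA-template ratio (a
    line of equilibria, not a single attractor); the extremes starve one
    catalyst and collapse.
    """
    params = params or KineticParams()
    out = []
    for ratio in ratios:
        system = transcription_system()
        y0 = system.zero_state()
        frac = ratio / (1.0 + ratio) if np.isfinite(ratio) else 1.0
        system.set_free(y0, "Rp", Form.DNA, dna_total * frac)
        system.set_free(y0, "Dp", Form.DNA, dna_total * (1.0 - frac))
        system.set_free(y0, "Rp", Form.RNA, rna_each)
        system.set_free(y0, "Dp", Form.RNA, rna_each)
        res = integrate(system, params, y0, t_end)
        yf = res.final()
        out.append({
            "ratio": ratio,
            "outcome": res.outcome,
            "Rp_DNA": system.total_of(yf, "Rp", Form.DNA),
            "Dp_DNA": system.total_of(yf, "Dp", Form.DNA),
            "Rp_RNA": system.total_of(yf, "Rp", Form.RNA),
            "Dp_RNA": system.total_of(yf, "Dp", Form.RNA),
        })
    return out


def invasion_experiment(mutant: Species, inoculum: float = 0.001,
                        params: Optional[KineticParams] = None,
                        rp_rrec: float = 1.0,
                        t_equil: float = 5e3, t_invade: float = 5e3,
                        equil_tol: float = 1e-7) -> dict:
    """Introduce a mutant Rp into the equilibrated transcription-like system.

    The resident (dual-specificity Rp + DNA replicase) is integrated to
    equilibrium; the mutant's free RNA and DNA forms are then each raised to
    ``inoculum`` and the combined system is integrated on.  The outcome
    classifies whether the mutant pool grew, stayed small, or the resident
    collapsed.
    """
    params = params or KineticParams()
    resident = transcription_like_system(rp_rrec)
    res = integrate(resident, params, symmetric_start(resident), t_equil)
    rhs = build_derivatives(resident, params)
    if float(np.max(np.abs(rhs(0.0, res.final())))) > equil_tol:
        warnings.warn("resident system not at equilibrium before invasion")
    full = ODESystem([Species("Rp", Role.Rp, rp_rrec, 1.0),
                      Species("Dp", Role.Dp, 0.0, 1.0),
                      mutant])
    y0 = full.zero_state()
    for name in ("Rp", "Dp"):
        for f in (Form.RNA, Form.DNA):
            full.set_free(y0, name, f, resident.get_free(res.final(), name, f))
    # complexes re-form quickly; free-molecule transfer is sufficient
    full.set_free(y0, mutant.name, Form.RNA, inoculum)
    full.set_free(y0, mutant.name, Form.DNA, inoculum)
    res2 = integrate(full, params, y0, t_invade)
    mutant_total = res2.final_total(mutant.name)
    resident_cat = (res2.final_total("Rp", Form.RNA)
                    + res2.final_total("Dp", Form.RNA))
    initial_mutant = 2.0 * inoculum
    if resident_cat < EXTINCTION_FRACTION:
        verdict = "resident_collapsed"
    elif mutant_total <= 10.0 * initial_mutant:
        verdict = "mutant_stays_small"
    else:
        verdict = "mutant_grows"
    return {
        "verdict": verdict,
        "mutant_total": mutant_total,
        "initial_mutant": initial_mutant,
        "resident_catalysts": resident_cat,
        "outcome": res2.outcome,
    }


def free_supply_ratio_for_equal_complex_production() -> float:
    """Free-molecule requirement ratio Rp^RNA : Dp^RNA for equal production
    of the two RNA-replication complexes.

    In a transcription system with added RNA replication, the Rp-catalysed
    RNA-replication step forms two complex types: Rp^RNA binding an Rp^RNA
    template, and Rp^RNA binding a Dp^RNA template.  Producing them at equal
    rates draws free molecules according to the formation stoichiometry; the
    ratio of the two demands quantifies the intrinsic asymmetry that makes
    Dp^RNA better replicated, per molecule, than Rp^RNA.
    """
    # stoichiometric consumption of (free Rp^RNA, free Dp^RNA) per formation
    consume_rr = np.array([2, 0])   # Rp^RNA catalyst + Rp^RNA template
    consume_rd = np.array([1, 1])   # Rp^RNA catalyst + Dp^RNA template
    demand = consume_rr + consume_rd    # equal unit fluxes of each complex
    return float(demand[0] / demand[1])
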