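"""Template-descent labeling: measuring the direction of information flow.

Every molecule carries a lineage label that is inherited strictly from the
template side of a replication event, regardless of the product's chemical
form.  The descent protocol labels each molecule by its *current* form
(RNA-origin or DNA-origin), runs the dynamics until, for each tracked
species, the whole surviving population carries a single label (per-species
fixation), records which label won and the standing DNA-form fraction at
labeling time, then re-labels and repeats.  A species whose descent fixes on
DNA-origin labels more often than its standing DNA-form fraction predicts
receives its information predominantly through DNA templates — the
operational signature of a division of labor between template (DNA) and
catalyst (RNA).

Labels are observers only: they never enter any rate, so a labeled and an
unlabeled run with the same seed are bit-identical in everything but the
label layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .reaction_core import Form, KineticParams, Label
from .surface_ca import Grid, _check_dt, default_dt, step_surface

__all__ = [
    "assign_labels",
    "detect_fixation",
    "DescentRecord",
    "DescentSummary",
    "run_descent_protocol",
    "fixation_bias_test",
]


def assign_labels(grid: Grid) -> Grid:
    """Label every molecule by its current form (deterministic, in place)."""
    occ = grid.kind != 0
    grid.label[:] = 0
    grid.label[occ] = grid.form[occ] + 1   # RNA->RNA_origin, DNA->DNA_origin
    return grid


def detect_fixation(grid: Grid, species_names: Sequence[str],
                    thresholds=None) -> dict[str, dict]:
    """Per classified species: is the whole population on one label, and
    which?

    Extinct species are reported as absent rather than fixed.
    """
    from .io_analysis import classify_array

    codes, names = classify_array(grid, thresholds)
    out: dict[str, dict] = {}
    for name in species_names:
        idx = names.index(name)
        members = np.flatnonzero(codes == idx)
        if members.size == 0:
            out[name] = {"present": False, "fixed": False, "label": None,
                         "n": 0, "dna_fraction": np.nan}
            continue
        labels = grid.label[members]
        uniq = np.unique(labels[labels != 0])
        fixed = uniq.size == 1 and np.all(labels != 0)
        out[name] = {
            "present": True,
            "fixed": bool(fixed),
            "label": Label(int(uniq[0])).name if fixed else None,
            "n": int(members.size),
            "dna_fraction": float(np.mean(grid.form[members] == Form.DNA)),
        }
    return out


@dataclass
class DescentRecord:
    cycle_index: int
    species: str
    fixed_label: Optional[str]          # None if the cycle ran out of budget
    fraction_dna_form: float            # at labeling time
    completed: bool
    passes_used: int


@dataclass
class DescentSummary:
    records: list[DescentRecord] = field(default_factory=list)
    cycles_run: int = 0

    def species_summary(self, species: str) -> dict:
        recs = [r for r in self.records if r.species == species]
        done = [r for r in recs if r.completed]
        n_dna = sum(r.fixed_label == "DNA_origin" for r in done)
        n_rna = sum(r.fixed_label == "RNA_origin" for r in done)
        return {
            "species": species,
            "cycles_completed": len(done),
            "cycles_incomplete": len(recs) - len(done),
            "frac_fixed_dna": n_dna / len(done) if done else np.nan,
            "frac_fixed_rna": n_rna / len(done) if done else np.nan,
            "mean_dna_form_fraction": float(np.nanmean(
                [r.fraction_dna_form for r in recs])) if recs else np.nan,
        }


def protocol_params(params: KineticParams) -> KineticParams:
    """The protocol is run with the Rp->Dp mutation channel disabled."""
    return dc_replace(params, mu_rp_to_dp=0.0)


def run_descent_protocol(grid: Grid, params: KineticParams,
                         n_cycles: int,
                         tracked_species: Sequence[str],
                         dt: Optional[float] = None,
                         seed: Optional[int] = None,
                         check_interval: int = 25,
                         budget_passes: Optional[int] = None,
                         pilot_cap: int = 200_000,
                         budget_factor: float = 50.0,
                         thresholds=None) -> DescentSummary:
    """Run the label / wait-for-fixation / re-label cycle ``n_cycles`` times.

    The per-cycle step budget defaults to ``budget_factor`` times the mean
    fixation time of the first (pilot) cycle, which itself is capped at
    ``pilot_cap`` passes.  Cycles that do not fix every tracked species
    within budget are flagged incomplete and excluded from the fixation
    denominators (with a warning).  The Rp->Dp mutation channel is disabled
    for the duration of the protocol.
    """
    params = protocol_params(params)
    if dt is None:
        dt = default_dt(params)
    _check_dt(params, dt)
    grid.seed_kernel_rng(seed)
    summary = DescentSummary()
    budget = budget_passes
    cycle_times: list[int] = []     # passes to complete each full cycle
    for cycle in range(n_cycles):
        assign_labels(grid)
        start = detect_fixation(grid, tracked_species, thresholds)
        fractions = {s: start[s]["dna_fraction"] for s in tracked_species}
        passes = 0
        cap = budget if budget is not None else pilot_cap
        fixed_at: dict[str, Optional[int]] = {s: None for s in tracked_species}
        while passes < cap:
            step_surface(grid, params, dt, check_interval)
            passes += check_interval
            state = detect_fixation(grid, tracked_species, thresholds)
            for s in tracked_species:
                if fixed_at[s] is None and (state[s]["fixed"]
                                            or not state[s]["present"]):
                    fixed_at[s] = passes
            if all(v is not None for v in fixed_at.values()):
                break
        state = detect_fixation(grid, tracked_species, thresholds)
        for s in tracked_species:
            done = state[s]["fixed"] or not state[s]["present"]
            summary.records.append(DescentRecord(
                cycle_index=cycle,
                species=s,
                fixed_label=state[s]["label"] if state[s]["fixed"] else None,
                fraction_dna_form=fractions[s],
                completed=bool(done and state[s]["present"]),
                passes_used=fixed_at[s] if fixed_at[s] is not None
                else passes,
            ))
            if not done:
                warnings.warn(
                    f"cycle {cycle}: {s} did not fix within {cap} passes; "
                    "excluded from fixation fractions")
        summary.cycles_run += 1
        # the budget is set from whole-cycle completion times (the slowest
        # species dominates); a trivially instant species cannot shrink it
        if all(v is not None for v in fixed_at.values()):
            cycle_times.append(max(fixed_at.values()))
        if budget is None and cycle_times:
            # 50x the pilot's completion time, never beyond the hard cap
            budget = int(min(max(budget_factor * float(np.mean(cycle_times)),
                                 10 * check_interval), pilot_cap))
    return summary


def fixation_bias_test(n_fixed_dna: int, n_cycles: int,
                       standing_dna_fraction: float) -> dict:
    """Is descent fixation biased toward DNA beyond the standing DNA-form
    fraction?

    Under the null that a cycle fixes on the DNA-origin label with
    probability equal to the standing DNA-form fraction (labels are assigned
    by form, so a neutral lineage process would fix on each label with
    probability equal to its initial share), the number of DNA-fixed cycles
    is binomial.  Returns the one-sided exact binomial p-value for an excess
    of DNA fixations, plus the observed fraction.
    """
    test = stats.binomtest(n_fixed_dna, n_cycles, standing_dna_fraction,
                           alternative="greater")
    return {
        "observed_fraction": n_fixed_dna / n_cycles if n_cycles else np.nan,
        "null_fraction": standing_dna_fraction,
        "p_value": float(test.pvalue),
        "biased": bool(test.pvalue < 0.05),
    }
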