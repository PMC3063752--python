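"""Canned experiments: the package's headline analyses at configurable scale.

Each function sets up a study condition from the scenario presets, runs the
relevant engine, and returns plain dictionaries of measured quantities.
They are consumed by the acceptance checks and by ``scripts/acceptance.py``;
scales default to desk-sized lattices (the methods note discusses what the
full-scale runs add).
"""

from __future__ import annotations

import numpy as np

from . import ode_models as om
from .compartment_cpm import CompartmentModel, CPMParams, cpm_sweep, \
    divide_compartment, make_compartment_grid
from .io_analysis import neutral_trait_drift
from .lineage import fixation_bias_test, run_descent_protocol
from .reaction_core import Form, KineticParams, Role
from .surface_ca import (Grid, PopulationSpec, SurfaceScenario, census,
                         default_dt, initialize_surface, run_surface,
                         step_surface)

__all__ = [
    "wellmixed_vs_ode",
    "ode_outcome_table",
    "deterioration_experiment",
    "parasite_experiment",
    "cpm_mechanics",
    "descent_experiment",
    "fitness_assay",
    "moran_i",
]

# calibrated (decay, diffusion) pairs of the two preset families
WAVE_KINETICS = dict(d_rna=0.05, d_dna=0.05, diff=0.01)
TRANS_KINETICS = dict(d_rna=0.02, d_dna=0.02, diff=0.1)


# ---------------------------------------------------------------------------
# 1. lattice vs mass action
# ---------------------------------------------------------------------------

def _wellmixed_system(which: str, params: KineticParams):
    if which == "selfrep":
        comp = [PopulationSpec(Role.Rp, Form.RNA, 0.4, 0.0, 1.0)]
        system = om.selfrep_system(0.4, 0.0)
        density = 0.5        # inside the interior attractor's basin
    elif which == "transcription":
        comp = [PopulationSpec(r, f, 0.0, 1.0, 0.25)
                for r in (Role.Rp, Role.Dp) for f in (Form.RNA, Form.DNA)]
        system = om.transcription_system()
        density = 0.4
    else:
        raise ValueError(which)
    return comp, system, density


def wellmixed_vs_ode(which: str = "selfrep", size: int = 256,
                     t_end: float = 40.0, dt: float = 0.01,
                     n_checkpoints: int = 20,
                     seeds: tuple[int, ...] = (0, 1, 2)) -> dict:
    """Species-density trajectories of the global-interaction lattice
    against the mass-action companion with the same constants.

    Returns per-checkpoint lattice means across seeds, the ODE solution,
    and the largest |z| score with sigma estimated from the replicate
    spread (floored at the binomial sampling error).
    """
    params = KineticParams()
    comp, system, density = _wellmixed_system(which, params)
    interval = t_end / n_checkpoints
    pools = [(f"{'Rp' if s.role == Role.Rp else 'Dp'}_{s.form.name}",
              "Rp" if s.role == Role.Rp else "Dp", s.form)
             for s in comp]
    runs = []
    for seed in seeds:
        sc = SurfaceScenario(size, size, density, comp, params,
                             seed=int(seed), wellmixed=True)
        g = initialize_surface(sc)
        traj = run_surface(g, params, t_end, dt=dt,
                           record_interval=interval)
        runs.append(np.stack([traj.series(key) / g.n_sites
                              for key, _, _ in pools]))
        times = np.array(traj.times)
    ca = np.stack(runs)                       # (seed, pool, time)
    ca_mean = ca.mean(axis=0)
    ca_std = ca.std(axis=0, ddof=1)
    y0 = system.zero_state()
    per = density / len(comp)
    for _, name, form in pools:
        system.set_free(y0, name, form, per)
    res = om.integrate(system, params, y0, t_end, t_eval=times)
    ode = np.stack([[system.total_of(res.y[:, i], name, form)
                     for i in range(times.size)]
                    for _, name, form in pools])
    binom = np.sqrt(np.maximum(ode * (1 - ode), 1e-5) / (size * size))
    sigma = np.maximum(ca_std, binom)
    # the band is the Monte-Carlo fluctuation scale itself: a replicate-mean
    # trajectory must stay within 3 sigma of the mass-action path
    z = np.abs(ca_mean - ode) / sigma
    return {"times": times, "pools": [p[0] for p in pools],
            "ca_mean": ca_mean, "ode": ode, "sigma": sigma,
            "z": z, "max_z": float(z[:, 1:].max()),
            "final_density_ca": float(ca_mean[:, -1].sum()),
            "final_density_ode": float(ode[:, -1].sum())}


# ---------------------------------------------------------------------------
# 2. ODE outcome table
# ---------------------------------------------------------------------------

def ode_outcome_table(rt_small: float = 0.01) -> dict:
    """Survival/extinction of the four deterministic experiments."""
    params = KineticParams()
    out: dict = {}
    s1 = om.transcription_system()
    out["transcription"] = om.integrate(
        s1, params, om.symmetric_start(s1), 2e4).outcome
    s2 = om.transcription_like_system()
    out["transcription_like"] = om.integrate(
        s2, params, om.symmetric_start(s2), 2e4).outcome
    s3 = om.transcription_rt_system(rt_small)
    out["transcription_rt"] = om.integrate(
        s3, params, om.symmetric_start(s3), 2e7).outcome
    inv = om.invasion_experiment(om.Species("Rpm", Role.Rp, 0.0, 0.0),
                                 inoculum=0.001, params=params)
    out["invasion_verdict"] = inv["verdict"]
    out["invasion_mutant_total"] = inv["mutant_total"]
    return out


# ---------------------------------------------------------------------------
# 3. evolutionary deterioration (well-mixed, large population)
# ---------------------------------------------------------------------------

_DETERIORATION_SYSTEMS = {
    "selfrep": [("Rp", Form.RNA, 1.0, 1.0, 1.0)],
    "translike": [("Rp", Form.RNA, 1.0, 1.0, 0.25),
                  ("Rp", Form.DNA, 1.0, 1.0, 0.25),
                  ("Dp", Form.RNA, 0.0, 1.0, 0.25),
                  ("Dp", Form.DNA, 0.0, 1.0, 0.25)],
    "translike_rt": [("Rp", Form.RNA, 1.0, 1.0, 0.25),
                     ("Rp", Form.DNA, 1.0, 1.0, 0.25),
                     ("Dp", Form.RNA, 1.0, 1.0, 0.25),
                     ("Dp", Form.DNA, 1.0, 1.0, 0.25)],
}


def deterioration_experiment(size: int = 128, t_end: float = 6000.0,
                             seeds: tuple[int, ...] = (0, 1),
                             dt: float = 0.4) -> dict:
    """Decline of the mean RNA-replication activity (``rrec`` of Rp) in the
    three well-mixed replicator systems, plus a mutation-only neutral null.

    The null matches the stationary per-capita turnover (the decay rate)
    and the mutation kernel; its decline is entirely the boundary-clamp
    drift of a trait starting at 1.
    """
    params = KineticParams(mu_r=0.01, mu_d=0.01, **WAVE_KINETICS)
    out: dict = {"t_end": t_end}
    for name, spec in _DETERIORATION_SYSTEMS.items():
        declines = []
        for seed in seeds:
            comp = [PopulationSpec(Role[r], f, rr, dd, fr)
                    for r, f, rr, dd, fr in spec]
            sc = SurfaceScenario(size, size, 0.3, comp, params,
                                 seed=int(seed), wellmixed=True)
            g = initialize_surface(sc)
            traj = run_surface(g, params, t_end, dt=dt,
                               record_interval=t_end / 10)
            rr = traj.series("mean_rrec_Rp")
            final = rr[np.isfinite(rr)][-1]
            declines.append(1.0 - final)
        out[f"decline_{name}"] = float(np.mean(declines))
        out[f"decline_{name}_per_seed"] = [float(x) for x in declines]
    # neutral reference: same turnover (decay rate) and mutation kernel
    rng = np.random.default_rng(int(seeds[0]) + 9173)
    nulls = []
    for _ in range(len(seeds)):
        null = neutral_trait_drift(
            n=int(0.3 * size * size), v0=1.0, mu=params.mu_r,
            delta=params.delta, turnover=params.d_rna,
            times=[t_end], rng=rng)
        nulls.append(1.0 - null[-1])
    out["decline_neutral"] = float(np.mean(nulls))
    return out


# ---------------------------------------------------------------------------
# 4. parasites: well-mixed catastrophe vs spatial rescue
# ---------------------------------------------------------------------------

def moran_i(field: np.ndarray) -> float:
    """Moran's I spatial autocorrelation (rook weights) of a 2-D field."""
    f = field - field.mean()
    num = (f[:-1, :] * f[1:, :]).sum() + (f[:, :-1] * f[:, 1:]).sum()
    n_pairs = f[:-1, :].size + f[:, :-1].size
    denom = (f ** 2).mean()
    if denom == 0:
        return 0.0
    return float((num / n_pairs) / denom)


def parasite_experiment(size: int = 128, t_end: float = 2500.0,
                        seed: int = 0, block: int = 4) -> dict:
    """Self-replicators with a mutational parasite influx: extinction under
    global interactions, survival with spatial pattern under local ones.

    Pattern formation is quantified by Moran's I of the coarse-grained
    catalyst occupancy against a site-permutation null (z-score).
    """
    params = KineticParams(mu_par=1e-4, **WAVE_KINETICS)
    comp = [PopulationSpec(Role.Rp, Form.RNA, 0.9, 0.0, 1.0)]
    out: dict = {}
    for mode in ("wellmixed", "spatial"):
        sc = SurfaceScenario(size, size, 0.3, comp, params,
                             seed=int(seed), wellmixed=(mode == "wellmixed"))
        g = initialize_surface(sc)
        traj = run_surface(g, params, t_end, dt=default_dt(params),
                           record_interval=t_end / 20)
        out[f"{mode}_final_molecules"] = int(traj.counts[-1]["total"])
        out[f"{mode}_extinct"] = bool(traj.extinct)
        if mode == "spatial":
            occ = (g.kind == int(Role.Rp)).reshape(size, size).astype(float)
            coarse = occ.reshape(size // block, block,
                                 size // block, block).mean(axis=(1, 3))
            obs = moran_i(coarse)
            rng = np.random.default_rng(int(seed) + 55)
            null = np.array([moran_i(rng.permutation(
                coarse.ravel()).reshape(coarse.shape)) for _ in range(200)])
            out["moran_i"] = obs
            out["moran_z"] = float((obs - null.mean())
                                   / max(null.std(), 1e-12))
    return out


# ---------------------------------------------------------------------------
# 5. CPM mechanics
# ---------------------------------------------------------------------------

def cpm_mechanics(seed: int = 0) -> dict:
    """Volume-vs-target tracking RMS, exact conservation at division, and
    the death of an empty compartment."""
    from . import _kernels

    g = Grid(64, 64)
    xs, ys = np.meshgrid(np.arange(64), np.arange(64))
    g.comp[((xs - 32) ** 2 + (ys - 32) ** 2 <= 100).ravel()] = 1
    model = CompartmentModel(g, KineticParams(), CPMParams())
    target = 250.0
    model._target[1] = target
    _kernels.seed_kernel(int(seed) + 1)
    vols = []
    for s in range(2500):
        cpm_sweep(model, 1)
        if s >= 500:
            vols.append(model._volume[1])
    vols = np.asarray(vols, float)
    rms = float(np.sqrt(np.mean((vols - target) ** 2)) / target)

    rng = np.random.default_rng(int(seed) + 2)
    g2 = Grid(64, 64)
    g2.comp[((xs - 32) ** 2 + (ys - 32) ** 2 <= 81).ravel()] = 1
    sites = np.flatnonzero(g2.comp == 1)
    g2.kind[rng.choice(sites, 40, replace=False)] = int(Role.Rp)
    model2 = CompartmentModel(g2, KineticParams(), CPMParams())
    v0 = int(model2._volume[1])
    ids = divide_compartment(model2, 1, rng)
    counts = model2.replicator_counts()
    conserved = (int(model2._volume[ids[0]] + model2._volume[ids[1]]) == v0
                 and int(counts[ids[0]] + counts[ids[1]]) == 40)

    g3 = Grid(48, 48)
    g3.comp[((xs[:48, :48] - 24) ** 2
             + (ys[:48, :48] - 24) ** 2 <= 36).ravel()] = 1
    model3 = CompartmentModel(g3, KineticParams(), CPMParams())
    model3.refresh_targets()          # no molecules -> target 0
    _kernels.seed_kernel(int(seed) + 3)
    died_after = None
    for s in range(4000):
        cpm_sweep(model3, 1)
        if model3._volume[1] == 0:
            died_after = s
            break
    return {"volume_rms": rms, "division_conserved": bool(conserved),
            "empty_compartment_died": died_after is not None,
            "death_sweep": died_after}


# ---------------------------------------------------------------------------
# 6. descent protocol
# ---------------------------------------------------------------------------

def coexistence_grid(size: int, params: KineticParams, seed: int) -> Grid:
    """Self-replication band + transcription band (the evolved community of
    the standard surface run, set up directly)."""
    selfrep = [PopulationSpec(Role.Rp, Form.RNA, 0.9, 0.0, 1.0)]
    trans = [PopulationSpec(r, f, 0.0, 1.0, 0.25)
             for r in (Role.Rp, Role.Dp) for f in (Form.RNA, Form.DNA)]
    sc = SurfaceScenario(size, size, 0.3, [], params, seed=int(seed),
                         bands=[selfrep, trans])
    return initialize_surface(sc)


def descent_experiment(size: int = 256, n_cycles: int = 30,
                       seed: int = 0, warmup: float = 1000.0,
                       cycles_per_community: int = 5) -> dict:
    """Template-descent fixation statistics on the surface community.

    Runs the label / fix / re-label protocol and reports, per tracked
    species, the fraction of completed cycles fixed on DNA-origin labels,
    the standing DNA-form fraction, and the binomial bias comparison
    between the two.

    At desk scale the three-species community has a finite lifetime (the
    transcription clumps slowly coarsen away on small lattices), so the
    protocol is run in batches over independently seeded communities,
    ``cycles_per_community`` cycles each — the per-cycle statistic is
    unchanged, only the substrate is refreshed.
    """
    params = KineticParams(mu_par=1e-5, **TRANS_KINETICS)
    tracked = ["transcriptase", "DNA_replicase", "RNA_replicase"]
    records = []
    cycles_done = 0
    batch = 0
    while cycles_done < n_cycles:
        want = min(cycles_per_community, n_cycles - cycles_done)
        g = coexistence_grid(size, params, int(seed) + 1000 * batch)
        run_surface(g, params, warmup, seed=int(seed) + 1000 * batch + 1)
        summary = run_descent_protocol(
            g, params, want, tracked,
            seed=int(seed) + 1000 * batch + 2, check_interval=50,
            pilot_cap=6_000)
        for r in summary.records:
            r.cycle_index += cycles_done
        records.extend(summary.records)
        cycles_done += summary.cycles_run
        batch += 1
    from .lineage import DescentSummary

    merged = DescentSummary(records=records, cycles_run=cycles_done)
    out: dict = {"cycles_run": cycles_done, "communities": batch}
    for sp in tracked:
        s = merged.species_summary(sp)
        out[sp] = s
        if s["cycles_completed"] and np.isfinite(s["mean_dna_form_fraction"]):
            n_dna = round(s["frac_fixed_dna"] * s["cycles_completed"])
            out[sp]["bias_test"] = fixation_bias_test(
                int(n_dna), s["cycles_completed"],
                s["mean_dna_form_fraction"])
    return out


# ---------------------------------------------------------------------------
# 7. fixed-boundary compartment fitness assay
# ---------------------------------------------------------------------------

def fitness_assay(seed: int = 0, size: int = 128, radius: int = 10,
                  t_end: float = 1000.0) -> dict:
    """Internal replicator density and compartment death under immobilised
    boundaries, for the transcription-like system versus Rp^RNA alone.

    Compartments are sized at the division threshold and filled at half
    density; mutations are off.  Density is averaged over surviving
    compartments, matching how compartment growth rate is driven.
    """
    params = KineticParams(diff=1.0)
    translike = [PopulationSpec(Role.Rp, Form.RNA, 1.0, 1.0, 0.25),
                 PopulationSpec(Role.Rp, Form.DNA, 1.0, 1.0, 0.25),
                 PopulationSpec(Role.Dp, Form.RNA, 0.0, 1.0, 0.25),
                 PopulationSpec(Role.Dp, Form.DNA, 0.0, 1.0, 0.25)]
    rponly = [PopulationSpec(Role.Rp, Form.RNA, 1.0, 1.0, 1.0)]
    spacing = 32
    centers = [(spacing // 2 + spacing * i, spacing // 2 + spacing * j)
               for i in range(size // spacing) for j in range(size // spacing)]
    out: dict = {}
    for name, comp_spec in (("translike", translike), ("rponly", rponly)):
        g = make_compartment_grid(size, size, centers, radius, 0.5,
                                  comp_spec, params, seed=int(seed))
        model = CompartmentModel(g, params,
                                 CPMParams(frozen_boundaries=True))
        g.seed_kernel_rng(int(seed) + 7)
        dt = default_dt(params)
        step_surface(g, params, dt, int(round(t_end / dt)))
        vols = np.asarray(model._volume[1:], float)
        counts = np.asarray(
            model.replicator_counts()[1:vols.size + 1], float)
        alive = counts > 0
        out[f"{name}_survivor_density"] = (
            float((counts[alive] / vols[alive]).mean()) if alive.any()
            else 0.0)
        out[f"{name}_dead"] = int((~alive).sum())
        out[f"{name}_n_compartments"] = int(vols.size)
    return out
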