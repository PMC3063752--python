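"""Two-dimensional cellular-automaton engine for surface-bound replicators.

One lattice square holds at most one molecule; empty squares are the shared
resource consumed by replication and regenerated by decay.  Reactions are
adjacency-limited (Moore neighbourhood by default), diffusion exchanges the
contents of adjacent squares, and the lattice boundary has no flux.  A
well-mixed variant samples interaction partners uniformly from the whole
lattice (with diffusion disabled) and converges, for large lattices, to the
mass-action trajectories of :mod:`replisim.ode_models` — that correspondence
defines the timescale of the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from ._kernels import (DNA, DP, EMPTY, MOORE_X, MOORE_Y, PARASITE, RNA, RP,
                       VON_NEUMANN_X, VON_NEUMANN_Y)
from .reaction_core import ConfigurationError, Form, KineticParams, Role

__all__ = [
    "Grid",
    "PopulationSpec",
    "SurfaceScenario",
    "initialize_surface",
    "step_surface",
    "diffuse",
    "run_surface",
    "SurfaceTrajectory",
    "census",
    "mean_recognition",
    "default_dt",
    "populate_sites",
]


@dataclass
class PopulationSpec:
    """One molecular species in an initial population."""

    role: Role
    form: Form
    rrec: float
    drec: float
    fraction: float


@dataclass
class SurfaceScenario:
    """Initial condition + parameters for one surface (or well-mixed) run.

    ``bands``, when given, overrides ``composition``: the lattice is split
    into equal-width vertical bands, one per inner species list, each
    populated at ``density`` with its own fractions.  Band initialisation is
    how spatially separated sub-communities (e.g. a self-replication region
    next to a transcription region) are set up.
    """

    width: int
    height: int
    density: float
    composition: Sequence[PopulationSpec]
    params: KineticParams
    seed: int = 0
    wellmixed: bool = False
    neighborhood: str = "moore"
    rt_suppressed: bool = False
    cross_boundary_diffusion: bool = False
    bands: Optional[Sequence[Sequence[PopulationSpec]]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.density <= 1.0):
            raise ConfigurationError("density must lie in [0, 1]")
        if self.neighborhood not in ("moore", "vonneumann"):
            raise ConfigurationError(
                f"unknown neighborhood {self.neighborhood!r}")
        groups = list(self.bands) if self.bands else [self.composition]
        for grp in groups:
            total = sum(s.fraction for s in grp)
            if grp and not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    "composition fractions must sum to 1")


class Grid:
    """Flat-array lattice state (see :mod:`replisim._kernels` for layout)."""

    def __init__(self, width: int, height: int, rng_seed: int = 0,
                 wellmixed: bool = False, neighborhood: str = "moore",
                 rt_suppressed: bool = False,
                 cross_boundary_diffusion: bool = False):
        n = width * height
        self.width = width
        self.height = height
        self.rng_seed = rng_seed
        self.wellmixed = wellmixed
        self.neighborhood = neighborhood
        self.rt_suppressed = rt_suppressed
        self.cross_boundary_diffusion = cross_boundary_diffusion
        self.time = 0.0
        self.kind = np.zeros(n, dtype=np.int8)
        self.form = np.zeros(n, dtype=np.int8)
        self.rrec = np.zeros(n, dtype=np.float64)
        self.drec = np.zeros(n, dtype=np.float64)
        self.bond = np.zeros(n, dtype=np.int8)
        self.partner = np.full(n, -1, dtype=np.int64)
        self.label = np.zeros(n, dtype=np.int8)
        self.comp = np.zeros(n, dtype=np.int32)

    # -- convenience -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def n_molecules(self) -> int:
        return int(np.count_nonzero(self.kind))

    def occupied(self) -> np.ndarray:
        return self.kind != EMPTY

    def copy(self) -> "Grid":
        g = Grid(self.width, self.height, self.rng_seed, self.wellmixed,
                 self.neighborhood, self.rt_suppressed,
                 self.cross_boundary_diffusion)
        for name in ("kind", "form", "rrec", "drec", "bond", "partner",
                     "label", "comp"):
            getattr(g, name)[:] = getattr(self, name)
        g.time = self.time
        return g

    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        if self.neighborhood == "vonneumann":
            return VON_NEUMANN_X, VON_NEUMANN_Y
        return MOORE_X, MOORE_Y

    def seed_kernel_rng(self, seed: Optional[int] = None) -> None:
        _kernels.seed_kernel(int(self.rng_seed if seed is None else seed)
                             & 0x7FFFFFFF)

    def validate(self) -> None:
        """Assert the occupancy / adjacency / bookkeeping invariants."""
        occ = self.occupied()
        free = self.bond == 0
        if np.any(~occ & ~free):
            raise AssertionError("empty square with bond state")
        bound = np.flatnonzero(~free & occ)
        for i in bound:
            p = self.partner[i]
            if p < 0 or self.partner[p] != i:
                raise AssertionError("partner back-reference broken")
            if {int(self.bond[i]), int(self.bond[p])} != {1, 2}:
                raise AssertionError("complex must pair catalyst and template")
            if not self.wellmixed and not _kernels._adjacent(
                    int(i), int(p), self.width):
                raise AssertionError("complex members not adjacent")
            if self.bond[i] == 1:
                if self.form[i] != RNA or self.kind[i] == PARASITE:
                    raise AssertionError(
                        "catalyst side must be RNA-form, non-parasite")
        if np.any((self.rrec < 0) | (self.rrec > 1)
                  | (self.drec < 0) | (self.drec > 1)):
            raise AssertionError("recognition parameter out of [0, 1]")
        if np.any(occ & (self.comp < 0)):
            raise AssertionError("invalid compartment id")


def initialize_surface(scenario: SurfaceScenario) -> Grid:
    """Populate a lattice uniformly at random at the scenario's density.

    Deterministic for a fixed scenario seed.
    """
    grid = Grid(scenario.width, scenario.height, rng_seed=scenario.seed,
                wellmixed=scenario.wellmixed,
                neighborhood=scenario.neighborhood,
                rt_suppressed=scenario.rt_suppressed,
                cross_boundary_diffusion=scenario.cross_boundary_diffusion)
    rng = np.random.default_rng(scenario.seed)
    groups = (list(scenario.bands) if scenario.bands
              else [list(scenario.composition)])
    x = np.arange(grid.n_sites) % scenario.width
    edges = np.linspace(0, scenario.width, len(groups) + 1)
    for b, grp in enumerate(groups):
        band_sites = np.flatnonzero((x >= edges[b]) & (x < edges[b + 1]))
        n_mol = int(round(scenario.density * band_sites.size))
        if n_mol == 0 or not grp:
            continue
        sites = rng.choice(band_sites, size=n_mol, replace=False)
        fractions = np.array([s.fraction for s in grp])
        picks = rng.choice(len(grp), size=n_mol, p=fractions)
        populate_sites(grid, sites, picks, grp)
    return grid


def populate_sites(grid: Grid, sites: np.ndarray, picks: np.ndarray,
                   composition: Sequence[PopulationSpec]) -> None:
    for spec_idx, spec in enumerate(composition):
        sel = sites[picks == spec_idx]
        grid.kind[sel] = int(spec.role)
        grid.form[sel] = int(spec.form)
        grid.rrec[sel] = spec.rrec
        grid.drec[sel] = spec.drec


def default_dt(params: KineticParams, safety: float = 1.0) -> float:
    """Largest admissible step: the per-attempt event menu must sum <= 1."""
    return safety / params.max_event_rate()


def _check_dt(params: KineticParams, dt: float) -> None:
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if dt * params.max_event_rate() > 1.0 + 1e-9:
        raise ConfigurationError(
            f"dt={dt} overflows event probabilities "
            f"(max total rate {params.max_event_rate():.3f}); "
            f"use dt <= {default_dt(params):.4f}")


def step_surface(grid: Grid, params: KineticParams, dt: float,
                 n_passes: int = 1) -> Grid:
    """Advance the lattice in place by ``n_passes`` update passes of ``dt``.

    The kernel RNG must have been seeded (``grid.seed_kernel_rng()``); the
    caller owns the seeding so that runs are reproducible end to end.
    """
    _check_dt(params, dt)
    ox, oy = grid.offsets()
    _kernels.run_passes(
        grid.kind, grid.form, grid.rrec, grid.drec, grid.bond, grid.partner,
        grid.label, grid.comp,
        grid.width, grid.height, n_passes, dt,
        params.k, params.d_rna, params.d_dna, params.diff, params.k_p,
        params.mu_r, params.mu_d, params.mu_rp_to_dp, params.mu_dp_to_rp,
        params.mu_par, params.delta,
        params.complex_formation_enabled, grid.wellmixed, grid.rt_suppressed,
        grid.cross_boundary_diffusion,
        ox, oy)
    grid.time += n_passes * dt
    return grid


def diffuse(grid: Grid, diff: float, dt: float, n_passes: int = 1) -> Grid:
    """Diffusion-only passes: random adjacent content exchanges at ``diff``.

    Swaps never cross lattice or compartment boundaries and never separate
    complex partners.
    """
    if diff * dt > 1.0 + 1e-9:
        raise ConfigurationError("diff * dt must not exceed 1")
    ox, oy = grid.offsets()
    _kernels.diffusion_passes(
        grid.kind, grid.form, grid.rrec, grid.drec, grid.bond, grid.partner,
        grid.label, grid.comp,
        grid.width, grid.height, n_passes, diff, dt, ox, oy,
        grid.cross_boundary_diffusion)
    grid.time += n_passes * dt
    return grid


_COUNT_KEYS = ("Rp_RNA", "Rp_DNA", "Dp_RNA", "Dp_DNA",
               "parasite_RNA", "parasite_DNA")


def census(grid: Grid) -> dict[str, int]:
    """Molecule counts by (role, form), complexes and totals."""
    out: dict[str, int] = {}
    for key, role, form in (("Rp_RNA", RP, RNA), ("Rp_DNA", RP, DNA),
                            ("Dp_RNA", DP, RNA), ("Dp_DNA", DP, DNA),
                            ("parasite_RNA", PARASITE, RNA),
                            ("parasite_DNA", PARASITE, DNA)):
        out[key] = int(np.count_nonzero((grid.kind == role)
                                        & (grid.form == form)))
    out["complexes"] = int(np.count_nonzero(grid.bond == 1))
    out["total"] = int(np.count_nonzero(grid.kind))
    return out


def mean_recognition(grid: Grid) -> dict[str, float]:
    """Population means of the recognition parameters per polymerase type."""
    out: dict[str, float] = {}
    for key, role in (("Rp", RP), ("Dp", DP)):
        sel = grid.kind == role
        n = int(np.count_nonzero(sel))
        out[f"mean_rrec_{key}"] = float(grid.rrec[sel].mean()) if n else np.nan
        out[f"mean_drec_{key}"] = float(grid.drec[sel].mean()) if n else np.nan
    return out


@dataclass
class SurfaceTrajectory:
    times: list[float] = field(default_factory=list)
    counts: list[dict[str, int]] = field(default_factory=list)
    recognition: list[dict[str, float]] = field(default_factory=list)
    extinct: bool = False

    def series(self, key: str) -> np.ndarray:
        if self.counts and key in self.counts[0]:
            return np.array([c[key] for c in self.counts], dtype=float)
        return np.array([r[key] for r in self.recognition], dtype=float)

    def to_frame(self):
        import pandas as pd

        rows = []
        for t, c, r in zip(self.times, self.counts, self.recognition):
            row = {"time": t}
            row.update(c)
            row.update(r)
            rows.append(row)
        return pd.DataFrame(rows)


def run_surface(grid: Grid, params: KineticParams, t_end: float,
                dt: Optional[float] = None,
                record_interval: Optional[float] = None,
                observers: Sequence[Callable[[Grid], None]] = (),
                seed: Optional[int] = None,
                stop_on_extinction: bool = True) -> SurfaceTrajectory:
    """Drive :func:`step_surface` to ``t_end``, recording a census time series.

    The run is reproducible under a fixed seed (defaults to the grid's).
    Terminates early, with ``extinct=True`` in the result, if the lattice
    empties.
    """
    if t_end < 0:
        raise ConfigurationError("t_end must be non-negative")
    if dt is None:
        dt = default_dt(params)
    _check_dt(params, dt)
    grid.seed_kernel_rng(seed)
    traj = SurfaceTrajectory()

    def record() -> None:
        traj.times.append(grid.time)
        traj.counts.append(census(grid))
        traj.recognition.append(mean_recognition(grid))
        for obs in observers:
            obs(grid)

    record()
    if t_end == 0:
        # keep the contract: an empty time budget leaves the grid untouched
        traj.times.clear()
        traj.counts.clear()
        traj.recognition.clear()
        return traj
    interval = record_interval if record_interval is not None else t_end / 50
    passes_per_block = max(1, int(round(interval / dt)))
    total_passes = int(round(t_end / dt))
    done = 0
    while done < total_passes:
        block = min(passes_per_block, total_passes - done)
        step_surface(grid, params, dt, block)
        done += block
        record()
        if grid.n_molecules == 0:
            traj.extinct = True
            if stop_on_extinction:
                break
    return traj
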