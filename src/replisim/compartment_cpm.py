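"""Cellular Potts boundary dynamics coupled to the replicator lattice.

Compartments are connected sets of lattice squares carrying a shared integer
id (0 is the structureless medium).  Boundary motion is Metropolis dynamics
on the Hamiltonian

    H = sum_c lam * (volume_c - target_c)^2  +  J * (# unlike contacts),

with the target volume of every compartment tied to its replicator content,
``target = beta * n_replicators``, so compartments grow and shrink with
their internal population.  Boundaries are impermeable: copy attempts onto
molecule-occupied squares are rejected, and the reaction/diffusion kernel
never lets an event cross a compartment boundary.  A compartment whose
volume reaches the division threshold splits along the line of the second
principal component of its site coordinates, each daughter keeping the
molecules on its side; a compartment whose volume decays to zero dies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .reaction_core import ConfigurationError, KineticParams
from .surface_ca import Grid, _check_dt, default_dt

__all__ = [
    "CPMParams",
    "Compartment",
    "CompartmentModel",
    "cpm_sweep",
    "divide_compartment",
    "step_compartment_model",
]


@dataclass(frozen=True)
class CPMParams:
    beta: float = 2.0           # target volume per internal replicator
    V_div: int = 300            # division threshold (squares)
    J: float = 2.0              # contact energy per unlike neighbour pair
    lam: float = 1.0            # volume-constraint stiffness
    temp: float = 4.0           # Metropolis temperature
    frozen_boundaries: bool = False

    def __post_init__(self) -> None:
        if min(self.beta, self.J, self.lam, self.temp) <= 0 or self.V_div < 2:
            raise ConfigurationError("CPM parameters must be positive")


@dataclass
class Compartment:
    """Lightweight per-compartment record; site membership lives in the
    grid's ``comp`` layer."""

    id: int
    volume: int
    target_volume: float
    n_replicators: int

    def member_sites(self, grid: Grid) -> np.ndarray:
        return np.flatnonzero(grid.comp == self.id)


class CompartmentModel:
    """Grid plus compartment bookkeeping (volumes, targets, ids)."""

    def __init__(self, grid: Grid, params: KineticParams, cpm: CPMParams):
        self.grid = grid
        self.params = params
        self.cpm = cpm
        max_id = int(grid.comp.max(initial=0))
        self._volume = np.bincount(grid.comp[grid.comp >= 0],
                                   minlength=max_id + 1).astype(np.int64)
        self._target = np.zeros(max_id + 1)
        self.refresh_targets()

    # -- bookkeeping -------------------------------------------------------
    def _grow(self, new_max_id: int) -> None:
        if new_max_id >= self._volume.shape[0]:
            extra = new_max_id + 1 - self._volume.shape[0]
            self._volume = np.concatenate(
                [self._volume, np.zeros(extra, dtype=np.int64)])
            self._target = np.concatenate([self._target, np.zeros(extra)])

    def replicator_counts(self) -> np.ndarray:
        occ = self.grid.comp[self.grid.kind != 0]
        return np.bincount(occ, minlength=self._volume.shape[0])

    def refresh_targets(self) -> None:
        counts = self.replicator_counts()
        self._target[:] = self.cpm.beta * counts
        self._target[0] = 0.0   # the medium has no volume constraint

    def compartments(self) -> list[Compartment]:
        counts = self.replicator_counts()
        return [Compartment(cid, int(self._volume[cid]),
                            float(self._target[cid]), int(counts[cid]))
                for cid in range(1, self._volume.shape[0])
                if self._volume[cid] > 0]

    def validate(self) -> None:
        max_id = self._volume.shape[0] - 1
        actual = np.bincount(self.grid.comp, minlength=max_id + 1)
        if actual.shape[0] > max_id + 1 or \
                not np.array_equal(actual, self._volume[:actual.shape[0]]) \
                and not np.array_equal(
                    np.pad(actual, (0, max_id + 1 - actual.shape[0])),
                    self._volume):
            raise AssertionError("compartment-id layer inconsistent with "
                                 "volume records")
        if np.any((self.grid.kind != 0) & (self.grid.comp == 0)):
            raise AssertionError("molecule outside any compartment")
        self.grid.validate()


def cpm_sweep(model: CompartmentModel, n_sweeps: int = 1) -> None:
    """Metropolis boundary sweeps; compartments reaching volume 0 die.

    With ``frozen_boundaries`` the state is untouched and the model reduces
    to independent surface systems.
    """
    if model.cpm.frozen_boundaries:
        return
    g = model.grid
    _kernels.cpm_sweep_kernel(
        g.comp, g.kind, g.width, g.height, n_sweeps * g.n_sites,
        model._volume, model._target,
        model.cpm.lam, model.cpm.J, model.cpm.temp,
        _kernels.MOORE_X, _kernels.MOORE_Y, False)


def divide_compartment(model: CompartmentModel, cid: int,
                       rng: np.random.Generator) -> tuple[int, int] | None:
    """Split compartment ``cid`` along its second principal component.

    Member squares are projected onto the first principal axis of their
    coordinate covariance; the sign of the centred projection assigns each
    square (and the molecule on it) to a daughter, so the dividing line is
    the second principal axis.  Ties at exactly zero projection are settled
    by a fair coin.  Returns the two daughter ids, or ``None`` if the
    geometry is degenerate (fewer than two squares).
    """
    g = model.grid
    sites = np.flatnonzero(g.comp == cid)
    if sites.size < 2:
        warnings.warn(f"compartment {cid} too small to divide")
        return None
    coords = np.column_stack([sites % g.width, sites // g.width]).astype(float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / sites.size
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]      # first principal component
    proj = centered @ axis
    side = proj > 0
    ties = proj == 0
    if ties.any():
        side[ties] = rng.random(int(ties.sum())) < 0.5
    if side.all() or not side.any():
        # pathological collinear split; force a median cut
        order = np.argsort(proj)
        side[:] = False
        side[order[sites.size // 2:]] = True
    new_id = model._volume.shape[0]
    model._grow(new_id)
    moved = sites[side]
    g.comp[moved] = new_id
    model._volume[cid] -= moved.size
    model._volume[new_id] += moved.size
    model.refresh_targets()
    return cid, new_id


def step_compartment_model(model: CompartmentModel, dt: float | None = None,
                           n_steps: int = 1,
                           sweeps_per_step: int = 1,
                           rng: np.random.Generator | None = None) -> None:
    """Interleave reaction/diffusion passes with boundary sweeps.

    Each macro-step runs one boundary-respecting reaction pass of the
    surface kernel, refreshes every compartment's target volume from its
    replicator count, applies ``sweeps_per_step`` Metropolis sweeps, and
    triggers any due divisions.  The kernel RNG must be seeded by the caller
    (``model.grid.seed_kernel_rng()``); ``rng`` covers division tie-breaks.
    """
    from .surface_ca import step_surface

    if dt is None:
        dt = default_dt(model.params)
    _check_dt(model.params, dt)
    rng = rng or np.random.default_rng(model.grid.rng_seed + 1)
    for _ in range(n_steps):
        step_surface(model.grid, model.params, dt, 1)
        model.refresh_targets()
        if not model.cpm.frozen_boundaries:
            cpm_sweep(model, sweeps_per_step)
            for cid in np.flatnonzero(model._volume >= model.cpm.V_div):
                if cid > 0:
                    divide_compartment(model, int(cid), rng)


def make_compartment_grid(width: int, height: int, centers, radius: int,
                          fill_density: float, composition,
                          params: KineticParams, seed: int = 0,
                          wellmixed: bool = False) -> Grid:
    """Build a grid with disc-shaped compartments seeded with molecules."""
    from .surface_ca import populate_sites

    grid = Grid(width, height, rng_seed=seed, wellmixed=wellmixed)
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    for cid, (cx, cy) in enumerate(centers, start=1):
        mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
        sites = np.flatnonzero(mask.ravel())
        sites = sites[grid.comp[sites] == 0]
        grid.comp[sites] = cid
        n_mol = int(round(fill_density * sites.size))
        if n_mol == 0:
            continue
        chosen = rng.choice(sites, size=n_mol, replace=False)
        fracs = np.array([s.fraction for s in composition])
        picks = rng.choice(len(composition), size=n_mol, p=fracs)
        populate_sites(grid, chosen, picks, composition)
    return grid
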