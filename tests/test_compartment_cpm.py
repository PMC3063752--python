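"""Tests for the Cellular Potts compartment dynamics."""

import numpy as np
import pytest

from replisim import _kernels
from replisim.compartment_cpm import (CompartmentModel, CPMParams,
                                      cpm_sweep, divide_compartment,
                                      make_compartment_grid,
                                      step_compartment_model)
from replisim.reaction_core import Form, KineticParams, Role
from replisim.surface_ca import Grid, PopulationSpec, default_dt, \
    step_surface


def disc_grid(width=64, height=64, cx=32, cy=32, radius=10):
    g = Grid(width, height)
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    mask = ((xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2).ravel()
    g.comp[mask] = 1
    return g


class TestSweep:
    def test_frozen_boundaries_change_nothing(self):
        g = disc_grid()
        model = CompartmentModel(g, KineticParams(),
                                 CPMParams(frozen_boundaries=True))
        before = g.comp.copy()
        _kernels.seed_kernel(1)
        cpm_sweep(model, 50)
        np.testing.assert_array_equal(before, g.comp)

    def test_volume_fluctuates_tightly_around_fixed_target(self):
        """Boltzmann-fluctuation oracle: with H = lam (V - T)^2, the
        time-averaged volume sits on the target within a few percent."""
        g = disc_grid()
        model = CompartmentModel(g, KineticParams(), CPMParams())
        target = 250.0
        model._target[1] = target
        _kernels.seed_kernel(7)
        vols = []
        for s in range(2500):
            cpm_sweep(model, 1)
            if s >= 500:
                vols.append(model._volume[1])
        vols = np.asarray(vols, float)
        rms = np.sqrt(np.mean((vols - target) ** 2)) / target
        assert rms < 0.05
        assert abs(vols.mean() - target) / target < 0.02

    def test_zero_replicators_means_shrinkage_to_death(self):
        g = disc_grid(radius=6)       # no molecules anywhere -> target 0
        model = CompartmentModel(g, KineticParams(), CPMParams())
        model.refresh_targets()
        _kernels.seed_kernel(3)
        for _ in range(3000):
            cpm_sweep(model, 1)
            if model._volume[1] == 0:
                break
        assert model._volume[1] == 0
        assert model.compartments() == []

    def test_molecule_sites_never_change_compartment(self):
        g = disc_grid()
        inside = np.flatnonzero(g.comp == 1)[:20]
        g.kind[inside] = int(Role.Rp)
        g.rrec[inside] = 0.5
        model = CompartmentModel(g, KineticParams(), CPMParams())
        model._target[1] = 40.0       # strong shrink pressure
        _kernels.seed_kernel(11)
        cpm_sweep(model, 400)
        assert np.all(g.comp[inside] == 1)
        model.validate()


class TestDivision:
    def test_rectangle_splits_across_long_axis(self):
        g = Grid(32, 32)
        for x in range(10):
            for y in range(4):
                g.comp[(y + 6) * 32 + (x + 8)] = 1
        model = CompartmentModel(g, KineticParams(), CPMParams())
        rng = np.random.default_rng(0)
        ids = divide_compartment(model, 1, rng)
        assert ids is not None
        va, vb = model._volume[ids[0]], model._volume[ids[1]]
        assert sorted([va, vb]) == [20, 20]
        xa = np.flatnonzero(g.comp == ids[0]) % 32
        xb = np.flatnonzero(g.comp == ids[1]) % 32
        assert max(xa.max(), xb.max()) - min(xa.min(), xb.min()) == 9
        assert set(xa).isdisjoint(xb)     # cut orthogonal to the long axis

    def test_division_conserves_area_and_molecules(self):
        g = disc_grid(radius=9)
        sites = np.flatnonzero(g.comp == 1)
        rng = np.random.default_rng(5)
        mol = rng.choice(sites, 30, replace=False)
        g.kind[mol] = int(Role.Rp)
        model = CompartmentModel(g, KineticParams(), CPMParams())
        v0 = int(model._volume[1])
        ids = divide_compartment(model, 1, rng)
        counts = model.replicator_counts()
        assert model._volume[ids[0]] + model._volume[ids[1]] == v0
        assert counts[ids[0]] + counts[ids[1]] == 30
        assert np.all(g.comp[mol] > 0)

    def test_principal_axis_matches_dense_eigendecomposition(self):
        """Split direction oracle: an asymmetric blob's daughters separate
        along the leading eigenvector of the coordinate covariance,
        recomputed here by brute force."""
        g = Grid(64, 64)
        rng = np.random.default_rng(42)
        # anisotropic blob tilted 30 degrees
        th = np.pi / 6
        pts = rng.normal(size=(400, 2)) * [8.0, 2.5]
        rot = pts @ np.array([[np.cos(th), np.sin(th)],
                              [-np.sin(th), np.cos(th)]])
        ij = np.unique(np.round(rot + 32).astype(int), axis=0)
        ij = ij[(ij.min(axis=1) >= 0) & (ij.max(axis=1) < 64)]
        g.comp[ij[:, 1] * 64 + ij[:, 0]] = 1
        model = CompartmentModel(g, KineticParams(), CPMParams())
        ids = divide_compartment(model, 1, rng)
        coords = np.column_stack([np.flatnonzero(g.comp > 0) % 64,
                                  np.flatnonzero(g.comp > 0) // 64]).astype(float)
        centered = coords - coords.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        axis = evecs[:, np.argmax(evals)]
        side_a = np.flatnonzero(g.comp == ids[0])
        proj_a = (np.column_stack([side_a % 64, side_a // 64])
                  - coords.mean(axis=0)) @ axis
        side_b = np.flatnonzero(g.comp == ids[1])
        proj_b = (np.column_stack([side_b % 64, side_b // 64])
                  - coords.mean(axis=0)) @ axis
        assert proj_a.max() <= proj_b.min() or proj_b.max() <= proj_a.min()

    def test_degenerate_compartment_skips_division(self):
        g = Grid(16, 16)
        g.comp[5] = 1
        model = CompartmentModel(g, KineticParams(), CPMParams())
        with pytest.warns(UserWarning):
            assert divide_compartment(model, 1,
                                      np.random.default_rng(0)) is None


class TestCoupledModel:
    def test_frozen_boundaries_reduce_to_surface_dynamics(self):
        """Regression: with frozen boundaries the compartment model is the
        surface model restricted to each compartment (identical kernel
        trajectory under the same seed)."""
        params = KineticParams(diff=1.0)
        comp_spec = [PopulationSpec(Role.Rp, Form.RNA, 0.9, 0.0, 1.0)]
        runs = []
        for use_model in (False, True):
            g = make_compartment_grid(48, 48, [(24, 24)], 10, 0.5,
                                      comp_spec, params, seed=3)
            g.seed_kernel_rng(3)
            if use_model:
                model = CompartmentModel(g, params,
                                         CPMParams(frozen_boundaries=True))
                step_compartment_model(model, default_dt(params), 200)
            else:
                step_surface(g, params, default_dt(params), 200)
            runs.append(g.kind.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_reactions_never_cross_boundaries(self):
        params = KineticParams(diff=1.0)
        comp_spec = [PopulationSpec(Role.Rp, Form.RNA, 0.9, 0.0, 1.0)]
        g = make_compartment_grid(64, 64, [(16, 16), (48, 48)], 12, 0.5,
                                  comp_spec, params, seed=9)
        model = CompartmentModel(g, params, CPMParams())
        g.seed_kernel_rng(9)
        rng = np.random.default_rng(9)
        for _ in range(10):
            step_compartment_model(model, default_dt(params), 20, rng=rng)
            assert np.all(g.comp[g.kind != 0] > 0)
            model.validate()

    def test_growth_and_division_cycle(self):
        """Compartments fed by internal replication grow past the
        threshold and divide; the compartment census increases."""
        params = KineticParams(diff=1.0)
        comp_spec = [PopulationSpec(Role.Rp, Form.RNA, 0.9, 0.0, 1.0)]
        g = make_compartment_grid(96, 96, [(48, 48)], 8, 0.5, comp_spec,
                                  params, seed=5)
        model = CompartmentModel(g, params, CPMParams(beta=2.0, V_div=220))
        g.seed_kernel_rng(5)
        rng = np.random.default_rng(5)
        step_compartment_model(model, default_dt(params),
                               int(300 / default_dt(params)), rng=rng)
        assert len(model.compartments()) > 1
        assert np.count_nonzero(g.kind) > 100
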