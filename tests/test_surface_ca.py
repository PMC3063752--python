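"""Tests for the lattice engine: invariants, determinism, physical oracles."""

import numpy as np
import pytest

from replisim.reaction_core import ConfigurationError, Form, KineticParams, \
    Role
from replisim.surface_ca import (Grid, PopulationSpec, SurfaceScenario,
                                 census, default_dt, diffuse,
                                 initialize_surface, run_surface,
                                 step_surface)

from conftest import make_grid


class TestInitialization:
    def test_zero_density_gives_empty_grid(self):
        g = make_grid(density=0.0)
        assert g.n_molecules == 0

    def test_density_and_composition_respected(self, quiet_params):
        comp = [PopulationSpec(Role.Rp, Form.RNA, 0.4, 0.0, 0.5),
                PopulationSpec(Role.Dp, Form.DNA, 0.0, 1.0, 0.5)]
        g = make_grid(64, 64, 0.25, comp, quiet_params, seed=3)
        assert g.n_molecules == int(round(0.25 * 64 * 64))
        c = census(g)
        assert c["Rp_RNA"] + c["Dp_DNA"] == c["total"]

    def test_same_seed_gives_identical_grids(self, selfrep_spec):
        a = make_grid(32, 32, 0.4, selfrep_spec, seed=11)
        b = make_grid(32, 32, 0.4, selfrep_spec, seed=11)
        for name in ("kind", "form", "rrec", "drec"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_band_initialisation_separates_communities(self, quiet_params):
        left = [PopulationSpec(Role.Rp, Form.RNA, 0.9, 0.0, 1.0)]
        right = [PopulationSpec(Role.Dp, Form.DNA, 0.0, 1.0, 1.0)]
        g = make_grid(64, 32, 0.5, [], quiet_params, bands=[left, right])
        x = np.arange(g.n_sites) % 64
        assert np.all(x[g.kind == int(Role.Rp)] < 32)
        assert np.all(x[g.kind == int(Role.Dp)] >= 32)

    def test_overfull_density_rejected(self, quiet_params, selfrep_spec):
        with pytest.raises(ConfigurationError):
            SurfaceScenario(16, 16, 1.5, selfrep_spec, quiet_params)


class TestStepping:
    def test_empty_grid_unchanged(self, quiet_params):
        g = make_grid(24, 24)
        g.seed_kernel_rng(5)
        step_surface(g, quiet_params, default_dt(quiet_params), 20)
        assert g.n_molecules == 0

    def test_inert_molecule_is_immortal_and_immobile(self):
        params = KineticParams(d_rna=0.0, d_dna=0.0, diff=0.0)
        g = make_grid(16, 16)
        g.kind[40] = int(Role.Dp)   # DNA-form: cannot even catalyse
        g.form[40] = int(Form.DNA)
        g.seed_kernel_rng(5)
        step_surface(g, params, default_dt(params), 200)
        assert g.kind[40] == int(Role.Dp) and g.n_molecules == 1

    def test_run_is_reproducible_under_fixed_seed(self, selfrep_spec):
        params = KineticParams(mu_r=0.05, mu_par=1e-3)
        outs = []
        for _ in range(2):
            g = make_grid(40, 40, 0.3, selfrep_spec, params, seed=2)
            run_surface(g, params, 30.0, seed=123)
            outs.append((g.kind.copy(), g.rrec.copy(), g.bond.copy()))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        np.testing.assert_array_equal(outs[0][1], outs[1][1])
        np.testing.assert_array_equal(outs[0][2], outs[1][2])

    def test_overflowing_dt_rejected(self, quiet_params, selfrep_spec):
        g = make_grid(16, 16, 0.2, selfrep_spec)
        with pytest.raises(ConfigurationError):
            step_surface(g, quiet_params, 10.0)

    def test_invariants_hold_through_busy_dynamics(self, selfrep_spec):
        """Occupancy/adjacency/bond bookkeeping fuzz: every pass preserves
        the structural invariants, including parasite and Dp mutants."""
        params = KineticParams(mu_r=0.05, mu_d=0.05, mu_rp_to_dp=0.01,
                               mu_par=0.01)
        g = make_grid(32, 32, 0.4,
                      [PopulationSpec(Role.Rp, Form.RNA, 0.8, 0.8, 1.0)],
                      params, seed=9)
        g.seed_kernel_rng(9)
        for _ in range(30):
            step_surface(g, params, default_dt(params), 5)
            g.validate()

    def test_resource_accounting_is_exact(self, selfrep_spec):
        g = make_grid(32, 32, 0.5, selfrep_spec, seed=4)
        params = KineticParams()
        g.seed_kernel_rng(1)
        step_surface(g, params, default_dt(params), 50)
        assert g.n_molecules + np.count_nonzero(g.kind == 0) == g.n_sites


class TestDecayOracle:
    def test_exponential_survival(self):
        """Isolated molecules decay as a Poisson process: survivor counts
        follow exp(-d t) within 3 sigma binomial."""
        d = 0.05
        params = KineticParams(d_rna=d, d_dna=d, diff=0.0)
        comp = [PopulationSpec(Role.Dp, Form.DNA, 0.0, 0.0, 1.0)]  # inert
        g = make_grid(100, 100, 1.0, comp, params, seed=21)
        n0 = g.n_molecules
        g.seed_kernel_rng(21)
        dt = 0.1
        for t_target in (10.0, 30.0):
            step_surface(g, params, dt, int(round(
                (t_target - g.time) / dt)))
            p = np.exp(-d * t_target)
            sigma = np.sqrt(n0 * p * (1 - p))
            assert abs(g.n_molecules - n0 * p) < 3 * sigma


class TestDiffusion:
    def test_zero_rate_means_no_motion(self, selfrep_spec):
        g = make_grid(24, 24, 0.3, selfrep_spec, seed=2)
        before = g.kind.copy()
        g.seed_kernel_rng(3)
        diffuse(g, 0.0, 0.5, 50)
        np.testing.assert_array_equal(before, g.kind)

    def test_msd_grows_linearly_with_moore_step_variance(self):
        """Tracer mean-squared displacement ~ 1.5 * diff * t (random walk
        with unit and diagonal steps, independent 2-D walk oracle)."""
        diff, dt, n_passes = 1.0, 0.5, 160
        g = Grid(128, 128, rng_seed=6)
        rng = np.random.default_rng(6)
        sites = rng.choice(g.n_sites, size=60, replace=False)
        g.kind[sites] = int(Role.Dp)
        g.form[sites] = int(Form.DNA)
        start = {int(s): (int(s) % 128, int(s) // 128) for s in sites}
        g.seed_kernel_rng(6)
        diffuse(g, diff, dt, n_passes)
        t = n_passes * dt
        # molecules are indistinguishable; with 60 tracers on 16k sites and
        # rms displacement ~11 squares, nearest-start matching is unambiguous
        # in the mean-square sense only — so compare the *population* MSD
        ends = np.flatnonzero(g.kind != 0)
        assert ends.size == 60
        ex, ey = ends % 128, ends // 128
        sx = np.array([v[0] for v in start.values()])
        sy = np.array([v[1] for v in start.values()])
        # order-free MSD via distance to nearest start point is biased; use
        # the mean over optimal assignment (Hungarian) as the displacement
        from scipy.optimize import linear_sum_assignment

        d2 = (ex[:, None] - sx[None, :]) ** 2 + (ey[:, None] - sy[None, :]) ** 2
        rows, cols = linear_sum_assignment(d2)
        msd = d2[rows, cols].mean()
        expected = 1.5 * diff * t
        # assignment underestimates; accept a generous band around theory
        assert 0.4 * expected < msd < 1.3 * expected

    def test_no_flux_boundary_conserves_molecules(self, selfrep_spec):
        g = make_grid(16, 16, 0.5, selfrep_spec, seed=8)
        n0 = g.n_molecules
        g.seed_kernel_rng(8)
        diffuse(g, 1.0, 0.5, 400)
        assert g.n_molecules == n0


class TestWellMixedOdeLimit:
    def test_selfrep_matches_mass_action_trajectory(self):
        """Calibration contract: the well-mixed lattice converges to the
        mass-action trajectory with the same constants (timescale pin)."""
        from replisim import ode_models as om

        params = KineticParams()
        a, n = 0.4, 128
        comp = [PopulationSpec(Role.Rp, Form.RNA, a, 0.0, 1.0)]
        sc = SurfaceScenario(n, n, 0.2, comp, params, seed=31, wellmixed=True)
        g = initialize_surface(sc)
        traj = run_surface(g, params, 80.0, dt=0.01, record_interval=8.0)
        ca = traj.series("total") / g.n_sites

        system = om.selfrep_system(a, 0.0)
        y0 = system.zero_state()
        system.set_free(y0, "Rp", Form.RNA, 0.2)
        res = om.integrate(system, params, y0, 80.0,
                           t_eval=np.array(traj.times))
        ode = np.array([system.total_of(res.y[:, i], "Rp")
                        for i in range(res.t.size)])
        sigma = np.sqrt(np.maximum(ode * (1 - ode), 1e-4) / g.n_sites)
        # binomial sigma underestimates path fluctuations; allow 5x
        assert np.all(np.abs(ca - ode) < 5 * sigma + 0.01)

    def test_stationary_density_matches_mean_field_fixed_point(self):
        """Independent algebraic oracle: solve the reduced free/complex
        fixed-point equations with fsolve and compare the lattice's
        stationary density."""
        from scipy.optimize import fsolve

        a, k, d = 0.4, 1.0, 0.05
        params = KineticParams(d_rna=d, d_dna=d)

        def eqs(v):
            x, c = v
            r = 1 - x - 2 * c
            F = a * x * x
            D = (1 - a) * c
            R = k * c * r
            return [-2 * F + 2 * D + 3 * R + 2 * d * c - d * x,
                    F - D - R - 2 * d * c]

        x_star, c_star = fsolve(eqs, [0.3, 0.2])
        total_star = x_star + 2 * c_star
        # start inside the interior attractor's basin (the two-step cycle
        # has a strong Allee threshold at these rates)
        comp = [PopulationSpec(Role.Rp, Form.RNA, a, 0.0, 1.0)]
        sc = SurfaceScenario(128, 128, 0.5, comp, params, seed=17,
                             wellmixed=True)
        g = initialize_surface(sc)
        traj = run_surface(g, params, 220.0, dt=0.02, record_interval=10.0)
        tail = traj.series("total")[-8:] / g.n_sites
        assert abs(tail.mean() - total_star) < 0.01


class TestModelVariants:
    def test_instantaneous_mode_never_forms_complexes(self, selfrep_spec):
        """With complex formation disabled, replication is a single-step
        event: no complex ever exists, yet the population still grows."""
        params = KineticParams(complex_formation_enabled=False)
        g = make_grid(48, 48, 0.5, selfrep_spec, params, seed=14)
        n0 = g.n_molecules
        g.seed_kernel_rng(14)
        for _ in range(20):
            step_surface(g, params, default_dt(params), 10)
            assert np.count_nonzero(g.bond) == 0
        assert g.n_molecules > n0

    def test_cross_boundary_diffusion_toggle(self):
        """Swaps never cross compartment boundaries by default; with the
        permeable-membrane variant enabled, molecules leak out."""
        from replisim.reaction_core import Role, Form

        for toggle, expect_leak in ((False, False), (True, True)):
            g = Grid(32, 32, cross_boundary_diffusion=toggle)
            xs, ys = np.meshgrid(np.arange(32), np.arange(32))
            inside = (((xs - 16) ** 2 + (ys - 16) ** 2) <= 25).ravel()
            g.comp[inside] = 1
            sites = np.flatnonzero(inside)[:10]
            g.kind[sites] = int(Role.Dp)
            g.form[sites] = int(Form.DNA)
            g.seed_kernel_rng(77)
            diffuse(g, 1.0, 0.5, 300)
            leaked = np.any((g.kind != 0) & (g.comp == 0))
            assert leaked == expect_leak
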