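"""Simulation engines: drift, propensities, ODE, SSA, LNA."""

import itertools
import math

import numpy as np
import pytest

import crnasync as ca
from crnasync import Reaction


def motif_closed_form(t, x=10.0):
    """With X_hi = x and Y_lo(0) = x, Y_hi(t) = x (1 - exp(-x t)) exactly."""
    return x * (1.0 - np.exp(-x * t))


class TestDrift:
    def test_motif_drift_at_initial_state(self, motif):
        phi = motif.crs.z0
        F = ca.drift(motif.crs, phi)
        idx = motif.crs.index
        assert F[idx("Yhi")] == pytest.approx(100.0)
        assert F[idx("Ylo")] == pytest.approx(-100.0)
        assert F[idx("Xhi")] == 0.0  # catalysts are unchanged

    def test_zero_state_zero_drift(self, motif):
        assert np.all(ca.drift(motif.crs, np.zeros(4)) == 0.0)

    def test_dimension_mismatch_raises(self, motif):
        with pytest.raises(ca.CRNError):
            ca.drift(motif.crs, np.ones(3))


class TestPropensity:
    def test_exhaustive_against_mass_action_oracle(self):
        """alpha equals k*xA*xB, k*x*(x-1) or k*x on all states with <= 6 molecules."""
        distinct = Reaction.make(["A", "B"], ["A", "C"], rate=2.0)
        paired = Reaction.make(["A", "A"], ["A", "B"], rate=1.5)
        uni = Reaction.make(["A"], ["B"], rate=3.0)
        for xa, xb in itertools.product(range(7), repeat=2):
            x = {"A": xa, "B": xb}
            assert ca.propensity(distinct, x) == pytest.approx(2.0 * xa * xb)
            assert ca.propensity(paired, x) == pytest.approx(1.5 * xa * (xa - 1))
            assert ca.propensity(uni, x) == pytest.approx(3.0 * xa)

    def test_printed_formula_values(self):
        rxn = Reaction.make(["A", "B"], ["A", "C"])
        assert ca.propensity(rxn, {"A": 2, "B": 3}) == 6.0
        rxn = Reaction.make(["A", "A"], ["A", "B"])
        assert ca.propensity(rxn, {"A": 3}) == 6.0  # 2! * C(3,2)
        rxn = Reaction.make(["A"], ["B"])
        assert ca.propensity(rxn, {"A": 0}) == 0.0

    def test_volumetric_factor_scales_bimolecular(self):
        rxn = Reaction.make(["A", "B"], ["A", "C"])
        assert ca.propensity(rxn, {"A": 4, "B": 5}, N=2.0) == pytest.approx(10.0)


class TestOde:
    def test_motif_matches_closed_form(self, motif):
        traj = ca.simulate_ode(motif.crs, 1.0)
        expect = motif_closed_form(traj.times)
        assert np.max(np.abs(traj["Yhi"] - expect)) < 1e-6

    def test_no_reaction_crs_is_constant(self):
        crs = ca.CRS.from_reactions(
            [], init={"A": 5}, extra_species=["A", "B"]
        )
        traj = ca.simulate_ode(crs, 1.0)
        assert np.all(traj["A"] == 5.0) and np.all(traj["B"] == 0.0)

    def test_conservation_along_path(self, dual_rail_am_lowlow):
        traj = ca.simulate_ode(dual_rail_am_lowlow.crs, 2.0)
        pool = traj["Zhi"] + traj["Zlo"] + traj["lam"]
        assert np.max(np.abs(pool - 10.0)) < 1e-6

    def test_nonnegative_to_tolerance(self, motif):
        traj = ca.simulate_ode(motif.crs, 2.0)
        assert traj.values.min() > -1e-8


class TestSsa:
    def test_fixed_seed_bitwise_reproducible(self, motif):
        a = ca.simulate_ssa(motif.crs, 1.0, seed=123)
        b = ca.simulate_ssa(motif.crs, 1.0, seed=123)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.jump_times, b.jump_times)

    def test_motif_absorbs_at_correct_output(self, motif):
        """Every path ends with Y_hi = 10, Y_lo = 0 and no enabled reaction."""
        for seed in range(5):
            path = ca.simulate_ssa(motif.crs, 5.0, seed=seed)
            assert path.value("Yhi", 5.0) == 10.0
            assert path.value("Ylo", 5.0) == 0.0
            assert path.n_jumps == 10  # exactly ten conversions, then absorbing

    def test_no_applicable_reaction_gives_zero_jumps(self):
        crs = ca.parse_crn("A + B -> A + C").with_initial({"A": 5})  # no B
        path = ca.simulate_ssa(crs, 1.0, seed=0)
        assert path.n_jumps == 0

    def test_conservation_exact_along_path(self, dual_rail_am_lowlow):
        path = ca.simulate_ssa(dual_rail_am_lowlow.crs, 2.0, seed=11)
        idx = [path.species.index(s) for s in ("Zhi", "Zlo", "lam")]
        totals = path.states[:, idx].sum(axis=1)
        assert np.all(totals == 10)

    def test_empirical_mean_near_ode(self, motif):
        grid, mean, se = ca.mean_over_paths(motif.crs, 0.5, n_paths=200, seed=17)
        traj = ca.simulate_ode(motif.crs, 0.5)
        i = motif.crs.index("Yhi")
        j = int(np.argmin(np.abs(grid - 0.4)))
        ode_val = traj.value("Yhi", grid[j])
        assert abs(mean[i, j] - ode_val) < 3 * max(se[i, j], 1e-9)

    def test_mean_over_paths_single_path_is_a_path(self, motif):
        grid, mean, se = ca.mean_over_paths(motif.crs, 1.0, n_paths=1, seed=3)
        path = ca.simulate_ssa(motif.crs, 1.0, seed=ca.semantics.path_seed(3, 0))
        assert np.array_equal(mean, path.on_grid(grid))
        assert np.all(se == 0)


class TestLnaMatrices:
    def test_jacobian_entry_motif(self, motif):
        phi = motif.crs.z0
        J = ca.jacobian(motif.crs, phi)
        i, j = motif.crs.index("Yhi"), motif.crs.index("Ylo")
        assert J[i, j] == pytest.approx(10.0)  # d(dYhi/dt)/dYlo = Xhi

    @pytest.mark.parametrize("component", ["motif", "dual_rail_am", "arbiter"])
    def test_jacobian_matches_finite_differences(self, component):
        built = ca.COMPONENTS[component]()
        crs = built.crs
        rng = np.random.default_rng(0)
        phi = rng.uniform(0.5, 5.0, len(crs.species))
        J = ca.jacobian(crs, phi)
        eps = 1e-6
        for j in range(len(phi)):
            dp = phi.copy()
            dp[j] += eps
            dm = phi.copy()
            dm[j] -= eps
            col = (ca.drift(crs, dp) - ca.drift(crs, dm)) / (2 * eps)
            assert np.allclose(J[:, j], col, atol=1e-5)

    def test_diffusion_zero_at_zero_state(self, motif):
        W = ca.diffusion(motif.crs, np.zeros(4))
        assert np.all(W == 0.0)

    def test_diffusion_symmetric_psd(self, dual_rail_am_mixed):
        crs = dual_rail_am_mixed.crs
        W = ca.diffusion(crs, crs.z0 + 0.5)
        assert np.allclose(W, W.T)
        assert np.linalg.eigvalsh(W).min() > -1e-10


class TestLna:
    def test_mean_identical_to_ode(self, dual_rail_am_mixed):
        g = ca.simulate_lna(dual_rail_am_mixed.crs, 1.0)
        d = ca.simulate_ode(dual_rail_am_mixed.crs, 1.0)
        assert np.max(np.abs(g.mean - d.values)) < 1e-6

    def test_covariance_zero_at_t0_and_psd_later(self, dual_rail_am_mixed):
        g = ca.simulate_lna(dual_rail_am_mixed.crs, 1.0)
        assert np.abs(g.cov[0]).max() == 0.0
        assert np.linalg.eigvalsh(g.cov[-1]).min() > -1e-8
        assert np.allclose(g.cov[-1], g.cov[-1].T)

    def test_failure_mode_bands_overlap(self, dual_rail_am_mixed):
        """Mixed input: Z_hi and lam means are within one SD of each other."""
        g = ca.simulate_lna(dual_rail_am_mixed.crs, 1.0)
        z, l = g.value("Zhi", 0.3), g.value("lam", 0.3)
        assert z - g.sd("Zhi", 0.3) < l + g.sd("lam", 0.3)

    def test_conservation_of_lna_mean(self, dual_rail_am_lowlow):
        g = ca.simulate_lna(dual_rail_am_lowlow.crs, 1.0)
        pool = g["Zhi"] + g["Zlo"] + g["lam"]
        assert np.max(np.abs(pool - 10.0)) < 1e-6
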