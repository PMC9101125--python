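"""ESP charge fitting: constrained least squares, IpolQ combination,
shell grids, convergence rule."""

import numpy as np
import pytest

import puckerfit as pf
from puckerfit.chargefit import (ESPChargeModel, ESPGrid, MIN_GRID_DISTANCE,
                                 coulomb_design)
from puckerfit.errors import Mismatch, PointOnAtom


def _single_atom_grid(q, n=50, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts = 2.0 * pts / np.linalg.norm(pts, axis=1)[:, None]
    pts *= rng.uniform(1.0, 2.0, n)[:, None]
    coords = np.zeros((1, 3))
    V = coulomb_design(pts, coords) @ np.array([q])
    return ESPGrid(points=pts, potentials=V, environment="vacuum"), coords


class TestFitESP:
    def test_single_atom_exact(self):
        grid, coords = _single_atom_grid(0.5)
        cs = pf.fit_esp_charges(grid, coords, net_charge=0.5)
        assert cs.charges[0] == pytest.approx(0.5, abs=1e-10)

    def test_net_charge_constraint_exact(self, tpl_mixed, params, rng):
        pts = pf.make_shell_grid(tpl_mixed, density=0.5, seed=3,
                                 lj_radii=params.lj)
        V = rng.normal(size=len(pts))     # arbitrary potentials
        grid = ESPGrid(points=pts, potentials=V, environment="vacuum")
        cs = pf.fit_esp_charges(grid, tpl_mixed.coords, net_charge=0.0)
        assert abs(cs.charges.sum()) < 1e-8
        cs1 = pf.fit_esp_charges(grid, tpl_mixed.coords, net_charge=-1.0)
        assert cs1.charges.sum() == pytest.approx(-1.0, abs=1e-8)

    def test_oracle_inversion(self, tpl_mixed, params):
        oracle = pf.make_oracle(5, [tpl_mixed], params)
        vac, _ = pf.oracle_esp_grids(tpl_mixed, oracle, density=1.0, seed=9)
        cs = pf.fit_esp_charges(vac, tpl_mixed.coords,
                                tpl_mixed.net_charge)
        np.testing.assert_allclose(cs.charges,
                                   oracle.charges[tpl_mixed.name],
                                   atol=1e-6)

    def test_grid_potential_reproduction(self, tpl_mixed, params):
        """With >= 10x points per atom and noiseless grids, the fitted
        charges reproduce the grid potentials to numerical precision."""
        oracle = pf.make_oracle(6, [tpl_mixed], params)
        vac, _ = pf.oracle_esp_grids(tpl_mixed, oracle, density=2.0, seed=2)
        assert len(vac) >= 10 * tpl_mixed.n_atoms
        model = ESPChargeModel(vac, tpl_mixed.coords, tpl_mixed.net_charge)
        res = model.fit()
        assert res.rms_potential_error < 1e-6

    def test_optimality_against_constrained_perturbations(self, tpl_mixed,
                                                          params, rng):
        oracle = pf.make_oracle(8, [tpl_mixed], params)
        vac, _ = pf.oracle_esp_grids(tpl_mixed, oracle, density=1.0, seed=2)
        noisy = ESPGrid(points=vac.points,
                        potentials=vac.potentials
                        + rng.normal(0, 0.5, len(vac)),
                        environment="vacuum")
        model = ESPChargeModel(noisy, tpl_mixed.coords,
                               tpl_mixed.net_charge)
        res = model.fit()
        base = float(res.residuals @ res.residuals)
        n = tpl_mixed.n_atoms
        for _ in range(1000):
            d = rng.normal(0, 0.01, n)
            d -= d.mean()                 # stay on the constraint surface
            q = res.charges + d
            r = noisy.potentials - model.A @ q
            assert base <= float(r @ r) + 1e-10

    def test_restraint_pulls_toward_prior(self):
        grid, coords = _single_atom_grid(0.5)
        prior = pf.ChargeSet(charges=np.array([0.5]), net_charge=0.5)
        cs = pf.fit_esp_charges(grid, coords, net_charge=0.5,
                                restraint_weight=10.0, prior=prior)
        # single atom: constraint pins the charge regardless
        assert cs.charges[0] == pytest.approx(0.5, abs=1e-10)

    def test_point_on_atom_rejected(self, tpl_mixed):
        pts = np.vstack([tpl_mixed.coords[0], [10.0, 10.0, 10.0]])
        grid = ESPGrid(points=pts, potentials=np.zeros(2),
                       environment="vacuum")
        with pytest.raises(PointOnAtom):
            pf.fit_esp_charges(grid, tpl_mixed.coords, 0.0)

    def test_fewer_points_than_atoms_rejected(self, tpl_mixed):
        grid = ESPGrid(points=np.full((2, 3), 30.0),
                       potentials=np.zeros(2), environment="vacuum")
        with pytest.raises(Mismatch):
            pf.fit_esp_charges(grid, tpl_mixed.coords, 0.0)


class TestIpolQ:
    def test_identical_inputs_identity(self):
        a = pf.ChargeSet(np.array([0.2, -0.2]), 0.0)
        out = pf.combine_ipolq(a, a)
        np.testing.assert_allclose(out.charges, a.charges)

    def test_midpoint(self):
        a = pf.ChargeSet(np.array([0.2, -0.2]), 0.0)
        b = pf.ChargeSet(np.array([0.4, -0.4]), 0.0)
        out = pf.combine_ipolq(a, b)
        assert out.charges[0] == pytest.approx(0.3)
        assert out.environment == "ipolq"

    def test_oracle_midpoint_analytic(self, tpl_mixed, params):
        """Solvated grid built from q_vac + dq: the combined fit equals
        q_vac + dq/2 by linearity of the constrained fit."""
        oracle = pf.make_oracle(9, [tpl_mixed], params)
        vac, solv = pf.oracle_esp_grids(tpl_mixed, oracle, density=1.0,
                                        seed=13)
        qv = pf.fit_esp_charges(vac, tpl_mixed.coords, tpl_mixed.net_charge)
        qs = pf.fit_esp_charges(solv, tpl_mixed.coords, tpl_mixed.net_charge)
        comb = pf.combine_ipolq(qv, qs)
        np.testing.assert_allclose(
            comb.charges, pf.expected_ipolq(oracle, tpl_mixed.name),
            atol=1e-6)

    def test_net_charge_mismatch_rejected(self):
        a = pf.ChargeSet(np.array([0.0]), 0.0)
        b = pf.ChargeSet(np.array([1.0]), 1.0)
        with pytest.raises(Mismatch):
            pf.combine_ipolq(a, b)


class TestConvergedCharges:
    def test_three_percent_passes(self):
        a = pf.ChargeSet(np.array([0.5, -0.5]), 0.0)
        b = pf.ChargeSet(np.array([0.515, -0.515]), 0.0)
        assert pf.converged_charges(a, b) is True

    def test_six_percent_fails(self):
        a = pf.ChargeSet(np.array([0.5, -0.5]), 0.0)
        b = pf.ChargeSet(np.array([0.53, -0.53]), 0.0)
        assert pf.converged_charges(a, b) is False

    def test_floor_on_near_zero_charge(self):
        a = pf.ChargeSet(np.array([0.0, 0.0]), 0.0)
        b = pf.ChargeSet(np.array([0.0004, -0.0004]), 0.0)
        assert pf.converged_charges(a, b) is True


class TestShellGrid:
    def test_seed_determinism(self, tpl_mixed, params):
        a = pf.make_shell_grid(tpl_mixed, density=0.5, seed=4,
                               lj_radii=params.lj)
        b = pf.make_shell_grid(tpl_mixed, density=0.5, seed=4,
                               lj_radii=params.lj)
        np.testing.assert_array_equal(a, b)

    def test_density_scaling(self, tpl_mixed, params):
        counts = []
        for seed in range(5):
            n1 = len(pf.make_shell_grid(tpl_mixed, density=1.0, seed=seed,
                                        lj_radii=params.lj))
            n2 = len(pf.make_shell_grid(tpl_mixed, density=2.0, seed=seed,
                                        lj_radii=params.lj))
            counts.append(n2 / n1)
        assert np.mean(counts) == pytest.approx(2.0, rel=0.10)

    def test_distance_audit(self, tpl_mixed, params):
        """Every point is >= inner_scale*r* (and >= 1 A) from every atom."""
        from puckerfit.chargefit import _atom_radii
        pts = pf.make_shell_grid(tpl_mixed, inner_scale=1.4, density=1.0,
                                 seed=0, lj_radii=params.lj)
        radii = _atom_radii(tpl_mixed, params.lj)
        d = np.linalg.norm(pts[:, None, :] - tpl_mixed.coords[None], axis=2)
        inner = np.maximum(1.4 * radii, MIN_GRID_DISTANCE)
        assert np.all(d >= inner[None, :])


class TestGridIO:
    def test_roundtrip(self, tpl_mixed, params, tmp_path):
        oracle = pf.make_oracle(2, [tpl_mixed], params)
        vac, _ = pf.oracle_esp_grids(tpl_mixed, oracle, density=0.5, seed=1)
        path = tmp_path / "grid.dat"
        pf.write_esp_grid(path, vac)
        back = pf.read_esp_grid(path)
        assert back.environment == "vacuum"
        assert back.template_id == tpl_mixed.name
        np.testing.assert_allclose(back.points, vac.points, atol=1e-7)
        np.testing.assert_allclose(back.potentials, vac.potentials,
                                   atol=1e-9)
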