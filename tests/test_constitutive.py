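"""Constitutive laws: closed forms, consistency and invariance properties."""

import numpy as np
import pytest

from wiop.constitutive import (DeformationState, MaterialParams, hgo_energy,
                               hgo_stress, membrane_energy,
                               membrane_energy_derivs, neohookean_energy)

E1, E2, E3 = np.eye(3)
ROW2 = dict(C10=0.045, k1=0.027, k2=180.0)     # baseline corneal parameters


def small_random_F(rng, scale=0.03):
    return np.eye(3) + scale * rng.standard_normal((3, 3))


def corneal_params(**kw):
    p = dict(ROW2)
    p.update(kw)
    return MaterialParams(fibre_directions=[E1, E2], **p)


class TestEnergyClosedForms:
    def test_identity_energy_is_zero(self):
        state = DeformationState(np.eye(3))
        assert hgo_energy(state, corneal_params()) == 0.0
        assert neohookean_energy(state, MaterialParams(0.3)) == 0.0

    def test_k1_zero_reduces_to_neohookean(self, rng):
        p_fib = corneal_params(k1=0.0)
        p_nh = MaterialParams(ROW2["C10"])
        for _ in range(20):
            state = DeformationState(small_random_F(rng))
            assert hgo_energy(state, p_fib) == pytest.approx(
                neohookean_energy(state, p_nh), rel=1e-12)

    def test_uniaxial_isochoric_neohookean_closed_form(self):
        lam = 1.07
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        p = MaterialParams(0.3)
        expected = 0.3 * (lam ** 2 + 2.0 / lam - 3.0)
        assert neohookean_energy(DeformationState(F), p) == pytest.approx(
            expected, rel=1e-12)

    def test_equibiaxial_baseline_parameters_independent_evaluation(self):
        """Equi-biaxial isochoric stretch 1.05 with the baseline corneal set:
        the energy must equal a from-scratch evaluation of the formula."""
        lam = 1.05
        F = np.diag([lam, lam, lam ** -2])
        state = DeformationState(F)
        # independent evaluation (J = 1, so invariants are unmodified)
        I1 = 2 * lam ** 2 + lam ** -4
        I4 = I6 = lam ** 2
        expected = (ROW2["C10"] * (I1 - 3.0)
                    + ROW2["k1"] / (2 * ROW2["k2"])
                    * sum(np.exp(ROW2["k2"] * (I - 1.0) ** 2) - 1.0
                          for I in (I4, I6)))
        got = hgo_energy(state, corneal_params())
        assert got == pytest.approx(expected, rel=1e-12)
        # frozen value of that evaluation, for the record
        assert got == pytest.approx(2.0906343e-3, rel=1e-6)

    def test_rejects_nonpositive_jacobian(self):
        with pytest.raises(ValueError):
            DeformationState(np.diag([1.0, 1.0, -1.0]))


class TestStress:
    def test_identity_stress_is_zero(self):
        sigma = hgo_stress(DeformationState(np.eye(3)), corneal_params())
        np.testing.assert_allclose(sigma, 0.0, atol=1e-14)

    def test_stress_matches_numerical_energy_gradient(self, rng):
        """Analytic Cauchy stress vs central differences of the energy for
        100 random small deformations (energy-stress consistency)."""
        p = corneal_params()
        h = 1e-6
        worst = 0.0
        for _ in range(100):
            F = small_random_F(rng)
            state = DeformationState(F)
            # P_ij = dpsi/dF_ij by central differences
            P_num = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P_num[i, j] = (
                        hgo_energy(DeformationState(Fp), p, include_volumetric=True)
                        - hgo_energy(DeformationState(Fm), p, include_volumetric=True)
                    ) / (2 * h)
            sigma_num = P_num @ F.T / np.linalg.det(F)
            sigma_num = 0.5 * (sigma_num + sigma_num.T)
            sigma = hgo_stress(state, p)
            denom = max(np.abs(sigma_num).max(), 1e-6)
            worst = max(worst, np.abs(sigma - sigma_num).max() / denom)
        assert worst < 1e-4

    def test_material_frame_indifference(self, rng):
        p = corneal_params()
        F = small_random_F(rng)
        e0 = hgo_energy(DeformationState(F), p)
        for _ in range(10):
            A = rng.standard_normal((3, 3))
            Q, _ = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            e = hgo_energy(DeformationState(Q @ F), p)
            assert e == pytest.approx(e0, abs=1e-10, rel=1e-10)

    def test_monotone_in_invariants(self):
        """Energy strictly increases with I1 beyond 3 and with the fibre
        invariants beyond 1 (exponential stiffening, convex in tension)."""
        p = corneal_params()
        lams = np.linspace(1.0, 1.08, 30)
        energies = [hgo_energy(
            DeformationState(np.diag([l, l, l ** -2])), p) for l in lams]
        diffs = np.diff(energies)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) > 0)      # convex stiffening


class TestMaterialParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            MaterialParams(-0.1)
        with pytest.raises(ValueError):
            MaterialParams(0.1, k1=0.02, k2=0.0)
        with pytest.raises(ValueError):
            MaterialParams(0.1, bulk_penalty=1.0)
        with pytest.raises(ValueError):
            MaterialParams(0.1, fibre_directions=[[1.0, 1.0, 0.0]])

    def test_default_bulk_penalty_is_large(self):
        p = MaterialParams(0.045)
        assert p.bulk_penalty >= 1e3 * p.C10


class TestMembraneKernel:
    def test_matches_full_3d_law_on_plane_stress_states(self, rng):
        """The (lam_s, lam_t) kernel equals the 3-D law evaluated at
        F = diag(lam_s, lam_t, 1/(lam_s lam_t)) with axis-aligned fibres."""
        p = corneal_params()
        for _ in range(20):
            ls, lt = 1.0 + 0.06 * rng.random(2)
            F = np.diag([ls, lt, 1.0 / (ls * lt)])
            full = hgo_energy(DeformationState(F), p)
            red = membrane_energy(ls, lt, **ROW2, n_mer=1, n_circ=1)
            assert float(red) == pytest.approx(full, rel=1e-10)

    def test_derivatives_match_finite_differences(self, rng):
        h = 1e-7
        for _ in range(20):
            ls, lt = 1.0 + 0.08 * rng.random(2)
            _, ds, dt = membrane_energy_derivs(ls, lt, **ROW2, n_mer=1, n_circ=1)
            fd_s = (membrane_energy(ls + h, lt, **ROW2, n_mer=1, n_circ=1)
                    - membrane_energy(ls - h, lt, **ROW2, n_mer=1, n_circ=1)) / (2 * h)
            fd_t = (membrane_energy(ls, lt + h, **ROW2, n_mer=1, n_circ=1)
                    - membrane_energy(ls, lt - h, **ROW2, n_mer=1, n_circ=1)) / (2 * h)
            assert float(ds) == pytest.approx(float(fd_s), rel=1e-5)
            assert float(dt) == pytest.approx(float(fd_t), rel=1e-5)

    def test_fibres_inactive_in_compression(self):
        """Contracting a fibre direction must not add fibre energy."""
        e = membrane_energy(0.97, 1.0, **ROW2, n_mer=1, n_circ=0)
        e_nh = membrane_energy(0.97, 1.0, C10=ROW2["C10"])
        assert float(e) == pytest.approx(float(e_nh), rel=1e-12)


def test_physiological_corneal_stress_magnitude(pressurized):
    """Mean in-plane corneal Cauchy stress at 15 mmHg is of the order of
    0.02 MPa (for an incompressible membrane sigma_i = lam_i dpsi/dlam_i)."""
    system = pressurized.system
    mesh = system.mesh
    lam_s, lam_t, _, _ = system.stretches(pressurized.coords)
    cor = mesh.corneal_elements
    _, dps, dpt = membrane_energy_derivs(lam_s[cor], lam_t[cor], **ROW2,
                                         n_mer=1, n_circ=1)
    sigma = 0.5 * (lam_s[cor] * dps + lam_t[cor] * dpt)
    mean_stress = float(np.mean(sigma))
    assert 0.005 < mean_stress < 0.08
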