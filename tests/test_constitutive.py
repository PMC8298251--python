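"""Constitutive law: kinematics, energy, stress, and their oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquemech import constitutive as ct

PRESETS = ["vessel", "lipid", "calcification"]
E1 = np.array([1.0, 0.0])


def random_F(rng, scale=0.05):
    while True:
        F = np.eye(2) + scale * rng.standard_normal((2, 2))
        if np.linalg.det(F) > 0.2:
            return F


class TestKinematics:
    def test_identity(self):
        kin = ct.kinematics(np.eye(2), 1.0, E1)
        assert (kin.I1, kin.I2, kin.I4, kin.J) == (3.0, 3.0, 1.0, 1.0)
        assert np.allclose(kin.green_strain, 0.0)

    def test_isochoric_planar_stretch(self):
        lam = 1.3
        kin = ct.kinematics(np.diag([lam, 1 / lam]), 1.0, E1)
        assert kin.I4 == pytest.approx(lam**2)
        assert kin.J == pytest.approx(1.0)

    def test_invariants_against_eigen_oracle(self):
        """I1, I2 of random SPD C match the eigenvalue-based definitions."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            F = random_F(rng, 0.2)
            lz = rng.uniform(0.8, 1.3)
            kin = ct.kinematics(F, lz)
            C3 = np.zeros((3, 3))
            C3[:2, :2] = F.T @ F
            C3[2, 2] = lz**2
            ev = np.linalg.eigvalsh(C3)
            assert kin.I1 == pytest.approx(ev.sum(), rel=1e-12)
            i2 = ev[0] * ev[1] + ev[1] * ev[2] + ev[0] * ev[2]
            assert kin.I2 == pytest.approx(i2, rel=1e-12)
            assert kin.J == pytest.approx(np.sqrt(np.prod(ev)), rel=1e-12)

    def test_singular_F_rejected(self):
        with pytest.raises(ValueError):
            ct.kinematics(np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestStrainEnergy:
    @pytest.mark.parametrize("name", PRESETS)
    def test_reference_normalization(self, name):
        mat = ct.material_preset(name)
        kin = ct.kinematics(np.eye(2), 1.0, E1)
        assert ct.strain_energy(kin, mat) == 0.0

    def test_lipid_scalar_example(self):
        """Lipid at I1 = I2 = 4, J = 1:
        W = 0.5*1 + 0.5*(e^1.5 - 1) = 2.2408... kPa."""
        lam2 = (3 + np.sqrt(5)) / 2      # lam^2 + lam^-2 + 1 = 4
        F = np.diag([np.sqrt(lam2), 1 / np.sqrt(lam2)])
        kin = ct.kinematics(F)
        assert (kin.I1, kin.J) == (pytest.approx(4.0), pytest.approx(1.0))
        W = ct.strain_energy(kin, ct.material_preset("lipid"))
        assert W == pytest.approx(0.5 + 0.5 * np.expm1(1.5), rel=1e-12)
        assert W == pytest.approx(2.2408, abs=1e-4)

    def test_fiber_term_vanishes_at_natural_length(self):
        mat = ct.material_preset("vessel")
        iso = ct.material_preset("vessel", K1=0.0)
        # compression along the fiber: tension-only term stays off
        F = np.diag([1.05, 0.9])
        kin = ct.kinematics(F, 1.0, np.array([0.0, 1.0]))
        assert ct.strain_energy(kin, mat) == pytest.approx(
            ct.strain_energy(kin, iso), rel=1e-12)

    def test_overflow_raises_range_error(self):
        mat = ct.material_preset("vessel")
        kin = ct.kinematics(np.diag([3.0, 3.0]), 1.0, E1)
        with pytest.raises(ct.ConstitutiveRangeError):
            ct.strain_energy(kin, mat)

    @pytest.mark.parametrize("name", PRESETS)
    def test_objectivity(self, name):
        """W(QF) = W(F) for rotations Q."""
        mat = ct.material_preset(name)
        rng = np.random.default_rng(11)
        for _ in range(20):
            F = random_F(rng, 0.1)
            th = rng.uniform(0, 2 * np.pi)
            Q = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            n = np.array([0.6, 0.8])
            w1 = ct.strain_energy(ct.kinematics(F, 1.0, n), mat)
            w2 = ct.strain_energy(ct.kinematics(Q @ F, 1.0, n), mat)
            assert w2 == pytest.approx(w1, rel=1e-10, abs=1e-10)

    @pytest.mark.parametrize("name", PRESETS)
    def test_nonnegative_near_identity(self, name):
        mat = ct.material_preset(name)
        rng = np.random.default_rng(5)
        for _ in range(200):
            F = random_F(rng, 0.03)
            kin = ct.kinematics(F, rng.uniform(0.97, 1.03), E1)
            assert ct.strain_energy(kin, mat) >= 0.0


class TestCauchyStress:
    @pytest.mark.parametrize("name", PRESETS)
    def test_stress_free_reference(self, name):
        mat = ct.material_preset(name)
        sig = ct.cauchy_stress(ct.kinematics(np.eye(2), 1.0, E1), mat)
        assert np.allclose(sig.cauchy, 0.0, atol=1e-12)

    @pytest.mark.parametrize("name", PRESETS)
    def test_finite_difference_of_energy(self, name):
        """sigma = J^-1 (dW/dF) F^T against central differences of W."""
        mat = ct.material_preset(name)
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(100):
            F = random_F(rng)
            n = np.array([1.0, 0.0])
            kin = ct.kinematics(F, 1.0, n)
            sig = ct.cauchy_stress(kin, mat).cauchy[:2, :2]
            h = 1e-6
            P = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (ct.strain_energy(ct.kinematics(Fp, 1.0, n), mat)
                               - ct.strain_energy(ct.kinematics(Fm, 1.0, n),
                                                  mat)) / (2 * h)
            ref = 0.5 * (P @ F.T + (P @ F.T).T) / np.linalg.det(F)
            scale = max(np.abs(sig).max(), 1e-8)
            worst = max(worst, np.abs(sig - ref).max() / scale)
        assert worst < 1e-5

    def test_equibiaxial_symmetry(self):
        mat = ct.material_preset("calcification")
        kin = ct.kinematics(np.diag([1.1, 1.1]))
        sig = ct.cauchy_stress(kin, mat).cauchy
        assert sig[0, 0] == pytest.approx(sig[1, 1], rel=1e-12)
        assert sig[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_principal_decomposition_reconstructs(self):
        mat = ct.material_preset("vessel")
        rng = np.random.default_rng(2)
        st_ = ct.cauchy_stress(ct.kinematics(random_F(rng), 1.0, E1), mat)
        rebuilt = (st_.principal_dirs
                   @ np.diag(st_.principal_values)
                   @ st_.principal_dirs.T)
        assert np.allclose(rebuilt, st_.cauchy, atol=1e-10)

    def test_batched_tangent_matches_finite_difference(self):
        mat = ct.material_preset("vessel")
        rng = np.random.default_rng(7)
        C = np.stack([ct.kinematics(random_F(rng)).C for _ in range(8)])
        nc = np.tile(np.array([0.0, 1.0]), (8, 1))
        S, H, W, J = ct.pk2_and_tangent(C, 1.1, nc, mat)
        h = 1e-6
        for k in range(2):
            for l in range(2):
                Cp, Cm = C.copy(), C.copy()
                Cp[:, k, l] += h
                Cm[:, k, l] -= h
                Sp = ct.pk2_and_tangent(Cp, 1.1, nc, mat)[0]
                Sm = ct.pk2_and_tangent(Cm, 1.1, nc, mat)[0]
                fd = (Sp - Sm) / (2 * h)
                assert np.abs(fd - H[:, :, :, k, l]).max() \
                    < 1e-5 * np.abs(H).max()


class TestPrincipalMax:
    @pytest.mark.parametrize("tensor,expected", [
        (np.diag([3.0, 1.0]), 3.0),
        (np.array([[0.0, 2.0], [2.0, 0.0]]), 2.0),
        (np.diag([1.0, 2.0, 5.0]), 5.0),
    ])
    def test_known_cases(self, tensor, expected):
        assert ct.principal_max(tensor) == pytest.approx(expected)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            ct.principal_max(np.array([[0.0, 1.0], [0.0, 0.0]]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_characteristic_polynomial_oracle(self, seed):
        """2x2 closed form: mean + sqrt(((a-c)/2)^2 + b^2)."""
        rng = np.random.default_rng(seed)
        a, b, c = rng.standard_normal(3) * 10
        T = np.array([[a, b], [b, c]])
        expected = 0.5 * (a + c) + np.sqrt(0.25 * (a - c) ** 2 + b**2)
        assert ct.principal_max(T) == pytest.approx(expected, abs=1e-12)


class TestPresets:
    def test_printed_values_stored_verbatim(self):
        v = ct.MATERIAL_PRESETS["vessel"]
        assert (v.c1, v.c2, v.D1, v.D2) == (-1312.9, 114.7, 629.7, 2.0)
        assert (v.K1, v.K2) == (35.9, 23.5)
        li = ct.MATERIAL_PRESETS["lipid"]
        assert (li.c1, li.c2, li.D1, li.D2) == (0.5, 0.0, 0.5, 1.5)
        ca = ct.MATERIAL_PRESETS["calcification"]
        assert (ca.c1, ca.c2, ca.D1, ca.D2) == (92.0, 0.0, 36.0, 2.0)

    @pytest.mark.parametrize("name", PRESETS)
    def test_tangent_positive_definite_at_identity(self, name):
        """The vessel preset's negative c1 still yields a stable reference
        state (checked on the full 6x6 small-strain tangent)."""
        K = ct.tangent_at_identity(ct.material_preset(name))
        assert np.linalg.eigvalsh(0.5 * (K + K.T)).min() > 0

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            ct.material_preset("rubber")

    def test_override(self):
        mat = ct.material_preset("lipid", kappa_vol=500.0)
        assert mat.kappa_vol == 500.0
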