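"""Hyperelastic constitutive laws for vessel wall and plaque components.

The vessel wall / fibrous cap is modelled with a modified Mooney--Rivlin
strain-energy density carrying an exponential isotropic term and an
exponential circumferential-fiber reinforcement::

    W = c1 (I1b - 3) + c2 (I2b - 3) + D1 [exp(D2 (I1b - 3)) - 1]
        + (K1/K2) {exp[K2 (I4 - 1)^2] - 1} + (kappa/2) (J - 1)^2

Here ``I1b = J^(-2/3) I1`` and ``I2b = J^(-4/3) I2`` are the isochoric
invariants of the right Cauchy--Green tensor ``C = F^T F`` (with the
prescribed axial stretch folded into the 3D tensor), ``I4 = n_c . C n_c``
is the squared stretch along the circumferential fiber direction ``n_c``,
and ``J = det F``.  Plaque components (lipid-rich necrotic core,
calcification) use the isotropic form (``K1 = 0``).  Near-incompressibility
is the multiplicative isochoric/volumetric split with a quadratic penalty
(bulk modulus ``kappa_vol`` at the reference state); the fiber term is
active only in tension (``I4 > 1``), the usual convention for exponential
fiber models.  With this construction both ``W`` and the Cauchy stress
vanish identically in the reference state.

Kinematics are in-plane 2x2 with a prescribed (generalized plane strain)
axial stretch ``lambda_z``; ``lambda_z = 1`` is plane strain, while the
thin-layer models prescribe ``lambda_z = 1/0.9`` to undo the 10% axial
shrink.  Moduli and stresses are in kPa, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "KinematicState",
    "StressState",
    "ConstitutiveRangeError",
    "material_preset",
    "MATERIAL_PRESETS",
    "kinematics",
    "strain_energy",
    "cauchy_stress",
    "principal_max",
    "pk2_and_tangent",
    "tangent_at_identity",
    "small_strain_moduli",
]

# Guard for the exponential terms: beyond this exponent the material model is
# far outside its calibrated range and float64 is close to overflow.
_EXP_GUARD = 60.0

_I2 = np.eye(2)


class ConstitutiveRangeError(ValueError):
    """Raised when an exponential term overflows (extreme stretch)."""


@dataclass(frozen=True)
class MaterialParams:
    """Parameters of the (an)isotropic modified Mooney--Rivlin law.

    ``c1, c2, D1, K1`` are in kPa, ``D2, K2`` dimensionless, ``kappa_vol``
    (the volumetric penalty / bulk modulus) in kPa.  ``fiber_direction`` is
    the in-plane circumferential unit vector; it may be ``None`` for
    isotropic materials or when the direction is supplied per element by
    the solver.
    """

    name: str
    c1: float
    c2: float
    D1: float
    D2: float
    K1: float = 0.0
    K2: float = 1.0
    kappa_vol: float = 3000.0
    fiber_direction: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kappa_vol <= 0:
            raise ValueError("kappa_vol must be positive")
        if self.anisotropic and self.K2 <= 0:
            raise ValueError("K2 must be positive for anisotropic materials")
        if self.fiber_direction is not None:
            v = np.asarray(self.fiber_direction, dtype=float)
            if v.shape != (2,) or not np.isclose(np.linalg.norm(v), 1.0):
                raise ValueError("fiber_direction must be an in-plane unit 2-vector")
            object.__setattr__(self, "fiber_direction", v)

    @property
    def anisotropic(self) -> bool:
        return self.K1 != 0.0

    def with_stiffness_scale(self, factor: float) -> "MaterialParams":
        """Scale every stress-like modulus by ``factor`` (kappa included)."""
        return replace(
            self,
            name=f"{self.name}*{factor:g}",
            c1=self.c1 * factor,
            c2=self.c2 * factor,
            D1=self.D1 * factor,
            K1=self.K1 * factor,
            kappa_vol=self.kappa_vol * factor,
        )


# Printed parameter sets: vessel tissue / fibrous cap (anisotropic), lipid
# core and calcification (isotropic).  kPa throughout.
MATERIAL_PRESETS: dict[str, MaterialParams] = {
    "vessel": MaterialParams("vessel", c1=-1312.9, c2=114.7, D1=629.7, D2=2.0,
                             K1=35.9, K2=23.5),
    "lipid": MaterialParams("lipid", c1=0.5, c2=0.0, D1=0.5, D2=1.5),
    "calcification": MaterialParams("calcification", c1=92.0, c2=0.0, D1=36.0, D2=2.0),
}
MATERIAL_PRESETS["calc"] = MATERIAL_PRESETS["calcification"]


def material_preset(name: str, **overrides) -> MaterialParams:
    """Return a named preset, optionally overriding individual parameters.

    The tangent stiffness of each preset is checked to be positive definite
    at the reference state (the printed vessel ``c1`` is negative; stability
    at identity is not obvious by inspection and is verified here).
    """
    try:
        base = MATERIAL_PRESETS[name]
    except KeyError as exc:
        raise KeyError(f"unknown material preset {name!r}; "
                       f"choose from {sorted(MATERIAL_PRESETS)}") from exc
    mat = replace(base, **overrides) if overrides else base
    K = tangent_at_identity(mat)
    if np.linalg.eigvalsh(0.5 * (K + K.T)).min() <= 0:
        raise ValueError(f"preset {name!r} has a non-positive-definite "
                         f"tangent stiffness at the reference state")
    return mat


@dataclass(frozen=True)
class KinematicState:
    """Deformation measures at a material point.

    ``F`` is the in-plane 2x2 deformation gradient and ``lambda_z`` the
    prescribed axial stretch; ``C`` is the in-plane right Cauchy--Green
    block.  ``I1, I2`` are the *full* invariants of ``diag(C, lambda_z^2)``
    (the energy uses their isochoric counterparts internally).
    ``green_strain`` is the 3D Green--Lagrange strain (block diagonal).
    """

    F: np.ndarray
    lambda_z: float
    C: np.ndarray
    I1: float
    I2: float
    I4: float
    J: float
    green_strain: np.ndarray
    n_c: np.ndarray | None = None


@dataclass(frozen=True)
class StressState:
    """Symmetric Cauchy stress with its principal decomposition (kPa)."""

    cauchy: np.ndarray
    principal_values: np.ndarray
    principal_dirs: np.ndarray


def kinematics(F: np.ndarray, lambda_z: float = 1.0,
               n_c: np.ndarray | None = None) -> KinematicState:
    """Build the kinematic state from an in-plane deformation gradient."""
    F = np.asarray(F, dtype=float)
    if F.shape != (2, 2):
        raise ValueError("F must be 2x2 (in-plane)")
    detF = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]
    if not detF > 0:
        raise ValueError(f"non-invertible or orientation-reversing F (det = {detF:g})")
    if lambda_z <= 0:
        raise ValueError("lambda_z must be positive")
    C = F.T @ F
    lz2 = lambda_z**2
    I1 = C[0, 0] + C[1, 1] + lz2
    trC3sq = np.sum(C * C) + lz2**2
    I2 = 0.5 * (I1**2 - trC3sq)
    if n_c is not None:
        n_c = np.asarray(n_c, dtype=float)
        I4 = float(n_c @ C @ n_c)
    else:
        I4 = 1.0
    J = detF * lambda_z
    E = np.zeros((3, 3))
    E[:2, :2] = 0.5 * (C - _I2)
    E[2, 2] = 0.5 * (lz2 - 1.0)
    return KinematicState(F=F, lambda_z=lambda_z, C=C, I1=float(I1),
                          I2=float(I2), I4=I4, J=float(J), green_strain=E,
                          n_c=n_c)


# ----------------------------------------------------------------------
# Batched core: energy, in-plane 2nd Piola-Kirchhoff stress, axial stress
# ----------------------------------------------------------------------
# These accept complex input so that material tangents can be obtained by
# complex-step differentiation (exact to machine precision).

def _invariants(C, lambda_z):
    lz2 = lambda_z**2
    trC = C[..., 0, 0] + C[..., 1, 1]
    detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    I1 = trC + lz2
    trC3sq = np.einsum("...ij,...ij->...", C, C) + lz2**2
    I2 = 0.5 * (I1**2 - trC3sq)
    J = np.sqrt(detC) * lambda_z
    return I1, I2, J, detC


def _check_exponents(mat, e1, e4=None) -> None:
    if np.any(np.real(e1) > _EXP_GUARD):
        raise ConstitutiveRangeError(
            f"isotropic exponential overflow: D2*(I1b-3) = {np.max(np.real(e1)):.3g}")
    if e4 is not None and np.any(np.real(e4) > _EXP_GUARD):
        raise ConstitutiveRangeError(
            f"fiber exponential overflow: K2*(I4-1)^2 = {np.max(np.real(e4)):.3g}")


def _energy_batch(C, lambda_z, n_c, mat):
    """W(C) for a batch of in-plane C tensors (complex-safe)."""
    I1, I2, J, _ = _invariants(C, lambda_z)
    I1b = J**(-2.0 / 3.0) * I1
    I2b = J**(-4.0 / 3.0) * I2
    e1 = mat.D2 * (I1b - 3.0)
    _check_exponents(mat, e1)
    W = (mat.c1 * (I1b - 3.0) + mat.c2 * (I2b - 3.0) + mat.D1 * np.expm1(e1)
         + 0.5 * mat.kappa_vol * (J - 1.0) ** 2)
    if mat.anisotropic:
        I4 = np.einsum("...i,...ij,...j->...", n_c, C, n_c)
        x = I4 - 1.0
        e4 = mat.K2 * x**2
        _check_exponents(mat, 0.0, e4)
        active = np.real(I4) > 1.0
        W = W + np.where(active, mat.K1 / mat.K2 * np.expm1(e4), 0.0 * W)
    return W


def _pk2_batch(C, lambda_z, n_c, mat):
    """In-plane second Piola--Kirchhoff stress S = 2 dW/dC (complex-safe).

    Isochoric part (3D invariants restricted to the in-plane block)::

        S_iso = 2 J^(-2/3) W1b (I - (I1/3) Cinv)
              + 2 c2 J^(-4/3) (I1 I - C - (2 I2/3) Cinv)
        S_fib = 4 K1 (I4-1) exp(K2 (I4-1)^2) n (x) n      (I4 > 1 only)
        S_vol = kappa (J-1) J Cinv
    """
    I1, I2, J, detC = _invariants(C, lambda_z)
    I1b = J**(-2.0 / 3.0) * I1
    e1 = mat.D2 * (I1b - 3.0)
    _check_exponents(mat, e1)
    W1b = mat.c1 + mat.D1 * mat.D2 * np.exp(e1)

    Cinv = np.empty_like(C)
    Cinv[..., 0, 0] = C[..., 1, 1] / detC
    Cinv[..., 1, 1] = C[..., 0, 0] / detC
    Cinv[..., 0, 1] = -C[..., 0, 1] / detC
    Cinv[..., 1, 0] = -C[..., 1, 0] / detC

    eye = np.zeros_like(C)
    eye[..., 0, 0] = 1.0
    eye[..., 1, 1] = 1.0

    S = (2.0 * (J**(-2.0 / 3.0) * W1b)[..., None, None]
         * (eye - (I1 / 3.0)[..., None, None] * Cinv)
         + 2.0 * mat.c2 * J[..., None, None]**(-4.0 / 3.0)
         * (I1[..., None, None] * eye - C - (2.0 * I2 / 3.0)[..., None, None] * Cinv)
         + (mat.kappa_vol * (J - 1.0) * J)[..., None, None] * Cinv)

    if mat.anisotropic:
        I4 = np.einsum("...i,...ij,...j->...", n_c, C, n_c)
        x = I4 - 1.0
        _check_exponents(mat, 0.0, mat.K2 * x**2)
        active = np.real(I4) > 1.0
        coef = np.where(active, 4.0 * mat.K1 * x * np.exp(mat.K2 * x**2), 0.0 * x)
        S = S + coef[..., None, None] * np.einsum("...i,...j->...ij", n_c, n_c)
    return S


def _pk2_axial_batch(C, lambda_z, mat):
    """S_zz (fiber lies in plane, so only isotropic + volumetric parts)."""
    I1, I2, J, _ = _invariants(C, lambda_z)
    lz2 = lambda_z**2
    I1b = J**(-2.0 / 3.0) * I1
    W1b = mat.c1 + mat.D1 * mat.D2 * np.exp(mat.D2 * (I1b - 3.0))
    return (2.0 * J**(-2.0 / 3.0) * W1b * (1.0 - I1 / (3.0 * lz2))
            + 2.0 * mat.c2 * J**(-4.0 / 3.0) * (I1 - lz2 - 2.0 * I2 / (3.0 * lz2))
            + mat.kappa_vol * (J - 1.0) * J / lz2)


def pk2_and_tangent(C: np.ndarray, lambda_z: float, n_c: np.ndarray,
                    mat: MaterialParams):
    """Vectorized in-plane S(C) and tangent dS/dC by complex step.

    Parameters
    ----------
    C : (n, 2, 2) right Cauchy--Green tensors.
    lambda_z : prescribed axial stretch (scalar, shared across the batch).
    n_c : (n, 2) per-point fiber directions (ignored for isotropic laws).

    Returns ``(S, H, W, J)`` with ``S`` (n,2,2), ``H[n,i,j,k,l] =
    dS_ij/dC_kl`` (n,2,2,2,2), energy densities ``W`` (n,) and volume
    ratios ``J`` (n,).  The complex-step derivative is exact to round-off;
    the one-sided fiber activation is handled by freezing the active set at
    the real evaluation point (the kink at I4 = 1 has zero stress value, so
    the tangent jump is benign for Newton).
    """
    C = np.asarray(C, dtype=float)
    if mat.anisotropic:
        n_c = np.asarray(n_c, dtype=float)
    _, _, J, _ = _invariants(C, lambda_z)
    S = _pk2_batch(C, lambda_z, n_c, mat)
    W = _energy_batch(C, lambda_z, n_c, mat)
    h = 1e-30
    H = np.empty(C.shape[:1] + (2, 2, 2, 2))
    for k in range(2):
        for l in range(2):
            Cp = C.astype(complex)
            Cp[:, k, l] += 1j * h
            H[:, :, :, k, l] = np.imag(_pk2_batch(Cp, lambda_z, n_c, mat)) / h
    return np.real(S), H, np.real(W), np.real(J)


# ----------------------------------------------------------------------
# Scalar API
# ----------------------------------------------------------------------

def _resolve_fiber(kin: KinematicState, mat: MaterialParams) -> np.ndarray:
    n = kin.n_c if kin.n_c is not None else mat.fiber_direction
    if mat.anisotropic and n is None:
        raise ValueError("anisotropic material requires a fiber direction")
    return np.zeros(2) if n is None else np.asarray(n, dtype=float)


def strain_energy(kin: KinematicState, mat: MaterialParams) -> float:
    """Strain-energy density W in kPa; W = 0 in the reference state."""
    n = _resolve_fiber(kin, mat)
    # recompute I4 with the resolved fiber if the state carried none
    return float(np.real(_energy_batch(kin.C[None], kin.lambda_z, n[None], mat)[0]))


def cauchy_stress(kin: KinematicState, mat: MaterialParams) -> StressState:
    """Cauchy stress sigma = J^-1 F S F^T (3D, block diagonal), kPa."""
    n = _resolve_fiber(kin, mat)
    S = np.real(_pk2_batch(kin.C[None], kin.lambda_z, n[None], mat)[0])
    sig = np.zeros((3, 3))
    sig[:2, :2] = kin.F @ S @ kin.F.T / kin.J
    szz = float(np.real(_pk2_axial_batch(kin.C[None], kin.lambda_z, mat)[0]))
    sig[2, 2] = szz * kin.lambda_z**2 / kin.J
    sig[:2, :2] = 0.5 * (sig[:2, :2] + sig[:2, :2].T)  # exact symmetry
    vals, dirs = np.linalg.eigh(sig)
    order = np.argsort(vals)[::-1]
    return StressState(cauchy=sig, principal_values=vals[order],
                       principal_dirs=dirs[:, order])


def principal_max(tensor: np.ndarray) -> float:
    """Largest (signed) eigenvalue of a symmetric 2x2 or 3x3 tensor.

    Used as the scalar wall-stress (PWS, from Cauchy stress) and wall-strain
    (PWSn, from Green--Lagrange strain) summary at lumen points.
    """
    T = np.asarray(tensor, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1] or T.shape[0] not in (2, 3):
        raise ValueError("expected a 2x2 or 3x3 tensor")
    if not np.allclose(T, T.T, rtol=1e-8, atol=1e-10 * max(1.0, np.abs(T).max())):
        raise ValueError("tensor must be symmetric")
    return float(np.linalg.eigvalsh(0.5 * (T + T.T))[-1])


# ----------------------------------------------------------------------
# Small-strain tangent (for stability checks and linear-limit oracles)
# ----------------------------------------------------------------------

def tangent_at_identity(mat: MaterialParams, n_c=(0.0, 1.0)) -> np.ndarray:
    """Full 3D small-strain stiffness (6x6 Voigt) at the reference state.

    Includes the one-sided (tension-active) fiber contribution, so for the
    vessel preset the result is cylindrically orthotropic with the stiff
    axis along ``n_c``.  Obtained by finite differences of W on the tension
    side of the fiber switch.
    """
    h = 1e-5
    n = np.asarray(n_c, float)
    n3 = np.array([n[0], n[1], 0.0])

    def W3(eps):
        E = np.array([[eps[0], eps[3] / 2, eps[4] / 2],
                      [eps[3] / 2, eps[1], eps[5] / 2],
                      [eps[4] / 2, eps[5] / 2, eps[2]]])
        C3 = 2.0 * E + np.eye(3)
        I1 = np.trace(C3)
        I2 = 0.5 * (I1**2 - np.sum(C3 * C3))
        J = np.sqrt(np.linalg.det(C3))
        I1b = J**(-2.0 / 3.0) * I1
        I2b = J**(-4.0 / 3.0) * I2
        I4 = n3 @ C3 @ n3
        W = (mat.c1 * (I1b - 3) + mat.c2 * (I2b - 3)
             + mat.D1 * np.expm1(mat.D2 * (I1b - 3))
             + 0.5 * mat.kappa_vol * (J - 1) ** 2)
        if mat.anisotropic and I4 > 1.0:
            W += mat.K1 / mat.K2 * np.expm1(mat.K2 * (I4 - 1) ** 2)
        return W

    K = np.zeros((6, 6))
    for i in range(6):
        for j in range(i, 6):
            ei = np.zeros(6); ei[i] = h
            ej = np.zeros(6); ej[j] = h
            kij = (W3(ei + ej) - W3(ei) - W3(ej) + W3(np.zeros(6))) / h**2
            K[i, j] = K[j, i] = kij
    return K


def small_strain_moduli(mat: MaterialParams) -> tuple[float, float]:
    """(lambda, mu) Lamé constants of the isotropic part of the tangent.

    ``mu = 2 (c1 + c2 + D1 D2)``; ``lambda`` follows from the volumetric
    penalty (bulk modulus = kappa_vol under the isochoric split).
    """
    mu = 2.0 * (mat.c1 + mat.c2 + mat.D1 * mat.D2)
    lam = mat.kappa_vol - 2.0 * mu / 3.0
    return lam, mu
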