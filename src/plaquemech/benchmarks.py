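"""Independent semi-analytic benchmarks for the cross-section solver.

These solutions never touch the FEM machinery: they reduce the pressurized
circular ring (thick-walled annulus) to one-dimensional radial problems and
serve as oracles in the test suite and in the acceptance study.

* :func:`ring_inflation` -- finite-strain, exactly incompressible
  plane-strain inflation.  With ``J = 1`` the deformation is fully
  determined by the inner radius (``r^2 = R^2 - Ri^2 + ri^2``), the hoop
  stretch is ``lam = r/R``, and radial equilibrium integrates to
  ``p = int_ri^ro lam W'(lam) dr / r`` for the (isochorically evaluated)
  strain energy ``W(lam)``, fiber term included.  A scalar root-find on the
  deformed inner radius inverts the pressure relation.

* :func:`lame_hoop_stress` -- the classical isotropic Lamé thick-wall
  solution (small strain); its stresses are modulus-free.

* :func:`orthotropic_ring_hoop_stress` -- the Lekhnitskii-type power-law
  solution for a cylindrically orthotropic ring in plane strain, built from
  the small-strain tangent of the material law (the vessel preset's fiber
  term makes the hoop direction stiffer, so the isotropic Lamé formula is
  not its small-load limit).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from . import constitutive as ct

__all__ = [
    "ring_slice",
    "ring_inflation",
    "lame_hoop_stress",
    "orthotropic_ring_hoop_stress",
]


def ring_slice(r_inner: float, r_outer: float, n_points: int = 128):
    """Circular-annulus SliceContours for benchmarks (mm)."""
    from .synthetic_cohort import SliceContours
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    ring = lambda r: np.column_stack([r * np.cos(th), r * np.sin(th)])
    return SliceContours(0, 0.0, {"lumen": ring(r_inner), "outer": ring(r_outer)})


def _w_of_stretch(mat: ct.MaterialParams):
    """W(lam) along the incompressible plane-strain path diag(1/lam, lam, 1),
    with the fiber circumferential (I4 = lam^2).  J = 1 so the isochoric and
    full invariants coincide."""

    def W(lam):
        I1 = lam**2 + lam**-2 + 1.0
        w = (mat.c1 * (I1 - 3.0) + mat.c2 * (I1 - 3.0)
             + mat.D1 * np.expm1(mat.D2 * (I1 - 3.0)))
        if mat.anisotropic and lam > 1.0:
            w += mat.K1 / mat.K2 * np.expm1(mat.K2 * (lam**2 - 1.0) ** 2)
        return w

    def dW(lam):
        h = 1e-30
        # complex step; W is analytic on either side of lam = 1
        lamc = lam + 1j * h
        I1 = lamc**2 + lamc**-2 + 1.0
        w = (mat.c1 * (I1 - 3.0) + mat.c2 * (I1 - 3.0)
             + mat.D1 * (np.exp(mat.D2 * (I1 - 3.0)) - 1.0))
        if mat.anisotropic and lam > 1.0:
            w += mat.K1 / mat.K2 * (np.exp(mat.K2 * (lamc**2 - 1.0) ** 2) - 1.0)
        return np.imag(w) / h

    return W, dW


def ring_inflation(mat: ct.MaterialParams, R_i: float, R_o: float,
                   pressure_kpa: float):
    """Incompressible plane-strain inflation of a ring; returns a dict with
    the deformed radii and a ``hoop_stress(R)`` evaluator (kPa).

    For the anisotropic vessel preset the fiber direction is circumferential,
    exactly as in the FEM; note I2 = I1 on this deformation path.
    """
    _, dW = _w_of_stretch(mat)

    def pressure_of(ri):
        def integrand(r):
            R = np.sqrt(r**2 - ri**2 + R_i**2)
            lam = r / R
            return lam * dW(lam) / r
        ro = np.sqrt(R_o**2 - R_i**2 + ri**2)
        val, _ = quad(integrand, ri, ro, limit=200)
        return val

    f = lambda ri: pressure_of(ri) - pressure_kpa
    # grow the bracket gently: the exponential fiber term makes the
    # pressure-radius curve extremely steep, so a wide bracket overflows
    lo = R_i * (1 + 1e-9)
    hi = R_i * 1.02
    while f(hi) < 0:
        lo = hi
        hi *= 1.02
        if hi > 3.0 * R_i:
            raise RuntimeError("ring inflation bracket failure")
    ri = brentq(f, lo, hi, xtol=1e-12)
    ro = np.sqrt(R_o**2 - R_i**2 + ri**2)

    def sigma_rr(r):
        def integrand(rr):
            R = np.sqrt(rr**2 - ri**2 + R_i**2)
            lam = rr / R
            return lam * dW(lam) / rr
        val, _ = quad(integrand, r, ro, limit=200)
        return -val

    def hoop_stress(R):
        """Cauchy hoop stress at reference radius R."""
        r = np.sqrt(R**2 - R_i**2 + ri**2)
        lam = r / R
        return sigma_rr(r) + lam * dW(lam)

    return {"r_inner": ri, "r_outer": ro, "hoop_stress": hoop_stress,
            "lumen_area": np.pi * ri**2}


def lame_hoop_stress(R_i: float, R_o: float, pressure_kpa: float,
                     R: float) -> float:
    """Isotropic small-strain thick-wall (Lamé) hoop stress at radius R."""
    return pressure_kpa * R_i**2 * (1.0 + R_o**2 / R**2) / (R_o**2 - R_i**2)


def orthotropic_ring_hoop_stress(mat: ct.MaterialParams, R_i: float,
                                 R_o: float, pressure_kpa: float,
                                 R: float) -> float:
    """Small-strain hoop stress for a cylindrically orthotropic ring.

    Plane strain, axisymmetric: with condensed stiffnesses ``Crr, Ctt, Crt``
    (from the 6x6 tangent of W at identity, x = radial, y = hoop, eps_z = 0)
    the displacement is ``u = A r^k + B r^-k`` with ``k = sqrt(Ctt/Crr)``;
    A, B follow from sigma_rr(R_i) = -p, sigma_rr(R_o) = 0.  Reduces to
    Lamé when k = 1.
    """
    K6 = ct.tangent_at_identity(mat, n_c=(0.0, 1.0))
    Crr, Ctt, Crt = K6[0, 0], K6[1, 1], K6[0, 1]
    k = np.sqrt(Ctt / Crr)

    def srr_coeffs(r):
        # sigma_rr = Crr u' + Crt u/r for u = r^k and u = r^-k
        return (Crr * k * r**(k - 1) + Crt * r**(k - 1),
                -Crr * k * r**(-k - 1) + Crt * r**(-k - 1))

    a1, b1 = srr_coeffs(R_i)
    a2, b2 = srr_coeffs(R_o)
    A, B = np.linalg.solve(np.array([[a1, b1], [a2, b2]]),
                           np.array([-pressure_kpa, 0.0]))

    up = A * k * R**(k - 1) - B * k * R**(-k - 1)
    uor = A * R**(k - 1) + B * R**(-k - 1)
    return float(Crt * up + Ctt * uor)
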