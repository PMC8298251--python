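"""Shared fixtures: expensive FEM solves are session-scoped so the suite
stays within a desk-scale runtime."""

import numpy as np
import pytest

from plaquemech import benchmarks as bm
from plaquemech import constitutive as ct
from plaquemech import fem_solid as fem
from plaquemech.units import mmhg_to_kpa

RING_RI, RING_RO = 1.5, 3.0
RING_PRESSURE_KPA = mmhg_to_kpa(100.0)   # 13.3322 kPa


@pytest.fixture(scope="session")
def vessel_mat():
    return ct.material_preset("vessel")


@pytest.fixture(scope="session")
def ring_slice_session():
    return bm.ring_slice(RING_RI, RING_RO)


@pytest.fixture(scope="session")
def ring_mesh(ring_slice_session):
    return fem.build_mesh(ring_slice_session, 0.2)


@pytest.fixture(scope="session")
def ring_solution(ring_mesh, vessel_mat):
    """Vessel-preset ring inflated at 100 mmHg (plane strain)."""
    cfg = fem.SolveConfig(pressure=RING_PRESSURE_KPA)
    return fem.solve_static(ring_mesh, {"wall": vessel_mat}, cfg)


@pytest.fixture(scope="session")
def ring_oracle(vessel_mat):
    """Independent incompressible 1D inflation oracle for the same ring."""
    return bm.ring_inflation(vessel_mat, RING_RI, RING_RO, RING_PRESSURE_KPA)


def midwall_hoop_stress(solution, r_mid=0.5 * (RING_RI + RING_RO),
                        band=0.35):
    """Hoop Cauchy stress at reference radius ``r_mid`` by a linear fit
    over nearby element values (removes the element-centroid offset bias)."""
    mesh = solution.mesh
    cen = mesh.element_centroids()
    rc = np.linalg.norm(cen, axis=1)
    mask = np.abs(rc - r_mid) < band
    th = np.arctan2(cen[mask, 1], cen[mask, 0])
    tv = np.column_stack([-np.sin(th), np.cos(th)])
    hoop = np.einsum("ei,eij,ej->e", tv, solution.cauchy[mask][:, :2, :2], tv)
    A = np.vstack([np.ones(mask.sum()), rc[mask] - r_mid]).T
    return float(np.linalg.lstsq(A, hoop, rcond=None)[0][0])
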