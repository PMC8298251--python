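"""Desk-scale wall-shear-stress surrogate: fully developed axial flow.

The full problem couples 3D unsteady Navier--Stokes blood flow to the
deforming wall.  This module replaces it -- deliberately and visibly -- by
the classical fully-developed laminar flow on each cross-section: the axial
velocity ``w(x, y)`` solves

    -mu * laplacian(w) = G     in the lumen,      w = 0 on the wall,

where ``G`` is the axial pressure gradient, chosen so the section carries a
prescribed flow rate Q (the default drive, so geometric effects are
isolated when comparing model variants).  Wall shear stress is
``FSS = mu |dw/dn|`` on the lumen boundary, evaluated by the variationally
consistent boundary flux (superconvergent) and reported at the same 100
arc-length-uniform lumen points used for PWS/PWSn.  Every output is stamped
``surrogate: fully-developed``.

Units: the lumen polygon arrives in mm and is converted to cm; viscosity in
Poise (dyn*s/cm^2, default 0.04 -- typical blood), Q in mL/s, G in
dyn/cm^3, velocities cm/s, FSS dyn/cm^2.

The one-way coupled variant (structure solve, then flow on the deformed
lumen) stands in for FSI; the flow-only variant runs on the undeformed
imaged lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from shapely.geometry import Polygon

from . import constitutive as ct
from . import fem_solid as fem
from .preconditioning import ShrinkResult
from .synthetic_cohort import SliceContours
from .units import MM_TO_CM

__all__ = [
    "FlowConfig",
    "FlowSolution",
    "solve_axial_flow",
    "fss_summary",
    "coupled_fss",
    "flow_mesh_convergence",
    "SURROGATE_STAMP",
]

SURROGATE_STAMP = "surrogate: fully-developed"


@dataclass(frozen=True)
class FlowConfig:
    """Flow drive and discretization.  Exactly one of ``flow_rate_ml_s``
    (default 1.0, a typical mean coronary flow) or ``pressure_gradient``
    (dyn/cm^3) must be set."""

    viscosity_poise: float = 0.04
    flow_rate_ml_s: float | None = 1.0
    pressure_gradient: float | None = None
    mesh_h_mm: float = 0.12

    def __post_init__(self):
        if self.viscosity_poise <= 0:
            raise ValueError("viscosity must be positive")
        if (self.flow_rate_ml_s is None) == (self.pressure_gradient is None):
            raise ValueError("specify exactly one of flow_rate_ml_s and "
                             "pressure_gradient")
        if self.mesh_h_mm <= 0:
            raise ValueError("mesh_h_mm must be positive")


@dataclass
class FlowSolution:
    """Fully developed flow on one lumen cross-section (cm / cm/s units).

    ``wall_shear`` holds FSS at the ``n_points`` arc-length-uniform lumen
    points (dyn/cm^2, CCW from the +x reference ray); summary values are
    taken over those points.
    """

    nodes: np.ndarray                # (n, 2) cm
    velocity: np.ndarray             # (n,) cm/s
    boundary_loop: np.ndarray        # ordered node ids, CCW
    boundary_shear: np.ndarray       # FSS at boundary nodes, dyn/cm^2
    wall_shear: np.ndarray           # FSS at sample points, dyn/cm^2
    sample_points: np.ndarray        # (n_points, 2) cm
    flow_rate: float                 # mL/s, integrated
    pressure_gradient: float         # dyn/cm^3
    max_fss: float
    min_fss: float
    ave_fss: float
    meta: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# Disk meshing (rays from the centroid, rings to the boundary)
# ----------------------------------------------------------------------

def _disk_mesh(polygon_mm: np.ndarray, h_mm: float):
    """Structured P2 disk mesh of a star-shaped lumen polygon (cm units).

    Returns (nodes, elements(m,6), boundary_vertices, boundary_loop,
    boundary_edges) with the boundary resampled at ray angles.
    """
    poly = Polygon(polygon_mm)
    if poly.area <= 0 or not poly.is_valid:
        raise fem.MeshingError("degenerate lumen polygon", "lumen")
    cen = np.asarray(poly.centroid.coords[0])
    n_theta = max(40, int(round(poly.exterior.length / h_mm)))
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    from .synthetic_cohort import _ray_crossing
    r_b = np.empty(n_theta)
    for j, t in enumerate(theta):
        hits = _ray_crossing(cen, np.array([np.cos(t), np.sin(t)]), polygon_mm)
        if not hits:
            raise fem.MeshingError("lumen not star-shaped about centroid",
                                   "lumen")
        r_b[j] = hits[-1]
    n_r = max(3, int(round(np.mean(r_b) / h_mm)))

    # node ids: 0 = center; ring i (1..n_r) has n_theta nodes
    nodes = [cen[None, :]]
    for i in range(1, n_r + 1):
        r = r_b * (i / n_r)
        nodes.append(np.column_stack([cen[0] + r * np.cos(theta),
                                      cen[1] + r * np.sin(theta)]))
    nodes = np.vstack(nodes)

    def nid(i, j):
        return 0 if i == 0 else 1 + (i - 1) * n_theta + (j % n_theta)

    tris = []
    for j in range(n_theta):
        tris.append((0, nid(1, j), nid(1, j + 1)))
    for i in range(1, n_r):
        for j in range(n_theta):
            a, b = nid(i, j), nid(i, j + 1)          # inner ring
            c, d = nid(i + 1, j + 1), nid(i + 1, j)  # outer ring
            tris += [(a, d, c), (a, c, b)]           # CCW
    elements = np.array(tris, dtype=np.int64)
    boundary_vertices = np.array([nid(n_r, j) for j in range(n_theta)])

    elements, nodes, loop, _loop2, edges = fem._to_quadratic(
        elements, nodes, boundary_vertices, boundary_vertices)
    return nodes * MM_TO_CM, elements, loop, edges


# ----------------------------------------------------------------------
# Poisson solve and consistent boundary flux
# ----------------------------------------------------------------------

def solve_axial_flow(lumen_polygon_mm: np.ndarray, config: FlowConfig,
                     n_points: int = 100) -> FlowSolution:
    """Fully developed axial flow on one cross-section.

    Solves the Poisson problem with unit pressure gradient, scales to the
    requested drive (the problem is linear), extracts the wall shear by the
    consistent boundary-flux method and resamples it at ``n_points``
    arc-length-uniform boundary points starting at the +x reference ray.
    """
    nodes, elements, loop, edges = _disk_mesh(lumen_polygon_mm,
                                              config.mesh_h_mm)
    mu = config.viscosity_poise
    qp, qw = fem._tri_quadrature(2)
    N, dNxi = fem._tri_shape(2, qp)
    v = nodes[elements[:, :3]]
    J = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]], axis=2)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    if np.any(detJ <= 0):
        raise fem.MeshingError("inverted element in lumen mesh", "lumen")
    Jinv = np.empty_like(J)
    Jinv[:, 0, 0] = J[:, 1, 1] / detJ
    Jinv[:, 1, 1] = J[:, 0, 0] / detJ
    Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
    Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
    dNdX = np.einsum("qni,mij->mqnj", dNxi, Jinv)
    wdet = 0.5 * np.abs(detJ)[:, None] * qw[None, :]

    ke = mu * np.einsum("mq,mqaj,mqbj->mab", wdet, dNdX, dNdX)
    nn = nodes.shape[0]
    rows = np.repeat(elements, 6, axis=1).ravel()
    cols = np.tile(elements, (1, 6)).ravel()
    K = coo_matrix((ke.ravel(), (rows, cols)), shape=(nn, nn)).tocsr()
    fe = np.einsum("mq,qa->ma", wdet, N)       # unit source
    f = np.bincount(elements.ravel(), weights=fe.ravel(), minlength=nn)

    free = np.ones(nn, dtype=bool)
    free[loop] = False
    w = np.zeros(nn)
    w[free] = spsolve(K[free][:, free], f[free])

    # integrate the flow for G = 1
    we = w[elements]
    q1 = float(np.einsum("mq,qa,ma->", wdet, N, we))
    if config.flow_rate_ml_s is not None:
        scale = config.flow_rate_ml_s / q1
        G = scale                      # dyn/cm^3, since solved with G = 1
    else:
        G = config.pressure_gradient
        scale = G
    w *= scale
    Q = q1 * scale

    # consistent boundary flux: (K w - f)_a = cint mu dw/dn N_a ds
    # Consistent boundary flux, extracted per edge: the nodal reactions
    # R_a = (K w - f)_a represent cint mu dw/dn N_a ds, but their pointwise
    # vertex/midside split is an O(1) discrete artifact; only functionals
    # against smooth tests are superconvergent.  Lumping each boundary
    # edge's total reaction (half of each endpoint vertex + its midside)
    # over the edge length yields an exactly conservative, O(h^2)
    # edge-average flux at the edge midpoint.
    R_nodal = np.zeros(nn)
    R_nodal[loop] = (K @ w - G * f)[loop]
    x_e = nodes[edges]                                 # (e, 3, 2): v0, m, v1
    len_e = (np.linalg.norm(x_e[:, 1] - x_e[:, 0], axis=1)
             + np.linalg.norm(x_e[:, 2] - x_e[:, 1], axis=1))
    R_edge = (0.5 * R_nodal[edges[:, 0]] + R_nodal[edges[:, 1]]
              + 0.5 * R_nodal[edges[:, 2]])
    fss_edge = np.abs(R_edge) / len_e                  # at edge midpoints

    # loop-aligned nodal field: midside nodes carry their edge's flux,
    # vertices the mean of their two adjacent edges
    ne = len(edges)
    fss_nodes = np.empty(2 * ne)
    fss_nodes[1::2] = fss_edge
    fss_nodes[0::2] = 0.5 * (fss_edge + np.roll(fss_edge, 1))

    pts, fss = _resample_boundary(nodes, loop, fss_nodes, n_points)
    mx, mn, av = fss_summary(fss)
    return FlowSolution(nodes=nodes, velocity=w, boundary_loop=loop,
                        boundary_shear=fss_nodes, wall_shear=fss,
                        sample_points=pts, flow_rate=Q, pressure_gradient=G,
                        max_fss=mx, min_fss=mn, ave_fss=av,
                        meta={"stamp": SURROGATE_STAMP,
                              "viscosity_poise": mu})


def _resample_boundary(nodes, loop, values, n):
    """Arc-length-uniform resampling starting at the +x ray (as the solid
    sampler does), linear along the boundary polyline."""
    xs = nodes[loop]
    cen = np.asarray(Polygon(xs).centroid.coords[0])
    ang = np.arctan2(xs[:, 1] - cen[1], xs[:, 0] - cen[0])
    npts = len(xs)
    start_seg, start_t = 0, 0.0
    for i in range(npts):
        a0, a1 = ang[i], ang[(i + 1) % npts]
        d = a1 - a0
        if d <= -np.pi:
            d += 2 * np.pi
        if a0 <= 0.0 < a0 + d and d > 0 and abs(d) < np.pi:
            start_seg, start_t = i, -a0 / d
            break
    seglen = np.linalg.norm(np.roll(xs, -1, axis=0) - xs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    L = cum[-1]
    s0 = cum[start_seg] + start_t * seglen[start_seg]
    s = (s0 + np.arange(n) * L / n) % L
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, npts - 1)
    t = (s - cum[idx]) / np.maximum(seglen[idx], 1e-14)
    nxt = (idx + 1) % npts
    pts = xs[idx] * (1 - t)[:, None] + xs[nxt] * t[:, None]
    vals = values[idx] * (1 - t) + values[nxt] * t   # values loop-aligned
    return pts, vals


def fss_summary(fss) -> tuple[float, float, float]:
    """(max, min, arithmetic mean) over the lumen points."""
    fss = np.asarray(fss, dtype=float)
    if fss.size == 0:
        raise ValueError("empty FSS field")
    return float(fss.max()), float(fss.min()), float(fss.mean())


def coupled_fss(sl: SliceContours, materials: dict[str, ct.MaterialParams],
                pressure_kpa: float, shrink: ShrinkResult,
                flow_config: FlowConfig, config: fem.SolveConfig | None = None,
                h: float = 0.25, n_points: int = 100) -> fem.LumenProfile:
    """Sequential structure-then-flow surrogate for FSI.

    Structural solve on the shrink-preconditioned geometry at the given
    pressure, then fully developed flow on the *deformed* lumen; FSS is
    written into the LumenProfile alongside PWS/PWSn (``sl`` is only used
    for provenance; the reference geometry is ``shrink.shrunk_slice``).
    """
    cfg = config or fem.SolveConfig(pressure=pressure_kpa)
    if cfg.pressure != pressure_kpa:
        cfg = fem.SolveConfig(pressure=pressure_kpa, load_steps=cfg.load_steps,
                              newton_tol=cfg.newton_tol,
                              max_newton_iters=cfg.max_newton_iters,
                              axial_stretch=cfg.axial_stretch,
                              variant=cfg.variant)
    mesh = fem.build_mesh(shrink.shrunk_slice, h)
    sol = fem.solve_static(mesh, materials, cfg)
    profile = fem.sample_lumen(sol, n=n_points)
    deformed = fem.deformed_lumen_polygon(sol)
    flow = solve_axial_flow(deformed, flow_config, n_points=n_points)
    profile.FSS = flow.wall_shear
    profile.meta.update({"flow": "coupled", "stamp": SURROGATE_STAMP,
                         "flow_rate_ml_s": flow.flow_rate,
                         "shrink_ratio": shrink.circ_shrink_ratio})
    return profile


def flow_mesh_convergence(lumen_polygon_mm, config: FlowConfig,
                          max_refinements: int = 12, rel_tol: float = 0.01):
    """10%-refinement mesh study on the FSS summaries; Min-FSS is tracked
    separately as the most sensitive summary.  Returns (solution, table)."""
    import pandas as pd
    h = config.mesh_h_mm
    rows, prev = [], None
    flow = None
    for k in range(max_refinements + 1):
        cfg = FlowConfig(viscosity_poise=config.viscosity_poise,
                         flow_rate_ml_s=config.flow_rate_ml_s,
                         pressure_gradient=config.pressure_gradient,
                         mesh_h_mm=h)
        flow = solve_axial_flow(lumen_polygon_mm, cfg)
        cur = np.array([flow.max_fss, flow.min_fss, flow.ave_fss])
        change = (np.abs(cur - prev) / np.abs(prev)).max() if prev is not None \
            else np.nan
        rows.append({"step": k, "h_mm": h, "max_fss": cur[0],
                     "min_fss": cur[1], "ave_fss": cur[2],
                     "rel_change": change})
        if prev is not None and change < rel_tol:
            return flow, pd.DataFrame(rows)
        prev = cur
        h /= 1.1
    raise RuntimeError("flow mesh independence not reached:\n"
                       + pd.DataFrame(rows).to_string(index=False))
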