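"""Zero-load geometry recovery: circumferential pre-shrink + axial shrink.

An in vivo IVUS cross-section is imaged under pressure, so using it
directly as a stress-free reference overestimates stress.  The shrink-
stretch construction recovers a no-load surrogate geometry (opening-angle
residual stress excluded):

* axial: the vessel is shortened by a fixed 10%; the solver later imposes
  the inverse stretch ``lambda_z = 1/0.9``.  Wall cross-sectional area is
  scaled by ``1/0.9`` so tissue volume is conserved.
* circumferential: a uniform per-slice shrink ratio ``k`` scales the lumen
  about its centroid (the outer contour follows by wall-area conservation;
  inclusions by radial-fraction mapping).  ``k`` is found by bisection so
  that re-pressurizing the shrunk slice at the imaging pressure recovers
  the in vivo lumen area within a relative tolerance (default 0.5%).  Each
  trial is a full FEM solve, which is why robust bisection is preferred
  over a faster root-finder.

The imaging pressure (acquisition pressure) is not generally known; the
package defaults it to the diastolic minimum and records it in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from . import constitutive as ct
from . import fem_solid as fem
from .synthetic_cohort import LUMEN, OUTER, SliceContours, VesselSpec

__all__ = [
    "ShrinkResult",
    "ShrinkBracketError",
    "shrink_slice",
    "find_circ_shrink",
    "apply_axial_shrink",
    "AXIAL_SHRINK",
]

AXIAL_SHRINK = 0.10


class ShrinkBracketError(RuntimeError):
    """No shrink ratio in the bracket reproduces the in vivo lumen area;
    carries the achieved interval."""

    def __init__(self, msg, interval):
        super().__init__(msg)
        self.interval = interval


@dataclass
class ShrinkResult:
    """Outcome of the circumferential pre-shrink root-find."""

    circ_shrink_ratio: float
    axial_shrink: float
    shrunk_slice: SliceContours
    iterations: int
    achieved_area_error: float          # relative, vs the in vivo lumen area
    target_lumen_area: float
    pressurized_lumen_area: float
    contour_distance: float = float("nan")   # Hausdorff diagnostic, mm

    def to_json_dict(self) -> dict:
        return {
            "circ_shrink_ratio": self.circ_shrink_ratio,
            "axial_shrink": self.axial_shrink,
            "iterations": self.iterations,
            "achieved_area_error": self.achieved_area_error,
            "contour_distance_mm": self.contour_distance,
        }


def shrink_slice(sl: SliceContours, k: float) -> SliceContours:
    """Scale the lumen by ``k`` about its centroid, conserving wall area.

    The outer contour is rescaled about the same centroid so that the wall
    (outer minus lumen) area is unchanged; inclusion contours follow by
    mapping their radial fraction between the old and new lumen/outer
    boundaries, which preserves nesting by construction.
    """
    if not 0 < k <= 1.0:
        raise ValueError("shrink ratio must be in (0, 1]")
    if k == 1.0:
        return sl
    lumen_poly = sl.polygon(LUMEN)
    cen = np.asarray(lumen_poly.centroid.coords[0])
    a_lum, a_out = sl.lumen_area, sl.wall_area
    a_wall = a_out - a_lum
    s = np.sqrt((k**2 * a_lum + a_wall) / a_out)   # outer scale factor

    def scale(pts, f):
        return cen + f * (np.asarray(pts) - cen)

    new = {LUMEN: scale(sl.contours[LUMEN], k),
           OUTER: scale(sl.contours[OUTER], s)}

    # radial-fraction remap for inclusions
    from .synthetic_cohort import _ray_crossing
    for region, pts in sl.contours.items():
        if region in (LUMEN, OUTER):
            continue
        out = np.empty_like(np.asarray(pts, dtype=float))
        for i, p in enumerate(np.asarray(pts, dtype=float)):
            v = p - cen
            r = np.linalg.norm(v)
            d = v / r
            rl = _ray_crossing(cen, d, sl.contours[LUMEN])[-1]
            ro = _ray_crossing(cen, d, sl.contours[OUTER])[-1]
            t = np.clip((r - rl) / (ro - rl), 0.0, 1.0)
            out[i] = cen + (k * rl + t * (s * ro - k * rl)) * d
        new[region] = out
    return SliceContours(sl.slice_id, sl.axial_position, new)


def _pressurized_area(sl: SliceContours, materials, pressure_kpa: float,
                      config: fem.SolveConfig, h: float):
    mesh = fem.build_mesh(sl, h)
    sol = fem.solve_static(mesh, materials, config)
    return fem.deformed_lumen_area(sol), sol


def find_circ_shrink(sl: SliceContours, materials: dict[str, ct.MaterialParams],
                     imaging_pressure_kpa: float,
                     config: fem.SolveConfig | None = None,
                     h: float = 0.25, tol: float = 0.005,
                     bracket: tuple[float, float] = (0.7, 1.0),
                     target_lumen_area: float | None = None,
                     max_iterations: int = 40) -> ShrinkResult:
    """Bisection on the circumferential shrink ratio.

    Finds ``k`` such that the slice shrunk by ``k`` and re-pressurized at
    the imaging pressure recovers ``target_lumen_area`` (default: the
    slice's own in vivo lumen area) within relative ``tol``.  For the
    thin-layer pipeline pass the axially pre-shrunk slice together with a
    ``thin_layer`` config and the *original* in vivo lumen area.
    """
    if imaging_pressure_kpa < 0:
        raise ValueError("imaging pressure must be >= 0")
    cfg = config or fem.SolveConfig(pressure=imaging_pressure_kpa)
    if cfg.pressure != imaging_pressure_kpa:
        cfg = fem.SolveConfig(pressure=imaging_pressure_kpa,
                              load_steps=cfg.load_steps,
                              newton_tol=cfg.newton_tol,
                              max_newton_iters=cfg.max_newton_iters,
                              axial_stretch=cfg.axial_stretch,
                              variant=cfg.variant)
    target = sl.lumen_area if target_lumen_area is None else target_lumen_area

    if imaging_pressure_kpa == 0.0:
        return ShrinkResult(1.0, _axial_of(cfg), sl, 0, 0.0, target,
                            sl.lumen_area, 0.0)

    def area_err(k):
        shrunk = shrink_slice(sl, k)
        try:
            area, sol = _pressurized_area(shrunk, materials,
                                          imaging_pressure_kpa, cfg, h)
        except (fem.NewtonDivergenceError, ct.ConstitutiveRangeError):
            # the solver failing to re-inflate a strongly shrunk slice means
            # the target area is unreachable at this k: treat as undershoot
            return -np.inf, shrunk, None
        return (area - target) / target, shrunk, sol

    lo, hi = bracket
    g_hi, slice_hi, sol_hi = area_err(hi)
    if not np.isfinite(g_hi):
        raise ShrinkBracketError(
            f"solver failure at the unshrunk end of the bracket (k={hi})",
            (lo, hi))
    if g_hi < -tol:
        raise ShrinkBracketError(
            f"pressurization at k={hi} does not reach the in vivo area "
            f"(relative error {g_hi:.3%}); material too soft for bracket",
            (lo, hi))
    if abs(g_hi) <= tol:
        best = (hi, g_hi, slice_hi, sol_hi)
        iters = 1
    else:
        g_lo, slice_lo, sol_lo = area_err(lo)
        if g_lo > 0:
            raise ShrinkBracketError(
                f"no sign change in bracket [{lo}, {hi}]: error at {lo} is "
                f"{g_lo:+.3%}; material too stiff for bracket", (lo, hi))
        best = (hi, g_hi, slice_hi, sol_hi) if abs(g_hi) < abs(g_lo) \
            else (lo, g_lo, slice_lo, sol_lo)
        iters = 2
        while iters < max_iterations:
            mid = 0.5 * (lo + hi)
            g_mid, slice_mid, sol_mid = area_err(mid)
            iters += 1
            if abs(g_mid) < abs(best[1]):
                best = (mid, g_mid, slice_mid, sol_mid)
            if abs(g_mid) <= tol:
                break
            if g_mid > 0:
                hi = mid
            else:
                lo = mid
        else:
            raise ShrinkBracketError(
                f"bisection did not reach tol={tol} in {max_iterations} "
                f"iterations (best error {best[1]:.3%})", (lo, hi))

    k, g, shrunk, sol = best
    # contour-shape diagnostic: Hausdorff distance between the
    # re-pressurized lumen and the in vivo lumen contour
    dist = Polygon(fem.deformed_lumen_polygon(sol)).hausdorff_distance(
        sl.polygon(LUMEN))
    return ShrinkResult(circ_shrink_ratio=k, axial_shrink=_axial_of(cfg),
                        shrunk_slice=shrunk, iterations=iters,
                        achieved_area_error=abs(g), target_lumen_area=target,
                        pressurized_lumen_area=(1 + g) * target,
                        contour_distance=float(dist))


def _axial_of(cfg: fem.SolveConfig) -> float:
    return AXIAL_SHRINK if cfg.variant == fem.THIN_LAYER else 0.0


def apply_axial_shrink(vessel: VesselSpec) -> tuple[VesselSpec, float]:
    """Shorten the vessel axially by 10%, conserving tissue volume.

    Axial positions scale by 0.9 and in-plane coordinates by
    ``1/sqrt(0.9)`` (each slice about its lumen centroid), so per-slice
    wall areas scale by ``1/0.9``.  Returns the shrunk vessel and the
    stretch ``1/0.9`` the solver must apply to recover the in vivo length.
    """
    f = 1.0 / np.sqrt(1.0 - AXIAL_SHRINK)
    new_slices = []
    for sl in vessel.slices:
        cen = np.asarray(sl.polygon(LUMEN).centroid.coords[0])
        shrunk = sl.transformed(lambda pts: cen + f * (np.asarray(pts) - cen))
        shrunk.axial_position = sl.axial_position * (1.0 - AXIAL_SHRINK)
        new_slices.append(shrunk)
    out = VesselSpec(vessel.patient_id, new_slices,
                     vessel.slice_spacing * (1.0 - AXIAL_SHRINK),
                     vessel.pressure_range, vessel.imaging_pressure)
    return out, 1.0 / (1.0 - AXIAL_SHRINK)
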