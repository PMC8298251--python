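"""Seeded generator for VH-IVUS-like segmented plaque cross-sections.

Real inputs to this kind of analysis are segmented intravascular-ultrasound
contours: an eccentric lumen inside an outer-wall ring, optionally with a
lipid-rich necrotic core behind a thin fibrous cap and/or a calcification.
No such data are publicly deposited, so this module emulates them: it draws
smooth, strictly nested, counterclockwise polygons (dense polylines, the
form IVUS segmentations take), stacks them into multi-slice vessels with
per-patient diastolic/systolic pressure ranges, and computes the standard
cross-sectional severity metrics (stenosis, plaque burden).

Construction notes
------------------
* The lumen is an area-preserving ellipse, offset from the vessel axis by
  the eccentricity parameter, perturbed by a band-limited (low-harmonic)
  radial noise so polygons stay simple.
* The lipid core sits on the thick-wall side.  Its inner boundary is the
  lumen offset outward by exactly ``cap_thickness`` (a true Euclidean
  offset), so the minimum lumen-to-lipid distance equals the cap thickness
  by construction; its thickness tapers smoothly to zero at the arc ends.
* A calcification, when requested, is a mid-wall band on a disjoint arc.

Everything is a pure function of its spec and seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "SliceSpec",
    "SliceContours",
    "VesselSpec",
    "Morphology",
    "CohortConfig",
    "InfeasibleSpecError",
    "generate_slice",
    "generate_cohort",
    "stenosis",
    "plaque_burden",
    "morphology",
    "shoelace_area",
    "validate_slice",
    "write_vessel_csv",
    "read_vessel_csv",
]

LUMEN, OUTER, LIPID, CALC = "lumen", "outer", "lipid", "calc"
_REGIONS = (LUMEN, OUTER, LIPID, CALC)


class InfeasibleSpecError(ValueError):
    """The requested morphology cannot be realized (e.g. cap + lipid do not
    fit inside the wall)."""


@dataclass(frozen=True)
class SliceSpec:
    """Parameters of one synthetic cross-section.  Lengths in mm, arcs in
    degrees; ``lumen_eccentricity`` in [0, 1) controls both the lumen
    center offset and its elliptical aspect."""

    lumen_radius: float = 1.5
    lumen_eccentricity: float = 0.0
    wall_thickness: float = 1.0
    lipid_arc: float = 0.0
    lipid_thickness: float = 0.0
    cap_thickness: float = 0.0
    calc_present: bool = False
    calc_arc: float = 45.0
    calc_thickness: float = 0.25
    noise_amplitude: float = 0.0
    n_points: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.lumen_radius <= 0 or self.wall_thickness <= 0:
            raise InfeasibleSpecError("lumen_radius and wall_thickness must be > 0")
        if not (0 <= self.lumen_eccentricity < 1):
            raise InfeasibleSpecError("lumen_eccentricity must be in [0, 1)")
        if not (0 <= self.lipid_arc < 360) or not (0 <= self.calc_arc < 360):
            raise InfeasibleSpecError("arcs must be in [0, 360) degrees")
        if self.lipid_arc > 0:
            if self.cap_thickness <= 0 or self.lipid_thickness <= 0:
                raise InfeasibleSpecError(
                    "cap_thickness and lipid_thickness must be > 0 when a lipid "
                    "core is requested")
        if not (64 <= self.n_points <= 256):
            raise InfeasibleSpecError("n_points must be in [64, 256]")

    @property
    def has_lipid(self) -> bool:
        return self.lipid_arc > 0


@dataclass
class SliceContours:
    """Segmented cross-section: ordered CCW polygons per region (mm).

    ``contours`` maps region labels (lumen / outer / lipid / calc) to
    (n, 2) point arrays; rings are stored unclosed (last point joins back
    to the first).
    """

    slice_id: int
    axial_position: float
    contours: dict[str, np.ndarray]

    def polygon(self, region: str) -> Polygon:
        return Polygon(self.contours[region])

    def area(self, region: str) -> float:
        return shoelace_area(self.contours[region])

    @property
    def lumen_area(self) -> float:
        return self.area(LUMEN)

    @property
    def wall_area(self) -> float:
        return self.area(OUTER)

    def transformed(self, fn) -> "SliceContours":
        """New slice with ``fn((n,2) array) -> (n,2) array`` applied to all
        contours."""
        return SliceContours(self.slice_id, self.axial_position,
                             {k: np.asarray(fn(v), dtype=float)
                              for k, v in self.contours.items()})


@dataclass
class VesselSpec:
    """A stacked multi-slice vessel with its pressure conditions (mmHg)."""

    patient_id: str
    slices: list[SliceContours]
    slice_spacing: float = 0.5
    pressure_range: tuple[float, float] = (70.0, 125.0)
    imaging_pressure: float | None = None

    def __post_init__(self):
        if len(self.slices) < 2:
            raise ValueError("a vessel needs at least 2 slices")
        pmin, pmax = self.pressure_range
        if not pmin < pmax:
            raise ValueError("pressure_range must satisfy P_min < P_max")
        if self.imaging_pressure is None:
            # imaging pressure (the pressure at acquisition) defaults to the
            # diastolic minimum; this choice is surfaced in all reports.
            self.imaging_pressure = pmin
        if not pmin <= self.imaging_pressure <= pmax:
            raise ValueError("imaging_pressure must lie within pressure_range")

    @property
    def length(self) -> float:
        return self.slices[-1].axial_position - self.slices[0].axial_position


@dataclass(frozen=True)
class Morphology:
    stenosis_pct: float
    plaque_burden_pct: float
    lumen_area: float
    wall_area: float


# ----------------------------------------------------------------------
# Geometry helpers
# ----------------------------------------------------------------------

def shoelace_area(points: np.ndarray) -> float:
    """Unsigned polygon area by the shoelace formula (ring unclosed)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _signed_area(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def _band_limited_noise(theta: np.ndarray, amplitude: float,
                        rng: np.random.Generator,
                        harmonics=(2, 3, 4, 5)) -> np.ndarray:
    """Smooth periodic radial perturbation with unit-free output in mm.

    A few low harmonics with random phases; the summed amplitude is scaled
    to ``amplitude`` so polygons remain simple for any draw.
    """
    amps = rng.uniform(0.3, 1.0, size=len(harmonics))
    phases = rng.uniform(0, 2 * np.pi, size=len(harmonics))
    amps *= amplitude / np.sum(amps)
    out = np.zeros_like(theta)
    for a, k, ph in zip(amps, harmonics, phases):
        out += a * np.cos(k * theta + ph)
    return out


def _ray_crossing(origin: np.ndarray, direction: np.ndarray,
                  ring: np.ndarray) -> list[float]:
    """Distances from origin at which the ray crosses the (unclosed) ring."""
    line = LineString([origin, origin + direction * 1e3])
    inter = line.intersection(Polygon(ring).exterior)
    if inter.is_empty:
        return []
    pts = []
    if inter.geom_type == "Point":
        pts = [inter]
    elif inter.geom_type == "MultiPoint":
        pts = list(inter.geoms)
    else:  # rare grazing contact
        pts = [Point(c) for g in getattr(inter, "geoms", [inter])
               for c in g.coords]
    o = Point(origin)
    return sorted(p.distance(o) for p in pts)


# ----------------------------------------------------------------------
# Slice generation
# ----------------------------------------------------------------------

def generate_slice(spec: SliceSpec, slice_id: int = 0,
                   axial_position: float = 0.0) -> SliceContours:
    """Generate one nested-contour cross-section from its spec.

    Deterministic: identical specs (seed included) give bit-identical
    point lists.  Raises :class:`InfeasibleSpecError` when the requested
    components do not fit inside the wall.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_points
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)

    ecc = spec.lumen_eccentricity
    # area-preserving elliptical aspect + center offset toward +x; the wall
    # is then thinnest near theta = 0 and thickest near theta = pi, where
    # the plaque is placed.
    q = 1.0 - 0.4 * ecc
    a, b = spec.lumen_radius / np.sqrt(q), spec.lumen_radius * np.sqrt(q)
    offset = 0.4 * ecc * spec.wall_thickness
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    r_lum = r_ell + _band_limited_noise(theta, spec.noise_amplitude, rng)
    if np.any(r_lum <= 0.05 * spec.lumen_radius):
        raise InfeasibleSpecError("noise_amplitude too large for lumen radius")
    lumen = np.column_stack([offset + r_lum * np.cos(theta),
                             r_lum * np.sin(theta)])

    r_out0 = spec.lumen_radius + spec.wall_thickness
    r_out = r_out0 + _band_limited_noise(theta, 0.5 * spec.noise_amplitude, rng)
    outer = np.column_stack([r_out * np.cos(theta), r_out * np.sin(theta)])

    lumen_poly = Polygon(lumen)
    outer_poly = Polygon(outer)
    min_wall = lumen_poly.exterior.distance(outer_poly.exterior)
    if not outer_poly.contains(lumen_poly) or min_wall < 0.05:
        raise InfeasibleSpecError(
            f"lumen not strictly inside outer wall (min gap {min_wall:.3g} mm); "
            "reduce eccentricity or noise, or thicken the wall")

    contours: dict[str, np.ndarray] = {LUMEN: lumen, OUTER: outer}

    if spec.has_lipid:
        contours[LIPID] = _inclusion_band(
            spec, lumen_poly, outer_poly, center_deg=180.0,
            arc_deg=spec.lipid_arc, inner_gap=spec.cap_thickness,
            thickness=spec.lipid_thickness, label=LIPID)
    if spec.calc_present:
        if spec.has_lipid and (spec.lipid_arc + spec.calc_arc) / 2 + 20 > 120:
            if spec.lipid_arc / 2 + spec.calc_arc / 2 > 160:
                raise InfeasibleSpecError("lipid and calcification arcs overlap")
        # mid-wall band, rotated away from the lipid arc
        center = 180.0 + spec.lipid_arc / 2 + spec.calc_arc / 2 + 25.0 \
            if spec.has_lipid else 180.0
        gap = 0.45 * spec.wall_thickness - spec.calc_thickness / 2
        contours[CALC] = _inclusion_band(
            spec, lumen_poly, outer_poly, center_deg=center,
            arc_deg=spec.calc_arc, inner_gap=max(gap, 0.1),
            thickness=spec.calc_thickness, label=CALC)

    sl = SliceContours(slice_id, axial_position, contours)
    validate_slice(sl)
    return sl


def _inclusion_band(spec: SliceSpec, lumen_poly: Polygon, outer_poly: Polygon,
                    center_deg: float, arc_deg: float, inner_gap: float,
                    thickness: float, label: str) -> np.ndarray:
    """Closed band between the lumen offset (by ``inner_gap``) and an outer
    curve ``thickness`` further out, tapered to zero at the arc ends."""
    cen = np.asarray(lumen_poly.centroid.coords[0])
    inner_curve = lumen_poly.buffer(inner_gap, quad_segs=32).exterior
    m = max(24, int(spec.n_points * arc_deg / 360.0))
    th = np.radians(center_deg) + np.radians(arc_deg) * \
        (np.linspace(0.0, 1.0, m) - 0.5)
    u = np.linspace(0.0, 1.0, m)
    taper = np.sin(np.pi * u)

    r_in = np.empty(m)
    r_wall = np.empty(m)
    for i, t in enumerate(th):
        d = np.array([np.cos(t), np.sin(t)])
        hits_in = _ray_crossing(cen, d, np.asarray(inner_curve.coords)[:-1])
        hits_out = _ray_crossing(cen, d, np.asarray(outer_poly.exterior.coords)[:-1])
        if not hits_in or not hits_out:
            raise InfeasibleSpecError(f"{label}: geometry not star-shaped about "
                                      "the lumen centroid")
        r_in[i] = hits_in[-1]
        r_wall[i] = hits_out[-1]
    r_out = r_in + thickness * taper
    margin = 0.05 * spec.wall_thickness
    if np.any(r_out > r_wall - margin):
        raise InfeasibleSpecError(
            f"{label} does not fit: inner gap {inner_gap:.3g} + thickness "
            f"{thickness:.3g} reaches the outer wall")
    fwd = np.column_stack([cen[0] + r_out * np.cos(th), r_out * np.sin(th) + cen[1]])
    bwd = np.column_stack([cen[0] + r_in * np.cos(th), r_in * np.sin(th) + cen[1]])[::-1]
    band = np.vstack([fwd[1:-1], bwd])  # drop zero-thickness duplicate tips
    if _signed_area(band) < 0:
        band = band[::-1]
    return band


def validate_slice(sl: SliceContours) -> None:
    """Check the contour invariants: simple, CCW, strictly nested."""
    for region, pts in sl.contours.items():
        if region not in _REGIONS:
            raise ValueError(f"unknown region label {region!r}")
        poly = Polygon(pts)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError(f"{region} polygon is not simple/valid")
        if _signed_area(pts) <= 0:
            raise ValueError(f"{region} polygon is not counterclockwise")
    lumen, outer = sl.polygon(LUMEN), sl.polygon(OUTER)
    if not outer.contains(lumen):
        raise ValueError("lumen is not strictly inside the outer wall")
    for region in (LIPID, CALC):
        if region in sl.contours:
            inc = sl.polygon(region)
            if not outer.contains(inc):
                raise ValueError(f"{region} is not inside the outer wall")
            if inc.intersects(lumen) and inc.intersection(lumen).area > 1e-12:
                raise ValueError(f"{region} overlaps the lumen")


# ----------------------------------------------------------------------
# Cohort generation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Distributions for the synthetic cohort.

    Every ``*_range`` is sampled uniformly; ``variability`` in [0, 1]
    scales all spreads about their midpoints (0 freezes the cohort at the
    midpoint morphology and removes slice-to-slice variation).  Pressure
    ranges bracket the values reported for real patients (diastolic 60-97,
    systolic 110-144 mmHg); morphology ranges give stenoses of roughly
    35-65% and plaque burdens of 55-80%, the severity band of a vulnerable-
    plaque cohort.
    """

    n_slices_range: tuple[int, int] = (2, 4)
    slice_spacing: float = 0.5
    p_min_range: tuple[float, float] = (60.0, 97.0)
    p_max_range: tuple[float, float] = (110.0, 144.0)
    lumen_radius_range: tuple[float, float] = (1.2, 1.8)
    eccentricity_range: tuple[float, float] = (0.2, 0.6)
    wall_thickness_range: tuple[float, float] = (0.8, 1.3)
    stenosis_depth_range: tuple[float, float] = (0.2, 0.45)
    lipid_probability: float = 0.7
    lipid_arc_range: tuple[float, float] = (60.0, 130.0)
    lipid_thickness_frac_range: tuple[float, float] = (0.3, 0.5)
    cap_thickness_range: tuple[float, float] = (0.08, 0.3)
    calc_probability: float = 0.25
    calc_arc_range: tuple[float, float] = (30.0, 60.0)
    noise_amplitude: float = 0.02
    n_points: int = 128
    variability: float = 1.0


def _draw(rng, rng_range, variability):
    lo, hi = rng_range
    mid = 0.5 * (lo + hi)
    return mid + (rng.uniform(lo, hi) - mid) * variability


def generate_cohort(n_patients: int, base_seed: int,
                    config: CohortConfig | None = None) -> list[VesselSpec]:
    """Draw a cohort of multi-slice vessels; pure function of its inputs."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cfg = config or CohortConfig()
    v = cfg.variability
    ss = np.random.SeedSequence(base_seed)
    vessels = []
    for ip, child in enumerate(ss.spawn(n_patients)):
        rng = np.random.default_rng(child)
        n_slices = int(round(_draw(rng, cfg.n_slices_range, v)))
        n_slices = max(2, n_slices)
        p_min = _draw(rng, cfg.p_min_range, v)
        p_max = _draw(rng, cfg.p_max_range, v)
        r_lum = _draw(rng, cfg.lumen_radius_range, v)
        ecc = _draw(rng, cfg.eccentricity_range, v)
        wall = _draw(rng, cfg.wall_thickness_range, v)
        depth = _draw(rng, cfg.stenosis_depth_range, v) * (1.0 if v > 0 else 0.0)
        has_lipid = rng.uniform() < cfg.lipid_probability
        lipid_arc = _draw(rng, cfg.lipid_arc_range, v) if has_lipid else 0.0
        lipid_frac = _draw(rng, cfg.lipid_thickness_frac_range, v)
        cap = _draw(rng, cfg.cap_thickness_range, v)
        has_calc = rng.uniform() < cfg.calc_probability
        calc_arc = _draw(rng, cfg.calc_arc_range, v)
        slice_seeds = rng.integers(0, 2**31 - 1, size=n_slices)

        slices = []
        for i in range(n_slices):
            # stenotic narrowing, absent at the inlet, deepest past mid-vessel
            g = np.sin(np.pi * i / n_slices) if i > 0 else 0.0
            spec = SliceSpec(
                lumen_radius=r_lum * (1.0 - depth * g),
                lumen_eccentricity=ecc,
                wall_thickness=wall * (1.0 + 0.5 * depth * g),
                lipid_arc=lipid_arc,
                lipid_thickness=lipid_frac * wall if has_lipid else 0.0,
                cap_thickness=cap if has_lipid else 0.0,
                calc_present=has_calc,
                calc_arc=calc_arc,
                calc_thickness=0.25 * wall,
                noise_amplitude=cfg.noise_amplitude * v,
                n_points=cfg.n_points,
                seed=int(slice_seeds[i] if v > 0 else slice_seeds[0]),
            )
            slices.append(generate_slice(spec, slice_id=i,
                                         axial_position=i * cfg.slice_spacing))
        vessels.append(VesselSpec(
            patient_id=f"P{ip + 1}",
            slices=slices,
            slice_spacing=cfg.slice_spacing,
            pressure_range=(p_min, p_max),
        ))
    return vessels


# ----------------------------------------------------------------------
# Morphology metrics
# ----------------------------------------------------------------------

def stenosis(vessel: VesselSpec) -> float:
    """Area stenosis in percent: (1 - min lumen area / inlet lumen area) x 100.

    The inlet is the first slice.  Areas by the shoelace formula.
    """
    areas = np.array([s.lumen_area for s in vessel.slices])
    if np.any(areas <= 0):
        raise ValueError("degenerate (zero-area) lumen")
    return float((1.0 - areas.min() / areas[0]) * 100.0)


def plaque_burden(sl: SliceContours) -> float:
    """Plaque burden in percent: (wall area - lumen area) / wall area x 100.

    'Wall area' is the area enclosed by the outer contour.
    """
    wall, lumen = sl.wall_area, sl.lumen_area
    if wall <= 0:
        raise ValueError("degenerate outer contour")
    if lumen > wall:
        raise ValueError("invalid nesting: lumen area exceeds wall area")
    return float((wall - lumen) / wall * 100.0)


def morphology(vessel: VesselSpec) -> Morphology:
    """Vessel-level severity summary (plaque burden at the minimal lumen)."""
    areas = [s.lumen_area for s in vessel.slices]
    worst = vessel.slices[int(np.argmin(areas))]
    return Morphology(
        stenosis_pct=stenosis(vessel),
        plaque_burden_pct=plaque_burden(worst),
        lumen_area=worst.lumen_area,
        wall_area=worst.wall_area,
    )


# ----------------------------------------------------------------------
# Contour CSV interface
# ----------------------------------------------------------------------

_CSV_COLUMNS = ["slice_id", "region", "point_index", "x_mm", "y_mm", "axial_mm"]


def write_vessel_csv(vessel: VesselSpec, path_or_buf) -> None:
    """One CSV per vessel: slice_id, region, point_index, x_mm, y_mm, axial_mm."""
    rows = []
    for sl in vessel.slices:
        for region, pts in sl.contours.items():
            for k, (x, y) in enumerate(pts):
                rows.append((sl.slice_id, region, k, x, y, sl.axial_position))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path_or_buf, index=False)


def read_vessel_csv(path_or_buf, patient_id: str = "P?",
                    pressure_range=(70.0, 125.0),
                    imaging_pressure: float | None = None,
                    slice_spacing: float | None = None) -> VesselSpec:
    """Read a contour CSV back into a :class:`VesselSpec`."""
    df = pd.read_csv(path_or_buf)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contour CSV missing columns: {sorted(missing)}")
    slices = []
    for sid, g in df.groupby("slice_id", sort=True):
        contours = {}
        for region, gr in g.groupby("region"):
            gr = gr.sort_values("point_index")
            contours[region] = gr[["x_mm", "y_mm"]].to_numpy(dtype=float)
        axial = float(g["axial_mm"].iloc[0])
        slices.append(SliceContours(int(sid), axial, contours))
    if slice_spacing is None and len(slices) >= 2:
        slice_spacing = slices[1].axial_position - slices[0].axial_position
    return VesselSpec(patient_id, slices, slice_spacing or 0.5,
                      tuple(pressure_range), imaging_pressure)
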