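"""Model-variant orchestration and pointwise comparison statistics.

Variants (feature matrix mirroring the modelling-strategy comparison):

====== ============ ============ ============== =========
name   circ shrink  axial shrink kinematics     flow
====== ============ ============ ============== =========
M1     yes          no           2D plane strain none
M2     no           no           2D plane strain none
M5     yes          yes          thin layer      none
FSI    yes          yes          thin layer      coupled
M7     no           no           --              flow only
====== ============ ============ ============== =========

``FSI`` is the sequential structure-then-flow surrogate used as the
comparison baseline; ``M7`` runs flow on the undeformed imaged lumen.  In
this one-way surrogate the structural field of ``FSI`` coincides with
``M5`` by construction (flow does not feed back), so structure-only vs
coupled differences are exactly zero here -- the package reports them as
computed.

For two aligned 100-point lumen profiles of models p and q the pointwise
statistics are::

    Delta_i  = |x_p,i - x_q,i|
    MeanDelta = sum_i Delta_i / n
    MeanBase  = sum_i x_p,i / n          (model p is the base)
    RelErr    = MeanDelta / MeanBase * 100%

Aggregation at slice, patient and cohort level pools the per-point data
(n = total points pooled), never averages of averages.  Flow summaries
(Max/Min/Ave-FSS) are compared per patient at systolic and diastolic
pressure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constitutive as ct
from . import fem_solid as fem
from . import lumen_flow as lflow
from . import preconditioning as pre
from .synthetic_cohort import (CALC, LIPID, LUMEN, CohortConfig,
                               SliceContours, VesselSpec)
from .units import MM_TO_CM, mmhg_to_kpa

logger = logging.getLogger("plaquemech")

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "StudyConfig",
    "DeltaStats",
    "CohortReport",
    "pointwise_delta",
    "run_variant",
    "cohort_report",
    "load_study_yaml",
    "default_materials",
]


@dataclass(frozen=True)
class ModelVariant:
    name: str
    circ_shrink: bool
    axial_shrink: bool
    kinematics: str | None          # plane_strain_2d / thin_layer / None
    flow: str                       # none / flow_only / coupled

    def __post_init__(self):
        if self.flow not in ("none", "flow_only", "coupled"):
            raise ValueError(f"unknown flow mode {self.flow!r}")
        if self.flow == "flow_only":
            if self.kinematics is not None:
                raise ValueError("flow-only variant has no solid kinematics")
        elif self.kinematics not in (fem.PLANE_STRAIN_2D, fem.THIN_LAYER):
            raise ValueError(f"unknown kinematics {self.kinematics!r}")
        if self.axial_shrink and self.kinematics != fem.THIN_LAYER:
            raise ValueError("axial shrink requires the thin-layer model")


VARIANTS: dict[str, ModelVariant] = {
    "M1": ModelVariant("M1", True, False, fem.PLANE_STRAIN_2D, "none"),
    "M2": ModelVariant("M2", False, False, fem.PLANE_STRAIN_2D, "none"),
    "M5": ModelVariant("M5", True, True, fem.THIN_LAYER, "none"),
    "FSI": ModelVariant("FSI", True, True, fem.THIN_LAYER, "coupled"),
    "M7": ModelVariant("M7", False, False, None, "flow_only"),
}


@dataclass(frozen=True)
class StudyConfig:
    """Settings shared by all pipeline stages of one study."""

    mesh_h: float = 0.3                 # mm, structural mesh size
    load_steps: int = 10
    newton_tol: float = 1e-8
    shrink_tol: float = 0.005           # relative lumen-area tolerance
    shrink_bracket: tuple[float, float] = (0.7, 1.0)
    imaging_pressure: str | float = "p_min"   # acquisition pressure rule
    n_points: int = 100
    flow: lflow.FlowConfig = field(default_factory=lflow.FlowConfig)
    material_overrides: dict = field(default_factory=dict)

    def imaging_pressure_mmhg(self, vessel: VesselSpec) -> float:
        if self.imaging_pressure == "p_min":
            return vessel.pressure_range[0]
        if self.imaging_pressure == "p_max":
            return vessel.pressure_range[1]
        return float(self.imaging_pressure)


def default_materials(sl: SliceContours,
                      overrides: dict | None = None
                      ) -> dict[str, ct.MaterialParams]:
    """Region -> material map for a slice: vessel wall / lipid / calc
    presets, with optional per-region parameter overrides."""
    overrides = overrides or {}
    mapping = {fem.WALL: "vessel", LIPID: "lipid", CALC: "calcification"}
    mats = {}
    for region in [fem.WALL] + [r for r in (LIPID, CALC) if r in sl.contours]:
        ov = dict(overrides.get(region, {}))
        preset = ov.pop("preset", mapping[region])
        mats[region] = ct.material_preset(preset, **ov)
    return mats


# ----------------------------------------------------------------------
# Pointwise statistics
# ----------------------------------------------------------------------

@dataclass
class DeltaStats:
    """Pointwise absolute differences and the base-relative error (%)."""

    delta: np.ndarray
    mean_delta: float
    mean_base: float
    relative_error: float

    @classmethod
    def from_arrays(cls, p: np.ndarray, q: np.ndarray) -> "DeltaStats":
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        if p.shape != q.shape:
            raise ValueError("profiles are not aligned (length mismatch)")
        delta = np.abs(p - q)
        mean_delta = float(delta.mean())
        mean_base = float(p.mean())
        return cls(delta=delta, mean_delta=mean_delta, mean_base=mean_base,
                   relative_error=100.0 * mean_delta / mean_base)


def pointwise_delta(profile_p: fem.LumenProfile, profile_q: fem.LumenProfile,
                    quantity: str = "PWS") -> DeltaStats:
    """Eq.-style pointwise comparison of one quantity between two aligned
    profiles; model p is the base of the relative error."""
    xp = getattr(profile_p, quantity, None)
    xq = getattr(profile_q, quantity, None)
    if xp is None or xq is None:
        raise ValueError(f"quantity {quantity!r} absent from a profile")
    if profile_p.n != profile_q.n:
        raise ValueError("profiles are not aligned (different n)")
    mp = profile_p.meta, profile_q.meta
    if all("slice_id" in m for m in mp) and mp[0]["slice_id"] != mp[1]["slice_id"]:
        raise ValueError("profiles belong to different slices")
    return DeltaStats.from_arrays(xp, xq)


# ----------------------------------------------------------------------
# Variant pipeline
# ----------------------------------------------------------------------

def _axial_shrink_slice(sl: SliceContours) -> SliceContours:
    f = 1.0 / np.sqrt(1.0 - pre.AXIAL_SHRINK)
    cen = np.asarray(sl.polygon(LUMEN).centroid.coords[0])
    out = sl.transformed(lambda pts: cen + f * (np.asarray(pts) - cen))
    out.axial_position = sl.axial_position * (1.0 - pre.AXIAL_SHRINK)
    return out


def run_variant(vessel: VesselSpec, variant: ModelVariant,
                study: StudyConfig | None = None, phase: str = "max",
                shrink_cache: dict | None = None) -> list[fem.LumenProfile]:
    """Run one model variant over all slices of a vessel.

    ``phase`` selects the pressure level ("max" or "min" of the vessel's
    range).  Deterministic given its inputs; per-slice failures carry the
    slice index.  ``shrink_cache`` (optional dict) reuses circumferential
    shrink results across variants that share kinematics.
    """
    study = study or StudyConfig()
    cache = shrink_cache if shrink_cache is not None else {}
    p_mmhg = vessel.pressure_range[1] if phase == "max" \
        else vessel.pressure_range[0]
    p_kpa = mmhg_to_kpa(p_mmhg)
    imaging_kpa = mmhg_to_kpa(study.imaging_pressure_mmhg(vessel))

    profiles = []
    for sl in vessel.slices:
        try:
            profiles.append(_run_slice(sl, vessel, variant, study, p_kpa,
                                       imaging_kpa, cache))
        except Exception as exc:
            raise RuntimeError(
                f"variant {variant.name} failed on {vessel.patient_id} "
                f"slice {sl.slice_id}: {exc}") from exc
    return profiles


def _run_slice(sl, vessel, variant, study, p_kpa, imaging_kpa, cache):
    n = study.n_points
    meta = {"variant": variant.name, "patient": vessel.patient_id,
            "slice_id": sl.slice_id, "pressure_kpa": p_kpa,
            "imaging_pressure_kpa": imaging_kpa}

    if variant.flow == "flow_only":
        flow = lflow.solve_axial_flow(sl.contours[LUMEN], study.flow,
                                      n_points=n)
        pts_mm = flow.sample_points / MM_TO_CM
        arc = np.linalg.norm(np.diff(np.vstack([pts_mm, pts_mm[:1]]),
                                     axis=0), axis=1).cumsum()
        profile = fem.LumenProfile(points=pts_mm,
                                   arc_s=np.concatenate([[0.0], arc[:-1]]),
                                   PWS=None, PWSn=None, FSS=flow.wall_shear,
                                   meta={**meta, **flow.meta})
        return profile

    mats = default_materials(sl, study.material_overrides)
    lam_z = 1.0 / (1.0 - pre.AXIAL_SHRINK) if variant.axial_shrink else 1.0
    base = _axial_shrink_slice(sl) if variant.axial_shrink else sl
    cfg_kw = dict(load_steps=study.load_steps, newton_tol=study.newton_tol,
                  axial_stretch=lam_z, variant=variant.kinematics)

    shrink = None
    if variant.circ_shrink:
        key = (vessel.patient_id, sl.slice_id, variant.kinematics,
               round(imaging_kpa, 9))
        if key not in cache:
            cache[key] = pre.find_circ_shrink(
                base, mats, imaging_kpa,
                fem.SolveConfig(pressure=imaging_kpa, **cfg_kw),
                h=study.mesh_h, tol=study.shrink_tol,
                bracket=study.shrink_bracket,
                target_lumen_area=sl.lumen_area)
        shrink = cache[key]
        ref = shrink.shrunk_slice
        meta["circ_shrink_ratio"] = shrink.circ_shrink_ratio
        meta["shrink_area_error"] = shrink.achieved_area_error
    else:
        ref = base

    mesh = fem.build_mesh(ref, study.mesh_h)
    sol = fem.solve_static(mesh, mats,
                           fem.SolveConfig(pressure=p_kpa, **cfg_kw))
    profile = fem.sample_lumen(sol, n=n)
    profile.meta.update(meta)

    if variant.flow == "coupled":
        flow = lflow.solve_axial_flow(fem.deformed_lumen_polygon(sol),
                                      study.flow, n_points=n)
        profile.FSS = flow.wall_shear
        profile.meta.update({"flow": "coupled", **flow.meta})
    else:
        profile.FSS = None
    return profile


# ----------------------------------------------------------------------
# Cohort-level report
# ----------------------------------------------------------------------

@dataclass
class CohortReport:
    """Per-patient and cohort-pooled comparison tables plus provenance."""

    tables: dict[str, pd.DataFrame]
    provenance: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "provenance.json", "w") as f:
            json.dump(self.provenance, f, indent=2, default=str)
        with open(outdir / "summary.txt", "w") as f:
            f.write(self.text_summary())

    def text_summary(self) -> str:
        lines = ["Model-comparison report (%s)" % lflow.SURROGATE_STAMP, ""]
        for name, df in self.tables.items():
            lines += [name, "-" * len(name), df.to_string(index=False), ""]
        return "\n".join(lines)


def _flag_extremes(df: pd.DataFrame, err_cols) -> pd.DataFrame:
    """Mark the min/max error across patients (the tables' bold convention)."""
    df = df.copy()
    for col in err_cols:
        flags = [""] * len(df)
        sub = df[df["patient"] != "Ave"][col]
        if len(sub) >= 2:
            imin, imax = sub.idxmin(), sub.idxmax()
            flags[imin] = "min"
            flags[imax] = "max"
        df[col.replace("error", "flag")] = flags
    return df


def _pooled(profiles_p, profiles_q, quantity):
    xp = np.concatenate([np.asarray(getattr(pr, quantity))
                         for pr in profiles_p])
    xq = np.concatenate([np.asarray(getattr(pr, quantity))
                         for pr in profiles_q])
    return DeltaStats.from_arrays(xp, xq)


def cohort_report(cohort: list[VesselSpec],
                  variant_pairs: list[tuple[str, str]] | None = None,
                  study: StudyConfig | None = None,
                  cohort_meta: dict | None = None) -> CohortReport:
    """Run the requested variant pairs over a cohort and build the report.

    Each pair is (base p, compared q).  Structural quantities (PWS, PWSn)
    are compared pointwise at systolic pressure; FSS summaries
    (Max/Min/Ave) per patient at systolic and diastolic pressure when both
    variants carry flow.  Cohort rows pool per-point (or per-patient-
    summary) data, not means of means.
    """
    if not cohort:
        raise ValueError("empty cohort")
    study = study or StudyConfig()
    pairs = variant_pairs or [("M1", "M2"), ("FSI", "M1"), ("FSI", "M5"),
                              ("FSI", "M7")]
    needed: set[tuple[str, str]] = set()
    for p, q in pairs:
        vp, vq = VARIANTS[p], VARIANTS[q]
        needed.add((p, "max"))
        needed.add((q, "max"))
        if vp.flow != "none" and vq.flow != "none":
            needed.add((p, "min"))
            needed.add((q, "min"))

    shrink_cache: dict = {}
    runs: dict[tuple[str, str], dict[str, list[fem.LumenProfile]]] = {}
    for name, phase in sorted(needed):
        runs[(name, phase)] = {}
        for vessel in cohort:
            logger.info("running %s (%s pressure) on %s", name, phase,
                        vessel.patient_id)
            runs[(name, phase)][vessel.patient_id] = run_variant(
                vessel, VARIANTS[name], study, phase, shrink_cache)

    tables: dict[str, pd.DataFrame] = {}
    for p, q in pairs:
        vp, vq = VARIANTS[p], VARIANTS[q]
        structural = vp.flow != "flow_only" and vq.flow != "flow_only"
        if structural:
            for quantity in ("PWS", "PWSn"):
                rows = []
                for vessel in cohort:
                    pid = vessel.patient_id
                    st = _pooled(runs[(p, "max")][pid], runs[(q, "max")][pid],
                                 quantity)
                    rows.append({"patient": pid, f"{p}_mean": st.mean_base,
                                 f"{q}_mean": np.mean(np.concatenate(
                                     [np.asarray(getattr(pr, quantity))
                                      for pr in runs[(q, "max")][pid]])),
                                 "error_pct": st.relative_error})
                allp = [pr for v in cohort for pr in runs[(p, "max")][v.patient_id]]
                allq = [pr for v in cohort for pr in runs[(q, "max")][v.patient_id]]
                st = _pooled(allp, allq, quantity)
                rows.append({"patient": "Ave", f"{p}_mean": st.mean_base,
                             f"{q}_mean": float(np.mean(np.concatenate(
                                 [np.asarray(getattr(pr, quantity))
                                  for pr in allq]))),
                             "error_pct": st.relative_error})
                df = pd.DataFrame(rows).round(4)
                tables[f"{p}_vs_{q}_{quantity}"] = _flag_extremes(
                    df, ["error_pct"])
        if vp.flow != "none" and vq.flow != "none":
            for phase in ("max", "min"):
                rows = []
                summ = {}
                for vessel in cohort:
                    pid = vessel.patient_id
                    fss_p = np.concatenate([pr.FSS for pr in
                                            runs[(p, phase)][pid]])
                    fss_q = np.concatenate([pr.FSS for pr in
                                            runs[(q, phase)][pid]])
                    sp = lflow.fss_summary(fss_p)
                    sq = lflow.fss_summary(fss_q)
                    summ[pid] = (sp, sq)
                    rows.append({
                        "patient": pid,
                        f"max_{p}": sp[0], f"max_{q}": sq[0],
                        "max_error_pct": 100 * abs(sp[0] - sq[0]) / sp[0],
                        f"min_{p}": sp[1], f"min_{q}": sq[1],
                        "min_error_pct": 100 * abs(sp[1] - sq[1]) / sp[1],
                        f"ave_{p}": sp[2], f"ave_{q}": sq[2],
                        "ave_error_pct": 100 * abs(sp[2] - sq[2]) / sp[2],
                    })
                # cohort row: pool the per-patient summaries
                row = {"patient": "Ave"}
                for k, idx in (("max", 0), ("min", 1), ("ave", 2)):
                    sp = np.array([summ[v.patient_id][0][idx] for v in cohort])
                    sq = np.array([summ[v.patient_id][1][idx] for v in cohort])
                    row[f"{k}_{p}"] = sp.mean()
                    row[f"{k}_{q}"] = sq.mean()
                    row[f"{k}_error_pct"] = 100 * np.abs(sp - sq).sum() / sp.sum()
                rows.append(row)
                df = pd.DataFrame(rows).round(4)
                tables[f"{p}_vs_{q}_FSS_p{phase}"] = _flag_extremes(
                    df, ["max_error_pct", "min_error_pct", "ave_error_pct"])

    shrink_prov = {f"{k[0]}/slice{k[1]}/{k[2]}": cache_val.to_json_dict()
                   for k, cache_val in shrink_cache.items()}
    provenance = {
        "surrogate": lflow.SURROGATE_STAMP,
        "study_config": _study_dict(study),
        "imaging_pressure_rule": study.imaging_pressure,
        "variant_pairs": pairs,
        "patients": {v.patient_id: {
            "n_slices": len(v.slices),
            "pressure_range_mmhg": list(v.pressure_range),
            "imaging_pressure_mmhg": study.imaging_pressure_mmhg(v),
        } for v in cohort},
        "shrink_results": shrink_prov,
    }
    if cohort_meta:
        provenance["cohort"] = cohort_meta
    return CohortReport(tables=tables, provenance=provenance)


def _study_dict(study: StudyConfig) -> dict:
    d = asdict(study)
    return d


# ----------------------------------------------------------------------
# Study YAML
# ----------------------------------------------------------------------

def load_study_yaml(path):
    """Parse the study YAML: blocks cohort / materials / solver /
    preconditioning / flow / comparison (all optional).

    Returns ``(study_config, cohort_config, n_patients, base_seed, pairs)``.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cohort_raw = dict(raw.get("cohort", {}))
    n_patients = int(cohort_raw.pop("n_patients", 7))
    base_seed = int(cohort_raw.pop("base_seed", 42))
    for key in ("n_slices_range", "p_min_range", "p_max_range",
                "lumen_radius_range", "eccentricity_range",
                "wall_thickness_range", "stenosis_depth_range",
                "lipid_arc_range", "lipid_thickness_frac_range",
                "cap_thickness_range", "calc_arc_range"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    cohort_cfg = CohortConfig(**cohort_raw)

    solver = raw.get("solver", {})
    precon = raw.get("preconditioning", {})
    flow_raw = raw.get("flow", {})
    comp = raw.get("comparison", {})
    flow_cfg = lflow.FlowConfig(
        viscosity_poise=flow_raw.get("viscosity_poise", 0.04),
        flow_rate_ml_s=flow_raw.get("flow_rate_ml_s",
                                    None if "pressure_gradient" in flow_raw
                                    else 1.0),
        pressure_gradient=flow_raw.get("pressure_gradient"),
        mesh_h_mm=flow_raw.get("mesh_h_mm", 0.12))
    study = StudyConfig(
        mesh_h=solver.get("mesh_h", 0.3),
        load_steps=solver.get("load_steps", 10),
        newton_tol=solver.get("newton_tol", 1e-8),
        shrink_tol=precon.get("tol", 0.005),
        shrink_bracket=tuple(precon.get("bracket", (0.7, 1.0))),
        imaging_pressure=precon.get("imaging_pressure", "p_min"),
        n_points=comp.get("n_points", 100),
        flow=flow_cfg,
        material_overrides=raw.get("materials", {}),
    )
    pairs = [tuple(p.split(":")) for p in comp.get(
        "pairs", ["M1:M2", "FSI:M1", "FSI:M5", "FSI:M7"])]
    return study, cohort_cfg, n_patients, base_seed, pairs
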