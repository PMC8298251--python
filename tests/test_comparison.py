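"""Pointwise comparison statistics, variant plumbing, and report tables."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquemech import comparison as cmp
from plaquemech import fem_solid as fem
from plaquemech import synthetic_cohort as sc


def profile(values, slice_id=0, **meta):
    v = np.asarray(values, dtype=float)
    pts = np.column_stack([np.cos(np.linspace(0, 2 * np.pi, len(v),
                                              endpoint=False)),
                           np.sin(np.linspace(0, 2 * np.pi, len(v),
                                              endpoint=False))])
    return fem.LumenProfile(points=pts, arc_s=np.arange(len(v), dtype=float),
                            PWS=v, PWSn=v / 100.0, FSS=None,
                            meta={"slice_id": slice_id, **meta})


class TestPointwiseDelta:
    def test_identical_profiles(self):
        p = profile(np.linspace(10, 20, 100))
        st_ = cmp.pointwise_delta(p, p, "PWS")
        assert st_.mean_delta == 0.0
        assert st_.relative_error == 0.0

    def test_hand_worked_example(self):
        """p = [1,2,3], q = [2,3,4]: MeanDelta = 1, MeanBase = 2,
        RelErr = 50% exactly."""
        st_ = cmp.pointwise_delta(profile([1, 2, 3]), profile([2, 3, 4]),
                                  "PWS")
        assert st_.mean_delta == 1.0
        assert st_.mean_base == 2.0
        assert st_.relative_error == 50.0

    def test_base_asymmetry(self):
        a, b = profile([1, 2, 3]), profile([2, 3, 4])
        ab = cmp.pointwise_delta(a, b)
        ba = cmp.pointwise_delta(b, a)
        assert ab.mean_delta == ba.mean_delta
        assert ab.relative_error != ba.relative_error
        assert ba.relative_error == pytest.approx(100.0 / 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cmp.pointwise_delta(profile([1, 2, 3]), profile([1, 2]))

    def test_slice_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cmp.pointwise_delta(profile([1, 2], slice_id=0),
                                profile([1, 2], slice_id=1))

    def test_missing_quantity_rejected(self):
        with pytest.raises(ValueError):
            cmp.pointwise_delta(profile([1, 2]), profile([1, 2]), "FSS")

    @given(st.integers(0, 10**6))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_bruteforce_recomputation(self, seed):
        """The implementation agrees with a 5-line brute-force recompute of
        the delta/mean/relative-error definitions to 1e-12."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 200)
        p = rng.uniform(1.0, 100.0, n)
        q = rng.uniform(1.0, 100.0, n)
        st_ = cmp.DeltaStats.from_arrays(p, q)
        delta = [abs(pi - qi) for pi, qi in zip(p, q)]
        mean_delta = sum(delta) / n
        mean_base = sum(p) / n
        rel = mean_delta / mean_base * 100.0
        assert st_.mean_delta == pytest.approx(mean_delta, abs=1e-12)
        assert st_.relative_error == pytest.approx(rel, abs=1e-12)


class TestVariantDefinitions:
    def test_feature_matrix(self):
        V = cmp.VARIANTS
        assert (V["M1"].circ_shrink, V["M1"].axial_shrink,
                V["M1"].kinematics, V["M1"].flow) \
            == (True, False, fem.PLANE_STRAIN_2D, "none")
        assert (V["M2"].circ_shrink, V["M2"].axial_shrink) == (False, False)
        assert V["M5"].kinematics == fem.THIN_LAYER
        assert V["FSI"].flow == "coupled"
        assert V["M7"].flow == "flow_only" and V["M7"].kinematics is None

    def test_invalid_variant_combinations(self):
        with pytest.raises(ValueError):
            cmp.ModelVariant("X", True, True, fem.PLANE_STRAIN_2D, "none")
        with pytest.raises(ValueError):
            cmp.ModelVariant("X", False, False, fem.PLANE_STRAIN_2D,
                             "flow_only")


@pytest.fixture(scope="module")
def tiny_vessel():
    cfg = sc.CohortConfig(n_slices_range=(2, 2), lipid_probability=1.0,
                          calc_probability=0.0)
    return sc.generate_cohort(1, 123, cfg)[0]


@pytest.fixture(scope="module")
def fast_study():
    return cmp.StudyConfig(mesh_h=0.4, load_steps=5)


class TestRunVariant:
    def test_flow_none_has_null_fss(self, tiny_vessel, fast_study):
        profs = cmp.run_variant(tiny_vessel, cmp.VARIANTS["M2"], fast_study)
        assert len(profs) == len(tiny_vessel.slices)
        for p in profs:
            assert p.FSS is None
            assert p.PWS is not None and p.n == 100

    def test_flow_only_has_only_fss(self, tiny_vessel, fast_study):
        profs = cmp.run_variant(tiny_vessel, cmp.VARIANTS["M7"], fast_study)
        for p in profs:
            assert p.PWS is None and p.PWSn is None
            assert p.FSS is not None and np.all(p.FSS > 0)

    def test_no_shrink_overestimates_pws_per_slice(self, tiny_vessel,
                                                   fast_study):
        cache = {}
        m1 = cmp.run_variant(tiny_vessel, cmp.VARIANTS["M1"], fast_study,
                             shrink_cache=cache)
        m2 = cmp.run_variant(tiny_vessel, cmp.VARIANTS["M2"], fast_study,
                             shrink_cache=cache)
        for p1, p2 in zip(m1, m2):
            assert p2.PWS.mean() > p1.PWS.mean()
            assert "circ_shrink_ratio" in p1.meta

    def test_determinism_byte_identical_csv(self, tiny_vessel, fast_study):
        out = []
        for _ in range(2):
            profs = cmp.run_variant(tiny_vessel, cmp.VARIANTS["M2"],
                                    fast_study)
            buf = io.StringIO()
            fem.profile_to_csv(profs[0], buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_failure_carries_slice_context(self, tiny_vessel, fast_study):
        import dataclasses
        bad = dataclasses.replace(fast_study, mesh_h=-1.0)
        with pytest.raises(RuntimeError, match="slice 0"):
            cmp.run_variant(tiny_vessel, cmp.VARIANTS["M2"], bad)


class TestCohortAggregation:
    def test_self_pair_zero_errors(self, tiny_vessel, fast_study):
        report = cmp.cohort_report([tiny_vessel], [("M2", "M2")], fast_study)
        df = report.tables["M2_vs_M2_PWS"]
        assert np.allclose(df["error_pct"], 0.0)

    def test_pooled_vs_grouped_mean_oracle(self):
        """Patient-level MeanDelta equals the pooled per-point mean, not
        the mean of per-slice means (checked on hand-set profiles of
        different magnitudes)."""
        p_slices = [np.array([10.0, 12.0]), np.array([100.0, 104.0])]
        q_slices = [np.array([11.0, 13.0]), np.array([90.0, 94.0])]
        st_ = cmp._pooled([profile(v) for v in p_slices],
                          [profile(v) for v in q_slices], "PWS")
        pooled_delta = np.abs(np.concatenate(p_slices)
                              - np.concatenate(q_slices)).mean()
        assert st_.mean_delta == pytest.approx(pooled_delta, abs=1e-12)
        per_slice = np.mean([np.abs(p - q).mean()
                             for p, q in zip(p_slices, q_slices)])
        assert st_.mean_delta == pytest.approx(per_slice)  # equal n here
        # relative error uses the pooled base mean
        assert st_.relative_error == pytest.approx(
            100 * pooled_delta / np.concatenate(p_slices).mean())

    def test_cohort_row_pools_points_not_patient_means(self):
        """The Ave row must differ from the mean of per-patient relative
        errors when patients have different magnitudes."""
        pa = [profile(np.full(100, 10.0))]
        qa = [profile(np.full(100, 12.0))]     # 20% error, base 10
        pb = [profile(np.full(100, 100.0))]
        qb = [profile(np.full(100, 101.0))]    # 1% error, base 100
        pooled = cmp._pooled(pa + pb, qa + qb, "PWS")
        mean_of_errors = np.mean([20.0, 1.0])
        assert pooled.relative_error == pytest.approx(
            100 * (2 + 1) / 2 / 55.0)          # (2+1)/2 over base 55
        assert pooled.relative_error != pytest.approx(mean_of_errors)

    def test_empty_cohort_rejected(self, fast_study):
        with pytest.raises(ValueError):
            cmp.cohort_report([], [("M1", "M2")], fast_study)


class TestStudyYaml:
    def test_round_trip_defaults(self, tmp_path):
        y = tmp_path / "study.yaml"
        y.write_text(
            "cohort:\n  n_patients: 3\n  base_seed: 9\n"
            "  n_slices_range: [2, 3]\n"
            "solver:\n  mesh_h: 0.4\n  load_steps: 5\n"
            "preconditioning:\n  tol: 0.004\n"
            "flow:\n  viscosity_poise: 0.035\n"
            "comparison:\n  pairs: ['M1:M2']\n")
        study, cohort_cfg, n, seed, pairs = cmp.load_study_yaml(y)
        assert (n, seed) == (3, 9)
        assert cohort_cfg.n_slices_range == (2, 3)
        assert study.mesh_h == 0.4 and study.load_steps == 5
        assert study.shrink_tol == 0.004
        assert study.flow.viscosity_poise == 0.035
        assert pairs == [("M1", "M2")]

    def test_empty_yaml_gives_defaults(self, tmp_path):
        y = tmp_path / "empty.yaml"
        y.write_text("")
        study, cohort_cfg, n, seed, pairs = cmp.load_study_yaml(y)
        assert n == 7 and study.n_points == 100
        assert ("M1", "M2") in pairs


class TestReportOutput:
    def test_save_writes_tables_and_provenance(self, tmp_path, tiny_vessel,
                                               fast_study):
        report = cmp.cohort_report([tiny_vessel], [("M1", "M2")], fast_study)
        report.save(tmp_path)
        assert (tmp_path / "M1_vs_M2_PWS.csv").exists()
        assert (tmp_path / "M1_vs_M2_PWSn.csv").exists()
        import json
        prov = json.loads((tmp_path / "provenance.json").read_text())
        assert prov["surrogate"].startswith("surrogate")
        assert "shrink_results" in prov
        assert "P1" in prov["patients"]
        txt = (tmp_path / "summary.txt").read_text()
        assert "M1_vs_M2_PWS" in txt

    def test_flag_extremes(self):
        df = pd.DataFrame({"patient": ["P1", "P2", "P3", "Ave"],
                           "error_pct": [5.0, 1.0, 9.0, 4.0]})
        out = cmp._flag_extremes(df, ["error_pct"])
        flags = dict(zip(out["patient"], out["flag_pct"]))
        assert flags["P2"] == "min" and flags["P3"] == "max"
        assert flags["Ave"] == ""
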