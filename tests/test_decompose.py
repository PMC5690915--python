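"""Component estimators: per-treatment mask/setup, pooled frame, localizer
and registration noise, axis summaries with t-tests, Winston-Lutz
composition, and couch-sag selection."""

import math

import numpy as np
import pytest

from setupbudget import (
    CohortTruth,
    IsoOffsetRecord,
    SetupRecord,
    ShiftVector6D,
    ValidationError,
    axis_summary,
    couch_sag_component,
    frame_systematic,
    generate_cohort,
    localizer_and_xray,
    per_treatment_stats,
    winston_lutz_components,
)
from setupbudget.records import AXES, CouchSagRecord
from setupbudget.synthetic import DEFAULT_COUCH_SAG_TABLE
from conftest import signflip_pvalue


def rec(tid, frac, stage, lat=0.0, long=0.0, vert=0.0, pitch=0.0, roll=0.0, yaw=0.0, pid="P1"):
    return SetupRecord(pid, tid, frac, stage, ShiftVector6D(lat, long, vert, pitch, roll, yaw))


class TestPerTreatmentStats:
    def test_single_fraction_mean_is_datum_sd_zero(self):
        s = ShiftVector6D(0.5, -0.2, 1.1, 0.1, 0.0, -0.3)
        out = per_treatment_stats([SetupRecord("P1", "T1", 1, "XC", s)])
        mask, setup = out["T1"]
        assert mask.per_axis == s and mask.n == 1
        assert all(v == 0.0 for v in setup.per_axis.as_dict().values())
        assert setup.radial == 0.0

    def test_two_point_mean_and_sample_sd(self):
        out = per_treatment_stats([rec("T1", 1, "XC", lat=1.0), rec("T1", 2, "XC", lat=3.0)])
        mask, setup = out["T1"]
        assert mask.per_axis.lat == pytest.approx(2.0)
        assert setup.per_axis.lat == pytest.approx(math.sqrt(2.0))

    def test_mask_radial_is_mean_of_fraction_radials(self):
        out = per_treatment_stats([rec("T1", 1, "XC", lat=1.0), rec("T1", 2, "XC", lat=-1.0)])
        mask, _ = out["T1"]
        assert mask.per_axis.lat == pytest.approx(0.0)
        assert mask.radial == pytest.approx(1.0)  # not the quadrature of means (0)
        assert mask.radial_of_means == pytest.approx(0.0)

    def test_recovers_generator_truth_per_treatment(self):
        truth = CohortTruth(seed=99)
        records, mask_truth = generate_cohort(truth)
        stats = per_treatment_stats(records)
        noise = np.sqrt(np.array(truth.setup_sd) ** 2 + np.array(truth.xray_sd) ** 2)
        checks = ok = 0
        for tid, (mask, _) in stats.items():
            m_t = mask_truth[tid]
            for i, a in enumerate(AXES):
                expected = (getattr(m_t, a) or 0.0) + (getattr(truth.frame_systematic, a) or 0.0)
                se = noise[i] / math.sqrt(mask.n)
                checks += 1
                ok += abs(getattr(mask.per_axis, a) - expected) < 3 * se
        assert ok / checks > 0.95

    def test_requires_xc_records(self):
        with pytest.raises(ValidationError):
            per_treatment_stats([rec("T1", 1, "XV")])

    def test_grouping_by_patient(self):
        records = [rec("T1", 1, "XC", lat=1.0, pid="P1"), rec("T2", 1, "XC", lat=3.0, pid="P1")]
        by_pat = per_treatment_stats(records, group_by="patient_id")
        assert by_pat["P1"][0].per_axis.lat == pytest.approx(2.0)


class TestFrameSystematic:
    def test_constant_data_returns_constant(self):
        c = ShiftVector6D(0.3, -0.1, 0.2, 0.0, 0.1, -0.2)
        recs = [SetupRecord("P1", "T1", f, "XC", c) for f in (1, 2, 3)]
        comp = frame_systematic(recs)
        assert comp.n == 3
        for a in AXES:
            assert getattr(comp.per_axis, a) == pytest.approx(getattr(c, a), abs=1e-12)

    def test_symmetric_pair_mean_zero_radial_one(self):
        recs = [rec("T1", 1, "XC", lat=1.0), rec("T1", 2, "XC", lat=-1.0)]
        comp = frame_systematic(recs)
        assert comp.per_axis.lat == pytest.approx(0.0)
        assert comp.radial == pytest.approx(1.0)

    def test_pooling_identity_with_per_treatment_means(self, study_cohort):
        """The pooled frame mean equals the fraction-count-weighted mean of
        the per-treatment mask means, exactly."""
        records, _ = study_cohort
        frame = frame_systematic(records)
        stats = per_treatment_stats(records)
        n_total = sum(mask.n for mask, _ in stats.values())
        for a in AXES:
            weighted = sum(mask.n * getattr(mask.per_axis, a) for mask, _ in stats.values()) / n_total
            assert getattr(frame.per_axis, a) == pytest.approx(weighted, abs=1e-12)

    def test_recovers_truth_at_large_n(self):
        truth = CohortTruth(n_treatments=500, fractions_per_treatment=(5,) * 500, n_patients=500, seed=4)
        records, _ = generate_cohort(truth)
        comp = frame_systematic(records)
        n = comp.n
        for i, a in enumerate(AXES):
            se = math.sqrt(truth.mask_sd[i] ** 2 * 500 * (5 / n) ** 2
                           + (truth.setup_sd[i] ** 2 + truth.xray_sd[i] ** 2) / n)
            assert abs(getattr(comp.per_axis, a) - (getattr(truth.frame_systematic, a) or 0.0)) < 3 * se

    def test_requires_two_records(self):
        with pytest.raises(ValidationError):
            frame_systematic([rec("T1", 1, "XC")])


class TestLocalizerAndXray:
    def test_all_zero_xv(self):
        recs = [rec("T1", f, "XV") for f in (1, 2, 3)]
        loc, xr = localizer_and_xray(recs)
        assert all(v == 0.0 for v in loc.per_axis.as_dict().values())
        assert all(v == 0.0 for v in xr.per_axis.as_dict().values())

    def test_two_point_formulas(self):
        recs = [rec("T1", 1, "XV", lat=0.1), rec("T1", 2, "XV", lat=0.3)]
        loc, xr = localizer_and_xray(recs)
        assert loc.per_axis.lat == pytest.approx(0.2)
        assert xr.per_axis.lat == pytest.approx(0.1414, abs=1e-4)

    def test_recovery_at_study_scale(self):
        truth = CohortTruth(seed=13, force_xv=True)
        records, _ = generate_cohort(truth)
        loc, xr = localizer_and_xray(records)
        n = loc.n
        for i, a in enumerate(AXES):
            se = truth.xray_sd[i] / math.sqrt(n)
            assert abs(getattr(loc.per_axis, a) - (getattr(truth.localizer_systematic, a) or 0.0)) < 3 * se
            se_sd = truth.xray_sd[i] / math.sqrt(2 * (n - 1))
            assert abs(getattr(xr.per_axis, a) - truth.xray_sd[i]) < 3 * se_sd

    def test_sd_of_treatment_means_convention_differs(self):
        truth = CohortTruth(seed=13, force_xv=True)
        records, _ = generate_cohort(truth)
        _, pooled = localizer_and_xray(records, convention="pooled")
        _, of_means = localizer_and_xray(records, convention="sd_of_treatment_means")
        # averaging within treatments shrinks the spread
        assert of_means.per_axis.long < pooled.per_axis.long
        assert "sd_of_treatment_means" in of_means.flags

    def test_requires_two_xv(self):
        with pytest.raises(ValidationError):
            localizer_and_xray([rec("T1", 1, "XV")])


class TestAxisSummary:
    def test_symmetric_pair_gives_p_one(self):
        s = axis_summary([-1.0, 1.0])
        assert s.mean == 0.0 and s.p_value == 1.0

    def test_degenerate_variance_flagged(self):
        s = axis_summary([1.0, 1.0, 1.0])
        assert s.sd == 0.0 and s.p_value == 0.0
        assert "degenerate-variance" in s.flags

    def test_all_zero_sample_has_no_p(self):
        s = axis_summary([0.0, 0.0])
        assert s.p_value is None and "degenerate-zero" in s.flags

    def test_single_value_flagged(self):
        s = axis_summary([0.7])
        assert s.sd is None and s.p_value is None and "insufficient-n" in s.flags

    def test_min_mean_max_ordering(self):
        s = axis_summary([0.4, -0.2, 1.3, 0.0])
        assert s.min <= s.mean <= s.max
        assert (s.min, s.max) == (-0.2, 1.3)

    def test_p_value_matches_sign_flip_oracle(self):
        rng = np.random.default_rng(2016)
        values = rng.normal(0.0, 1.0, size=50)
        p_t = axis_summary(values).p_value
        p_flip = signflip_pvalue(values, n_resamples=20_000, seed=1)
        assert abs(p_t - p_flip) < 0.02


class TestWinstonLutz:
    def _records(self, rows):
        return [IsoOffsetRecord(axis=a, offset=ShiftVector6D(*t), date="S1") for a, t in rows]

    def test_mv_composition_with_absent_verticals(self):
        rows = [
            ("gantry", (0.27, 0.24, 0.34)),
            ("collimator", (0.32, 0.24, None)),
            ("couch_rotation", (0.32, 0.22, None)),
        ]
        comps = winston_lutz_components(self._records(rows))
        mv = comps["iso_mv"]
        assert mv.per_axis.translations() == pytest.approx((0.91, 0.70, 0.34))
        assert "absent-contributed-zero" in mv.flags

    def test_all_zero_offsets(self):
        rows = [(a, (0.0, 0.0, 0.0)) for a in ("gantry", "collimator", "couch_rotation", "kv_imager", "infrared")]
        comps = winston_lutz_components(self._records(rows))
        for name in ("iso_mv", "iso_kv", "iso_ir"):
            assert comps[name].radial == 0.0

    def test_single_record_mean_is_record(self):
        comps = winston_lutz_components(self._records([("kv_imager", (0.15, -0.40, 0.21))]))
        assert comps["iso_kv"].per_axis.translations() == pytest.approx((0.15, -0.40, 0.21))

    def test_missing_axis_type_component_absent_with_warning(self):
        with pytest.warns(UserWarning, match="iso_mv absent"):
            comps = winston_lutz_components(self._records([("kv_imager", (0.1, 0.1, 0.1))]))
        assert "iso_mv" not in comps and "iso_kv" in comps


class TestCouchSag:
    def test_worst_case_matches_tie_break(self):
        comp = couch_sag_component(DEFAULT_COUCH_SAG_TABLE)
        # two rows tie at radial 1.09; larger angle wins
        assert comp.per_axis.translations() == pytest.approx((0.85, 0.01, -0.68))
        assert round(comp.radial, 2) == 1.09

    def test_single_record(self):
        r = CouchSagRecord(10, 45, ShiftVector6D(0.1, 0.2, 0.3, 0.0, 0.0, None))
        comp = couch_sag_component([r])
        assert comp.per_axis == r.sag

    def test_all_zero_sags(self):
        recs = [CouchSagRecord(0, 0, ShiftVector6D(0, 0, 0, 0, 0, None))]
        assert couch_sag_component(recs).radial == 0.0

    def test_at_angle_policy(self):
        comp = couch_sag_component(DEFAULT_COUCH_SAG_TABLE, policy="at_angle", at=(70, 270))
        assert comp.per_axis.translations() == pytest.approx((0.40, -0.97, -0.29))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            couch_sag_component([])
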