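"""Correction policies: schedules, fits, corrections, residual courses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from setupcorr import (
    CorrectionPolicy,
    SetupError6DoF,
    TreatmentCourse,
    apply_policy,
    enal_correction,
    enal_fit,
    imaging_schedule,
    nal_correction,
    workload,
)

from conftest import make_course


class TestCorrectionPolicy:
    @pytest.mark.parametrize("name", ["none", "online", "nal", "enal", "enal_pp"])
    def test_valid_names(self, name):
        assert CorrectionPolicy(name).name == name

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown policy"):
            CorrectionPolicy("sal")

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(nal_length=0), "nal_length"),
            (dict(followup_start=3), "followup_start"),
            (dict(followup_interval=0), "followup_interval"),
            (dict(couch_limit_deg=0.0), "couch_limit_deg"),
            (dict(couch_limit_deg=-1.0), "couch_limit_deg"),
        ],
    )
    def test_invalid_parameters(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            CorrectionPolicy("enal", **kwargs)


class TestImagingSchedule:
    def test_enal_30_fractions(self):
        schedule = imaging_schedule(CorrectionPolicy("enal"), 30)
        assert schedule == (1, 2, 3, 8, 13, 18, 23, 28)
        assert len(schedule) == 8

    def test_enal_28_fractions(self):
        # arithmetic sequence 8 + 5k capped at 28
        assert imaging_schedule(CorrectionPolicy("enal"), 28) == (1, 2, 3, 8, 13, 18, 23, 28)

    def test_online_images_every_fraction(self):
        assert imaging_schedule(CorrectionPolicy("online"), 30) == tuple(range(1, 31))

    def test_none_images_nothing(self):
        assert imaging_schedule(CorrectionPolicy("none"), 30) == ()

    def test_nal_initial_block_only(self):
        assert imaging_schedule(CorrectionPolicy("nal"), 30) == (1, 2, 3)

    @given(st.integers(min_value=1, max_value=60))
    def test_enal_matches_enal_pp(self, n):
        enal = imaging_schedule(CorrectionPolicy("enal"), n)
        enal_pp = imaging_schedule(CorrectionPolicy("enal_pp"), n)
        assert enal == enal_pp

    @given(st.integers(min_value=1, max_value=60))
    def test_schedule_sorted_unique_in_range(self, n):
        for name in ("nal", "enal", "online"):
            schedule = imaging_schedule(CorrectionPolicy(name), n)
            assert list(schedule) == sorted(set(schedule))
            assert all(1 <= f <= n for f in schedule)


class TestNalCorrection:
    def test_mean_of_three(self):
        corr = nal_correction(np.array([[1.0], [2.0], [3.0]]).reshape(3, 1))
        assert corr == pytest.approx(-2.0)

    def test_zero_measurements(self):
        np.testing.assert_array_equal(nal_correction(np.zeros((3, 6))), np.zeros(6))

    def test_observed_range_mean(self):
        # arithmetic mean of (-1.7, 1.4, 0.3) is exactly 0
        corr = nal_correction(np.array([-1.7, 1.4, 0.3]).reshape(3, 1))
        assert corr == pytest.approx(0.0, abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            nal_correction(np.empty((0, 6)))


class TestEnalFit:
    def test_exact_line(self):
        f = [1, 2, 3, 8]
        values = 0.5 + 0.1 * np.asarray(f, dtype=float)
        fit = enal_fit(f, values)
        assert fit.S_k == pytest.approx(0.5, abs=1e-12)
        assert fit.a_k == pytest.approx(0.1, abs=1e-12)
        assert fit.f_k == 8
        assert fit.n_points == 4

    def test_single_point_fallback(self):
        fit = enal_fit([1], [0.7])
        assert fit.S_k == pytest.approx(0.7)
        assert fit.a_k == pytest.approx(0.0)
        assert fit.f_k == 1

    def test_frozen_normal_equations_example(self):
        # oracle: solving the normal equations by hand for
        # (1, 1.0), (2, 0.0), (3, 1.0), (8, 0.0) gives
        # slope = -12/116, intercept = (2 - slope*14)/4
        fit = enal_fit([1, 2, 3, 8], [1.0, 0.0, 1.0, 0.0])
        assert fit.a_k == pytest.approx(-12 / 116, abs=1e-12)
        assert fit.S_k == pytest.approx((2 + (12 / 116) * 14) / 4, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            enal_fit([], np.empty((0, 6)))

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            enal_fit([1, 3, 3], [0.0, 1.0, 2.0])

    @given(
        st.lists(st.integers(1, 40), min_size=2, max_size=10, unique=True),
        st.data(),
    )
    @settings(max_examples=60)
    def test_against_lstsq_oracle(self, fractions, data):
        fractions = sorted(fractions)
        values = np.array(
            [
                data.draw(st.floats(-5, 5, allow_nan=False, allow_infinity=False))
                for _ in fractions
            ]
        )
        fit = enal_fit(fractions, values)
        design = np.column_stack([np.ones(len(fractions)), np.asarray(fractions, float)])
        (intercept, slope), *_ = np.linalg.lstsq(design, values, rcond=None)
        assert fit.S_k == pytest.approx(intercept, abs=1e-10)
        assert fit.a_k == pytest.approx(slope, abs=1e-10)

    def test_vectorized_over_axes(self, rng):
        values = rng.normal(size=(5, 6))
        fractions = [1, 2, 3, 8, 13]
        fit = enal_fit(fractions, values)
        for axis in range(6):
            single = enal_fit(fractions, values[:, axis])
            assert fit.S_k[axis] == pytest.approx(single.S_k.item(), abs=1e-12)
            assert fit.a_k[axis] == pytest.approx(single.a_k.item(), abs=1e-12)


class TestEnalCorrection:
    def test_formula(self):
        from setupcorr.protocols import FitResult

        fit = FitResult(S_k=np.array([0.5]), a_k=np.array([0.1]), f_k=8, n_points=4)
        assert enal_correction(fit) == pytest.approx(-1.3)

    def test_zero_slope_reduces_to_running_mean(self):
        fit = enal_fit([1, 2, 3], [1.0, 2.0, 0.0])
        fit_no_slope = type(fit)(S_k=np.atleast_1d(np.mean([1.0, 2.0, 0.0])),
                                 a_k=np.zeros(1), f_k=3, n_points=3)
        assert enal_correction(fit_no_slope) == pytest.approx(-1.0)


class TestApplyPolicy:
    def test_none_is_identity(self, constant_course):
        rc = apply_policy(constant_course, CorrectionPolicy("none"))
        np.testing.assert_array_equal(rc.residuals, constant_course.error_matrix())
        assert rc.n_cbct == 0
        assert not rc.online_corrected.any()

    def test_online_noiseless_is_zero(self, constant_course):
        rc = apply_policy(constant_course, CorrectionPolicy("online"))
        np.testing.assert_array_equal(rc.residuals, np.zeros((30, 6)))
        assert rc.n_cbct == 30
        assert rc.online_corrected.all()

    def test_nal_zeroes_constant_error_from_fraction_4(self, constant_course):
        rc = apply_policy(constant_course, CorrectionPolicy("nal"))
        np.testing.assert_array_equal(
            rc.residuals[:3], constant_course.error_matrix()[:3]
        )
        np.testing.assert_allclose(rc.residuals[3:], 0.0, atol=1e-12)

    def test_enal_zeroes_constant_error_from_fraction_4(self, constant_course):
        rc = apply_policy(constant_course, CorrectionPolicy("enal"))
        np.testing.assert_array_equal(
            rc.residuals[:3], constant_course.error_matrix()[:3]
        )
        np.testing.assert_allclose(rc.residuals[3:], 0.0, atol=1e-12)

    def test_enal_pp_zeroes_constant_error_everywhere(self, constant_course):
        rc = apply_policy(constant_course, CorrectionPolicy("enal_pp"))
        np.testing.assert_allclose(rc.residuals, 0.0, atol=1e-12)

    def test_enal_pp_flags_on_30_fractions(self, constant_course):
        rc = apply_policy(constant_course, CorrectionPolicy("enal_pp"))
        assert int(rc.online_corrected.sum()) == 8
        assert int((~rc.online_corrected).sum()) == 22
        np.testing.assert_array_equal(rc.imaged, rc.online_corrected)

    def test_enal_trend_residuals(self, trend_course):
        # pure trend e_f = 0.1 f: NAL-style initial mean leaves 0.1 (f - 2)
        # over (3, 8]; after the f_k = 8 follow-up the exact fit leaves
        # 0.1 (f - f_k) in each later interval
        rc = apply_policy(trend_course, CorrectionPolicy("enal"))
        f = np.arange(1, 31)
        pitch = rc.residuals[:, 3]
        np.testing.assert_allclose(pitch[3:8], 0.1 * (f[3:8] - 2), atol=1e-10)
        for f_k, f_next in [(8, 13), (13, 18), (18, 23), (23, 28)]:
            span = slice(f_k, f_next)
            np.testing.assert_allclose(
                pitch[span], 0.1 * (f[span] - f_k), atol=1e-10
            )

    def test_enal_trend_residuals_initial_fit(self, trend_course):
        # with initial_fit the 3-point fit is exact, so every interval
        # (f_k, f_{k+1}] leaves 0.1 (f - f_k)
        rc = apply_policy(trend_course, CorrectionPolicy("enal", initial_fit=True))
        f = np.arange(1, 31)
        pitch = rc.residuals[:, 3]
        for f_k, f_next in [(3, 8), (8, 13), (13, 18), (18, 23), (23, 28)]:
            span = slice(f_k, f_next)
            np.testing.assert_allclose(
                pitch[span], 0.1 * (f[span] - f_k), atol=1e-10
            )

    def test_measured_fraction_uses_previous_correction(self, trend_course):
        # at follow-up fraction 8 the correction in force still comes from
        # the initial block: measurements inform later fractions only
        rc = apply_policy(trend_course, CorrectionPolicy("enal"))
        assert rc.residuals[7, 3] == pytest.approx(0.1 * (8 - 2), abs=1e-10)

    def test_correction_clipped_to_couch_limit(self):
        matrix = np.zeros((30, 6))
        matrix[:, 3] = 5.0  # systematic pitch beyond the 3 deg couch limit
        course = make_course(matrix)
        rc = apply_policy(course, CorrectionPolicy("nal"))
        assert np.abs(rc.corrections[:, 3:]).max() <= 3.0
        assert rc.residuals[5, 3] == pytest.approx(2.0)

    def test_clipping_disabled(self):
        matrix = np.zeros((30, 6))
        matrix[:, 3] = 5.0
        course = make_course(matrix)
        rc = apply_policy(course, CorrectionPolicy("nal", clip_enabled=False))
        assert rc.residuals[5, 3] == pytest.approx(0.0, abs=1e-12)

    def test_translations_never_clipped(self):
        matrix = np.zeros((30, 6))
        matrix[:, 0] = 25.0
        course = make_course(matrix)
        rc = apply_policy(course, CorrectionPolicy("nal"))
        assert rc.residuals[10, 0] == pytest.approx(0.0, abs=1e-12)

    def test_course_too_short(self):
        course = make_course(np.zeros((2, 6)))
        with pytest.raises(ValueError, match="shorter than nal_length"):
            apply_policy(course, CorrectionPolicy("nal"))

    def test_negative_noise_sd_rejected(self, constant_course, rng):
        with pytest.raises(ValueError, match="non-negative"):
            apply_policy(
                constant_course, CorrectionPolicy("online"), online_sd=-0.1, rng=rng
            )

    def test_noise_without_rng_rejected(self, constant_course):
        with pytest.raises(ValueError, match="rng"):
            apply_policy(constant_course, CorrectionPolicy("online"), online_sd=0.2)

    def test_online_noise_bit_reproducible(self, constant_course):
        policy = CorrectionPolicy("enal_pp")
        a = apply_policy(constant_course, policy, online_sd=0.2,
                         rng=np.random.default_rng(7))
        b = apply_policy(constant_course, policy, online_sd=0.2,
                         rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.residuals, b.residuals)

    def test_n_cbct_matches_imaged_flags(self, constant_course):
        for name in ("none", "nal", "enal", "enal_pp", "online"):
            rc = apply_policy(constant_course, CorrectionPolicy(name))
            assert rc.n_cbct == int(rc.imaged.sum())

    @given(st.integers(min_value=3, max_value=45))
    @settings(max_examples=20, deadline=None)
    def test_clipping_bound_property(self, n):
        rng = np.random.default_rng(n)
        course = make_course(rng.normal(0, 4.0, size=(n, 6)))
        for name in ("nal", "enal", "enal_pp"):
            rc = apply_policy(course, CorrectionPolicy(name))
            assert np.abs(rc.corrections[:, 3:]).max() <= 3.0 + 1e-12


class TestWorkload:
    def test_enal_pp_reduction(self):
        n_cbct, reduction = workload(CorrectionPolicy("enal_pp"), 30)
        assert n_cbct == 8
        assert reduction == pytest.approx(100 * 22 / 30)
        assert reduction >= 70.0

    def test_online_no_reduction(self):
        assert workload(CorrectionPolicy("online"), 30) == (30, 0.0)

    def test_nal_90_percent(self):
        n_cbct, reduction = workload(CorrectionPolicy("nal"), 30)
        assert n_cbct == 3
        assert reduction == pytest.approx(90.0)

    @given(st.integers(min_value=1, max_value=80))
    def test_enal_and_enal_pp_workload_equal(self, n):
        assert workload(CorrectionPolicy("enal"), n) == workload(
            CorrectionPolicy("enal_pp"), n
        )
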