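"""Calibrant-based linear session correction, MRE and residual screening."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from cimpass import (
    AffineMap,
    LinearDriftCorrector,
    SessionDrift,
    apply_correction,
    fit_correction_line,
    group_self_correction,
    mean_relative_error,
    sample_compounds,
    screen_by_residual,
    session_values,
)


class TestFitLine:
    def test_exact_affine_recovery(self):
        measured = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        reference = 1.02 * measured - 0.5
        line = fit_correction_line(zip(measured, reference), quantity="tp")
        assert line.slope == pytest.approx(1.02)
        assert line.intercept == pytest.approx(-0.5)
        assert line.r2 == pytest.approx(1.0)

    def test_one_pair_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_correction_line([(10.0, 10.2)])

    def test_degenerate_measured_values(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_correction_line([(10.0, 10.2), (10.0, 10.4)])

    def test_quantities_validated(self):
        with pytest.raises(ValueError, match="quantity"):
            fit_correction_line([(10.0, 10.2), (11.0, 11.3)], quantity="ccs")

    def test_noisy_calibrants_recover_slope_within_three_se(self, rng):
        """5 calibrants at 0.05% noise: slope unbiased, R^2 essentially 1."""
        true = AffineMap(0.97, 0.1)
        tp = np.linspace(10, 14, 5)
        slopes, r2s = [], []
        for _ in range(100):
            measured = tp * (1 + rng.normal(0, 5e-4, 5))
            reference = true(tp) * (1 + rng.normal(0, 5e-4, 5))
            # direction: map the drifted session back to the reference -> slope ~ 1/0.97
            line = fit_correction_line(zip(reference, measured))
            slopes.append(line.slope)
            r2s.append(line.r2)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - 1 / 0.97) < 3 * se
        assert np.mean(r2s) > 0.9999


class TestApply:
    def test_identity_line_is_a_no_op(self):
        line = fit_correction_line([(10.0, 10.0), (12.0, 12.0), (14.0, 14.0)])
        values = np.array([10.5, 11.5, 13.2])
        assert apply_correction(line, values) == pytest.approx(values)

    def test_inverse_map_round_trip(self):
        est = LinearDriftCorrector().fit([10.0, 12.0, 14.0], [10.3, 12.5, 14.7])
        values = np.array([10.1, 13.9])
        assert est.transform(est.inverse_transform(values)) == pytest.approx(values, rel=1e-12)

    def test_order_preserved_and_monotone(self):
        line = fit_correction_line([(10.0, 10.4), (14.0, 14.9)])
        values = np.array([11.0, 12.0, 13.0])
        out = apply_correction(line, values)
        assert np.all(np.diff(out) > 0)

    def test_analytes_under_shared_drift_correct_below_0p2_pct(self, rng):
        """Analytes sharing the calibrants' affine drift: post-correction MRE < 0.2%."""
        compounds = sample_compounds(20, rng=rng)
        drift = SessionDrift(tp_map=AffineMap(0.97, 0.1), t0_map=AffineMap(0.99, 0.05),
                             noise_cv=5e-4)
        ref = session_values(compounds, SessionDrift.identity(noise_cv=5e-4), rng)
        meas = session_values(compounds, drift, rng)
        line = fit_correction_line(zip(meas["tp"][:5], ref["tp"][:5]))
        corrected = apply_correction(line, meas["tp"][5:].to_numpy())
        assert mean_relative_error(corrected, ref["tp"][5:]) < 0.2


class TestMeanRelativeError:
    @pytest.mark.parametrize(
        "value, reference, expected",
        [
            (117.01, 114.32, 2.35),  # precorrection arrival-time offsets of the
            (111.65, 109.22, 2.22),  # two isomeric lysolipids vs their database values
        ],
    )
    def test_worked_examples(self, value, reference, expected):
        assert mean_relative_error([value], [reference]) == pytest.approx(expected, abs=0.005)

    def test_zero_when_equal(self):
        assert mean_relative_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mean_relative_error([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero reference"):
            mean_relative_error([1.0], [0.0])

    @given(st.floats(0.01, 100))
    def test_invariant_under_common_rescaling(self, scale):
        v = np.array([10.3, 11.9, 14.2])
        r = np.array([10.0, 12.0, 14.0])
        assert mean_relative_error(v * scale, r * scale) == pytest.approx(
            mean_relative_error(v, r), rel=1e-9
        )


class TestScreening:
    def test_flags_above_threshold_only(self):
        results = screen_by_residual([0.1, 0.2, 1.5], threshold=0.7)
        assert [r.class_flag for r in results] == ["in-class", "in-class", "out-of-class"]

    def test_none_flagged_when_all_below(self):
        assert all(
            r.class_flag == "in-class" for r in screen_by_residual([0.1, 0.7], threshold=0.7)
        )

    def test_exactly_at_threshold_stays_in_class(self):
        # strict inequality
        assert screen_by_residual([0.7], threshold=0.7)[0].class_flag == "in-class"

    def test_two_class_drift_recovers_labels(self, rng):
        """Features on a second affine map are exactly the flagged set."""
        lipids = sample_compounds(12, rng=rng, prefix="LIP", class_tag="lipid")
        nonlipids = sample_compounds(
            6, rng=rng, prefix="NL", class_tag="nonlipid", mz_start=1000.0
        )
        drift = SessionDrift(
            tp_map=AffineMap(0.97, 0.1),
            t0_map=AffineMap(0.99, 0.05),
            noise_cv=5e-4,
            class_maps={"nonlipid": (AffineMap(0.90, 0.3), AffineMap(0.97, 0.1))},
        )
        all_cpds = lipids + nonlipids
        ref = session_values(all_cpds, SessionDrift.identity(noise_cv=5e-4), rng)
        meas = session_values(all_cpds, drift, rng)
        lipid_cal = ref["class_tag"] == "lipid"
        line = fit_correction_line(
            zip(meas["tp"][lipid_cal][:5], ref["tp"][lipid_cal][:5])
        )
        corrected = apply_correction(line, meas["tp"].to_numpy())
        residuals = 100 * np.abs(corrected - ref["tp"]) / ref["tp"]
        results = screen_by_residual(residuals, threshold=0.7, feature_ids=ref["name"])
        flagged = {r.feature_id for r in results if r.class_flag == "out-of-class"}
        assert flagged == set(ref.loc[ref["class_tag"] == "nonlipid", "name"])

    def test_group_self_correction_beats_cross_class_line(self, rng):
        """Flagged features refit among themselves correct far better."""
        nonlipids = sample_compounds(6, rng=rng, class_tag="nonlipid")
        drift = SessionDrift(tp_map=AffineMap(0.90, 0.3), t0_map=AffineMap(1, 0), noise_cv=5e-4)
        ref = session_values(nonlipids, SessionDrift.identity(noise_cv=5e-4), rng)
        meas = session_values(nonlipids, drift, rng)
        cross_line = fit_correction_line([(10.0, 10.0 / 0.97), (14.0, 14.0 / 0.97)])
        cross_mre = mean_relative_error(
            apply_correction(cross_line, meas["tp"].to_numpy()), ref["tp"]
        )
        group = group_self_correction(zip(meas["tp"], ref["tp"]))
        assert group.mre_pct < cross_mre

    def test_group_self_correction_exact_map_gives_zero(self):
        measured = np.array([10.0, 11.0, 13.0])
        group = group_self_correction(zip(measured, 0.9 * measured + 0.3))
        assert group.mre_pct == pytest.approx(0.0, abs=1e-10)

    def test_single_flagged_feature_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_self_correction([(10.0, 10.3)])


class TestEstimatorContract:
    def test_clone_and_params(self):
        est = LinearDriftCorrector(quantity="t0")
        assert clone(est).get_params() == {"quantity": "t0"}

    def test_unfitted_transform_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            LinearDriftCorrector().transform([1.0])

    def test_self_consistency_on_calibrants(self):
        """Correcting calibrants with their own line reproduces the fit residuals."""
        measured = np.array([10.0, 11.1, 12.0, 13.2, 14.0])
        reference = 1.03 * measured - 0.2 + np.array([0.01, -0.02, 0.0, 0.02, -0.01])
        est = LinearDriftCorrector().fit(measured, reference)
        resid = 100 * np.abs(est.transform(measured) - reference) / reference
        assert resid == pytest.approx(est.calibrant_residuals_pct_)

    @pytest.mark.parametrize("noise_cv", [0.0, 1e-4, 5e-4])
    def test_post_correction_mre_vanishes_with_noise(self, noise_cv, rng):
        compounds = sample_compounds(10, rng=rng)
        drift = SessionDrift(tp_map=AffineMap(0.96, 0.2), t0_map=AffineMap(1, 0),
                             noise_cv=noise_cv)
        ref = session_values(compounds, SessionDrift.identity(noise_cv=noise_cv), rng)
        meas = session_values(compounds, drift, rng)
        est = LinearDriftCorrector().fit(meas["tp"], ref["tp"])
        mre = mean_relative_error(est.transform(meas["tp"]), ref["tp"])
        assert mre <= 4 * 100 * noise_cv + 1e-9
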