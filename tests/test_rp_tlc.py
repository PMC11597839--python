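"""Retention-to-lipophilicity chain: Rf, the Bate-Smith-Westall transform,
replicate averaging, R_M0 extrapolation, calibration and the full pipeline,
checked against closed-form oracles and the printed standards panel."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromlip import (
    CalibrationModel,
    apply_calibration,
    average_replicates,
    fit_calibration,
    fit_retention_series,
    retardation_factor,
    rm_value,
    round_half_up,
    run_pipeline,
    simulate_tlc,
    TlcSimSpec,
)
from chromlip.rp_tlc import RetentionSeries, validate_plates
from chromlip.errors import (
    DegenerateDesignError,
    InputError,
    InsufficientDataError,
    InvalidSpotError,
)

# printed calibration of the reference experiment
PRINTED_MODEL = CalibrationModel(
    slope=1.0587, intercept=-0.0267, r=0.989, n_standards=7, residual_sd=float("nan")
)


def ols_oracle(x, y):
    """Normal-equations simple regression, independent of scipy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    sxy = ((x - xb) * (y - yb)).sum()
    syy = ((y - yb) ** 2).sum()
    slope = sxy / sxx
    intercept = yb - slope * xb
    r = sxy / math.sqrt(sxx * syy)
    return slope, intercept, r


class TestRetardationFactor:
    def test_midpoint_and_tenth(self):
        assert retardation_factor(4.0, 8.0) == 0.5
        assert retardation_factor(1.0, 10.0) == pytest.approx(0.1)

    @pytest.mark.parametrize("d,front", [(8.0, 8.0), (0.0, 8.0), (9.0, 8.0), (-1.0, 8.0)])
    def test_unusable_spots_raise(self, d, front):
        with pytest.raises(InvalidSpotError):
            retardation_factor(d, front)


class TestRmValue:
    def test_symmetry_point(self):
        assert rm_value(0.5) == 0.0

    def test_closed_form(self):
        assert rm_value(0.1) == pytest.approx(math.log10(9), abs=1e-12)
        assert round(rm_value(0.1), 4) == 0.9542
        assert round(rm_value(0.9), 4) == -0.9542

    @pytest.mark.parametrize("rf", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, rf):
        with pytest.raises(InvalidSpotError):
            rm_value(rf)

    @given(st.floats(min_value=1e-3, max_value=1 - 1e-3))
    @settings(derandomize=True, deadline=None)
    def test_antisymmetry(self, rf):
        assert rm_value(rf) == pytest.approx(-rm_value(1 - rf), abs=1e-9)

    @given(
        st.floats(min_value=1e-3, max_value=1 - 2e-3),
        st.floats(min_value=1e-3, max_value=1e-2),
    )
    @settings(derandomize=True, deadline=None)
    def test_strictly_decreasing(self, rf, step):
        if rf + step < 1:
            assert rm_value(rf + step) < rm_value(rf)


def _plate_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "role",
            "organic_fraction",
            "replicate",
            "d_compound_cm",
            "d_front_cm",
        ],
    )


class TestAverageReplicates:
    def test_rf_scale_averaging_before_transform(self):
        rows = [
            ("x", "test", 0.5, i + 1, rf * 10.0, 10.0)
            for i, rf in enumerate([0.48, 0.50, 0.52])
        ]
        series = average_replicates(_plate_df(rows), "x")
        assert series.phi == (0.5,)
        assert series.r_m[0] == pytest.approx(0.0, abs=1e-12)
        assert series.n_replicates == (3,)

    def test_rm_scale_averaging_differs(self):
        # the transform is nonlinear, so the two orders disagree off-centre
        rows = [
            ("x", "test", 0.5, i + 1, rf * 10.0, 10.0)
            for i, rf in enumerate([0.2, 0.4, 0.6])
        ]
        df = _plate_df(rows)
        rf_avg = average_replicates(df, "x", average_on="rf").r_m[0]
        rm_avg = average_replicates(df, "x", average_on="rm").r_m[0]
        assert rf_avg != pytest.approx(rm_avg, abs=1e-6)
        assert rf_avg == pytest.approx(rm_value(0.4), abs=1e-12)

    def test_single_replicate_passthrough(self):
        series = average_replicates(_plate_df([("x", "test", 0.4, 1, 3.0, 10.0)]), "x")
        assert series.r_m[0] == pytest.approx(rm_value(0.3), abs=1e-12)

    def test_five_phase_three_replicate_design(self):
        plates, _ = simulate_tlc(TlcSimSpec(seed=3, noise_sd_cm=0.0, n_tests=1))
        cid = plates.query("role == 'test'")["compound_id"].iloc[0]
        series = average_replicates(plates, cid)
        assert len(series.phi) >= 3
        assert all(n == 3 for n in series.n_replicates)

    def test_unknown_compound_is_input_error(self):
        with pytest.raises(InputError):
            average_replicates(_plate_df([("x", "test", 0.4, 1, 3.0, 10.0)]), "y")


class TestFitRetentionSeries:
    def test_exact_line(self):
        series = RetentionSeries("x", (0.4, 0.5, 0.6), (-0.8, -1.1, -1.4), (1, 1, 1))
        fit = fit_retention_series(series)
        assert fit.r_m0 == pytest.approx(0.4, abs=1e-12)
        assert fit.b == pytest.approx(-3.0, abs=1e-12)
        assert fit.r == pytest.approx(-1.0, abs=1e-12)

    def test_noiseless_simulated_compound_recovered_exactly(self):
        r_m0, b = 2.0, -4.0
        phi = (0.4, 0.5, 0.6, 0.7, 0.8)
        series = RetentionSeries("x", phi, tuple(r_m0 + b * p for p in phi), (1,) * 5)
        fit = fit_retention_series(series)
        assert fit.r_m0 == pytest.approx(r_m0, abs=1e-12)
        assert fit.b == pytest.approx(b, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            phi = np.sort(rng.uniform(0.2, 0.9, rng.integers(3, 8)))
            phi += np.arange(len(phi)) * 1e-6  # ensure distinct
            rm = rng.normal(1.5, 1.0) + rng.normal(-4, 1) * phi + rng.normal(0, 0.05, len(phi))
            fit = fit_retention_series(
                RetentionSeries("x", tuple(phi), tuple(rm), (1,) * len(phi))
            )
            slope, intercept, r = ols_oracle(phi, rm)
            assert fit.b == pytest.approx(slope, abs=1e-10)
            assert fit.r_m0 == pytest.approx(intercept, abs=1e-10)
            assert fit.r == pytest.approx(r, abs=1e-10)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_retention_series(RetentionSeries("x", (0.4, 0.5), (0.1, 0.2), (1, 1)))

    def test_degenerate_design(self):
        series = RetentionSeries.__new__(RetentionSeries)
        object.__setattr__(series, "compound_id", "x")
        object.__setattr__(series, "phi", (0.5, 0.5, 0.5))
        object.__setattr__(series, "r_m", (0.1, 0.2, 0.3))
        object.__setattr__(series, "n_replicates", (1, 1, 1))
        with pytest.raises(DegenerateDesignError):
            fit_retention_series(series)


class TestCalibration:
    def test_perfect_identity_line(self):
        pairs = [(x, x) for x in (0.5, 1.5, 2.5, 3.5)]
        model = fit_calibration(pairs)
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.r == pytest.approx(1.0, abs=1e-12)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_six_unflagged_standards(self, standards):
        clean = standards[standards["flagged"] == 0]
        model = fit_calibration(list(zip(clean["logp_lit"], clean["r_m0"])))
        slope, intercept, r = ols_oracle(clean["r_m0"], clean["logp_lit"])
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)
        # frozen oracle values: the clean panel supports ~1.05 x - 0.01
        assert model.slope == pytest.approx(1.0539, abs=1e-4)
        assert model.intercept == pytest.approx(-0.0099, abs=1e-4)

    def test_all_seven_standards_do_not_reproduce_printed_slope(self, standards):
        model = fit_calibration(list(zip(standards["logp_lit"], standards["r_m0"])))
        # frozen oracle value on the seven printed pairs; the flagged
        # benzamide row pulls the slope off the printed 1.0587
        assert model.slope == pytest.approx(1.0992, abs=1e-4)
        assert abs(model.slope - PRINTED_MODEL.slope) > 0.03

    def test_too_few_standards(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([(1.0, 1.0), (2.0, 2.0)])

    def test_duplicate_r_m0_warns_but_fits(self):
        with pytest.warns(UserWarning, match="duplicate"):
            model = fit_calibration([(1.0, 1.0), (1.2, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert np.isfinite(model.slope)


class TestApplyCalibration:
    @pytest.mark.parametrize(
        "r_m0,expected",
        [(1.2020, 1.25), (1.6729, 1.74), (3.9213, 4.12), (4.8432, 5.10), (2.7252, 2.86)],
    )
    def test_printed_model_reproduces_reported_standards(self, r_m0, expected):
        assert round_half_up(apply_calibration(PRINTED_MODEL, r_m0), 2) == expected

    def test_flagged_benzamide_row_is_inconsistent(self, standards):
        row = standards[standards["flagged"] == 1].iloc[0]
        predicted = round_half_up(apply_calibration(PRINTED_MODEL, row["r_m0"]), 2)
        assert predicted == 0.98
        assert predicted != row["logp_tlc_reported"]

    def test_identity_model(self):
        identity = CalibrationModel(1.0, 0.0, 1.0, 3, 0.0)
        assert apply_calibration(identity, 2.5) == 2.5


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "value,expected", [(1.245, 1.25), (1.244, 1.24), (-1.245, -1.25), (2.675, 2.68)]
    )
    def test_half_up_convention(self, value, expected):
        assert round_half_up(value, 2) == expected


class TestPipeline:
    def _run(self, seed=0, noise=0.0, **kwargs):
        plates, truth = simulate_tlc(TlcSimSpec(seed=seed, noise_sd_cm=noise, **kwargs))
        std = (
            truth.per_compound.query("role == 'standard'")[["compound_id", "logp"]]
            .rename(columns={"logp": "logp_lit"})
        )
        return plates, truth, run_pipeline(plates, std)

    def test_zero_noise_recovers_generating_truth_exactly(self):
        plates, truth, report = self._run(seed=11)
        tests = truth.per_compound.query("role == 'test'").set_index("compound_id")
        for res in report.results:
            assert res.logp_tlc == pytest.approx(tests.loc[res.compound_id, "logp"], abs=1e-9)
            assert res.r_m0 == pytest.approx(tests.loc[res.compound_id, "r_m0"], abs=1e-9)
            assert res.b == pytest.approx(tests.loc[res.compound_id, "b"], abs=1e-9)
        assert report.calibration.slope == pytest.approx(1.0587, abs=1e-9)
        assert report.calibration.intercept == pytest.approx(-0.0267, abs=1e-9)

    def test_noise_keeps_mean_logp_error_small(self):
        plates, truth, report = self._run(seed=5, noise=0.02)
        tests = truth.per_compound.query("role == 'test'").set_index("compound_id")
        errs = [abs(r.logp_tlc - tests.loc[r.compound_id, "logp"]) for r in report.results]
        assert np.mean(errs) < 0.1

    def test_shift_equivariance(self):
        # adding a constant to every literature logP shifts every
        # prediction by that constant
        plates, truth, report = self._run(seed=7)
        std = (
            truth.per_compound.query("role == 'standard'")[["compound_id", "logp"]]
            .rename(columns={"logp": "logp_lit"})
        )
        shifted = std.assign(logp_lit=std["logp_lit"] + 1.7)
        shifted_report = run_pipeline(plates, shifted)
        for a, b in zip(report.results, shifted_report.results):
            assert b.logp_tlc - a.logp_tlc == pytest.approx(1.7, abs=1e-9)

    def test_scale_invariance_of_distances(self):
        # Rf is a ratio: re-measuring the same plate in different units
        # changes nothing
        plates, truth, report = self._run(seed=9)
        std = (
            truth.per_compound.query("role == 'standard'")[["compound_id", "logp"]]
            .rename(columns={"logp": "logp_lit"})
        )
        scaled = plates.assign(
            d_compound_cm=plates["d_compound_cm"] * 3.7,
            d_front_cm=plates["d_front_cm"] * 3.7,
        )
        scaled_report = run_pipeline(scaled, std)
        for a, b in zip(report.results, scaled_report.results):
            assert b.logp_tlc == pytest.approx(a.logp_tlc, abs=1e-9)

    def test_unfittable_compound_is_reported_not_dropped(self):
        plates, truth, _ = self._run(seed=13)
        std = (
            truth.per_compound.query("role == 'standard'")[["compound_id", "logp"]]
            .rename(columns={"logp": "logp_lit"})
        )
        # cripple one test compound to two phases
        victim = plates.query("role == 'test'")["compound_id"].iloc[0]
        keep_phi = sorted(plates["organic_fraction"].unique())[:2]
        mask = (plates["compound_id"] != victim) | plates["organic_fraction"].isin(keep_phi)
        report = run_pipeline(plates[mask], std)
        assert victim in [cid for cid, _ in report.excluded]
        assert victim not in [r.compound_id for r in report.results]

    def test_conflicting_roles_rejected(self):
        rows = [
            ("x", "standard", 0.4, 1, 3.0, 10.0),
            ("x", "test", 0.5, 1, 3.0, 10.0),
        ]
        with pytest.raises(InputError, match="conflicting roles"):
            validate_plates(_plate_df(rows))

    def test_percent_fractions_normalised_with_warning(self):
        rows = [("x", "test", 40.0, 1, 3.0, 10.0)]
        with pytest.warns(UserWarning, match="percent"):
            valid, _ = validate_plates(_plate_df(rows))
        assert valid["organic_fraction"].iloc[0] == pytest.approx(0.4)

    def test_front_running_spot_flagged_not_clamped(self):
        rows = [
            ("x", "test", 0.4, 1, 10.0, 10.0),
            ("x", "test", 0.5, 1, 3.0, 10.0),
        ]
        valid, flagged = validate_plates(_plate_df(rows))
        assert len(flagged) == 1 and len(valid) == 1
        assert "front" in flagged["reason"].iloc[0]
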