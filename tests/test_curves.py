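"""Adjusted-prevalence curves, bands and landmark extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from omegadose.curves import (
    CurveSummary,
    adjusted_prevalence_curve,
    band_crossing,
    extract_landmarks,
    find_minimum,
    percentile_of,
    pooled_prevalence_curve,
)
from omegadose.gamm import fit_gamm


def make_curve(intake, prevalence, half_width=0.002):
    prevalence = np.asarray(prevalence, dtype=float)
    return CurveSummary(
        grid=pd.DataFrame(
            {
                "intake": np.asarray(intake, dtype=float),
                "percentile": np.linspace(0, 100, len(prevalence)),
                "prevalence": prevalence,
                "sem_lower": prevalence - half_width,
                "sem_upper": prevalence + half_width,
            }
        )
    )


def sim_fit(n=4000, f=lambda z: -1.5 + 0.4 * (z - 0.5) ** 2, seed=0, lam=5.0, covariate=False):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0.5, 0.6, n)
    z = np.log(x + 0.005)
    eta = f(z)
    cov = None
    if covariate:
        g = rng.choice(["a", "b"], size=n)
        eta = eta + 0.5 * (g == "b")
        cov = pd.DataFrame({"g": g})
    y = (rng.random(n) < expit(eta)).astype(float)
    fit = fit_gamm(z, y, cov, None, lam=lam, sigma2_u=0.0)
    return fit, x, y


class TestCurveSummary:
    def test_validation_rejects_unsorted_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            make_curve([2.0, 1.0, 3.0], [0.1, 0.1, 0.1])

    def test_validation_rejects_probabilities_outside_unit_interval(self):
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            make_curve([1.0, 2.0], [0.0, 0.5])

    def test_validation_rejects_band_not_bracketing(self):
        g = make_curve([1.0, 2.0], [0.1, 0.1]).grid.copy()
        g["sem_lower"] = [0.2, 0.2]
        with pytest.raises(ValueError, match="bracket"):
            CurveSummary(grid=g)

    def test_csv_round_trip(self, tmp_path):
        c = make_curve(np.linspace(1, 2, 5), np.full(5, 0.1))
        c.to_csv(tmp_path / "c.csv")
        back = pd.read_csv(tmp_path / "c.csv")
        pd.testing.assert_frame_equal(back, c.grid)


class TestPercentileOf:
    def test_below_all_is_zero_and_above_all_is_hundred(self):
        s = [1.0, 2.0, 3.0]
        assert percentile_of(s, 0.5) == 0.0
        assert percentile_of(s, 9.0) == 100.0

    def test_midrank_at_observed_value(self):
        # at the median of {1,2,3}: one below + half of one equal = 50%
        assert percentile_of([1.0, 2.0, 3.0], 2.0) == pytest.approx(50.0)

    def test_hand_worked_ten_point_sample(self):
        s = list(range(10))
        assert percentile_of(s, 4) == pytest.approx(100 * 4.5 / 10)
        assert percentile_of(s, 4.5) == pytest.approx(50.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percentile_of([], 1.0)


class TestAdjustedCurve:
    def test_null_model_gives_near_flat_curve_at_observed_prevalence(self):
        """With no exposure effect and heavy smoothing only a noise-level
        linear trend remains, and the curve level matches the observed
        prevalence."""
        fit, x, y = sim_fit(n=6000, f=lambda z: -1.6 + 0.0 * z, seed=1, lam=1e8)
        curve = adjusted_prevalence_curve(fit, x)
        prev = curve.grid["prevalence"].to_numpy()
        assert np.median(prev) == pytest.approx(y.mean(), abs=0.01)
        # residual tilt is sampling noise: well within +/-3 slope standard
        # errors, i.e. the logit range stays small relative to the band
        eta_rng = np.ptp(logit(prev))
        band = logit(curve.grid["sem_upper"]) - logit(curve.grid["sem_lower"])
        assert eta_rng < 3.0 * band.median()

    def test_grid_spans_requested_percentiles(self):
        fit, x, _ = sim_fit()
        curve = adjusted_prevalence_curve(fit, x, percentile_range=(1.0, 99.0))
        lo, hi = np.percentile(x, [1.0, 99.0])
        assert curve.grid["intake"].iloc[0] == pytest.approx(lo, rel=1e-12)
        assert curve.grid["intake"].iloc[-1] == pytest.approx(hi, rel=1e-12)
        assert len(curve.grid) == 200

    def test_logit_scale_point_matches_direct_enumeration(self):
        """Curve value equals expit of the sample-mean linear predictor."""
        fit, x, _ = sim_fit(covariate=True)
        curve = adjusted_prevalence_curve(fit, x, grid_size=10)
        for _, row in curve.grid.iloc[[0, 4, 9]].iterrows():
            z = np.log(row["intake"] + 0.005)
            eta = fit.row_offsets + fit.spline_values([z])[0]
            assert row["prevalence"] == pytest.approx(expit(eta.mean()), rel=1e-9)

    def test_response_scale_point_matches_direct_enumeration(self):
        fit, x, _ = sim_fit(covariate=True)
        curve = adjusted_prevalence_curve(fit, x, grid_size=10, scale="response")
        for _, row in curve.grid.iloc[[0, 5, 9]].iterrows():
            z = np.log(row["intake"] + 0.005)
            eta = fit.row_offsets + fit.spline_values([z])[0]
            assert row["prevalence"] == pytest.approx(expit(eta).mean(), rel=1e-9)

    def test_band_width_shrinks_with_sample_size(self):
        widths = []
        for n in (2000, 8000, 32000):
            fit, x, _ = sim_fit(n=n, seed=2, lam=50.0)
            curve = adjusted_prevalence_curve(fit, x)
            g = curve.grid
            widths.append(np.median(g["sem_upper"] - g["sem_lower"]))
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): a factor 16 in n gives a factor ~4 in width
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.4)

    def test_band_coverage_is_near_one_sigma(self):
        """The true curve lands inside the +/-1 SEM band roughly 68% of the time."""
        f = lambda z: -1.6 + 0.4 * (z - 0.5) ** 2
        inside = 0
        reps = 100
        for rep in range(reps):
            fit, x, _ = sim_fit(n=4000, f=f, seed=300 + rep, lam=5.0)
            curve = adjusted_prevalence_curve(fit, x, grid_size=31)
            row = curve.grid.iloc[15]
            truth = expit(f(np.log(row["intake"] + 0.005)))
            inside += row["sem_lower"] <= truth <= row["sem_upper"]
        assert 0.55 <= inside / reps <= 0.85

    def test_invalid_scale_and_range_rejected(self):
        fit, x, _ = sim_fit()
        with pytest.raises(ValueError, match="scale"):
            adjusted_prevalence_curve(fit, x, scale="probit")
        with pytest.raises(ValueError, match="percentile"):
            adjusted_prevalence_curve(fit, x, percentile_range=(50.0, 10.0))


class TestPooling:
    def test_identical_curves_pool_to_themselves(self):
        c = make_curve(np.linspace(1, 2, 8), np.linspace(0.10, 0.12, 8))
        pooled = pooled_prevalence_curve([c, c, c])
        np.testing.assert_allclose(
            pooled.grid["prevalence"], c.grid["prevalence"], rtol=1e-12
        )
        # no between-imputation variance: band width is unchanged
        np.testing.assert_allclose(
            logit(pooled.grid["sem_upper"]) - logit(pooled.grid["prevalence"]),
            logit(c.grid["sem_upper"]) - logit(c.grid["prevalence"]),
            rtol=1e-9,
        )

    def test_disagreement_widens_the_band(self):
        a = make_curve(np.linspace(1, 2, 8), np.full(8, 0.10))
        b = make_curve(np.linspace(1, 2, 8), np.full(8, 0.14))
        pooled = pooled_prevalence_curve([a, b])
        width_a = logit(a.grid["sem_upper"]) - logit(a.grid["sem_lower"])
        width_p = logit(pooled.grid["sem_upper"]) - logit(pooled.grid["sem_lower"])
        assert (width_p > width_a).all()

    def test_single_curve_passthrough_and_empty_rejected(self):
        c = make_curve([1.0, 2.0], [0.1, 0.1])
        assert pooled_prevalence_curve([c]) is c
        with pytest.raises(ValueError, match="at least one"):
            pooled_prevalence_curve([])


class TestLandmarks:
    def test_minimum_of_constructed_parabola(self):
        x = np.linspace(0.5, 5.0, 101)
        prev = 0.08 + 0.01 * (np.log(x) - np.log(2.2)) ** 2
        c = make_curve(x, prev)
        mv, ml = find_minimum(c)
        assert mv == pytest.approx(0.08, abs=1e-6)
        assert abs(ml - 2.2) <= np.diff(x).max()

    def test_monotone_curve_minimum_at_edge(self):
        c = make_curve([1.0, 2.0, 3.0], [0.10, 0.09, 0.08])
        assert find_minimum(c) == (0.08, 3.0)

    def test_tie_broken_toward_smaller_intake(self):
        c = make_curve([1.0, 2.0, 3.0], [0.08, 0.10, 0.08])
        assert find_minimum(c)[1] == 1.0

    def test_band_crossing_linear_interpolation(self):
        # upper limit rises from 0.100 at x=5.0 to 0.104 at x=5.4:
        # crossing of 0.101 sits a quarter of the way: x = 5.1
        c = make_curve([5.0, 5.4], [0.098, 0.102], half_width=0.002)
        loc = band_crossing(c, "upper", 0.101)
        assert loc == pytest.approx(5.1, abs=1e-9)

    def test_crossing_respects_start_location(self):
        x = [1.0, 2.0, 3.0, 4.0]
        c = make_curve(x, [0.10, 0.12, 0.10, 0.12])
        first = band_crossing(c, "upper", 0.11 + 0.002)
        later = band_crossing(c, "upper", 0.11 + 0.002, from_location=2.6)
        assert first < 2.0 < 2.6 < later

    def test_no_crossing_returns_none(self):
        c = make_curve([1.0, 2.0], [0.10, 0.10])
        assert band_crossing(c, "upper", 0.5) is None

    def test_invalid_arguments_rejected(self):
        c = make_curve([1.0, 2.0], [0.1, 0.1])
        with pytest.raises(ValueError, match="side"):
            band_crossing(c, "middle", 0.1)
        with pytest.raises(ValueError, match="reference"):
            band_crossing(c, "upper", 1.5)

    def test_extracted_landmarks_are_consistent(self):
        x = np.linspace(0.5, 5.0, 101)
        prev = 0.08 + 0.01 * (np.log(x) - np.log(2.2)) ** 2
        c = make_curve(x, prev)
        lm = extract_landmarks(c)
        assert lm.start_value == pytest.approx(prev[0])
        assert lm.min_value == pytest.approx(0.08, abs=1e-6)
        assert 0.0 <= lm.min_percentile <= 100.0
        assert len(lm.crossings) == 1
        cross = lm.crossings[0]
        if cross["location"] is not None:
            assert cross["location"] >= lm.min_location

    def test_landmarks_yaml_round_trip(self, tmp_path):
        import yaml

        c = make_curve(np.linspace(1, 3, 21), np.full(21, 0.1))
        c.landmarks = extract_landmarks(c)
        c.landmarks.to_yaml(tmp_path / "lm.yaml")
        with open(tmp_path / "lm.yaml") as fh:
            d = yaml.safe_load(fh)
        assert d["min_value"] == pytest.approx(0.1)
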