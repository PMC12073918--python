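"""Sample weights, median-matched splits, clock backends and age gaps."""

import numpy as np
import pandas as pd
import pytest

from organclock.clocks import (
    ClockSpec,
    MatchingError,
    OrganClock,
    OrganClockResults,
    abs_residual_slope,
    build_splits,
    compute_age_gaps,
    compute_sample_weights,
)

from conftest import make_participants


class TestSampleWeights:
    def test_zero_variance_ages_give_unit_weights(self):
        np.testing.assert_array_equal(compute_sample_weights(np.full(5, 50.0)), np.ones(5))

    def test_symmetry_about_the_mean(self):
        ages = np.array([40.0, 45.0, 55.0, 60.0])
        w = compute_sample_weights(ages)
        np.testing.assert_allclose(w, w[::-1])

    def test_distance_formula(self):
        """Pre-normalisation w = 1 + |a - mean|/sd, so the weight one sd
        from the mean is exactly twice the weight at the mean."""
        rng = np.random.default_rng(0)
        ages = rng.uniform(40, 70, 2000)
        mean, sd = ages.mean(), ages.std()
        w = compute_sample_weights(ages)
        at_mean = w[np.argmin(np.abs(ages - mean))]
        at_1sd = w[np.argmin(np.abs(ages - (mean + sd)))]
        assert at_1sd / at_mean == pytest.approx(2.0, abs=0.02)

    def test_positive_normalised_monotone(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(37, 73, 500)
        w = compute_sample_weights(ages)
        assert (w > 0).all()
        assert w.mean() == pytest.approx(1.0)
        dist = np.abs(ages - ages.mean())
        order = np.argsort(dist)
        assert (np.diff(w[order]) >= -1e-12).all()

    def test_invalid_ages_rejected(self):
        with pytest.raises(ValueError):
            compute_sample_weights(np.array([]))
        with pytest.raises(ValueError):
            compute_sample_weights(np.array([50.0, np.nan]))


def _status_frame(index, statuses):
    return pd.DataFrame({"status": statuses}, index=index)


class TestSplits:
    def _cohort(self, n=6000, seed=0, case_rate=0.04, older_cases=True):
        parts = make_participants(n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        p = case_rate * (1 + (parts["age"] - parts["age"].mean()) / 20) if older_cases else case_rate
        status = np.where(rng.uniform(size=n) < p, "incident", "control")
        return parts, _status_frame(parts.index, status)

    def test_cases_never_enter_either_pool(self):
        parts, status = self._cohort()
        splits = build_splits(parts, status, seed=1)
        cases = set(status.index[status["status"] == "incident"])
        assert not cases & set(splits["train"])
        assert not cases & set(splits["test"])
        assert len(splits["train"].intersection(splits["test"])) == 0

    def test_medians_match_cases_within_tolerance(self):
        parts, status = self._cohort(n=10_000)
        splits = build_splits(parts, status, seed=2)
        cases = status.index[status["status"] == "incident"]
        for var, tol in (("age", 0.5), ("bmi", 0.5), ("packyears", 1.0)):
            diff = abs(parts.loc[splits["test"], var].median() - parts.loc[cases, var].median())
            assert diff <= tol, var

    def test_unmatched_mode_is_simple_random_subset(self):
        parts, status = self._cohort()
        splits = build_splits(parts, status, match=False, seed=3)
        pool = status.index[status["status"] == "control"]
        assert len(splits["test"]) == round(0.214 * len(pool))
        assert len(splits["train"]) + len(splits["test"]) == len(pool)

    def test_infeasible_matching_names_variable(self):
        parts = make_participants(500, seed=5, age=np.full(500, 40.0))
        parts.loc[parts.index[:20], "age"] = 72.0
        status = _status_frame(
            parts.index, ["incident"] * 20 + ["control"] * 480
        )
        with pytest.raises(MatchingError, match="age"):
            build_splits(parts, status, seed=1)

    def test_unknown_and_prevalent_excluded_from_pools(self):
        parts, status = self._cohort()
        status.iloc[:500, 0] = "unknown"
        status.iloc[500:700, 0] = "prevalent"
        splits = build_splits(parts, status, seed=4)
        off_limits = set(status.index[status["status"].isin(["unknown", "prevalent"])])
        assert not off_limits & (set(splits["train"]) | set(splits["test"]))


def _linear_panel(n, seed=0, noise=0.0, slope=1.0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(37, 73, n)
    X = pd.DataFrame(
        {
            "m0": slope * age + rng.normal(0, noise, n),
            "m1": slope * age + rng.normal(0, noise, n),
        },
        index=pd.RangeIndex(n),
    )
    return X, pd.Series(age, index=X.index, name="age")


class TestRidgeBackend:
    def test_noise_free_marker_recovers_age(self):
        X, age = _linear_panel(2000, noise=0.0)
        res = OrganClock(X.iloc[:1500], age.iloc[:1500], spec=ClockSpec(ridge_alpha=1e-8)).fit()
        ev = res.evaluate(X.iloc[1500:], age.iloc[1500:])
        assert ev["r"] >= 0.999

    def test_permuted_labels_give_null_correlation(self):
        rng = np.random.default_rng(7)
        X, age = _linear_panel(10_000, noise=15.0)
        shuffled = pd.Series(rng.permutation(age.to_numpy()), index=age.index)
        res = OrganClock(X.iloc[:8000], shuffled.iloc[:8000]).fit()
        ev = res.evaluate(X.iloc[8000:], shuffled.iloc[8000:])
        assert abs(ev["r"]) < 0.05

    def test_weighted_mean_training_residual_near_zero(self):
        X, age = _linear_panel(4000, noise=20.0)
        w = compute_sample_weights(age.to_numpy())
        res = OrganClock(X, age, weights=w).fit()
        assert abs(res.weighted_train_residual) < 0.2

    def test_input_validation(self):
        X, age = _linear_panel(100)
        with pytest.raises(ValueError, match="rows"):
            OrganClock(X.iloc[:10], age.iloc[:10])
        bad = X.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            OrganClock(bad, age)

    def test_bias_correction_restores_latent_scale(self):
        """A planted shift attenuated by shrinkage reappears after the
        training-slope correction."""
        X, age = _linear_panel(12_000, seed=3, noise=40.0)
        res = OrganClock(X.iloc[:8000], age.iloc[:8000]).fit()
        assert res.bias_slope < 0.9  # visible shrinkage
        shift = 2.0
        shifted = X.iloc[8000:] + shift  # latent age moved by 2 years
        raw = res.predict(shifted).mean() - res.predict(X.iloc[8000:]).mean()
        corrected = (
            res.predict(shifted, correct_bias=True).mean()
            - res.predict(X.iloc[8000:], correct_bias=True).mean()
        )
        assert raw < 0.9 * shift
        assert corrected == pytest.approx(shift, rel=0.05)


class TestNetworkBackend:
    SPEC = ClockSpec(
        hidden_layer_sizes=(16, 8), epochs=150, patience=30, batch_size=64,
        backend="network", learning_rate=3e-3, dropout=0.1,
    )

    def test_learns_linear_signal(self):
        X, age = _linear_panel(800, seed=1, noise=3.0)
        res = OrganClock(X.iloc[:600], age.iloc[:600], spec=self.SPEC).fit(seed=0)
        ev = res.evaluate(X.iloc[600:], age.iloc[600:])
        assert ev["r"] > 0.9

    def test_deterministic_given_seed(self):
        X, age = _linear_panel(400, seed=2, noise=3.0)
        a = OrganClock(X, age, spec=self.SPEC).fit(seed=5)
        b = OrganClock(X, age, spec=self.SPEC).fit(seed=5)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_early_stopping_restores_best_weights(self):
        # tiny sample + capacity to overfit: validation loss must
        # deteriorate, triggering patience and the best-weight restore
        spec = ClockSpec(hidden_layer_sizes=(64, 32), epochs=400, patience=10,
                         batch_size=16, backend="network", dropout=0.0,
                         learning_rate=5e-3, min_rows=10)
        X, age = _linear_panel(60, seed=4, noise=8.0)
        res = OrganClock(X, age, spec=spec).fit(seed=1)
        assert res.epochs_run < spec.epochs
        assert res.restored_best

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            ClockSpec(validation_fraction=0.0)
        with pytest.raises(ValueError):
            ClockSpec(patience=300, epochs=200)
        with pytest.raises(ValueError):
            ClockSpec(backend="boosting")


def _constant_model(organ, value):
    return OrganClockResults(
        organ=organ, spec=ClockSpec(), predictor=lambda X: np.full(len(X), float(value)),
        train_age_mean=55.0, train_pred_mean=float(value), bias_slope=1.0,
    )


class TestAgeGaps:
    def _panels(self, organs, n=4):
        idx = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
        return {o: pd.DataFrame({"m0": np.zeros(n)}, index=idx) for o in organs}, idx

    def test_gap_is_predicted_minus_chronological(self):
        panels, idx = self._panels(["immune"])
        parts = pd.DataFrame({"age": np.full(len(idx), 62.86)}, index=idx)
        gaps = compute_age_gaps({"immune": _constant_model("immune", 56.63)}, panels, parts)
        np.testing.assert_allclose(gaps["immune"], -6.23, atol=1e-12)

    def test_identity_prediction_gives_zero_gaps(self):
        organs = ["immune", "hepatic"]
        panels, idx = self._panels(organs)
        parts = pd.DataFrame({"age": np.full(len(idx), 50.0)}, index=idx)
        models = {o: _constant_model(o, 50.0) for o in organs}
        gaps = compute_age_gaps(models, panels, parts)
        assert (gaps == 0).all().all()

    def test_composite_excludes_hepatic(self):
        organs = ["immune", "cardiovascular", "hepatic"]
        panels, idx = self._panels(organs)
        parts = pd.DataFrame({"age": np.full(len(idx), 50.0)}, index=idx)
        models = {o: _constant_model(o, 52.0) for o in organs}
        base = compute_age_gaps(models, panels, parts)
        models["hepatic"] = _constant_model("hepatic", 90.0)
        perturbed = compute_age_gaps(models, panels, parts)
        np.testing.assert_array_equal(base["composite"], perturbed["composite"])
        assert perturbed["hepatic"].iloc[0] == 40.0

    def test_missing_model_raises(self):
        panels, idx = self._panels(["immune", "renal"])
        parts = pd.DataFrame({"age": np.full(len(idx), 50.0)}, index=idx)
        with pytest.raises(KeyError, match="renal"):
            compute_age_gaps({"immune": _constant_model("immune", 50.0)}, panels, parts)


def test_distance_weights_flatten_residual_growth():
    """Shrinkage makes |residual| grow with age distance; distance weights
    reduce that growth on the same cohort and seed."""
    rng = np.random.default_rng(11)
    n = 12_000
    age = rng.uniform(37, 73, n)
    X = pd.DataFrame({f"m{j}": age + rng.normal(0, 25, n) for j in range(5)})
    ages = pd.Series(age)
    half = n // 2
    weighted = OrganClock(X.iloc[:half], ages.iloc[:half],
                          weights=compute_sample_weights(age[:half])).fit()
    uniform = OrganClock(X.iloc[:half], ages.iloc[:half]).fit()
    slope_w = abs_residual_slope(weighted.predict(X.iloc[half:]), age[half:])
    slope_u = abs_residual_slope(uniform.predict(X.iloc[half:]), age[half:])
    assert slope_u > 0  # heteroskedasticity present at all
    assert slope_w < slope_u
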