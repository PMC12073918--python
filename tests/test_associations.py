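"""Association designs: estimands, strata, invariants, degenerate inputs."""

import numpy as np
import pandas as pd
import pytest

from organclock.associations import (
    AssociationError,
    AssociationSuite,
    fit_age_gap_model,
    fit_grs_ageing_model,
    fit_joint_organ_model,
    fit_risk_factor_model,
    run_stratified_suite,
)

from conftest import make_participants

ORGANS7 = ("cardiovascular", "pulmonary", "musculoskeletal", "metabolic", "immune", "renal", "hepatic")


def _status(index, case_mask):
    return pd.DataFrame(
        {"status": np.where(case_mask, "incident", "control")}, index=index
    )


def _gap_table(parts, rng, organs=ORGANS7, case=None, effect=None, shared_sd=0.0):
    shared = rng.normal(0, shared_sd, len(parts)) if shared_sd else 0.0
    gaps = pd.DataFrame(index=parts.index)
    for organ in organs:
        gaps[organ] = rng.normal(0, 3, len(parts)) + shared
    if case is not None and effect:
        for organ, delta in effect.items():
            gaps[organ] += delta * case
    gaps["composite"] = gaps[list(organs)[:-1]].mean(axis=1)
    return gaps


class TestAgeGapModel:
    def test_unadjusted_estimate_equals_raw_mean_difference(self):
        rng = np.random.default_rng(0)
        parts = make_participants(3000, seed=0)
        case = rng.uniform(size=3000) < 0.05
        gaps = _gap_table(parts, rng, case=case.astype(float), effect={"immune": 0.8})
        status = _status(parts.index, case)
        res = fit_age_gap_model(gaps, status, parts, "immune", adjusted=False)
        raw = gaps.loc[case, "immune"].mean() - gaps.loc[~case, "immune"].mean()
        assert res.estimate == pytest.approx(raw, abs=1e-10)
        assert "case" in res.formula

    def test_null_exposure_ci_covers_zero(self):
        rng = np.random.default_rng(1)
        parts = make_participants(4000, seed=1)
        case = rng.uniform(size=4000) < 0.05
        gaps = _gap_table(parts, rng)
        res = fit_age_gap_model(gaps, _status(parts.index, case), parts, "immune")
        lo, hi = res.ci95
        assert lo <= 0.0 <= hi

    def test_adjustment_set_present_term_for_term(self):
        rng = np.random.default_rng(2)
        parts = make_participants(1000, seed=2)
        case = rng.uniform(size=1000) < 0.1
        gaps = _gap_table(parts, rng)
        res = fit_age_gap_model(gaps, _status(parts.index, case), parts, "immune")
        for term in ("age", "packyears", "C(alcohol)", "bmi", *(f"pc{k}" for k in range(1, 11))):
            assert term in res.formula, term

    def test_small_stratum_skipped_with_reason(self):
        rng = np.random.default_rng(3)
        parts = make_participants(500, seed=3)
        case = np.zeros(500, dtype=bool)
        case[:3] = True
        gaps = _gap_table(parts, rng)
        res = fit_age_gap_model(gaps, _status(parts.index, case), parts, "immune", min_cases=10)
        assert np.isnan(res.estimate)
        assert "skipped:too_few_cases" in res.flags

    def test_zero_gaps_flagged_degenerate(self):
        rng = np.random.default_rng(4)
        parts = make_participants(500, seed=4)
        case = rng.uniform(size=500) < 0.1
        gaps = _gap_table(parts, rng)
        gaps["immune"] = 0.0
        res = fit_age_gap_model(gaps, _status(parts.index, case), parts, "immune")
        assert res.estimate == pytest.approx(0.0, abs=1e-10)
        assert "degenerate" in res.flags


class TestJointModel:
    def test_independent_gaps_joint_matches_marginal(self):
        rng = np.random.default_rng(5)
        parts = make_participants(20_000, seed=5)
        case = rng.uniform(size=20_000) < 0.03
        gaps = _gap_table(parts, rng, case=case.astype(float), effect={"immune": 0.5})
        status = _status(parts.index, case)
        marginal = fit_age_gap_model(gaps, status, parts, "immune")
        joint = fit_joint_organ_model(gaps, status, parts, "immune")
        assert abs(joint.estimate - marginal.estimate) < 1.5 * marginal.se

    def test_shared_latent_factor_attenuates_joint_estimate(self):
        rng = np.random.default_rng(6)
        parts = make_participants(20_000, seed=6)
        case = rng.uniform(size=20_000) < 0.03
        shared = rng.normal(0, 2.5, 20_000) + 0.8 * case
        gaps = pd.DataFrame(
            {o: shared + rng.normal(0, 1.0, 20_000) for o in ORGANS7}, index=parts.index
        )
        gaps["composite"] = gaps[list(ORGANS7)[:-1]].mean(axis=1)
        status = _status(parts.index, case)
        marginal = fit_age_gap_model(gaps, status, parts, "immune")
        joint = fit_joint_organ_model(gaps, status, parts, "immune")
        assert joint.estimate < 0.6 * marginal.estimate

    def test_duplicate_gap_column_raises_naming_pair(self):
        rng = np.random.default_rng(7)
        parts = make_participants(500, seed=7)
        case = rng.uniform(size=500) < 0.1
        gaps = _gap_table(parts, rng)
        gaps["hepatic"] = gaps["immune"]
        with pytest.raises(AssociationError, match="immune"):
            fit_joint_organ_model(gaps, _status(parts.index, case), parts, "immune")


class TestGrsAgeingModel:
    def test_shuffled_score_ci_covers_zero(self):
        rng = np.random.default_rng(8)
        parts = make_participants(5000, seed=8)
        gaps = _gap_table(parts, rng, organs=("immune",))
        score = pd.Series(rng.normal(size=5000), index=parts.index)
        gaps["immune"] += 0.5 * score
        shuffled = pd.Series(rng.permutation(score.to_numpy()), index=parts.index)
        res = fit_grs_ageing_model(gaps, shuffled, parts, "immune")
        lo, hi = res.ci95
        assert lo <= 0.0 <= hi
        assert res.scale == "years_per_sd"

    def test_scaled_slope_equals_unscaled_times_reference_sd(self):
        rng = np.random.default_rng(9)
        parts = make_participants(3000, seed=9)
        gaps = _gap_table(parts, rng, organs=("immune",))
        raw = pd.Series(rng.normal(10, 4, 3000), index=parts.index)
        gaps["immune"] += 0.1 * raw
        sd = raw.std(ddof=1)
        scaled = (raw - raw.mean()) / sd
        b_raw = fit_grs_ageing_model(gaps, raw, parts, "immune").estimate
        b_sd = fit_grs_ageing_model(gaps, scaled, parts, "immune").estimate
        assert abs(b_raw * sd - b_sd) <= 1e-10


class TestRiskFactorModel:
    @staticmethod
    def _inputs(n=3000, seed=10, all_male=False):
        rng = np.random.default_rng(seed)
        parts = make_participants(n, seed=seed, sex=["male"] * n if all_male else None)
        case = rng.uniform(size=n) < 0.05
        grs = pd.Series(rng.normal(size=n), index=parts.index)
        cfh = pd.Series(rng.binomial(2, 0.36, n).astype(float), index=parts.index)
        arms2 = pd.Series(rng.binomial(2, 0.21, n).astype(float), index=parts.index)
        return _status(parts.index, case), parts, grs, cfh, arms2

    def test_null_exposures_cover_or_of_one(self):
        status, parts, grs, cfh, arms2 = self._inputs()
        results = {r.exposure: r for r in fit_risk_factor_model(status, parts, grs, cfh, arms2)}
        assert set(results) >= {"age", "sex_male", "bmi", "packyears", "cfh_dosage", "arms2_dosage", "grs_scaled"}
        lo, hi = results["grs_scaled"].ci95
        assert lo <= 0.0 <= hi  # log OR scale
        assert results["grs_scaled"].scale == "log_or"

    def test_all_male_design_flagged_rank_deficient(self):
        status, parts, grs, cfh, arms2 = self._inputs(all_male=True)
        results = fit_risk_factor_model(status, parts, grs, cfh, arms2)
        assert all("rank_deficient" in r.flags for r in results)

    def test_zero_incident_cases_raise(self):
        status, parts, grs, cfh, arms2 = self._inputs()
        status["status"] = "control"
        with pytest.raises(AssociationError):
            fit_risk_factor_model(status, parts, grs, cfh, arms2)


class TestStratifiedSuite:
    def test_grid_shape_and_age_boundary(self):
        rng = np.random.default_rng(11)
        parts = make_participants(6000, seed=11)
        parts.iloc[0, parts.columns.get_loc("age")] = 60.0  # exact cutpoint
        case = rng.uniform(size=6000) < 0.05
        gaps = _gap_table(parts, rng)
        results = run_stratified_suite(gaps, _status(parts.index, case), parts, min_cases=5)
        assert len(results) == 8 * 9  # 7 organs + composite, 9 strata
        under = next(r for r in results if r.outcome == "immune" and r.stratum == "all/<60")
        over = next(r for r in results if r.outcome == "immune" and r.stratum == "all/>=60")
        assert under.n + over.n == next(r for r in results if r.outcome == "immune" and r.stratum == "all/all").n

    def test_planted_male_only_effect_recovered_in_male_stratum(self):
        rng = np.random.default_rng(12)
        parts = make_participants(30_000, seed=12)
        case = rng.uniform(size=30_000) < 0.05
        male = (parts["sex"] == "male").to_numpy()
        gaps = _gap_table(parts, rng)
        gaps["immune"] += 1.2 * (case & male)
        status = _status(parts.index, case)
        male_res = fit_age_gap_model(gaps, status, parts, "immune", stratum=("male", "all"))
        female_res = fit_age_gap_model(gaps, status, parts, "immune", stratum=("female", "all"))
        assert male_res.ci95[0] <= 1.2 <= male_res.ci95[1]
        assert female_res.ci95[0] <= 0.0 <= female_res.ci95[1]

    def test_suite_results_frame_has_bh_column(self):
        rng = np.random.default_rng(13)
        parts = make_participants(2000, seed=13)
        case = rng.uniform(size=2000) < 0.08
        gaps = _gap_table(parts, rng, organs=("immune", "hepatic"))
        suite = AssociationSuite(gaps, _status(parts.index, case), parts, min_cases=5)
        frame = suite.fit(joint=False).to_frame()
        fitted = frame["p"].notna()
        assert (frame.loc[fitted, "p_bh"] >= frame.loc[fitted, "p"] - 1e-12).all()
        assert {"estimate", "ci975_low", "ci975_high", "stratum", "formula"} <= set(frame.columns)
        assert suite.fit(joint=False).summary()  # renders without error
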