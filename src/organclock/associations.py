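"""Regression designs linking age gaps, disease status and genetic scores.

Three families of fits, all mirroring the study design they package:

* a multivariable logistic risk-factor model for incident disease
  (age, sex, BMI, packyears, the CFH and ARMS2 dosages, the overall
  genetic risk score, plus ten ancestry PCs) reported as odds ratios;
* multivariable linear models of one organ's age gap on incident case
  status (primary exposure) adjusted for age at baseline, ancestry PCs
  1-10, packyears, alcohol (with "missing" as its own level) and BMI,
  reported in years, optionally within sex x age strata and optionally
  adjusted for the six other organ gaps (the joint model);
* linear models of one organ's age gap on a scaled genetic score,
  reported in years per SD of the score.

Intervals are reported at the 97.5% level to match the bracket
convention of the source results, with conventional 95% intervals
alongside; two-sided p < 0.05 flags significance and a
Benjamini-Hochberg column is emitted for transparency but never drives
verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "AssociationError",
    "AssociationSuite",
    "SuiteResults",
    "fit_risk_factor_model",
    "fit_age_gap_model",
    "fit_joint_organ_model",
    "fit_grs_ageing_model",
    "run_stratified_suite",
]

PC_COLUMNS = tuple(f"pc{k}" for k in range(1, 11))
SEX_STRATA = ("all", "male", "female")
AGE_STRATA = ("all", "<60", ">=60")
AGE_CUTPOINT = 60.0  # boundary itself lands in the upper stratum


class AssociationError(RuntimeError):
    pass


def _robust_logit(y, X):
    """Logit fit with a quasi-Newton fallback when Newton diverges."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if fit.mle_retvals.get("converged", False) and np.all(np.isfinite(fit.bse)):
                return fit
        except Exception:
            pass
        return sm.Logit(y, X).fit(disp=0, maxiter=500, method="lbfgs")


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    exposure: str
    estimate: float  # log OR (logistic) or years / years-per-SD (linear)
    se: float
    ci975: tuple[float, float]
    ci95: tuple[float, float]
    p: float
    n: int
    n_cases: int | None = None
    stratum: str = "all/all"
    formula: str = ""
    scale: str = "years"
    flags: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < 0.05)

    def as_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "exposure": self.exposure,
            "estimate": self.estimate,
            "se": self.se,
            "ci975_low": self.ci975[0],
            "ci975_high": self.ci975[1],
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p": self.p,
            "n": self.n,
            "n_cases": self.n_cases,
            "stratum": self.stratum,
            "scale": self.scale,
            "significant": self.significant,
            "flags": ";".join(self.flags),
            "formula": self.formula,
        }
        if self.scale == "log_or":
            d["odds_ratio"] = float(np.exp(self.estimate))
        return d


def _apply_stratum(frame: pd.DataFrame, stratum: tuple[str, str]) -> pd.DataFrame:
    sex_s, age_s = stratum
    if sex_s not in SEX_STRATA or age_s not in AGE_STRATA:
        raise ValueError(f"unknown stratum {stratum}")
    out = frame
    if sex_s != "all":
        out = out[out["sex"] == sex_s]
    if age_s == "<60":
        out = out[out["age"] < AGE_CUTPOINT]
    elif age_s == ">=60":
        out = out[out["age"] >= AGE_CUTPOINT]
    return out


def _adjust_terms(extra: tuple[str, ...] = ()) -> str:
    terms = ["age", *PC_COLUMNS, "packyears", "C(alcohol)", "bmi", *extra]
    return " + ".join(terms)


def _term_result(fit, term: str, outcome: str, stratum: str, scale: str, n_cases=None, flags=()) -> AssociationResult:
    ci975 = fit.conf_int(alpha=0.025)
    ci95 = fit.conf_int(alpha=0.05)
    return AssociationResult(
        outcome=outcome,
        exposure=term,
        estimate=float(fit.params[term]),
        se=float(fit.bse[term]),
        ci975=(float(ci975.loc[term, 0]), float(ci975.loc[term, 1])),
        ci95=(float(ci95.loc[term, 0]), float(ci95.loc[term, 1])),
        p=float(fit.pvalues[term]),
        n=int(fit.nobs),
        n_cases=n_cases,
        stratum=stratum,
        formula=getattr(fit.model, "formula", ""),
        scale=scale,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# logistic risk-factor model


def fit_risk_factor_model(
    status: pd.DataFrame,
    participants: pd.DataFrame,
    grs_scaled: pd.Series,
    cfh_dosage: pd.Series,
    arms2_dosage: pd.Series,
) -> list[AssociationResult]:
    """Incident case (vs control) ~ age + sex + BMI + packyears + CFH + ARMS2 + GRS + PCs.

    One multivariable logistic fit; per-term log odds ratios with 97.5%
    and 95% intervals.  Zero incident cases raise; separation or rank
    deficiency returns flagged results without estimates.
    """
    st = status["status"]
    keep = st.isin(["incident", "control"])
    ids = st.index[keep]
    y = (st.loc[ids] == "incident").astype(float)
    n_cases = int(y.sum())
    if n_cases == 0:
        raise AssociationError("no incident cases in the analysis set")
    design = pd.DataFrame(
        {
            "age": participants.loc[ids, "age"].astype(float),
            "sex_male": (participants.loc[ids, "sex"] == "male").astype(float),
            "bmi": participants.loc[ids, "bmi"].astype(float),
            "packyears": participants.loc[ids, "packyears"].astype(float),
            "cfh_dosage": cfh_dosage.reindex(ids).astype(float),
            "arms2_dosage": arms2_dosage.reindex(ids).astype(float),
            "grs_scaled": grs_scaled.reindex(ids).astype(float),
        }
    )
    for pc in PC_COLUMNS:
        design[pc] = participants.loc[ids, pc].astype(float)
    X = sm.add_constant(design, has_constant="add")

    flags: list[str] = []
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        flags.append("rank_deficient")
        return [
            AssociationResult("incident", t, np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                              np.nan, len(ids), n_cases, scale="log_or", flags=tuple(flags))
            for t in design.columns
        ]
    try:
        fit = _robust_logit(y.to_numpy(), X)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.asarray(fit.bse) > 50):
            flags.append("separation")
    except Exception:
        flags.append("separation")
        return [
            AssociationResult("incident", t, np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                              np.nan, len(ids), n_cases, scale="log_or", flags=tuple(flags))
            for t in design.columns
        ]
    return [
        _term_result(fit, term, "incident", "all/all", "log_or", n_cases, flags)
        for term in design.columns
    ]


# ---------------------------------------------------------------------------
# linear age-gap models


def _gap_frame(
    gaps: pd.DataFrame,
    status: pd.DataFrame,
    participants: pd.DataFrame,
    organ: str,
    analysis_ids: pd.Index | None,
) -> pd.DataFrame:
    st = status["status"]
    ids = st.index[st.isin(["incident", "control"])]
    if analysis_ids is not None:
        ids = ids.intersection(pd.Index(analysis_ids))
    frame = participants.loc[ids, ["age", "sex", "bmi", "packyears", *PC_COLUMNS]].copy()
    frame["alcohol"] = participants.loc[ids, "alcohol"].astype(str)
    frame["case"] = (st.loc[ids] == "incident").astype(float)
    frame["gap"] = gaps.loc[ids, organ].astype(float)
    for other in gaps.columns:
        if other not in (organ, "composite"):
            frame[f"gap_{other}"] = gaps.loc[ids, other].astype(float)
    return frame


def fit_age_gap_model(
    gaps: pd.DataFrame,
    status: pd.DataFrame,
    participants: pd.DataFrame,
    organ: str,
    stratum: tuple[str, str] = ("all", "all"),
    analysis_ids: pd.Index | None = None,
    min_cases: int = 10,
    adjusted: bool = True,
) -> AssociationResult:
    """Linear model: organ age gap ~ incident case + adjustment set, in years.

    The analysis set is intended to be matched-test controls plus
    incident cases (pass ``analysis_ids``); training participants never
    enter association fits.  With ``adjusted=False`` the fit is the bare
    two-group contrast, whose estimate equals the raw case-minus-control
    mean gap.
    """
    frame = _apply_stratum(_gap_frame(gaps, status, participants, organ, analysis_ids), stratum)
    stratum_label = f"{stratum[0]}/{stratum[1]}"
    n_cases = int(frame["case"].sum())
    flags: list[str] = []
    if n_cases < min_cases:
        return AssociationResult(
            organ, "case", np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan), np.nan,
            len(frame), n_cases, stratum_label, flags=("skipped:too_few_cases",),
        )
    formula = f"gap ~ case + {_adjust_terms()}" if adjusted else "gap ~ case"
    fit = smf.ols(formula, data=frame).fit()
    if float(np.var(frame["gap"])) < 1e-24:
        flags.append("degenerate")
    return _term_result(fit, "case", organ, stratum_label, "years", n_cases, flags)


def fit_joint_organ_model(
    gaps: pd.DataFrame,
    status: pd.DataFrame,
    participants: pd.DataFrame,
    organ: str,
    stratum: tuple[str, str] = ("all", "all"),
    analysis_ids: pd.Index | None = None,
    min_cases: int = 10,
) -> AssociationResult:
    """As :func:`fit_age_gap_model`, additionally adjusted for the other organ gaps."""
    organ_cols = [c for c in gaps.columns if c != "composite"]
    corr = gaps[organ_cols].corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    if np.any(np.abs(corr) >= 1.0 - 1e-12):
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise AssociationError(f"perfectly collinear gaps: {organ_cols[i]!r} and {organ_cols[j]!r}")
    frame = _apply_stratum(_gap_frame(gaps, status, participants, organ, analysis_ids), stratum)
    stratum_label = f"{stratum[0]}/{stratum[1]}"
    n_cases = int(frame["case"].sum())
    if n_cases < min_cases:
        return AssociationResult(
            organ, "case", np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan), np.nan,
            len(frame), n_cases, stratum_label, flags=("skipped:too_few_cases",),
        )
    others = tuple(f"gap_{o}" for o in organ_cols if o != organ)
    formula = f"gap ~ case + {_adjust_terms(others)}"
    fit = smf.ols(formula, data=frame).fit()
    return _term_result(fit, "case", f"{organ}(joint)", stratum_label, "years", n_cases)


def fit_grs_ageing_model(
    gaps: pd.DataFrame,
    scores_scaled: pd.Series,
    participants: pd.DataFrame,
    organ: str,
    panel_tag: str = "overall",
    stratum: tuple[str, str] = ("all", "all"),
    analysis_ids: pd.Index | None = None,
) -> AssociationResult:
    """Linear model: organ age gap ~ scaled score + adjustment set, years per SD."""
    ids = gaps.index if analysis_ids is None else pd.Index(analysis_ids)
    frame = participants.loc[ids, ["age", "sex", "bmi", "packyears", *PC_COLUMNS]].copy()
    frame["alcohol"] = participants.loc[ids, "alcohol"].astype(str)
    frame["gap"] = gaps.loc[ids, organ].astype(float)
    frame["score"] = scores_scaled.reindex(ids).astype(float)
    frame = _apply_stratum(frame, stratum)
    if frame.empty:
        raise AssociationError(f"empty stratum {stratum}")
    formula = f"gap ~ score + {_adjust_terms()}"
    fit = smf.ols(formula, data=frame).fit()
    return _term_result(fit, "score", f"{organ}~{panel_tag}", f"{stratum[0]}/{stratum[1]}", "years_per_sd")


def run_stratified_suite(
    gaps: pd.DataFrame,
    status: pd.DataFrame,
    participants: pd.DataFrame,
    analysis_ids: pd.Index | None = None,
    organs: tuple[str, ...] | None = None,
    min_cases: int = 10,
) -> list[AssociationResult]:
    """Every organ x {all, male, female} x {all, <60, >=60} case-gap cell."""
    if organs is None:
        organs = tuple(gaps.columns)
    results = []
    for organ in organs:
        for sex_s in SEX_STRATA:
            for age_s in AGE_STRATA:
                results.append(
                    fit_age_gap_model(
                        gaps, status, participants, organ,
                        stratum=(sex_s, age_s), analysis_ids=analysis_ids, min_cases=min_cases,
                    )
                )
    return results


# ---------------------------------------------------------------------------
# suite object


class AssociationSuite:
    """Model object bundling the full association battery for one cohort."""

    def __init__(
        self,
        gaps: pd.DataFrame,
        status: pd.DataFrame,
        participants: pd.DataFrame,
        scores_scaled: pd.DataFrame | None = None,
        analysis_ids: pd.Index | None = None,
        score_analysis_ids: pd.Index | None = None,
        min_cases: int = 10,
    ) -> None:
        self.gaps = gaps
        self.status = status
        self.participants = participants
        self.scores_scaled = scores_scaled
        self.analysis_ids = analysis_ids
        self.score_analysis_ids = score_analysis_ids if score_analysis_ids is not None else analysis_ids
        self.min_cases = min_cases

    def fit(self, joint: bool = True) -> "SuiteResults":
        results = run_stratified_suite(
            self.gaps, self.status, self.participants,
            analysis_ids=self.analysis_ids, min_cases=self.min_cases,
        )
        if joint:
            for organ in self.gaps.columns:
                if organ == "composite":
                    continue
                results.append(
                    fit_joint_organ_model(
                        self.gaps, self.status, self.participants, organ,
                        analysis_ids=self.analysis_ids, min_cases=self.min_cases,
                    )
                )
        if self.scores_scaled is not None:
            for tag in self.scores_scaled.columns:
                for organ in self.gaps.columns:
                    results.append(
                        fit_grs_ageing_model(
                            self.gaps, self.scores_scaled[tag], self.participants, organ,
                            panel_tag=tag, analysis_ids=self.score_analysis_ids,
                        )
                    )
        return SuiteResults(results)


@dataclass
class SuiteResults:
    results: list[AssociationResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([r.as_dict() for r in self.results])
        fitted = frame["p"].notna()
        p_bh = pd.Series(np.nan, index=frame.index)
        if fitted.any():
            p_bh.loc[fitted] = multipletests(frame.loc[fitted, "p"], method="fdr_bh")[1]
        frame["p_bh"] = p_bh  # informational only; verdicts use raw p < 0.05
        return frame

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [f"Association suite: {len(frame)} fits"]
        for _, row in frame.iterrows():
            est = row["estimate"]
            if pd.isna(est):
                lines.append(f"  {row['outcome']:<24} {row['exposure']:<10} {row['stratum']:<12} {row['flags']}")
                continue
            star = "*" if row["significant"] else " "
            shown = np.exp(est) if row["scale"] == "log_or" else est
            unit = "OR" if row["scale"] == "log_or" else row["scale"]
            lines.append(
                f"  {row['outcome']:<24} {row['exposure']:<10} {row['stratum']:<12} "
                f"{unit}={shown:+.3f} [97.5% CI {row['ci975_low']:+.3f};{row['ci975_high']:+.3f}] "
                f"p={row['p']:.2e}{star}"
            )
        return "\n".join(lines)
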