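"""Covariate coding and per-organ chained-equations imputation.

Covariate rules: packyears are zero by definition for never-smokers;
current or past smokers with missing packyears get the median packyears
of their smoking-status group; alcohol frequency is dichotomised at
three drinks a week (0 = less, 1 = more), respondents who stopped
drinking are set to missing (possible sick-quitters), and "missing" is
kept as its own factor level in association models.

Biomarker panels are imputed one organ at a time so the ageing signal
of one system cannot leak into another's imputed values.  Markers with
more than 20% missingness (strict inequality) are dropped before
imputation; the rest are completed by chained-equations regression
imputation (Bayesian-ridge conditional models with posterior-noise
draws, columns visited in ascending missingness order) using only
same-organ markers plus four auxiliary covariates: sex, smoking, BMI
and chronological age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_seed

__all__ = ["ImputationReport", "PipelineError", "code_covariates", "impute_organ_panel"]

MISSINGNESS_CUTOFF = 0.20
ALCOHOL_LEVELS = ("0", "1", "missing")


class PipelineError(RuntimeError):
    """Raised when preprocessing cannot produce a usable panel."""


@dataclass
class ImputationReport:
    organ: str
    dropped_markers: dict[str, float]  # marker -> missing fraction
    iterations: int
    imputed_counts: dict[str, int]  # retained marker -> cells imputed
    flags: tuple[str, ...] = ()


def code_covariates(participants: pd.DataFrame) -> pd.DataFrame:
    """Apply the smoking/packyears and alcohol coding rules.

    Returns a copy with ``packyears`` completed and an ``alcohol``
    categorical with levels {"0", "1", "missing"}.
    """
    known = {"never", "previous", "current"}
    unknown = set(participants["smoking_status"].unique()) - known
    if unknown:
        raise ValueError(f"unknown smoking categories: {sorted(unknown)}")

    out = participants.copy()
    packyears = out["packyears"].astype(float).copy()
    packyears[out["smoking_status"] == "never"] = 0.0
    for group in ("previous", "current"):
        in_group = out["smoking_status"] == group
        median = packyears[in_group].median()
        packyears[in_group & packyears.isna()] = median
    out["packyears"] = packyears

    raw = out["alcohol_raw"].astype(object)
    coded = pd.Series("missing", index=out.index, dtype=object)
    coded[raw == "low"] = "0"
    coded[raw == "high"] = "1"
    # stopped drinkers and unreported both land on the "missing" level
    out["alcohol"] = pd.Categorical(coded, categories=list(ALCOHOL_LEVELS))
    return out


def _auxiliary_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    smoking_code = covariates["smoking_status"].map({"never": 0.0, "previous": 1.0, "current": 2.0})
    return pd.DataFrame(
        {
            "_aux_sex": (covariates["sex"] == "female").astype(float),
            "_aux_smoking": smoking_code.astype(float),
            "_aux_bmi": covariates["bmi"].astype(float),
            "_aux_age": covariates["age"].astype(float),
        },
        index=covariates.index,
    )


def impute_organ_panel(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    organ: str = "",
    seed: int = 0,
    sweeps: int = 10,
    posterior_noise: bool = True,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Complete one organ's panel by chained equations, in isolation.

    Only same-organ markers plus the four auxiliary covariates enter the
    conditional models; no value from another organ's panel is read.
    The imputation RNG is derived from ``seed`` and the organ label so
    organs are reproducible independently.
    """
    missing_frac = panel.isna().mean()
    dropped = missing_frac[missing_frac > MISSINGNESS_CUTOFF]
    flags: list[str] = []
    retained = panel.drop(columns=list(dropped.index))

    never_observed = retained.columns[retained.notna().sum() == 0]
    if len(never_observed):
        flags.append(f"never_observed:{','.join(never_observed)}")
        dropped = pd.concat([dropped, pd.Series(1.0, index=never_observed)])
        retained = retained.drop(columns=list(never_observed))
    if retained.shape[1] == 0:
        raise PipelineError(f"all markers dropped for organ {organ!r}")

    imputed_counts = {m: int(retained[m].isna().sum()) for m in retained.columns}
    if retained.isna().to_numpy().sum() == 0:
        report = ImputationReport(organ, dropped.to_dict(), 0, imputed_counts, tuple(flags))
        return retained.copy(), report

    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import BayesianRidge

    aux = _auxiliary_covariates(covariates.loc[retained.index])
    design = pd.concat([retained, aux], axis=1)
    imputer = IterativeImputer(
        estimator=BayesianRidge(),
        max_iter=sweeps,
        sample_posterior=posterior_noise,
        imputation_order="ascending",
        random_state=stage_seed(seed, f"impute:{organ}"),
        keep_empty_features=True,
    )
    completed = imputer.fit_transform(design.to_numpy(dtype=float))
    result = pd.DataFrame(completed[:, : retained.shape[1]], index=retained.index, columns=retained.columns)
    # observed cells are passed through untouched by the imputer; enforce anyway
    observed = retained.notna()
    result = result.where(~observed, retained)
    report = ImputationReport(organ, dropped.to_dict(), int(imputer.n_iter_), imputed_counts, tuple(flags))
    return result, report
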