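"""Read-code phenotyping: family pooling, validation, case classification.

Primary-care records carry clinical codes whose first 2-3 characters
identify a code family.  Because code vocabularies mix genuinely
disease-specific codes with administrative or unrelated ones, each
family is validated against known risk factors (age, sex, smoking, the
two major risk variants, and an overall genetic risk score) with a
logistic model; families whose association pattern is absent are
removed.  Surviving records then classify each participant as an
incident case (first qualifying code strictly after recruitment),
prevalent case (code on/before recruitment), excluded (diagnosis before
age 40), control, or unknown (no GP coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CodeFamily",
    "FamilyValidationResult",
    "RetentionRule",
    "RecordValidationError",
    "pool_code_families",
    "validate_code_families",
    "merge_verdicts",
    "classify_amd_status",
]

STATUSES = ("incident", "prevalent", "control", "unknown", "excluded")


class RecordValidationError(ValueError):
    """Raised when diagnosis records violate the code contract."""


@dataclass(frozen=True)
class CodeFamily:
    prefix: str
    member_codes: tuple[str, ...]
    n_carriers: int
    carrier_ids: tuple[str, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class RetentionRule:
    """Operational form of the verbal filter used for code families.

    Retain a family iff the genetic-risk-score term is significant with a
    positive log OR AND at least one of {age, CFH, ARMS2} is significant
    with a risk-increasing sign.  Both thresholds are configurable.
    """

    grs_alpha: float = 0.05
    secondary_alpha: float = 0.05
    min_carriers: int = 20


@dataclass(frozen=True)
class FamilyValidationResult:
    prefix: str
    n_carriers: int
    estimates: dict  # term -> (log OR, ci_low, ci_high, p)
    verdict: str  # "retained" | "removed"
    flags: tuple[str, ...] = ()

    @property
    def retained(self) -> bool:
        return self.verdict == "retained"


def pool_code_families(records: pd.DataFrame, prefix_length: int = 3) -> list[CodeFamily]:
    """Group records by the first ``prefix_length`` characters of their code.

    Carrier counts are distinct-participant counts.  Codes shorter than
    the prefix raise with the offending codes listed.
    """
    if prefix_length not in (2, 3):
        raise ValueError("prefix_length must be 2 or 3")
    if records.empty:
        return []
    codes = records["code"].astype(str)
    short = sorted(codes[codes.str.len() < prefix_length].unique())
    if short:
        raise RecordValidationError(f"codes shorter than prefix length {prefix_length}: {short}")
    grouped = records.assign(prefix=codes.str[:prefix_length]).groupby("prefix", sort=True)
    families = []
    for prefix, group in grouped:
        carriers = tuple(sorted(group["participant_id"].unique()))
        families.append(
            CodeFamily(
                prefix=str(prefix),
                member_codes=tuple(sorted(group["code"].unique())),
                n_carriers=len(carriers),
                carrier_ids=carriers,
            )
        )
    return families


def _risk_factor_design(participants: pd.DataFrame) -> pd.DataFrame:
    design = pd.DataFrame(index=participants.index)
    design["age"] = participants["age"]
    design["sex_male"] = (participants["sex"] == "male").astype(float)
    design["packyears"] = participants["packyears"].fillna(0.0)
    design["cfh_dosage"] = participants["cfh_dosage"]
    design["arms2_dosage"] = participants["arms2_dosage"]
    design["grs_scaled"] = participants["grs_scaled"]
    return design


def validate_code_families(
    families: list[CodeFamily],
    participants: pd.DataFrame,
    rule: RetentionRule | None = None,
) -> list[FamilyValidationResult]:
    """One logistic fit per family: carrier ~ age + sex + packyears + CFH + ARMS2 + GRS.

    ``participants`` must provide age, sex, packyears, cfh_dosage,
    arms2_dosage and grs_scaled columns.  Families below the carrier
    minimum are removed unfit and flagged underpowered; separation or
    non-convergence also removes the family with a flag.
    """
    rule = rule or RetentionRule()
    design = _risk_factor_design(participants)
    X = sm.add_constant(design, has_constant="add")
    results: list[FamilyValidationResult] = []
    for fam in sorted(families, key=lambda f: f.prefix):
        carriers_here = participants.index.intersection(pd.Index(fam.carrier_ids))
        n_carriers = len(carriers_here)
        if n_carriers < rule.min_carriers:
            results.append(
                FamilyValidationResult(fam.prefix, n_carriers, {}, "removed", ("underpowered",))
            )
            continue
        y = participants.index.isin(carriers_here).astype(float)
        from .associations import _robust_logit

        try:
            fit = _robust_logit(y, X)
            if not fit.mle_retvals.get("converged", False):
                raise np.linalg.LinAlgError("no convergence")
            bse = np.asarray(fit.bse)
            if not np.all(np.isfinite(bse)) or np.any(bse > 50):
                raise np.linalg.LinAlgError("separation")
        except Exception:
            results.append(
                FamilyValidationResult(fam.prefix, n_carriers, {}, "removed", ("separation",))
            )
            continue
        ci = fit.conf_int(alpha=0.05)
        estimates = {
            term: (float(fit.params[term]), float(ci.loc[term, 0]), float(ci.loc[term, 1]), float(fit.pvalues[term]))
            for term in design.columns
        }
        grs_est, _, _, grs_p = estimates["grs_scaled"]
        primary = grs_p < rule.grs_alpha and grs_est > 0
        secondary = any(
            estimates[t][3] < rule.secondary_alpha and estimates[t][0] > 0
            for t in ("age", "cfh_dosage", "arms2_dosage")
        )
        verdict = "retained" if (primary and secondary) else "removed"
        results.append(FamilyValidationResult(fam.prefix, n_carriers, estimates, verdict))
    return results


def merge_verdicts(
    results_len2: list[FamilyValidationResult],
    results_len3: list[FamilyValidationResult],
) -> dict[str, FamilyValidationResult]:
    """Combine validations run at prefix lengths 2 and 3.

    Where a length-3 family exists its verdict wins; length-2 verdicts
    cover only prefixes with no length-3 refinement.
    """
    merged: dict[str, FamilyValidationResult] = {}
    covered2 = {r.prefix[:2] for r in results_len3}
    for r in results_len2:
        if r.prefix not in covered2:
            merged[r.prefix] = r
    for r in results_len3:
        merged[r.prefix] = r
    return merged


def classify_amd_status(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    retained_prefixes: list[str],
    followup_end=None,
) -> pd.DataFrame:
    """Assign exactly one status per participant from retained-family records.

    Order of precedence: unknown (no GP coverage) > excluded (first
    qualifying event before age 40) > prevalent (event on/before
    recruitment day, day-level comparison) > incident > control.
    """
    status = pd.DataFrame(index=participants.index)
    status["status"] = "control"
    status["first_event_date"] = pd.NaT
    status["age_at_first_event"] = np.nan

    if not records.empty:
        prefixes = tuple(retained_prefixes)
        qualifying = records[records["code"].astype(str).str.startswith(prefixes)] if prefixes else records.iloc[0:0]
        if followup_end is not None:
            qualifying = qualifying[qualifying["event_date"] <= pd.Timestamp(followup_end)]
        if not qualifying.empty:
            first = qualifying.groupby("participant_id")["event_date"].min()
            first = first[first.index.isin(participants.index)]
            dob = participants.loc[first.index, "date_of_birth"]
            recruit = participants.loc[first.index, "recruitment_date"]
            age_at_event = (first - dob).dt.days / 365.25
            if (age_at_event < 0).any():
                bad = list(age_at_event.index[age_at_event < 0])
                raise RecordValidationError(f"event date before birth for participants: {bad}")
            status.loc[first.index, "first_event_date"] = first
            status.loc[first.index, "age_at_first_event"] = age_at_event
            status.loc[first.index, "status"] = np.where(
                age_at_event < 40.0,
                "excluded",
                np.where(first.dt.normalize() <= recruit.dt.normalize(), "prevalent", "incident"),
            )

    no_gp = ~participants["gp_coverage"].astype(bool)
    status.loc[no_gp, "status"] = "unknown"
    return status
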