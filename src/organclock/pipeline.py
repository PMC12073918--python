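"""End-to-end orchestration: simulate -> phenotype -> impute -> train -> score -> associate."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import associations, clocks, phenotyping, preprocessing, scores
from .cohort import CohortConfig, SyntheticCohort, simulate_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    participants: pd.DataFrame  # covariate-coded, with dosage and score columns
    status: pd.DataFrame
    family_validation: dict[str, phenotyping.FamilyValidationResult]
    retained_prefixes: list[str]
    splits: dict[str, pd.Index]
    clock_results: dict[str, clocks.OrganClockResults]
    clock_evaluations: pd.DataFrame
    gaps: pd.DataFrame
    scores_scaled: pd.DataFrame
    analysis_ids: pd.Index
    score_analysis_ids: pd.Index
    risk_factor_results: list = field(default_factory=list)
    suite: associations.SuiteResults | None = None
    imputation_reports: dict[str, preprocessing.ImputationReport] = field(default_factory=dict)

    def summary(self) -> str:
        counts = self.status["status"].value_counts().to_dict()
        lines = [
            "Pipeline summary",
            f"  participants        {len(self.participants)}",
            f"  status counts       {counts}",
            f"  retained families   {sorted(self.retained_prefixes)}",
            f"  train/test sizes    {len(self.splits['train'])}/{len(self.splits['test'])}",
        ]
        for _, row in self.clock_evaluations.iterrows():
            lines.append(f"  clock r ({row['organ']:<16} {row['split']:<5}) {row['r']:.3f}")
        return "\n".join(lines)


def run_pipeline(
    config: CohortConfig,
    clock_spec: clocks.ClockSpec | None = None,
    correct_bias: bool = False,
    fit_associations: bool = True,
    joint: bool = True,
) -> PipelineResult:
    """Run the whole analysis on a synthetic cohort defined by ``config``."""
    seed = config.seed
    cohort = simulate_cohort(config)
    parts = preprocessing.code_covariates(cohort.participants)

    # genetic scores: overall + pathway panels, scaled on a declared reference
    panels_by_tag = scores.stratify_panels(cohort.variant_panel)
    raw = pd.DataFrame(index=parts.index)
    for tag, panel in panels_by_tag.items():
        raw[tag] = scores.compute_grs(cohort.genotypes, panel, score_name=tag)[tag]
    parts["cfh_dosage"] = cohort.genotypes["rs1061170"]
    parts["arms2_dosage"] = cohort.genotypes["rs10490924"]
    parts["grs_scaled"] = scores.scale_scores(raw[["overall"]], reference_ids=parts.index)["overall"]

    # phenotyping: pool at both prefix lengths, validate on GP-covered people
    fam2 = phenotyping.pool_code_families(cohort.records, 2)
    fam3 = phenotyping.pool_code_families(cohort.records, 3)
    gp_ids = parts.index[parts["gp_coverage"].astype(bool)]
    validation = phenotyping.merge_verdicts(
        phenotyping.validate_code_families(fam2, parts.loc[gp_ids]),
        phenotyping.validate_code_families(fam3, parts.loc[gp_ids]),
    )
    retained = [p for p, r in validation.items() if r.retained]
    status = phenotyping.classify_amd_status(cohort.records, parts, retained, config.followup_end)

    splits = clocks.build_splits(parts, status, seed=seed)

    # per-organ imputation and clock training
    spec = clock_spec or clocks.ClockSpec()
    completed: dict[str, pd.DataFrame] = {}
    reports: dict[str, preprocessing.ImputationReport] = {}
    models: dict[str, clocks.OrganClockResults] = {}
    evaluations = []
    train_ids, test_ids = splits["train"], splits["test"]
    train_ages = parts.loc[train_ids, "age"].to_numpy()
    weights = clocks.compute_sample_weights(train_ages)
    for organ, panel in cohort.panels.items():
        filled, report = preprocessing.impute_organ_panel(panel, parts, organ=organ, seed=seed)
        completed[organ] = filled
        reports[organ] = report
        model = clocks.OrganClock(
            filled.loc[train_ids], train_ages, weights=weights, spec=spec, organ=organ
        ).fit(seed=seed)
        models[organ] = model
        evaluations.append(model.evaluate(filled.loc[train_ids], train_ages, split="train"))
        evaluations.append(model.evaluate(filled.loc[test_ids], parts.loc[test_ids, "age"], split="test"))
    evaluations = pd.DataFrame(evaluations)

    incident_ids = status.index[status["status"] == "incident"]
    unknown_ids = status.index[status["status"] == "unknown"]
    analysis_ids = pd.Index(test_ids).union(incident_ids)
    gap_ids = analysis_ids.union(unknown_ids)
    gaps = clocks.compute_age_gaps(
        models, {o: p.loc[gap_ids] for o, p in completed.items()}, parts.loc[gap_ids],
        correct_bias=correct_bias,
    )

    score_ref = unknown_ids if len(unknown_ids) > 1 else parts.index
    scaled = scores.scale_scores(raw, reference_ids=score_ref)

    result = PipelineResult(
        cohort=cohort,
        participants=parts,
        status=status,
        family_validation=validation,
        retained_prefixes=retained,
        splits=splits,
        clock_results=models,
        clock_evaluations=evaluations,
        gaps=gaps,
        scores_scaled=scaled,
        analysis_ids=analysis_ids,
        score_analysis_ids=unknown_ids,
        imputation_reports=reports,
    )
    if fit_associations:
        result.risk_factor_results = associations.fit_risk_factor_model(
            status, parts, parts["grs_scaled"], parts["cfh_dosage"], parts["arms2_dosage"]
        )
        suite = associations.AssociationSuite(
            gaps, status, parts,
            scores_scaled=scaled,
            analysis_ids=analysis_ids,
            score_analysis_ids=unknown_ids if len(unknown_ids) else analysis_ids,
        )
        result.suite = suite.fit(joint=joint)
    return result
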