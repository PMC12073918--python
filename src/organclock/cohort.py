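"""Synthetic biobank-style cohort generator.

Emulates the statistical structure a differential organ-ageing analysis
assumes: a middle-aged cohort (recruited between ages 37 and 73 over a
four-year window), seven organ systems whose latent biological age is
chronological age plus a person-specific gap, biomarker panels linearly
loaded on latent age, genotypes at ~48 weighted risk variants in
Hardy-Weinberg proportions, a logistic disease liability driven by age,
smoking, BMI and genetic risk, and GP-style coded diagnosis records with
event dates, decoy code families and prevalent cases.

Every planted coefficient is echoed in :class:`TrueParameters` so that
downstream estimates can be compared against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import stage_rng

__all__ = [
    "ORGANS",
    "TRUE_CODE_FAMILIES",
    "DECOY_CODE_FAMILIES",
    "CohortConfig",
    "TrueParameters",
    "SyntheticCohort",
    "build_variant_panel",
    "build_clock_panels",
    "generate_participants",
    "generate_organ_biomarkers",
    "generate_genotypes",
    "generate_diagnosis_records",
    "assign_disease",
    "simulate_cohort",
]

ORGANS = (
    "cardiovascular",
    "pulmonary",
    "musculoskeletal",
    "metabolic",
    "immune",
    "renal",
    "hepatic",
)

#: Code families that genuinely mark the disease in synthetic records.
TRUE_CODE_FAMILIES = ("F42", "F45", "XaI")
#: Decoy families assigned independently of disease liability.  The first
#: three mirror the prefixes a real analysis discarded after validation.
DECOY_CODE_FAMILIES = ("X00", "XaE", "2BB", "9Q1", "7P3", "5K9")

_CODE_SUFFIXES = ("y", "z", "m", "l")

# Observed case/control age-gap differences (years) and gap-per-GRS-SD
# slopes used as planted defaults; immune ages fastest, hepatic slowest.
_DEFAULT_CASE_GAP = {
    "cardiovascular": 0.10,
    "pulmonary": 0.05,
    "musculoskeletal": 0.05,
    "metabolic": 0.05,
    "immune": 0.21,
    "renal": 0.05,
    "hepatic": -0.25,
}
_DEFAULT_GRS_GAP_SLOPE = {
    "cardiovascular": -0.012,
    "pulmonary": -0.018,
    "musculoskeletal": 0.0,
    "metabolic": 0.017,
    "immune": 0.010,
    "renal": 0.027,
    "hepatic": 0.019,
}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


def _packyears_truth(participants: pd.DataFrame) -> pd.Series:
    """Pre-masking packyears if the generator recorded them, else observed."""
    stored = participants.attrs.get("packyears_true")
    if stored is not None and len(stored) == len(participants):
        return pd.Series(np.asarray(stored, dtype=float), index=participants.index)
    return participants["packyears"].fillna(0.0)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults describe a desk-scale cohort in the weak-clock regime: five
    exchangeable markers per organ with noise calibrated so the population
    R-squared between a panel and chronological age is ~0.12 (held-out
    clock r ~0.35), a 3-year organ-gap SD, disease probability ~2% with a
    per-SD genetic odds ratio of 1.6, and 40% GP coverage.
    """

    n_participants: int = 20_000
    age_range: tuple[float, float] = (37.0, 73.0)
    female_fraction: float = 0.544
    organs: tuple[str, ...] = ORGANS
    markers_per_organ: int = 5
    loading_scale: float = 1.0
    noise_sd: float = 62.5
    gap_sd: float = 3.0
    case_gap_effect: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CASE_GAP))
    grs_gap_slope: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GRS_GAP_SLOPE))
    packyears_gap_slope: float = 0.01
    bmi_gap_slope: float = 0.02
    disease_prevalence_target: float = 0.02
    liability_age_beta: float = 0.09
    liability_packyears_beta: float = 0.008
    liability_bmi_beta: float = 0.02
    liability_grs_beta: float = math.log(1.6)
    missingness_rate: float = 0.10
    missing_depends_on_age: bool = False
    packyears_missing_rate: float = 0.15
    decoy_family_count: int = 3
    decoy_carrier_rate: float = 0.01
    prevalent_fraction: float = 0.30
    under40_fraction: float = 0.02
    gp_coverage: float = 0.40
    recruitment_start: str = "2006-01-01"
    recruitment_years: float = 4.0
    followup_end: str = "2017-12-31"
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.age_range
        if not (37.0 <= low < high <= 73.0):
            raise ConfigurationError(f"age_range must satisfy 37 <= low < high <= 73, got {self.age_range}")
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be non-negative")
        for name in (
            "female_fraction",
            "disease_prevalence_target",
            "missingness_rate",
            "packyears_missing_rate",
            "decoy_carrier_rate",
            "prevalent_fraction",
            "under40_fraction",
            "gp_coverage",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be a proportion in [0, 1], got {value}")
        if self.markers_per_organ < 2:
            raise ConfigurationError("markers_per_organ must be >= 2")
        if self.gap_sd <= 0:
            raise ConfigurationError("gap_sd must be > 0")
        unknown = set(self.organs) - set(ORGANS)
        unknown |= set(self.case_gap_effect) - set(ORGANS)
        unknown |= set(self.grs_gap_slope) - set(ORGANS)
        if unknown:
            raise ConfigurationError(f"unknown organ labels: {sorted(unknown)}")
        if self.decoy_family_count > len(DECOY_CODE_FAMILIES):
            raise ConfigurationError(f"decoy_family_count must be <= {len(DECOY_CODE_FAMILIES)}")

    # -- closed-form calibration helpers ------------------------------

    @property
    def age_variance(self) -> float:
        low, high = self.age_range
        return (high - low) ** 2 / 12.0

    def oracle_panel_r2(self) -> float:
        """Population R² between one organ's marker panel and age.

        For markers m_j = l·(age + gap) + ε_j with equal loadings, the
        best linear predictor of age achieves
        R² = var(age) / (var(age) + gap_sd² + σ²/(p·l²)),
        assuming no planted case/GRS/lifestyle gap shifts.
        """
        v = self.noise_sd**2 / (self.markers_per_organ * self.loading_scale**2)
        return self.age_variance / (self.age_variance + self.gap_sd**2 + v)

    def with_panel_r2(self, r2: float) -> "CohortConfig":
        """Copy of the config with noise_sd solved so oracle R² equals ``r2``."""
        if not 0.0 < r2 < 1.0:
            raise ConfigurationError("target R² must lie in (0, 1)")
        slack = self.age_variance * (1.0 - r2) / r2 - self.gap_sd**2
        if slack <= 0:
            raise ConfigurationError("target R² unreachable: gap_sd alone exceeds the noise budget")
        sigma = self.loading_scale * math.sqrt(self.markers_per_organ * slack)
        return replace(self, noise_sd=sigma)


@dataclass
class TrueParameters:
    """Planted truth stored alongside every generated cohort."""

    gaps: pd.DataFrame  # participants x organs, latent years
    liability: pd.Series  # logit of disease probability
    is_case: pd.Series  # bool, liability-designated disease
    grs_scaled: pd.Series  # per-SD genetic score used in the liability
    packyears_true: pd.Series  # before observational masking
    loadings: dict[str, np.ndarray]
    intercepts: dict[str, np.ndarray]
    liability_intercept: float
    config: CohortConfig


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    panels: dict[str, pd.DataFrame]
    genotypes: pd.DataFrame
    variant_panel: pd.DataFrame
    records: pd.DataFrame
    truth: TrueParameters
    config: CohortConfig


# ---------------------------------------------------------------------------
# variant panels


def build_variant_panel(seed: int = 0, n_variants: int = 48) -> pd.DataFrame:
    """Synthetic stand-in for a published disease risk-variant panel.

    48 variants partitioned into pathway groups (complement, lipid,
    extracellular matrix, the single ARMS2 variant, remaining).  The two
    named variants keep their field roles and effect magnitudes
    (per-allele OR ~1.59 and ~1.78); coordinates and the other 46 variants
    are synthetic, not literature look-ups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0DE]))
    if n_variants < 3:
        raise ConfigurationError("variant panel needs at least 3 variants")
    rows = [
        {"variant_id": "rs1061170", "risk_allele": "C", "freq": 0.36, "log_or": math.log(1.59), "tag": "complement"},
        {"variant_id": "rs10490924", "risk_allele": "T", "freq": 0.21, "log_or": math.log(1.78), "tag": "ARMS2"},
    ]
    tags = ["complement"] * 9 + ["lipid"] * 6 + ["ECM"] * 7
    tags += ["remaining"] * (n_variants - 2 - len(tags))
    for i, tag in enumerate(tags):
        rows.append(
            {
                "variant_id": f"rs9{i:06d}",
                "risk_allele": str(rng.choice(list("ACGT"))),
                "freq": float(rng.uniform(0.05, 0.95)),
                "log_or": float(rng.uniform(0.03, 0.25)),
                "tag": tag,
            }
        )
    return pd.DataFrame(rows)


def build_clock_panels(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Synthetic weight panels for epigenetic-clock genetic scores.

    Sizes follow the published panels: 24 variants for IEAA, 9 for
    HannumAge and 12 for PhenoAge acceleration; weights are synthetic.
    """
    sizes = {"IEAA": 24, "HannumAge": 9, "PhenoAge": 12}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC10C]))
    panels: dict[str, pd.DataFrame] = {}
    for name, size in sizes.items():
        panels[name] = pd.DataFrame(
            {
                "variant_id": [f"rs{name[:2].lower()}{i:05d}" for i in range(size)],
                "risk_allele": rng.choice(list("ACGT"), size=size),
                "freq": rng.uniform(0.05, 0.95, size=size),
                "log_or": rng.normal(0.0, 0.05, size=size),
                "tag": name,
            }
        )
    return panels


# ---------------------------------------------------------------------------
# participants


def generate_participants(config: CohortConfig) -> pd.DataFrame:
    """One row per person: demographics, lifestyle, ancestry PCs, dates.

    Chronological ages are uniform on ``age_range``; BMI is log-normal
    around 27; smoking status is never/previous/current with packyears
    zero by definition for never-smokers and log-normal otherwise (a
    fraction of ever-smokers has packyears masked to missing); raw
    alcohol frequency is low/high/stopped/missing; ten ancestry PCs are
    standard normal.  Deterministic given ``config.seed``.
    """
    rng = stage_rng(config.seed, "participants")
    n = config.n_participants
    low, high = config.age_range

    ids = pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id")
    age = rng.uniform(low, high, size=n)
    sex = np.where(rng.uniform(size=n) < config.female_fraction, "female", "male")
    bmi = np.exp(rng.normal(math.log(27.0), 0.17, size=n))
    smoking = rng.choice(["never", "previous", "current"], size=n, p=[0.55, 0.35, 0.10])
    packyears = np.zeros(n)
    prev = smoking == "previous"
    curr = smoking == "current"
    packyears[prev] = np.exp(rng.normal(2.2, 0.8, size=int(prev.sum())))
    packyears[curr] = np.exp(rng.normal(2.8, 0.7, size=int(curr.sum())))
    packyears_obs = packyears.copy()
    ever = prev | curr
    mask = ever & (rng.uniform(size=n) < config.packyears_missing_rate)
    packyears_obs[mask] = np.nan

    alcohol_raw = rng.choice(["low", "high", "stopped", "missing"], size=n, p=[0.55, 0.35, 0.06, 0.04])

    start = pd.Timestamp(config.recruitment_start)
    recruit_offset = rng.uniform(0, config.recruitment_years * 365.25, size=n)
    recruitment = start + pd.to_timedelta(np.floor(recruit_offset), unit="D")
    dob = recruitment - pd.to_timedelta(np.round(age * 365.25), unit="D")

    table = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "smoking_status": smoking,
            "packyears": packyears_obs,
            "alcohol_raw": alcohol_raw,
            "recruitment_date": recruitment,
            "date_of_birth": dob,
            "gp_coverage": rng.uniform(size=n) < config.gp_coverage,
        },
        index=ids,
    )
    for k in range(1, 11):
        table[f"pc{k}"] = rng.normal(size=n)
    # attrs must hold plain python values; consumers rebuild the Series
    table.attrs["packyears_true"] = packyears.tolist()
    return table


# ---------------------------------------------------------------------------
# genotypes and disease


def generate_genotypes(participants: pd.DataFrame, panel: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Per-person dosages drawn Binomial(2, freq), independently per variant."""
    freqs = np.asarray(panel["freq"], dtype=float)
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        bad = panel.loc[(freqs <= 0) | (freqs >= 1), "variant_id"].tolist()
        raise ConfigurationError(f"allele frequency must lie strictly in (0, 1): {bad}")
    rng = stage_rng(config.seed, "genotypes")
    n = len(participants)
    dosages = rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)
    return pd.DataFrame(dosages, index=participants.index, columns=list(panel["variant_id"]))


def assign_disease(
    participants: pd.DataFrame,
    grs_scaled: pd.Series,
    config: CohortConfig,
    packyears_true: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series, float]:
    """Logistic disease liability; intercept solved to hit the prevalence target.

    liability = b0 + b_age·(age − mean) + b_pack·packyears + b_bmi·(BMI − 27)
              + b_grs·GRS_sd, case ~ Bernoulli(expit(liability)).
    """
    rng = stage_rng(config.seed, "disease")
    if packyears_true is None:
        packyears_true = _packyears_truth(participants)
    age = participants["age"].to_numpy()
    xb = (
        config.liability_age_beta * (age - age.mean())
        + config.liability_packyears_beta * np.asarray(packyears_true, dtype=float)
        + config.liability_bmi_beta * (participants["bmi"].to_numpy() - 27.0)
        + config.liability_grs_beta * grs_scaled.reindex(participants.index).to_numpy()
    )
    target = config.disease_prevalence_target

    def shortfall(b0: float) -> float:
        return float(expit(b0 + xb).mean()) - target

    if len(xb) == 0 or target <= 0.0:
        intercept, prob = -np.inf, np.zeros_like(xb)
    else:
        intercept = brentq(shortfall, -40.0, 15.0)
        prob = expit(intercept + xb)
    is_case = pd.Series(rng.uniform(size=len(xb)) < prob, index=participants.index, name="is_case")
    liability = pd.Series(intercept + xb, index=participants.index, name="liability")
    return liability, is_case, float(intercept)


# ---------------------------------------------------------------------------
# biomarkers


def generate_organ_biomarkers(
    participants: pd.DataFrame,
    config: CohortConfig,
    is_case: pd.Series | None = None,
    grs_scaled: pd.Series | None = None,
    packyears_true: pd.Series | None = None,
) -> tuple[dict[str, pd.DataFrame], TrueParameters]:
    """Per-organ marker panels loaded on latent biological age.

    latent_o = age + gap_o with gap_o ~ N(0, gap_sd) plus planted case,
    genetic and lifestyle shifts; marker_j = intercept_j + loading_j ×
    latent + N(0, noise_sd); missingness injected MCAR at
    ``missingness_rate`` (optionally age-tilted).
    """
    unknown = set(config.organs) - set(ORGANS)
    if unknown:
        raise ConfigurationError(f"unknown organ labels: {sorted(unknown)}")
    rng = stage_rng(config.seed, "biomarkers")
    n = len(participants)
    idx = participants.index
    zeros = pd.Series(0.0, index=idx)
    case = (is_case.astype(float) if is_case is not None else zeros).reindex(idx).fillna(0.0)
    grs = (grs_scaled if grs_scaled is not None else zeros).reindex(idx).fillna(0.0)
    if packyears_true is None:
        packyears_true = _packyears_truth(participants)
    packyears_true = pd.Series(np.asarray(packyears_true, dtype=float), index=idx)

    age = participants["age"].to_numpy()
    bmi = participants["bmi"].to_numpy()
    lifestyle = config.packyears_gap_slope * packyears_true.to_numpy() + config.bmi_gap_slope * (bmi - 27.0)

    panels: dict[str, pd.DataFrame] = {}
    gaps = pd.DataFrame(index=idx)
    loadings: dict[str, np.ndarray] = {}
    intercepts: dict[str, np.ndarray] = {}
    p = config.markers_per_organ
    for organ in config.organs:
        gap = (
            rng.normal(0.0, config.gap_sd, size=n)
            + config.case_gap_effect.get(organ, 0.0) * case.to_numpy()
            + config.grs_gap_slope.get(organ, 0.0) * grs.to_numpy()
            + lifestyle
        )
        gaps[organ] = gap
        latent = age + gap
        load = np.full(p, config.loading_scale)
        inter = rng.normal(100.0, 10.0, size=p)
        values = inter + np.outer(latent, load) + rng.normal(0.0, config.noise_sd, size=(n, p))
        if config.missingness_rate > 0 and n > 0:
            if config.missing_depends_on_age:
                # tilt: older participants up to twice as likely to be missing
                rate = config.missingness_rate * (0.5 + (age - age.min()) / max(np.ptp(age), 1e-9))
                miss = rng.uniform(size=(n, p)) < rate[:, None]
            else:
                miss = rng.uniform(size=(n, p)) < config.missingness_rate
            values = np.where(miss, np.nan, values)
        panels[organ] = pd.DataFrame(values, index=idx, columns=[f"{organ}_m{j}" for j in range(p)])
        loadings[organ] = load
        intercepts[organ] = inter

    truth = TrueParameters(
        gaps=gaps,
        liability=pd.Series(np.nan, index=idx),
        is_case=case.astype(bool),
        grs_scaled=grs,
        packyears_true=packyears_true,
        loadings=loadings,
        intercepts=intercepts,
        liability_intercept=math.nan,
        config=config,
    )
    return panels, truth


# ---------------------------------------------------------------------------
# diagnosis records


def generate_diagnosis_records(
    participants: pd.DataFrame,
    config: CohortConfig,
    is_case: pd.Series,
) -> pd.DataFrame:
    """GP-style coded diagnosis records with event dates.

    Every liability-designated case receives at least one record from a
    true code family; a ``prevalent_fraction`` of cases is dated before
    recruitment and an ``under40_fraction`` is dated before age 40.
    Decoy families are assigned to random participants independently of
    liability.  Codes identify their family by their first 2-3 characters.
    """
    rng = stage_rng(config.seed, "records")
    followup = pd.Timestamp(config.followup_end)
    rows: list[tuple[str, str, pd.Timestamp]] = []

    case_ids = participants.index[is_case.reindex(participants.index).fillna(False).to_numpy(dtype=bool)]
    for pid in case_ids:
        recruit = participants.at[pid, "recruitment_date"]
        dob = participants.at[pid, "date_of_birth"]
        family = TRUE_CODE_FAMILIES[rng.integers(len(TRUE_CODE_FAMILIES))]
        u = rng.uniform()
        if u < config.prevalent_fraction:
            first = recruit - pd.Timedelta(days=float(rng.uniform(30, 5 * 365.25)))
        elif u < config.prevalent_fraction + config.under40_fraction:
            first = dob + pd.Timedelta(days=float(rng.uniform(37.2 * 365.25, 39.8 * 365.25)))
        else:
            horizon = max((followup - recruit).days - 1, 31)
            first = recruit + pd.Timedelta(days=float(rng.uniform(30, horizon)))
        n_rec = 1 + rng.poisson(0.5)
        for k in range(n_rec):
            code = family + _CODE_SUFFIXES[rng.integers(len(_CODE_SUFFIXES))]
            date = first + pd.Timedelta(days=float(rng.uniform(0, 365)) * k)
            rows.append((pid, code, min(date, followup)))

    for family in DECOY_CODE_FAMILIES[: config.decoy_family_count]:
        carriers = participants.index[rng.uniform(size=len(participants)) < config.decoy_carrier_rate]
        for pid in carriers:
            recruit = participants.at[pid, "recruitment_date"]
            code = family + _CODE_SUFFIXES[rng.integers(len(_CODE_SUFFIXES))]
            span = (followup - recruit).days + 2 * 365
            date = recruit - pd.Timedelta(days=2 * 365) + pd.Timedelta(days=float(rng.uniform(0, max(span, 1))))
            rows.append((pid, code, min(date, followup)))

    records = pd.DataFrame(rows, columns=["participant_id", "code", "event_date"])
    records["event_date"] = pd.to_datetime(records["event_date"]).dt.normalize()
    return records.sort_values(["participant_id", "event_date"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(config: CohortConfig, variant_panel: pd.DataFrame | None = None) -> SyntheticCohort:
    """Generate a full cohort: participants, genotypes, disease, panels, records."""
    from .scores import compute_grs, scale_scores

    if variant_panel is None:
        variant_panel = build_variant_panel(seed=config.seed)
    participants = generate_participants(config)
    genotypes = generate_genotypes(participants, variant_panel, config)
    packyears_true = _packyears_truth(participants)

    if len(participants):
        grs = compute_grs(genotypes, variant_panel)["score"]
        grs_scaled = scale_scores(grs.to_frame("score"), reference_ids=participants.index)["score"]
    else:
        grs_scaled = pd.Series(dtype=float)
    liability, is_case, intercept = assign_disease(participants, grs_scaled, config, packyears_true)
    panels, truth = generate_organ_biomarkers(participants, config, is_case, grs_scaled, packyears_true)
    truth.liability = liability
    truth.liability_intercept = intercept
    records = generate_diagnosis_records(participants, config, is_case)
    return SyntheticCohort(
        participants=participants,
        panels=panels,
        genotypes=genotypes,
        variant_panel=variant_panel,
        records=records,
        truth=truth,
        config=config,
    )
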