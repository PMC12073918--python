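"""Weighted genetic risk scores from dosages and variant-weight panels.

A score is the per-person count of risk-increasing alleles weighted
(multiplied) by each variant's published log odds ratio.  Panels can be
stratified by molecular pathway (complement, lipid, extracellular
matrix, the single ARMS2 variant, and the remaining variants) or carry
epigenetic-clock tags (IEAA, HannumAge, PhenoAge).  Scaled scores are
expressed in standard-deviation units over a declared reference sample
so downstream slopes read as years per SD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PATHWAY_TAGS",
    "CLOCK_TAGS",
    "PanelError",
    "compute_grs",
    "stratify_panels",
    "scale_scores",
    "read_weight_panel",
    "read_dosage_tsv",
    "read_vcf_dosages",
    "write_dosage_vcf",
]

PATHWAY_TAGS = ("complement", "lipid", "ECM", "ARMS2", "remaining")
CLOCK_TAGS = ("IEAA", "HannumAge", "PhenoAge")


class PanelError(ValueError):
    """Raised for malformed weight panels or missing variants in strict mode."""


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_id", "log_or"}
    missing = required - set(panel.columns)
    if missing:
        raise PanelError(f"weight panel lacks columns: {sorted(missing)}")
    if not np.isfinite(panel["log_or"].to_numpy(dtype=float)).all():
        raise PanelError("non-finite log odds ratio in weight panel")
    return panel


def compute_grs(
    genotypes: pd.DataFrame,
    panel: pd.DataFrame,
    strict: bool = False,
    score_name: str = "score",
) -> pd.DataFrame:
    """score_i = Σ_v dosage_iv × logOR_v over the panel's variants.

    Missing dosage cells are mean-imputed from the variant's sample mean.
    Variants absent from ``genotypes`` raise in strict mode, otherwise
    they are skipped and listed in ``result.attrs['missing_variants']``
    (the convention when a few panel variants were never imputed in the
    genotype data).
    """
    _check_panel(panel)
    present = panel["variant_id"].isin(genotypes.columns)
    absent = panel.loc[~present, "variant_id"].tolist()
    if absent and strict:
        raise PanelError(f"variants absent from genotypes: {absent}")
    used = panel.loc[present]
    dosages = genotypes[list(used["variant_id"])].to_numpy(dtype=float)
    imputed_cells = int(np.isnan(dosages).sum())
    if imputed_cells:
        col_means = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.where(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_means[nan_c]
    weights = used["log_or"].to_numpy(dtype=float)
    scores = pd.DataFrame({score_name: dosages @ weights}, index=genotypes.index)
    scores.attrs["missing_variants"] = absent
    scores.attrs["mean_imputed_cells"] = imputed_cells
    scores.attrs["n_variants_used"] = int(len(used))
    return scores


def stratify_panels(panel: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a tagged master panel into {overall, per-pathway} panels.

    Pathway panels partition the overall panel; the ARMS2 panel contains
    exactly the single rs10490924-role variant.
    """
    _check_panel(panel)
    if "tag" not in panel.columns or panel["tag"].isna().any() or (panel["tag"] == "").any():
        raise PanelError("every variant must carry exactly one pathway tag")
    bad = set(panel["tag"]) - set(PATHWAY_TAGS) - set(CLOCK_TAGS)
    if bad:
        raise PanelError(f"unknown pathway tags: {sorted(bad)}")
    out: dict[str, pd.DataFrame] = {"overall": panel.copy()}
    for tag, sub in panel.groupby("tag", sort=False):
        out[str(tag)] = sub.copy()
    return out


def scale_scores(
    scores: pd.DataFrame,
    reference_ids: pd.Index | list,
    center: bool = True,
) -> pd.DataFrame:
    """Express scores in SD units of a declared reference sample.

    scaled = (score − reference mean) / reference SD.  Slopes per SD are
    invariant to the centering choice, so ``center=False`` divides only.
    """
    ref = scores.loc[pd.Index(reference_ids)]
    sd = ref.std(ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = sd.index[(sd <= 0) | sd.isna()].tolist()
        raise PanelError(f"zero or undefined reference SD for score columns: {bad}")
    mean = ref.mean() if center else 0.0
    scaled = (scores - mean) / sd
    scaled.attrs["reference_n"] = len(ref)
    scaled.attrs["reference_sd"] = sd.to_dict()
    return scaled


# ---------------------------------------------------------------------------
# I/O


def read_weight_panel(path) -> pd.DataFrame:
    """Read a variant-weight panel TSV (variant_id, risk_allele, log_or, tag)."""
    return _check_panel(pd.read_csv(path, sep="\t"))


def read_dosage_tsv(path) -> pd.DataFrame:
    """Dosage TSV: rows = participants (index column), columns = variant ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf_dosages(path) -> pd.DataFrame:
    """Read per-sample dosages from a VCF: DS field, falling back to GT counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = None
        try:
            arr = variant.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            ds = None
        if ds is None or len(ds) != len(samples):
            ds = np.array(
                [
                    np.nan if g[0] < 0 or g[1] < 0 else float(g[0] > 0) + float(g[1] > 0)
                    for g in variant.genotypes
                ]
            )
        columns[vid] = ds
    return pd.DataFrame(columns, index=pd.Index(samples, name="participant_id"))


def write_dosage_vcf(genotypes: pd.DataFrame, path, chrom: str = "1") -> None:
    """Write dosages as a minimal single-chromosome VCF with a DS FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.index) + "\n")
        for pos, vid in enumerate(genotypes.columns, start=1):
            dosages = genotypes[vid].to_numpy(dtype=float)
            cells = []
            for d in dosages:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = "0/0" if d < 0.5 else ("0/1" if d < 1.5 else "1/1")
                    cells.append(f"{gt}:{d:.3f}")
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tG\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n")
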