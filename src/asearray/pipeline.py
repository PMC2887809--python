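"""End-to-end orchestration: simulate -> summarize -> QC -> normalize -> fit -> evaluate.

Every run is a pure function of (inputs, config, seed): reruns are
byte-identical. Intermediate tables use the documented TSV schemas, so each
stage can also be run standalone on files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from . import simulate as sim
from .summarize import summarize_array
from .qc import compute_array_qc, drop_flagged_arrays, normalize_summaries, DEFAULT_IQR_THRESHOLD
from .linear_models import (
    build_design_matrix, pivot_m_matrix, fit_snp_models,
    make_baseline_contrasts, apply_contrasts, empirical_bayes_moderate,
    estimate_dye_effects,
)
from .roc import build_truth_set, roc_curve, auc_by_mixture
from .filtering import (
    regress_response, filter_by_intensity, suggest_intensity_threshold,
    interpolation_ase_caller,
)

logger = logging.getLogger(__name__)

#: The preprocessing grid benchmarked by default: local background
#: subtraction on/off crossed with within-array quantile normalization.
DEFAULT_CONDITIONS = (
    {"background": True, "normalize": True},
    {"background": True, "normalize": False},
    {"background": False, "normalize": True},
    {"background": False, "normalize": False},
)


def condition_label(condition: dict) -> str:
    bg = "bg" if condition.get("background", True) else "nobg"
    nm = "norm" if condition.get("normalize", True) else "nonorm"
    return f"{bg}+{nm}"


def preprocess(
    beads: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    background: bool = True,
    normalize: bool = True,
    iqr_threshold: float = DEFAULT_IQR_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summarize beads, flag/drop failed arrays, optionally normalize.

    Returns ``(summary, kept_sample_sheet, qc_table)``. Flagged arrays are
    dropped before normalization and before any model fitting.
    """
    summary = summarize_array(beads, use_background=background)
    qc_table = compute_array_qc(summary, threshold=iqr_threshold)
    n_flagged = int(qc_table["flagged"].sum())
    if n_flagged:
        logger.info("QC flagged %d arrays: %s", n_flagged,
                    list(qc_table.loc[qc_table["flagged"], "array_id"]))
    summary = drop_flagged_arrays(summary, qc_table)
    kept = sample_sheet[sample_sheet["array_id"].isin(summary["array_id"].unique())].reset_index(drop=True)
    lost = set(sample_sheet["array_id"]) - set(kept["array_id"])
    for p in sorted(set(sample_sheet["mix_p"].dropna())):
        arrays_p = sample_sheet.loc[sample_sheet["mix_p"] == p, "array_id"]
        if set(arrays_p) <= lost and len(arrays_p):
            logger.warning("mixture %.2f lost all arrays to QC; it will be skipped", p)
    if normalize:
        summary = normalize_summaries(summary)
    return summary, kept, qc_table


def score_mixture_experiment(
    summary: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    baseline: float = 0.5,
    proportion: float = 0.01,
) -> pd.DataFrame:
    """Fit per-mixture models, contrast against the baseline, moderate.

    Returns the tidy moderated-statistics table (one row per SNP and
    mixture-vs-baseline contrast) whose ``log_odds`` column ranks SNPs by
    evidence of allelic imbalance.
    """
    design = build_design_matrix(sample_sheet, "per_mixture")
    base_label = f"mix_{int(round(baseline * 100)):03d}"
    if base_label not in design.columns:
        raise ValueError(f"baseline mixture {baseline} not present among arrays")
    m = pivot_m_matrix(summary)
    fit = fit_snp_models(m, design)
    C, labels = make_baseline_contrasts(design.columns, base_label)
    mod = empirical_bayes_moderate(apply_contrasts(fit, C, labels), proportion=proportion)
    return mod.to_frame()


def evaluate_conditions(
    beads: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    truth: pd.DataFrame,
    conditions: Sequence[dict] = DEFAULT_CONDITIONS,
    baseline: float = 0.5,
    iqr_threshold: float = DEFAULT_IQR_THRESHOLD,
    proportion: float = 0.01,
    keep_curves: bool = False,
) -> dict:
    """Benchmark preprocessing conditions on one generated experiment.

    Runs the full pipeline once per condition on the *same* bead table and
    evaluates each mixture-vs-baseline ranking against the truth set.
    Returns a dict with the long-form AUC table (condition x mixture), the
    per-condition QC tables, and optionally the ROC curves.
    """
    auc_rows, curves, qcs = [], {}, {}
    for condition in conditions:
        label = condition_label(condition)
        summary, kept, qc_table = preprocess(
            beads, sample_sheet,
            background=condition.get("background", True),
            normalize=condition.get("normalize", True),
            iqr_threshold=iqr_threshold,
        )
        qcs[label] = qc_table
        scores = score_mixture_experiment(summary, kept, baseline=baseline, proportion=proportion)
        tab = auc_by_mixture(scores, truth)
        tab.insert(0, "condition", label)
        auc_rows.append(tab)
        if keep_curves:
            for contrast, grp in scores.groupby("contrast"):
                curves[(label, contrast)] = roc_curve(grp.set_index("snp_id")["log_odds"], truth)
    out = {"auc": pd.concat(auc_rows, ignore_index=True), "qc": qcs}
    if keep_curves:
        out["curves"] = curves
    return out


def run_mixture_benchmark(
    cfg: SimConfig,
    conditions: Sequence[dict] = DEFAULT_CONDITIONS,
    baseline: float = 0.5,
    iqr_threshold: float = DEFAULT_IQR_THRESHOLD,
    proportion: float = 0.01,
    genotypes: Optional[pd.DataFrame] = None,
    maximize_discordance: bool = False,
    keep_curves: bool = False,
) -> dict:
    """Simulate a mixture-titration series and benchmark preprocessing.

    Generates genotypes for a discordant pair of individuals, simulates the
    titration experiment, derives the truth set, and evaluates each
    preprocessing condition's per-mixture ROC/AUC. The returned dict also
    carries the generated tables for inspection or file output.
    """
    if genotypes is None:
        genotypes = sim.sample_genotype_pair(
            cfg.n_snps, cfg.allele_freq, cfg.nn_rate, seed=cfg.seed,
            maximize_discordance=maximize_discordance)
    beads, sheet, manifest = sim.simulate_mixture_experiment(cfg, genotypes)
    truth = build_truth_set(genotypes)
    result = evaluate_conditions(
        beads, sheet, truth, conditions=conditions, baseline=baseline,
        iqr_threshold=iqr_threshold, proportion=proportion, keep_curves=keep_curves)
    result.update({"genotypes": genotypes, "truth": truth, "manifest": manifest,
                   "sample_sheet": sheet})
    return result


def run_dye_swap_analysis(
    cfg: SimConfig,
    materials: Sequence[str] = ("gDNA", "cDNA"),
    background: bool = True,
    iqr_threshold: float = DEFAULT_IQR_THRESHOLD,
) -> dict:
    """Dye-effect estimation before and after normalization, per material.

    For each material, simulates a dye-swap experiment, summarizes and QCs
    it once, then estimates per-SNP dye effects on the non-normalized and
    the quantile-normalized summaries (the four-condition comparison).

    Returns ``{"effects": long DataFrame, "trends": {(material, normalized):
    dict}, "manifests": {material: DataFrame}}``.
    """
    frames, trends, manifests = [], {}, {}
    for material in materials:
        beads, sheet, manifest = sim.simulate_dye_swap_experiment(cfg, material=material)
        manifests[material] = manifest
        summary, kept, _ = preprocess(beads, sheet, background=background,
                                      normalize=False, iqr_threshold=iqr_threshold)
        for normalized in (False, True):
            current = normalize_summaries(summary) if normalized else summary
            per_snp, trend = estimate_dye_effects(current, kept)
            per_snp = per_snp.assign(material=material, normalized=normalized)
            frames.append(per_snp)
            trends[(material, normalized)] = trend
    return {"effects": pd.concat(frames, ignore_index=True), "trends": trends,
            "manifests": manifests}


def run_cohort_filtering(
    cfg: SimConfig,
    n_individuals: int = 20,
    genotypes: Optional[pd.DataFrame] = None,
    normalize: bool = True,
    a_threshold: Optional[float] = None,
    robust: bool = True,
) -> dict:
    """Cohort simulation, non-responder regression, filtering and ASE calls.

    Simulates paired gDNA/cDNA summaries for a cohort, optionally quantile
    normalizes each material separately, regresses per-SNP cDNA on gDNA
    log-ratios over homozygotes, chooses (or applies) an intensity
    threshold, and runs the interpolation ASE caller on heterozygotes.
    """
    if genotypes is None:
        genotypes = sim.sample_genotype_cohort(
            cfg.n_snps, n_individuals, cfg.allele_freq, cfg.nn_rate, seed=cfg.seed)
    summaries, sheet, manifest = sim.simulate_cohort(cfg, genotypes)

    mats = {}
    for material in ("gDNA", "cDNA"):
        arrays = sheet.loc[sheet["material"] == material]
        block = summaries[summaries["array_id"].isin(arrays["array_id"])]
        if normalize:
            block = normalize_summaries(block)
        m = pivot_m_matrix(block)
        m.columns = [arrays.set_index("array_id")["sample_id"][c] for c in m.columns]
        a = pivot_m_matrix(block, "mean_A")
        a.columns = m.columns
        mats[material] = (m, a)

    gdna_m, _ = mats["gDNA"]
    cdna_m, cdna_a = mats["cDNA"]
    mean_a = cdna_a.mean(axis=1)

    stats = regress_response(cdna_m, gdna_m, genotypes, mean_a=mean_a)
    threshold = a_threshold if a_threshold is not None else suggest_intensity_threshold(stats)
    kept, report = filter_by_intensity(stats[stats["eligible"]].reset_index(drop=True), threshold)
    calls, lines = interpolation_ase_caller(cdna_m, gdna_m, genotypes, robust=robust)
    return {"stats": stats, "threshold": float(threshold), "kept": kept,
            "report": report, "calls": calls, "lines": lines,
            "manifest": manifest, "genotypes": genotypes,
            "gdna_m": gdna_m, "cdna_m": cdna_m, "mean_A": mean_a}
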