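"""Truth sets from genotype pairs and ROC evaluation of SNP rankings.

In a two-individual gDNA mixture, SNPs with different genotypes in the two
individuals have a built-in allelic imbalance at every unbalanced mixing
proportion (true positives), SNPs with identical genotypes stay balanced
(true negatives), and SNPs with missing calls are excluded. Ranking SNPs by
a detection score (log-odds by default) against this truth yields ROC
curves and AUCs used to benchmark preprocessing choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics


@dataclass
class ROCResult:
    """ROC sweep over score thresholds (descending) plus the trapezoid AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr})


def build_truth_set(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Label SNPs as true positives/negatives from a two-individual genotype table.

    Different genotypes (AA:BB, AA:AB, BB:AB, ...) mean mixing the two
    individuals' gDNA creates a real allelic imbalance -> ``true_positive``.
    Identical genotypes (AA:AA, AB:AB, BB:BB) are unaffected by the mixing
    proportion -> ``true_negative``. Any missing (NN) call -> ``excluded``.

    Returns a DataFrame indexed by snp_id with columns ``label``,
    ``genotype_class`` (e.g. "AA:BB") and ``reason`` for exclusions.
    """
    if genotypes.shape[1] != 2:
        raise ValueError("truth set requires genotypes for exactly 2 individuals")
    g1 = genotypes.iloc[:, 0].astype(str)
    g2 = genotypes.iloc[:, 1].astype(str)
    valid = {"AA", "AB", "BB", "NN"}
    bad = (set(g1) | set(g2)) - valid
    if bad:
        raise ValueError(f"unknown genotype calls: {sorted(bad)}")
    missing = (g1 == "NN") | (g2 == "NN")
    label = np.where(missing, "excluded", np.where(g1 == g2, "true_negative", "true_positive"))
    return pd.DataFrame({
        "label": label,
        "genotype_class": g1.str.cat(g2, sep=":"),
        "reason": np.where(missing, "NN", ""),
    }, index=genotypes.index)


def roc_curve(scores: pd.Series, truth: pd.DataFrame) -> ROCResult:
    """ROC curve of a SNP score against a truth set.

    Thresholds sweep the unique scores in descending order with tied scores
    entering together (diagonal segments); the AUC is the trapezoid area,
    which equals the tie-aware Mann-Whitney probability that a random true
    positive outscores a random true negative (ties counted 1/2). Excluded
    SNPs and SNPs without a score are ignored.
    """
    joined = truth.join(scores.rename("score"), how="inner")
    joined = joined[joined["label"].isin(["true_positive", "true_negative"])]
    joined = joined[np.isfinite(joined["score"])]
    y = (joined["label"] == "true_positive").to_numpy()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need at least one scored TP and TN (got {n_pos} TP, {n_neg} TN)")
    fpr, tpr, thr = metrics.roc_curve(y, joined["score"].to_numpy(), drop_intermediate=False)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr,
                     auc=float(metrics.auc(fpr, tpr)), n_positive=n_pos, n_negative=n_neg)


def compare_conditions(beads, sample_sheet, truth, conditions, **kwargs) -> pd.DataFrame:
    """AUC table (condition x mixture) for a grid of preprocessing settings.

    Runs the full pipeline per condition on the same generated experiment;
    thin wrapper over :func:`asearray.pipeline.evaluate_conditions`.
    """
    from .pipeline import evaluate_conditions  # deferred: avoids an import cycle

    return evaluate_conditions(beads, sample_sheet, truth, conditions=conditions, **kwargs)["auc"]


def auc_by_mixture(scores: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """AUC per contrast from a tidy moderated-statistics table.

    ``scores`` is long-form with columns ``snp_id``, ``contrast`` and a
    score column ``log_odds`` (or ``t_moderated`` via ``abs``); two-sided
    evidence is used — the direction of imbalance is not part of the truth.
    """
    rows = []
    for contrast, grp in scores.groupby("contrast", sort=True):
        s = grp.set_index("snp_id")["log_odds"]
        res = roc_curve(s, truth)
        rows.append({"contrast": contrast, "auc": res.auc,
                     "n_tp": res.n_positive, "n_tn": res.n_negative})
    return pd.DataFrame(rows)
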