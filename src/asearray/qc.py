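"""Array-level quality flagging and within-array quantile normalization.

Failed hybridizations show compressed signal in both channels; a low
interquartile range (IQR) of the summarized log2 intensities is a good
predictor, and arrays with IQR <= 1 in either channel are flagged and
excluded downstream. Within one array, the red and green channel summaries
are quantile normalized against each other to suppress dye bias; M and A
are then recomputed from the normalized channels. gDNA and cDNA arrays have
very different signal distributions and are always normalized separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_IQR_THRESHOLD = 1.0


def compute_array_qc(summary: pd.DataFrame, threshold: float = DEFAULT_IQR_THRESHOLD) -> pd.DataFrame:
    """Per-array channel IQRs and the failed-hybridization flag.

    The IQR is the 75th minus 25th percentile (linear interpolation) of the
    per-SNP ``mean_logR``/``mean_logG`` summaries; an array is flagged when
    either channel's IQR is at or below ``threshold``.
    """
    rows = []
    for array_id, grp in summary.groupby("array_id", sort=True):
        if len(grp) < 4:
            raise ValueError(f"array {array_id!r} has fewer than 4 SNPs; IQR unreliable")
        q1r, q3r = np.percentile(grp["mean_logR"], [25, 75])
        q1g, q3g = np.percentile(grp["mean_logG"], [25, 75])
        iqr_r, iqr_g = q3r - q1r, q3g - q1g
        rows.append({
            "array_id": array_id,
            "iqr_logR": iqr_r,
            "iqr_logG": iqr_g,
            "flagged": bool(min(iqr_r, iqr_g) <= threshold),
        })
    return pd.DataFrame(rows)


def quantile_normalize_within_array(log_r, log_g) -> tuple[np.ndarray, np.ndarray]:
    """Force the two channels of one array onto a common distribution.

    The target distribution is the element-wise mean of the two sorted
    channel vectors; each value is replaced by the target value at its rank.
    Tied values within a channel receive the mean target value over their
    tied ranks. Rank order within each channel is preserved, and (absent
    within-channel ties) the sorted normalized vectors of the two channels
    are identical.
    """
    r = np.asarray(log_r, dtype=float)
    g = np.asarray(log_g, dtype=float)
    if r.shape != g.shape or r.ndim != 1:
        raise ValueError("channels must be 1-D vectors of equal length")
    if r.size == 0:
        raise ValueError("channels are empty")
    if not (np.isfinite(r).all() and np.isfinite(g).all()):
        raise ValueError("channels must be finite")
    target = 0.5 * (np.sort(r) + np.sort(g))

    def _assign(x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="stable")
        out = np.empty_like(target)
        out[order] = target
        # average the target over runs of tied input values
        return pd.Series(out).groupby(x).transform("mean").to_numpy()

    return _assign(r), _assign(g)


def recompute_m_a(log_r, log_g) -> tuple[np.ndarray, np.ndarray]:
    """Log-ratio M = log2R - log2G and average intensity A = (log2R + log2G)/2."""
    r = np.asarray(log_r, dtype=float)
    g = np.asarray(log_g, dtype=float)
    return r - g, 0.5 * (r + g)


def normalize_summaries(summary: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalize each array's channel summaries and recompute M/A.

    Operates per array on ``mean_logR``/``mean_logG`` and replaces
    ``mean_M``/``mean_A`` by values recomputed from the normalized channels.
    Arrays from different materials should be normalized in separate calls
    (the pipeline never pools gDNA and cDNA).
    """
    out = summary.copy()
    for _, idx in out.groupby("array_id", sort=False).groups.items():
        r, g = quantile_normalize_within_array(
            out.loc[idx, "mean_logR"].to_numpy(), out.loc[idx, "mean_logG"].to_numpy())
        m, a = recompute_m_a(r, g)
        out.loc[idx, "mean_logR"] = r
        out.loc[idx, "mean_logG"] = g
        out.loc[idx, "mean_M"] = m
        out.loc[idx, "mean_A"] = a
    out["normalized"] = True
    return out


def drop_flagged_arrays(summary: pd.DataFrame, qc: pd.DataFrame) -> pd.DataFrame:
    """Remove all rows belonging to QC-flagged arrays."""
    bad = set(qc.loc[qc["flagged"], "array_id"])
    return summary.loc[~summary["array_id"].isin(bad)].reset_index(drop=True)
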