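"""Bead-level to per-SNP summarization with robust outlier removal.

Each SNP is represented by ~30 replicate beads per array. Four per-bead
quantities are summarized independently — log2(red), log2(green), the
log-ratio M = log2(red/green) and the average log-intensity
A = (log2 red + log2 green)/2 — by removing outlier beads (more than
``k`` MADs from the median, single pass) and averaging the survivors.
Summaries are produced with or without local background subtraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BEAD_COLUMNS = ("array_id", "snp_id", "bead_index", "red_fg", "green_fg", "red_bg", "green_bg")
QUANTITIES = ("logR", "logG", "M", "A")


def subtract_local_background(beads: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Subtract per-bead local background from the foreground channels.

    Returns a copy with ``red_fg``/``green_fg`` replaced by
    ``max(fg - bg, floor)``; the floor keeps subsequent logs defined.
    """
    for col in ("red_bg", "green_bg"):
        if col not in beads.columns:
            raise ValueError(f"bead table lacks background column {col!r}")
    out = beads.copy()
    out["red_fg"] = np.maximum(beads["red_fg"] - beads["red_bg"], floor)
    out["green_fg"] = np.maximum(beads["green_fg"] - beads["green_bg"], floor)
    return out


def remove_outliers(values, k: float = 3.0, scaled_mad: bool = False) -> np.ndarray:
    """Drop values more than ``k`` MADs above or below the median.

    Single pass: the median and MAD are computed once on the input. By
    default the MAD is the raw median absolute deviation; ``scaled_mad``
    multiplies it by the 1.4826 normal-consistency constant (which changes
    which beads are flagged). When the MAD is zero only values exactly at
    the median are kept.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("remove_outliers requires at least one value")
    return v[_inlier_mask(v, k, scaled_mad)]


def _inlier_mask(v: np.ndarray, k: float, scaled_mad: bool) -> np.ndarray:
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if scaled_mad:
        mad *= 1.4826
    if mad == 0:
        return v == med
    return np.abs(v - med) <= k * mad


def summarize_array(
    beads: pd.DataFrame,
    use_background: bool = False,
    floor: float = 1.0,
    k: float = 3.0,
    scaled_mad: bool = False,
) -> pd.DataFrame:
    """Summarize a bead table to one row per (array, SNP).

    Outlier removal is applied to each of the four quantities independently:
    a bead can be excluded from the M average yet contribute to the A
    average. ``mean_M``/``mean_A`` are therefore averages of per-bead values,
    not recomputed from the channel means.

    Returns a DataFrame with columns ``array_id, snp_id, mean_logR,
    mean_logG, mean_M, mean_A, n_logR, n_logG, n_M, n_A,
    background_corrected``.
    """
    if beads.empty:
        raise ValueError("bead table is empty")
    work = subtract_local_background(beads, floor=floor) if use_background else beads

    bad = ~np.isfinite(work["red_fg"]) | ~np.isfinite(work["green_fg"])
    if bad.any():
        logger.warning("dropping %d beads with non-finite intensities", int(bad.sum()))
        work = work.loc[~bad]

    log_r = np.log2(np.maximum(work["red_fg"].to_numpy(dtype=float), floor))
    log_g = np.log2(np.maximum(work["green_fg"].to_numpy(dtype=float), floor))
    vals = pd.DataFrame({
        "array_id": work["array_id"].to_numpy(),
        "snp_id": work["snp_id"].to_numpy(),
        "logR": log_r,
        "logG": log_g,
        "M": log_r - log_g,
        "A": 0.5 * (log_r + log_g),
    })

    grouped = vals.groupby(["array_id", "snp_id"], sort=True, observed=True)
    med = grouped[list(QUANTITIES)].transform("median")
    absdev = (vals[list(QUANTITIES)] - med).abs()
    absdev[["array_id", "snp_id"]] = vals[["array_id", "snp_id"]]
    mad = absdev.groupby(["array_id", "snp_id"], sort=True, observed=True)[list(QUANTITIES)].transform("median")
    if scaled_mad:
        mad = mad * 1.4826

    masked = vals[list(QUANTITIES)].copy()
    for q in QUANTITIES:
        dev = (vals[q] - med[q]).abs()
        keep = np.where(mad[q].to_numpy() == 0, vals[q] == med[q], dev <= k * mad[q])
        masked.loc[~keep, q] = np.nan
    masked[["array_id", "snp_id"]] = vals[["array_id", "snp_id"]]

    agg = masked.groupby(["array_id", "snp_id"], sort=True, observed=True)[list(QUANTITIES)].agg(["mean", "count"])
    out = pd.DataFrame({
        "array_id": agg.index.get_level_values(0),
        "snp_id": agg.index.get_level_values(1),
    })
    for q in QUANTITIES:
        out[f"mean_{q}"] = agg[(q, "mean")].to_numpy()
        out[f"n_{q}"] = agg[(q, "count")].to_numpy().astype(int)
    out["background_corrected"] = bool(use_background)

    empty = out[[f"n_{q}" for q in QUANTITIES]].min(axis=1) == 0
    if empty.any():
        logger.warning("dropping %d (array, SNP) records with no usable beads", int(empty.sum()))
        out = out.loc[~empty]
    return out.reset_index(drop=True)
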