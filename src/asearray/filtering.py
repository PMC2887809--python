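"""Non-responder detection, intensity filtering and the interpolation ASE caller.

Some SNP probes produce cDNA signal that ignores the alleles present (weak
or non-specific signal, typically from low- or non-expressed transcripts).
Regressing each SNP's per-individual average cDNA log-ratio on the gDNA
log-ratio over *homozygous* individuals summarizes responsiveness into a
slope (near the full gDNA dynamic range for responders, near 0 for
non-responders) and an intercept. Slope rises with average intensity, so
filtering out low-intensity SNPs removes most non-specific probes.

The interpolation caller predicts, for each heterozygous sample, the
expected cDNA log-ratio and a confidence band from the homozygote
populations: per SNP, center and spread (median +/- 2 MADs, or mean +/- 2
SDs) of the homozygote log-ratios are computed for cDNA and gDNA; across
SNPs, the cDNA upper bound is regressed on the gDNA lower bound, the cDNA
lower bound on the gDNA upper bound, and the centers on each other. ASE is
called when a heterozygote's observed cDNA log-ratio falls outside the band
interpolated at its own gDNA log-ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAD_SCALE = 1.4826  # normal-consistency constant: 2 MADs comparable to 2 SDs


def _simple_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ZeroDivisionError("zero variance in predictor")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return float(slope), float(ym - slope * xm)


def regress_response(
    cdna_m: pd.DataFrame,
    gdna_m: pd.DataFrame,
    genotypes: pd.DataFrame,
    mean_a: pd.Series | None = None,
    min_homozygotes: int = 3,
) -> pd.DataFrame:
    """Per-SNP regression of cDNA on gDNA log-ratios over homozygotes.

    ``cdna_m``/``gdna_m`` are SNP x individual matrices of per-individual
    average log-ratios (from the replicate-summarizing linear models);
    ``genotypes`` is the matching SNP x individual call table. Only SNPs
    with at least ``min_homozygotes`` AA and as many BB individuals are
    eligible; ineligible SNPs (including those whose homozygote gDNA
    log-ratios have zero variance) get NaN slope/intercept and a reason.

    Returns a DataFrame with columns ``snp_id, slope, intercept, n_AA,
    n_BB, mean_A, eligible, reason``.
    """
    common = cdna_m.index.intersection(gdna_m.index).intersection(genotypes.index)
    inds = [c for c in genotypes.columns if c in cdna_m.columns and c in gdna_m.columns]
    rows = []
    for snp in common:
        calls = genotypes.loc[snp, inds]
        cd = cdna_m.loc[snp, inds].to_numpy(dtype=float)
        gd = gdna_m.loc[snp, inds].to_numpy(dtype=float)
        ok = np.isfinite(cd) & np.isfinite(gd)
        hom = ok & calls.isin(["AA", "BB"]).to_numpy()
        n_aa = int((calls[hom].to_numpy() == "AA").sum())
        n_bb = int((calls[hom].to_numpy() == "BB").sum())
        rec = {"snp_id": snp, "slope": np.nan, "intercept": np.nan,
               "n_AA": n_aa, "n_BB": n_bb,
               "mean_A": float(mean_a.get(snp, np.nan)) if mean_a is not None else np.nan,
               "eligible": False, "reason": ""}
        if n_aa < min_homozygotes or n_bb < min_homozygotes:
            rec["reason"] = "too_few_homozygotes"
        else:
            try:
                rec["slope"], rec["intercept"] = _simple_regression(gd[hom], cd[hom])
                rec["eligible"] = True
            except ZeroDivisionError:
                rec["reason"] = "zero_gdna_variance"
        rows.append(rec)
    return pd.DataFrame(rows)


def filter_by_intensity(stats: pd.DataFrame, a_threshold: float) -> tuple[list, dict]:
    """Keep SNPs whose average intensity reaches ``a_threshold``.

    Returns the kept SNP ids and a report with removal counts and the slope
    distribution of kept versus removed SNPs.
    """
    keep = stats["mean_A"] >= a_threshold
    kept = stats.loc[keep, "snp_id"].tolist()
    report = {
        "a_threshold": float(a_threshold),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "kept_slope_median": float(stats.loc[keep, "slope"].median()) if keep.any() else np.nan,
        "removed_slope_median": float(stats.loc[~keep, "slope"].median()) if (~keep).any() else np.nan,
    }
    return kept, report


def suggest_intensity_threshold(stats: pd.DataFrame, n_bins: int = 10, slope_fraction: float = 0.5) -> float:
    """Pick an intensity cutoff from the slope-versus-intensity curve.

    Bins eligible SNPs by mean A, averages the slope per bin, and returns
    the lower edge of the first bin whose mean slope reaches
    ``slope_fraction`` of the brightest bin's mean slope. Stringency can be
    tuned by moving ``slope_fraction``.
    """
    el = stats[stats["eligible"] & np.isfinite(stats["mean_A"])]
    if len(el) < n_bins:
        raise ValueError("too few eligible SNPs to choose a threshold")
    edges = np.quantile(el["mean_A"], np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, el["mean_A"], side="right") - 1, 0, n_bins - 1)
    bin_slope = pd.Series(el["slope"].to_numpy()).groupby(bins).mean()
    target = slope_fraction * bin_slope.iloc[-1]
    for b in bin_slope.index:
        if bin_slope.loc[b] >= target:
            return float(edges[b])
    return float(edges[0])


@dataclass
class InterpolationLines:
    """The three global regression lines of the interpolation caller."""

    center: tuple[float, float]   # cDNA center ~ gDNA center
    upper: tuple[float, float]    # cDNA upper  ~ gDNA lower
    lower: tuple[float, float]    # cDNA lower  ~ gDNA upper


def _center_spread(values: np.ndarray, robust: bool) -> tuple[float, float]:
    if robust:
        med = float(np.median(values))
        return med, MAD_SCALE * float(np.median(np.abs(values - med)))
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def interpolation_ase_caller(
    cdna_m: pd.DataFrame,
    gdna_m: pd.DataFrame,
    genotypes: pd.DataFrame,
    robust: bool = True,
    k: float = 2.0,
    min_homozygotes: int = 3,
) -> tuple[pd.DataFrame, InterpolationLines]:
    """Call ASE in heterozygous samples by homozygote interpolation.

    For each SNP with enough homozygotes, the AA and BB populations each
    contribute a (gDNA, cDNA) summary point with center and ``center +/- k *
    spread`` bounds (robust: median and scaled MAD; else mean and SD). Three
    lines are fitted across all such points: cDNA center on gDNA center,
    cDNA upper on gDNA *lower*, and cDNA lower on gDNA *upper* — crossing
    the bounds widens the band conservatively. Each heterozygous sample's
    observed cDNA log-ratio is then compared with the band interpolated at
    its own gDNA log-ratio.

    Returns the calls table (``snp_id, sample_id, observed_M, center,
    upper, lower, call``; call in {above, below, none, uncallable}) and the
    fitted lines.
    """
    common = cdna_m.index.intersection(gdna_m.index).intersection(genotypes.index)
    inds = [c for c in genotypes.columns if c in cdna_m.columns and c in gdna_m.columns]

    pts_gc, pts_cc, pts_gl, pts_cu, pts_gu, pts_cl = [], [], [], [], [], []
    callable_snps = set()
    for snp in common:
        calls = genotypes.loc[snp, inds].to_numpy()
        cd = cdna_m.loc[snp, inds].to_numpy(dtype=float)
        gd = gdna_m.loc[snp, inds].to_numpy(dtype=float)
        ok = np.isfinite(cd) & np.isfinite(gd)
        groups = {}
        for geno in ("AA", "BB"):
            sel = ok & (calls == geno)
            if sel.sum() >= min_homozygotes:
                groups[geno] = sel
        if len(groups) < 2:
            continue
        callable_snps.add(snp)
        for sel in groups.values():
            gc, gs = _center_spread(gd[sel], robust)
            cc, cs = _center_spread(cd[sel], robust)
            pts_gc.append(gc)
            pts_cc.append(cc)
            pts_gl.append(gc - k * gs)
            pts_cu.append(cc + k * cs)
            pts_gu.append(gc + k * gs)
            pts_cl.append(cc - k * cs)

    if len(pts_gc) < 2:
        raise ValueError("too few SNPs with enough homozygotes to fit interpolation lines")
    lines = InterpolationLines(
        center=_simple_regression(np.array(pts_gc), np.array(pts_cc)),
        upper=_simple_regression(np.array(pts_gl), np.array(pts_cu)),
        lower=_simple_regression(np.array(pts_gu), np.array(pts_cl)),
    )

    rows = []
    for snp in common:
        calls = genotypes.loc[snp, inds].to_numpy()
        for j, ind in enumerate(inds):
            if calls[j] != "AB":
                continue
            obs = float(cdna_m.loc[snp, ind])
            gval = float(gdna_m.loc[snp, ind])
            if snp not in callable_snps or not (np.isfinite(obs) and np.isfinite(gval)):
                rows.append({"snp_id": snp, "sample_id": ind, "observed_M": obs,
                             "center": np.nan, "upper": np.nan, "lower": np.nan,
                             "call": "uncallable"})
                continue
            center = lines.center[0] * gval + lines.center[1]
            upper = lines.upper[0] * gval + lines.upper[1]
            lower = lines.lower[0] * gval + lines.lower[1]
            if obs > upper:
                call = "above"
            elif obs < lower:
                call = "below"
            else:
                call = "none"
            rows.append({"snp_id": snp, "sample_id": ind, "observed_M": obs,
                         "center": center, "upper": upper, "lower": lower, "call": call})
    return pd.DataFrame(rows), lines
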