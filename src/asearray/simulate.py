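"""Synthetic two-color allelic-array experiments with known ground truth.

Generates bead-level and summary-level data emulating GoldenGate-style ASE
designs: gDNA mixture titrations with built-in true positives/negatives,
dye-swap control experiments with injected intensity-dependent dye bias, and
gDNA/cDNA cohorts containing non-responding and silenced SNPs.

All randomness is driven by :class:`~asearray.config.SimConfig.seed`; the
stream is split per array so adding arrays leaves existing ones unchanged.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig

GENOTYPES = ("AA", "AB", "BB")

#: Diploid allele-A dosage of each genotype call.
ALLELE_A_DOSE = {"AA": 1.0, "AB": 0.5, "BB": 0.0}

# Raw (unscaled) MAD of a normal distribution is 0.6745 sigma; used to size
# injected outlier displacements in MAD units.
_NORMAL_MAD = 0.6745

_SNP_STREAM = 999_983  # sub-stream key for per-SNP (array-independent) draws
_FAIL_COMPRESSION = 0.08


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def _snp_ids(n: int) -> np.ndarray:
    return np.array([f"snp{i:05d}" for i in range(n)])


# ---------------------------------------------------------------------------
# genotype sampling and closed-form truth
# ---------------------------------------------------------------------------

def _hw_draw(rng: np.random.Generator, n: int, allele_freq: float) -> np.ndarray:
    """Hardy-Weinberg genotype draw; returns calls as strings."""
    f = allele_freq
    probs = np.array([f * f, 2 * f * (1 - f), (1 - f) ** 2])
    idx = rng.choice(3, size=n, p=probs / probs.sum())
    return np.asarray(GENOTYPES)[idx]


def sample_genotype_pair(
    n_snps: int,
    allele_freq: float,
    nn_rate: float = 0.0,
    seed: int = 0,
    maximize_discordance: bool = False,
) -> pd.DataFrame:
    """Sample genotypes for two individuals at ``n_snps`` SNPs.

    Each individual's call is an independent Hardy-Weinberg draw at
    ``allele_freq``; with ``maximize_discordance`` the second individual is
    redrawn from the Hardy-Weinberg distribution restricted to calls that
    differ from the first (emulating selecting pairs of individuals with the
    greatest genotype differences). ``NN`` (missing) calls are assigned
    independently at ``nn_rate``.

    Returns a DataFrame indexed by ``snp_id`` with columns ``ind1``/``ind2``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    for name, v in (("allele_freq", allele_freq), ("nn_rate", nn_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    rng = _rng(seed, 1)
    g1 = _hw_draw(rng, n_snps, allele_freq)
    g2 = _hw_draw(rng, n_snps, allele_freq)
    if maximize_discordance:
        f = allele_freq
        base = np.array([f * f, 2 * f * (1 - f), (1 - f) ** 2])
        for gi, call in enumerate(GENOTYPES):
            same = g1 == call
            n_same = int(same.sum())
            if n_same == 0:
                continue
            p = base.copy()
            p[gi] = 0.0
            if p.sum() == 0:  # monomorphic locus set: no discordant call exists
                continue
            idx = rng.choice(3, size=n_same, p=p / p.sum())
            g2[same] = np.asarray(GENOTYPES)[idx]
    nn = rng.random((2, n_snps)) < nn_rate
    g1 = np.where(nn[0], "NN", g1)
    g2 = np.where(nn[1], "NN", g2)
    return pd.DataFrame({"ind1": g1, "ind2": g2}, index=pd.Index(_snp_ids(n_snps), name="snp_id"))


def sample_genotype_cohort(
    n_snps: int,
    n_individuals: int,
    allele_freq: float,
    nn_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent Hardy-Weinberg genotypes for a cohort of individuals."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = _rng(seed, 2)
    cols = {}
    for j in range(n_individuals):
        g = _hw_draw(rng, n_snps, allele_freq)
        g = np.where(rng.random(n_snps) < nn_rate, "NN", g)
        cols[f"ind{j + 1}"] = g
    return pd.DataFrame(cols, index=pd.Index(_snp_ids(n_snps), name="snp_id"))


def expected_allele_a_fraction(genotype_pair: tuple[str, str], mix_p: float) -> float:
    """Allele-A fraction of a pool mixing two individuals' gDNA.

    ``mix_p`` is the proportion of individual 1. Uses diploid dosages
    AA=1, AB=0.5, BB=0; a pool at proportion p has allele-A fraction
    ``p * dose1 + (1 - p) * dose2``.
    """
    g1, g2 = genotype_pair
    if g1 not in ALLELE_A_DOSE or g2 not in ALLELE_A_DOSE:
        raise ValueError(f"allele fraction undefined for genotypes {genotype_pair}")
    if not 0.0 <= mix_p <= 1.0:
        raise ValueError(f"mix_p must lie in [0, 1], got {mix_p}")
    return mix_p * ALLELE_A_DOSE[g1] + (1.0 - mix_p) * ALLELE_A_DOSE[g2]


def expected_fold_change(mix_p: float) -> float:
    """Absolute fold-change between the two pooled amounts at ``mix_p``.

    A 56:44 mixture corresponds to a subtle ~1.3-fold imbalance; 60:40 is
    1.5-fold. Undefined (infinite) at the pure 100:0 and 0:100 endpoints.
    """
    if not 0.0 < mix_p < 1.0:
        raise ValueError("fold change is infinite for pure (0 or 1) mixtures")
    return max(mix_p, 1.0 - mix_p) / min(mix_p, 1.0 - mix_p)


# ---------------------------------------------------------------------------
# bead-level generation
# ---------------------------------------------------------------------------

def _per_snp_scales(cfg: SimConfig, material: str) -> np.ndarray:
    rng = _rng(cfg.seed, _SNP_STREAM, 1)
    base = cfg.signal_scale_gdna if material == "gDNA" else cfg.signal_scale_cdna
    scale = base * 2.0 ** rng.normal(0.0, cfg.snp_scale_log2_sd, cfg.n_snps)
    if material == "cDNA":
        scale = scale * _expression_levels(cfg)
    return scale


def _expression_levels(cfg: SimConfig) -> np.ndarray:
    if cfg.expression_levels is not None:
        return np.asarray(cfg.expression_levels, dtype=float)
    rng = _rng(cfg.seed, _SNP_STREAM, 2)
    return 2.0 ** rng.normal(0.0, cfg.expression_log2_sd, cfg.n_snps)


def _resolve_hidden(genos: np.ndarray, rng: np.random.Generator, allele_freq: float) -> np.ndarray:
    """Replace NN calls by a hidden true genotype used only for signal."""
    out = genos.copy()
    nn = out == "NN"
    if nn.any():
        out[nn] = _hw_draw(rng, int(nn.sum()), allele_freq)
    return out


def _nonspecific_floor(cfg: SimConfig) -> np.ndarray:
    """Per-SNP cross-hybridization floor, log-normal across SNPs."""
    if cfg.nonspecific_scale == 0:
        return np.zeros(cfg.n_snps)
    if cfg.nonspecific_log2_sd == 0:
        return np.full(cfg.n_snps, cfg.nonspecific_scale)
    rng = _rng(cfg.seed, _SNP_STREAM, 8)
    return cfg.nonspecific_scale * 2.0 ** rng.normal(0.0, cfg.nonspecific_log2_sd, cfg.n_snps)


def _probe_affinity(cfg: SimConfig) -> np.ndarray:
    """Per-SNP allele-A vs allele-B efficiency asymmetry, log2 units."""
    if cfg.probe_affinity_log2_sd == 0:
        return np.zeros(cfg.n_snps)
    rng = _rng(cfg.seed, _SNP_STREAM, 7)
    return rng.normal(0.0, cfg.probe_affinity_log2_sd, cfg.n_snps)


def _simulate_array_beads(
    cfg: SimConfig,
    array_index: int,
    theta: np.ndarray,
    scale: np.ndarray,
    kappa: np.ndarray,
    nonspecific: np.ndarray,
    swap: bool = False,
    failed: bool = False,
) -> dict[str, np.ndarray]:
    """Bead intensities for one array; flat arrays of length n_snps*n_beads."""
    rng = _rng(cfg.seed, 3, array_index)
    n, b = cfg.n_snps, cfg.n_beads_per_snp
    # allele-specific efficiency travels with the allele, so it swaps
    # channels together with the dye orientation
    allele_a = theta * scale * 2.0 ** (kappa / 2.0)
    allele_b = (1.0 - theta) * scale * 2.0 ** (-kappa / 2.0)
    red_sig = (allele_a if not swap else allele_b) + nonspecific
    green_sig = (allele_b if not swap else allele_a) + nonspecific

    # dye bias as a linear function of the SNP's noise-free average intensity
    a0 = 0.5 * (np.log2(np.maximum(red_sig, 1.0)) + np.log2(np.maximum(green_sig, 1.0)))
    bias = cfg.dye_bias_intercept + cfg.dye_bias_slope * a0

    eps_r = rng.normal(0.0, cfg.noise_sd, (n, b)) if cfg.noise_sd > 0 else np.zeros((n, b))
    eps_g = rng.normal(0.0, cfg.noise_sd, (n, b)) if cfg.noise_sd > 0 else np.zeros((n, b))
    red = red_sig[:, None] * 2.0 ** eps_r
    green = green_sig[:, None] * 2.0 ** eps_g

    if cfg.outlier_rate > 0:
        out_mask = rng.random((n, b)) < cfg.outlier_rate
        # displacement sized in (raw) MAD units of the bead noise, with
        # headroom so the displaced bead is >= outlier_magnitude MADs out
        delta = cfg.outlier_magnitude * max(2.0 * _NORMAL_MAD * cfg.noise_sd, 0.2)
        sign = np.where(rng.random((n, b)) < 0.5, -1.0, 1.0)
        red = np.where(out_mask, red * 2.0 ** (sign * delta), red)

    if cfg.background_mean > 0 or cfg.background_sd > 0:
        b_red = np.clip(rng.normal(cfg.background_mean, cfg.background_sd, (n, b)), 0.0, None)
        b_green = np.clip(rng.normal(cfg.background_mean, cfg.background_sd, (n, b)), 0.0, None)
        # recorded local background is an estimate from a few dim pixels: it
        # tracks the spatial variation but carries pixel-level error
        est_sd = cfg.background_est_sd
        bg_red = np.clip(b_red + rng.normal(0.0, est_sd, (n, b)), 0.0, None)
        bg_green = np.clip(b_green + rng.normal(0.0, est_sd, (n, b)), 0.0, None)
        red = red + b_red
        green = green + b_green
    else:
        bg_red = np.zeros((n, b))
        bg_green = np.zeros((n, b))

    # dye bias multiplies everything measured in the red channel
    red = red * 2.0 ** bias[:, None]
    bg_red = bg_red * 2.0 ** bias[:, None]

    if failed:
        # failed hybridization: signal compressed around the array median so
        # the log2 IQR collapses below the QC threshold
        for ch in (red, green):
            pos = ch > 0
            lx = np.log2(np.maximum(ch, 1e-9))
            med = np.median(lx[pos]) if pos.any() else 0.0
            ch[...] = np.where(pos, 2.0 ** (med + _FAIL_COMPRESSION * (lx - med)), 0.0)

    return {
        "red_fg": red.ravel(),
        "green_fg": green.ravel(),
        "red_bg": bg_red.ravel(),
        "green_bg": bg_green.ravel(),
    }


def _is_failed(cfg: SimConfig, array_index: int, array_id: str) -> bool:
    return array_index in set(
        i for i in cfg.failed_array_ids if isinstance(i, (int, np.integer))
    ) or array_id in set(i for i in cfg.failed_array_ids if isinstance(i, str))


def _assemble_beads(cfg: SimConfig, per_array: list[tuple[str, dict]]) -> pd.DataFrame:
    n, b = cfg.n_snps, cfg.n_beads_per_snp
    snp_col = np.repeat(_snp_ids(n), b)
    bead_col = np.tile(np.arange(b), n)
    frames = []
    for array_id, channels in per_array:
        frames.append(pd.DataFrame({
            "array_id": array_id,
            "snp_id": snp_col,
            "bead_index": bead_col,
            **channels,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------

def simulate_mixture_experiment(
    cfg: SimConfig,
    genotypes: pd.DataFrame,
    series: str = "A",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gDNA mixture-titration series with built-in truth.

    gDNA from two individuals of known genotype is pooled at each proportion
    in ``cfg.mixture_proportions`` and hybridized on ``cfg.n_replicates``
    arrays per mixture. SNPs where the individuals' genotypes differ carry a
    real allelic imbalance that varies with the mixing proportion; SNPs with
    identical genotypes stay balanced at every proportion.

    Returns ``(bead_table, sample_sheet, truth_manifest)``. NN calls are
    resolved to a hidden true genotype for signal generation (recorded in the
    manifest); the observed genotype table still reports NN.
    """
    if genotypes.shape[1] != 2:
        raise ValueError("mixture experiment requires genotypes for exactly 2 individuals")
    if len(genotypes) != cfg.n_snps:
        raise ValueError("genotype table length must equal cfg.n_snps")

    hid_rng = _rng(cfg.seed, _SNP_STREAM, 3)
    g1 = _resolve_hidden(genotypes.iloc[:, 0].to_numpy(), hid_rng, cfg.allele_freq)
    g2 = _resolve_hidden(genotypes.iloc[:, 1].to_numpy(), hid_rng, cfg.allele_freq)
    dose1 = np.array([ALLELE_A_DOSE[g] for g in g1])
    dose2 = np.array([ALLELE_A_DOSE[g] for g in g2])
    scale = _per_snp_scales(cfg, "gDNA")
    kappa = _probe_affinity(cfg)
    nonspecific = _nonspecific_floor(cfg)

    per_array, samples = [], []
    array_index = 0
    for mi, p in enumerate(cfg.mixture_proportions):
        theta = p * dose1 + (1.0 - p) * dose2
        for r in range(cfg.n_replicates):
            array_id = f"{series}_p{int(round(p * 100)):03d}_m{mi:02d}_r{r + 1}"
            failed = _is_failed(cfg, array_index, array_id)
            per_array.append((array_id, _simulate_array_beads(cfg, array_index, theta, scale, kappa, nonspecific, failed=failed)))
            samples.append({
                "array_id": array_id,
                "sample_id": f"mix_{series}_{int(round(p * 100)):03d}",
                "material": "gDNA",
                "dye": "standard",
                "mix_p": p,
                "replicate": r + 1,
                "series": series,
            })
            array_index += 1

    beads = _assemble_beads(cfg, per_array)
    sheet = pd.DataFrame(samples)

    manifest = pd.DataFrame({
        "snp_id": _snp_ids(cfg.n_snps),
        "genotype_1": genotypes.iloc[:, 0].to_numpy(),
        "genotype_2": genotypes.iloc[:, 1].to_numpy(),
        "hidden_genotype_1": g1,
        "hidden_genotype_2": g2,
        "responder": True,
        "scale": scale,
        "probe_affinity": kappa,
        "dye_bias_slope": cfg.dye_bias_slope,
        "dye_bias_intercept": cfg.dye_bias_intercept,
    })
    for p in sorted(set(cfg.mixture_proportions)):
        manifest[f"theta_p{int(round(p * 100)):03d}"] = p * dose1 + (1.0 - p) * dose2
    return beads, sheet, manifest


def simulate_dye_swap_experiment(
    cfg: SimConfig,
    material: str = "gDNA",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a dye-swap control experiment for one sample.

    One individual's sample is hybridized on ``cfg.n_replicates`` arrays with
    standard chemistry and the same number with the dye assignment swapped.
    Swapping flips which channel carries allele A, so the true allelic signal
    changes sign in the log-ratio while any dye bias does not: the per-SNP
    intercept of a dye-swap linear model isolates the bias.

    Returns ``(bead_table, sample_sheet, manifest)`` where the manifest
    records each SNP's genotype, true log-ratio and injected dye bias.
    """
    if material not in ("gDNA", "cDNA"):
        raise ValueError("material must be 'gDNA' or 'cDNA'")
    rng = _rng(cfg.seed, _SNP_STREAM, 4)
    geno = _hw_draw(rng, cfg.n_snps, cfg.allele_freq)
    theta = np.array([ALLELE_A_DOSE[g] for g in geno])
    scale = _per_snp_scales(cfg, material)
    kappa = _probe_affinity(cfg)
    nonspecific = _nonspecific_floor(cfg)

    red_sig = theta * scale * 2.0 ** (kappa / 2.0) + nonspecific
    green_sig = (1.0 - theta) * scale * 2.0 ** (-kappa / 2.0) + nonspecific
    a0 = 0.5 * (np.log2(np.maximum(red_sig, 1.0)) + np.log2(np.maximum(green_sig, 1.0)))
    injected_bias = cfg.dye_bias_intercept + cfg.dye_bias_slope * a0

    per_array, samples = [], []
    array_index = 0
    for dye, swap in (("standard", False), ("swapped", True)):
        for r in range(cfg.n_replicates):
            array_id = f"ds_{material}_{dye}_r{r + 1}"
            failed = _is_failed(cfg, array_index, array_id)
            per_array.append((array_id, _simulate_array_beads(cfg, array_index, theta, scale, kappa, nonspecific, swap=swap, failed=failed)))
            samples.append({
                "array_id": array_id,
                "sample_id": f"ds_{material}",
                "material": material,
                "dye": dye,
                "mix_p": np.nan,
                "replicate": r + 1,
                "series": "dyeswap",
            })
            array_index += 1

    beads = _assemble_beads(cfg, per_array)
    sheet = pd.DataFrame(samples)
    manifest = pd.DataFrame({
        "snp_id": _snp_ids(cfg.n_snps),
        "genotype": geno,
        "theta": theta,
        "scale": scale,
        "probe_affinity": kappa,
        "injected_bias": injected_bias,
    })
    return beads, sheet, manifest


def simulate_cohort(
    cfg: SimConfig,
    genotypes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate paired gDNA/cDNA summary data for a cohort of individuals.

    Each individual contributes one gDNA and one cDNA array, emitted directly
    at the per-SNP summary level (mean log2 intensities, M, A). gDNA signal
    follows the three-cluster genotype pattern. cDNA signal for *responder*
    SNPs tracks the genotype, scaled by a per-SNP expression level on top of
    a non-specific intensity floor — low-expression SNPs therefore show a
    compressed cDNA dynamic range (regression slope < 1). A
    ``cfg.nonresponder_rate`` fraction of SNPs emit allele-independent
    low-intensity cDNA signal; a ``cfg.silenced_rate`` fraction of responders
    express a single allele in heterozygotes (monoallelic expression).

    Returns ``(summaries, sample_sheet, manifest)``.
    """
    n_ind = genotypes.shape[1]
    n = cfg.n_snps
    if len(genotypes) != n:
        raise ValueError("genotype table length must equal cfg.n_snps")

    snp_rng = _rng(cfg.seed, _SNP_STREAM, 5)
    responder = snp_rng.random(n) >= cfg.nonresponder_rate
    silenced = responder & (snp_rng.random(n) < cfg.silenced_rate)
    silenced_allele = np.where(snp_rng.random(n) < 0.5, "A", "B")
    expr = _expression_levels(cfg)

    gdna_scale = _per_snp_scales(cfg, "gDNA")
    cdna_scale = cfg.signal_scale_cdna * expr
    kappa = _probe_affinity(cfg)
    aff_a = 2.0 ** (kappa / 2.0)
    aff_b = 2.0 ** (-kappa / 2.0)
    # summary-level cohort data are not background corrected: the floor seen
    # by the model is optical background plus the per-SNP non-specific signal
    ns = np.maximum(cfg.background_mean + _nonspecific_floor(cfg), 1.0)
    se = cfg.noise_sd / np.sqrt(cfg.n_beads_per_snp)
    snp_ids = _snp_ids(n)

    rows, samples = [], []
    array_index = 0
    for j, ind in enumerate(genotypes.columns):
        g = _resolve_hidden(genotypes[ind].to_numpy(), _rng(cfg.seed, _SNP_STREAM, 6, j), cfg.allele_freq)
        theta = np.array([ALLELE_A_DOSE[c] for c in g])
        for material in ("gDNA", "cDNA"):
            array_id = f"{ind}_{material}"
            rng = _rng(cfg.seed, 4, array_index)
            if material == "gDNA":
                red = theta * gdna_scale * aff_a + ns
                green = (1.0 - theta) * gdna_scale * aff_b + ns
            else:
                th = theta.copy()
                mono = silenced & (theta == 0.5)
                th[mono] = np.where(silenced_allele[mono] == "A", 1.0, 0.0)
                red = np.where(responder, th * cdna_scale * aff_a + ns, ns)
                green = np.where(responder, (1.0 - th) * cdna_scale * aff_b + ns, ns)
            log_r = np.log2(np.maximum(red, 1.0)) + rng.normal(0.0, se, n)
            log_g = np.log2(np.maximum(green, 1.0)) + rng.normal(0.0, se, n)
            rows.append(pd.DataFrame({
                "array_id": array_id,
                "snp_id": snp_ids,
                "mean_logR": log_r,
                "mean_logG": log_g,
                "mean_M": log_r - log_g,
                "mean_A": 0.5 * (log_r + log_g),
                "n_logR": cfg.n_beads_per_snp,
                "n_logG": cfg.n_beads_per_snp,
                "n_M": cfg.n_beads_per_snp,
                "n_A": cfg.n_beads_per_snp,
                "background_corrected": False,
            }))
            samples.append({
                "array_id": array_id,
                "sample_id": ind,
                "material": material,
                "dye": "standard",
                "mix_p": np.nan,
                "replicate": 1,
                "series": "cohort",
            })
            array_index += 1

    summaries = pd.concat(rows, ignore_index=True)
    sheet = pd.DataFrame(samples)
    manifest = pd.DataFrame({
        "snp_id": snp_ids,
        "responder": responder,
        "silenced": silenced,
        "silenced_allele": np.where(silenced, silenced_allele, ""),
        "expression_level": expr,
        "cdna_scale": cdna_scale,
    })
    return summaries, sheet, manifest
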