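"""Simulation configuration for synthetic two-color allelic-array experiments."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

#: Mixture titration series used by default: proportions of individual 1 pooled
#: with individual 2, spanning 100:0 down to 0:100 symmetrically (17 steps).
SERIES_A_PROPORTIONS: tuple[float, ...] = (
    0.00, 0.05, 0.09, 0.17, 0.33, 0.36, 0.40, 0.44, 0.50,
    0.56, 0.60, 0.64, 0.67, 0.83, 0.91, 0.95, 1.00,
)


@dataclass
class SimConfig:
    """Parameters of the synthetic bead-array generator.

    The generator produces bead-level two-channel intensities under a
    multiplicative log-normal signal model with additive local background.
    For a SNP whose pooled allele-A fraction is ``theta``, the red (Cy5)
    channel carries ``theta * scale`` signal and the green (Cy3) channel
    ``(1 - theta) * scale``, so the noise-free per-bead log-ratio
    ``M = log2(red/green)`` equals ``log2(theta / (1 - theta))`` plus any
    injected dye bias.

    Parameters
    ----------
    n_snps:
        Number of SNP probes per array.
    n_beads_per_snp:
        Replicate beads per SNP per array (around 30 on the real platform).
    mixture_proportions:
        Titration series: proportion of individual 1 in each pooled sample.
    n_replicates:
        Arrays hybridized per mixture (or per dye orientation).
    allele_freq:
        Allele-A frequency used for Hardy-Weinberg genotype sampling.
    nn_rate:
        Fraction of genotype calls replaced by missing (``NN``).
    background_mean, background_sd:
        Additive per-bead local (optical) background, raw intensity units.
        ``background_sd`` is bead-to-bead (spatial) variation; the recorded
        ``*_bg`` columns track it up to ``background_est_sd`` of
        pixel-level estimation error.
    background_est_sd:
        Error of the recorded local background estimate (the average of a
        few dim pixels around the bead), raw intensity units.
    nonspecific_scale, nonspecific_log2_sd:
        Allele-independent signal floor (cross-hybridization) present in
        both channels, log-normal across SNPs; unlike the local background
        it is *not* captured by the per-bead background estimate.
    signal_scale_gdna, signal_scale_cdna:
        Total two-channel signal for a typical SNP, raw intensity units;
        cDNA is dimmer than gDNA, as on the real platform.
    snp_scale_log2_sd:
        Per-SNP log2 spread of the probe brightness (gives the A-value range).
    probe_affinity_log2_sd:
        Per-SNP log2 spread of the allele-A vs allele-B amplification
        efficiency: a constant per-SNP log-ratio offset that shifts the
        baseline away from 0 (cancelled by contrasts against the 50:50
        baseline, and sign-flipping under dye swap like any true signal).
    noise_sd:
        Per-bead, per-channel multiplicative noise, log2 units.
    dye_bias_slope, dye_bias_intercept:
        Dye bias added to log2(red) as ``intercept + slope * A`` where A is
        the SNP's noise-free average log-intensity on that array.
    outlier_rate, outlier_magnitude:
        Fraction of beads displaced, and the displacement size in multiples
        of the bead population's MAD.
    nonresponder_rate:
        Fraction of SNPs whose cDNA signal ignores the alleles present
        (weak, allele-independent signal).
    silenced_rate:
        Fraction of responder SNPs where heterozygotes express one allele
        only (monoallelic expression) in cDNA.
    failed_array_ids:
        Arrays (0-based indices or array_id strings) generated with a
        compressed dynamic range, emulating failed hybridizations.
    expression_levels:
        Optional per-SNP positive scale factors for cDNA; when ``None`` they
        are drawn log-normally with ``expression_log2_sd``.
    expression_log2_sd:
        log2 standard deviation of the drawn cDNA expression levels.
    seed:
        Seed fixing all randomness; random streams are split per array so
        adding arrays does not perturb existing ones.
    """

    n_snps: int = 1300
    n_beads_per_snp: int = 30
    mixture_proportions: Sequence[float] = SERIES_A_PROPORTIONS
    n_replicates: int = 3
    allele_freq: float = 0.5
    nn_rate: float = 0.01
    background_mean: float = 250.0
    background_sd: float = 100.0
    background_est_sd: float = 15.0
    nonspecific_scale: float = 80.0
    nonspecific_log2_sd: float = 0.8
    signal_scale_gdna: float = 4000.0
    signal_scale_cdna: float = 600.0
    snp_scale_log2_sd: float = 1.0
    probe_affinity_log2_sd: float = 0.7
    noise_sd: float = 0.35
    dye_bias_slope: float = 0.0
    dye_bias_intercept: float = 0.0
    outlier_rate: float = 0.01
    outlier_magnitude: float = 5.0
    nonresponder_rate: float = 0.0
    silenced_rate: float = 0.0
    failed_array_ids: Sequence = ()
    expression_levels: Optional[np.ndarray] = None
    expression_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("allele_freq", "nn_rate", "outlier_rate",
                     "nonresponder_rate", "silenced_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_beads_per_snp < 1:
            raise ValueError("n_beads_per_snp must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        props = np.asarray(self.mixture_proportions, dtype=float)
        if props.size and (props.min() < 0.0 or props.max() > 1.0):
            raise ValueError("mixture proportions must lie in [0, 1]")
        if self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.expression_levels is not None:
            lv = np.asarray(self.expression_levels, dtype=float)
            if lv.shape != (self.n_snps,) or (lv <= 0).any():
                raise ValueError(
                    "expression_levels must be positive with length n_snps")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixture_proportions"] = list(map(float, self.mixture_proportions))
        d["failed_array_ids"] = list(self.failed_array_ids)
        if self.expression_levels is not None:
            d["expression_levels"] = [float(x) for x in self.expression_levels]
        return d
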