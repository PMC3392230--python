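"""Seeded Monte-Carlo calibration studies for the scan statistics.

These are the package's parameter-recovery and error-control experiments:
false-discovery behaviour of the G-test scan under a complete null, type-I
error of the permutation LOD threshold, power/localization for a simulated
sex-associated locus, and recovery of male terminal recombination
suppression from window rates.  Each study takes a master seed and is fully
reproducible; replicate counts are arguments so callers can trade precision
for runtime.
"""

from __future__ import annotations

import numpy as np

from . import recomb
from .qtlscan import _lod_from_counts, lod_scan, permutation_threshold, permuted_max_lods
from .sexscan import bh_fdr, g_test_tables
from .simcross import SimulationConfig, assign_sex, simulate_pedigree_genotypes


def null_fdr_flag_counts(n_seeds: int = 200, n_snps: int = 10_000,
                         n_male: int = 82, n_female: int = 63,
                         q_threshold: float = 0.001, seed: int = 0) -> np.ndarray:
    """Flags per replicate of a complete-null genome scan.

    Each replicate draws independent F2 genotype-class counts (1:2:1) for
    males and females — sex independent of genotype — runs the vectorized
    G-test over all SNPs and counts q < ``q_threshold`` after BH.  Under the
    global null BH controls the family-wise error at ``q_threshold``, so the
    flag count should almost always be zero.
    """
    rng = np.random.default_rng(seed)
    flags = np.empty(n_seeds, dtype=np.int64)
    probs = [0.25, 0.5, 0.25]
    for i in range(n_seeds):
        m = rng.multinomial(n_male, probs, size=n_snps)
        f = rng.multinomial(n_female, probs, size=n_snps)
        _, _, p = g_test_tables(m, f)
        flags[i] = int((bh_fdr(p) < q_threshold).sum())
    return flags


def observed_max_lod(classes: np.ndarray, is_male: np.ndarray) -> float:
    """Genome-wide maximum single-marker LOD for one dataset."""
    n_markers, n_ind = classes.shape
    males = np.zeros((n_markers, 4))
    totals = np.zeros((n_markers, 4))
    for k in range(4):
        mask = classes == k
        totals[:, k] = mask.sum(axis=1)
        males[:, k] = (mask & (is_male > 0)[None, :]).sum(axis=1)
    return float(_lod_from_counts(males, totals).max())


def permutation_type1_rate(n_reps: int = 200, n_markers: int = 500,
                           n_male: int = 82, n_female: int = 63,
                           n_perm: int = 1000, seed: int = 0) -> float:
    """Fraction of null replicates whose max LOD exceeds the 5 % threshold.

    Markers are independent (unlinked), four-way classes 1:1:1:1; sexes are
    assigned at random.  The observed data is exchangeable with its own
    permutations, so the exceedance rate estimates the nominal 5 %.
    """
    rng = np.random.default_rng(seed)
    n_ind = n_male + n_female
    hits = 0
    for _ in range(n_reps):
        classes = (2 * rng.integers(0, 2, (n_markers, n_ind))
                   + rng.integers(0, 2, (n_markers, n_ind))).astype(np.int8)
        is_male = np.zeros(n_ind)
        is_male[:n_male] = 1.0
        rng.shuffle(is_male)
        obs = observed_max_lod(classes, is_male)
        maxima = permuted_max_lods(classes, is_male, n_perm, rng)
        hits += obs > np.quantile(maxima, 0.95, method="linear")
    return hits / n_reps


def sar_detection_rate(n_reps: int = 100, n_perm: int = 1000, seed: int = 0,
                       config: SimulationConfig | None = None) -> tuple[float, float]:
    """Power and localization of the LOD scan for a simulated sex locus.

    Each replicate simulates a family under ``config`` (default: the
    standard 145-individual design with the single distal sex locus of
    penetrance 1.0 / 0.16 / 0.0), scans it, and records whether the peak
    exceeds the genome-wide 5 % permutation threshold and whether the peak
    marker lies on the true chromosome.  Returns ``(detection_rate,
    localization_rate)``.
    """
    config = config or SimulationConfig()
    sar_chrom = config.resolved_sex_model().loci[0][0]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    detected = located = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        gm = simulate_pedigree_genotypes(config, rng)
        sheet = assign_sex(gm, config.resolved_sex_model(), rng, family=config.family)
        scan = lod_scan(gm, sheet)
        thr = permutation_threshold(gm, sheet, n_perm=n_perm, seed=rng)
        peak = scan.loc[scan["LOD"].idxmax()]
        if peak["LOD"] > thr[0.95]:
            detected += 1
            if peak["chrom"] == sar_chrom:
                located += 1
    return detected / n_reps, located / n_reps


def suppression_recovery_rate(n_reps: int = 100, seed: int = 0,
                              config: SimulationConfig | None = None,
                              ratio: float = 1.0 / 3.0) -> float:
    """How often window rates recover male terminal recombination suppression.

    Per replicate the male and female maps of the suppressed chromosome are
    re-estimated from the simulated gametes, 3-marker window rates computed,
    and the replicate counts as a success when the mean male rate over
    terminal-region windows is below ``ratio`` times the female mean.
    """
    config = config or SimulationConfig()
    chrom = config.chromosomes[-1]
    cut = (1.0 - config.terminal_fraction) * chrom.length_bp
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        gm = simulate_pedigree_genotypes(config, rng)
        means = {}
        for sex in ("female", "male"):
            est = recomb.build_sex_map(gm, sex)
            win = recomb.sliding_window_rate(est, sex)
            term = win[(win["chrom"] == chrom.name) & (win["pos_bp"] > cut)]
            means[sex] = term["rate_cM_per_Mb"].mean()
        if means["male"] < ratio * means["female"]:
            hits += 1
    return hits / n_reps
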