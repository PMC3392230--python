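"""Binary-trait LOD scan on phase-known four-way genotypes.

Sex (male/female) is the binary trait.  At each marker the alternative
model gives every genotype class g its own penetrance p_g, estimated by the
class male fraction m_g / (m_g + f_g); the null model pools all classes.
The LOD score is the base-10 log of the maximized binomial likelihood
ratio:

    LOD = (1/ln 10) * sum_g [ m_g ln p_g + f_g ln(1 - p_g) ]
        - (1/ln 10) *       [ M  ln pbar + F  ln(1 - pbar) ]

with 0*ln 0 taken as 0.  This is a single-marker scan: with dense, fully
informative phase-known markers the hidden-genotype machinery of interval
mapping adds nothing, and at a fully typed marker the two coincide.

Genome-wide significance comes from a permutation test: the sex vector is
shuffled among individuals (preserving genotype correlation), the
genome-wide maximum LOD recorded per permutation, and the 95th/90th
percentiles (type-7 linear interpolation) give the 5 % and 10 % thresholds.
Support intervals extend from a peak to the outermost contiguous marker
within ``drop`` LOD of it, plus one flanking marker, clamped at chromosome
ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import fisher_exact as _scipy_fisher

from .simcross import FOURWAY_LABELS, GenotypeMatrix

log = logging.getLogger("radsexscan")

LN10 = np.log(10.0)


def _lod_from_counts(males: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """LOD from per-class male counts and class totals; class axis is last.

    Empty classes (total 0) contribute nothing.  Works on any leading shape,
    so one call scores all markers of all permutations at once.
    """
    m = np.asarray(males, dtype=float)
    t = np.asarray(totals, dtype=float)
    f = t - m
    with np.errstate(invalid="ignore", divide="ignore"):
        ll1 = (xlogy(m, np.where(t > 0, m / np.where(t > 0, t, 1), 0.0))
               + xlogy(f, np.where(t > 0, f / np.where(t > 0, t, 1), 0.0))).sum(axis=-1)
    big_m = m.sum(axis=-1)
    big_f = f.sum(axis=-1)
    big_t = big_m + big_f
    with np.errstate(invalid="ignore", divide="ignore"):
        ll0 = (xlogy(big_m, np.where(big_t > 0, big_m / np.where(big_t > 0, big_t, 1), 0.0))
               + xlogy(big_f, np.where(big_t > 0, big_f / np.where(big_t > 0, big_t, 1), 0.0)))
    return np.clip((ll1 - ll0) / LN10, 0.0, None)


def binary_lod(marker_classes, sexes) -> tuple[float, dict]:
    """LOD of a binary trait at one marker plus per-class penetrance estimates.

    ``marker_classes`` are arbitrary hashable class labels per individual
    (four-way classes, collapsed genotypes, haplotype groups ...); ``sexes``
    are "male"/"female" strings.  Individuals with missing class (None, NaN,
    or a negative integer code) are dropped.  A single surviving class gives
    LOD = 0 with a warning.
    """
    cls = pd.Series(list(marker_classes))
    sex = np.asarray(sexes, dtype=object)
    if len(cls) != len(sex):
        raise ValueError("marker_classes and sexes must align")
    numeric = pd.api.types.is_numeric_dtype(cls)
    keep = cls.notna().to_numpy()
    if numeric:
        keep &= (cls.fillna(-1).to_numpy() >= 0)
    cls, sex = cls[keep], sex[keep]
    if len(cls) == 0:
        raise ValueError("no informative individuals")
    is_male = sex == "male"
    tab = pd.crosstab(cls.to_numpy(), is_male)
    males = tab[True].to_numpy(float) if True in tab.columns else np.zeros(len(tab))
    totals = tab.sum(axis=1).to_numpy(float)
    if len(tab) < 2:
        log.warning("binary_lod: single genotype class; LOD = 0")
        return 0.0, {k: males[i] / totals[i] for i, k in enumerate(tab.index)}
    lod = float(_lod_from_counts(males, totals))
    penetrance = {k: males[i] / totals[i] for i, k in enumerate(tab.index)}
    return lod, penetrance


def lod_scan(gm: GenotypeMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Single-marker binary LOD at every marker of a genotype matrix.

    ``sheet`` is a sample sheet covering ``gm.sample_ids``; unknown-sex
    individuals are dropped.  Returns marker_id, chrom, pos_bp, cM (sex
    average, the consensus-map coordinate), LOD and the four-way penetrance
    estimates.
    """
    sex = sheet.set_index("sample_id").reindex(gm.sample_ids)["sex"]
    usable = sex.isin(["male", "female"]).to_numpy()
    is_male = (sex == "male").to_numpy()[usable]
    classes = gm.classes()[:, usable]
    males, totals = _class_counts(classes, is_male)
    lod = _lod_from_counts(males, totals)
    with np.errstate(invalid="ignore"):
        phat = np.where(totals > 0, males / np.where(totals > 0, totals, 1), np.nan)
    out = gm.markers[["marker_id", "chrom", "pos_bp", "cM_female", "cM_male"]].copy()
    out["cM"] = 0.5 * (out["cM_female"] + out["cM_male"])
    out["LOD"] = lod
    for k, label in enumerate(FOURWAY_LABELS):
        out[f"p_male[{label}]"] = phat[:, k]
    return out


def _class_counts(classes: np.ndarray, is_male: np.ndarray):
    """Per-marker four-way class totals and male counts, ignoring missing."""
    n_classes = 4
    m_markers = classes.shape[0]
    males = np.zeros((m_markers, n_classes))
    totals = np.zeros((m_markers, n_classes))
    for k in range(n_classes):
        mask = classes == k
        totals[:, k] = mask.sum(axis=1)
        males[:, k] = (mask & is_male[None, :]).sum(axis=1)
    return males, totals


def permutation_threshold(gm: GenotypeMatrix, sheet: pd.DataFrame,
                          n_perm: int = 10_000, quantiles=(0.95, 0.90),
                          seed=None) -> dict:
    """Genome-wide LOD thresholds from a sex-permutation null.

    Each permutation shuffles the observed sex labels among individuals and
    records the maximum single-marker LOD over all markers; thresholds are
    the requested quantiles (type-7 linear interpolation) of those maxima.
    Reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable quantiles")
    rng = np.random.default_rng(seed)
    sex = sheet.set_index("sample_id").reindex(gm.sample_ids)["sex"]
    usable = sex.isin(["male", "female"]).to_numpy()
    is_male = (sex == "male").to_numpy()[usable].astype(float)
    classes = gm.classes()[:, usable]
    maxima = permuted_max_lods(classes, is_male, n_perm, rng)
    return {q: float(np.quantile(maxima, q, method="linear")) for q in quantiles}


def permuted_max_lods(classes: np.ndarray, is_male: np.ndarray,
                      n_perm: int, rng: np.random.Generator,
                      batch: int = 250) -> np.ndarray:
    """Null distribution of the genome-wide max LOD (vectorized over perms)."""
    m_markers, n_ind = classes.shape
    onehot = np.zeros((n_ind, m_markers * 4))
    for k in range(4):
        onehot[:, k::4] = (classes == k).T
    totals = onehot.sum(axis=0).reshape(m_markers, 4)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.empty((b, n_ind))
        for i in range(b):
            perms[i] = rng.permutation(is_male)
        males = (perms @ onehot).reshape(b, m_markers, 4)
        lods = _lod_from_counts(males, np.broadcast_to(totals, (b, m_markers, 4)))
        maxima[done:done + b] = lods.max(axis=1)
        done += b
    return maxima


@dataclass(frozen=True)
class SupportInterval:
    chrom: str
    peak_marker: str
    peak_lod: float
    cm_lo: float
    cm_hi: float
    bp_lo: int
    bp_hi: int


def lod_support_interval(scan: pd.DataFrame, threshold: float,
                         drop: float = 1.5) -> list[SupportInterval]:
    """Drop-based support interval around each chromosome peak above threshold.

    From the peak marker the interval extends in both directions over the
    contiguous run of markers with LOD >= peak - drop, then one marker
    beyond (a conservative flank) unless the chromosome end is reached
    first.  Chromosomes whose peak does not exceed ``threshold`` contribute
    nothing; no peak anywhere gives an empty list.
    """
    intervals = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        grp = grp.sort_values("cM", kind="mergesort").reset_index(drop=True)
        lod = grp["LOD"].to_numpy()
        peak = int(np.argmax(lod))
        if lod[peak] <= threshold:
            continue
        floor = lod[peak] - drop
        lo = peak
        while lo > 0 and lod[lo - 1] >= floor:
            lo -= 1
        hi = peak
        while hi < len(lod) - 1 and lod[hi + 1] >= floor:
            hi += 1
        lo = max(lo - 1, 0)
        hi = min(hi + 1, len(lod) - 1)
        intervals.append(SupportInterval(
            chrom=str(chrom),
            peak_marker=str(grp.loc[peak, "marker_id"]),
            peak_lod=float(lod[peak]),
            cm_lo=float(grp.loc[lo, "cM"]), cm_hi=float(grp.loc[hi, "cM"]),
            bp_lo=int(grp.loc[lo, "pos_bp"]), bp_hi=int(grp.loc[hi, "pos_bp"]),
        ))
    return intervals


def haplotype_sex_table(gm: GenotypeMatrix, sheet: pd.DataFrame,
                        markers: list[str], collapse: bool = True) -> pd.DataFrame:
    """Cross-tabulate sex against genotype classes at one or two markers.

    With ``collapse`` the classes are G1G1 / G1G2 / G2G2 (heterozygote
    unordered); otherwise the full four-way maternal|paternal classes.  Only
    individuals fully typed at the requested markers and of known sex are
    included.  Empty classes are omitted.  Returns class, n_male, n_female,
    percent_male.
    """
    if not 1 <= len(markers) <= 2:
        raise ValueError("provide 1 or 2 marker ids")
    idx = [int(np.flatnonzero((gm.markers["marker_id"] == m).to_numpy())[0])
           for m in markers]
    codes = gm.collapsed() if collapse else gm.classes()
    labels = np.asarray(("G1G1", "G1G2", "G2G2") if collapse else FOURWAY_LABELS)
    sex = sheet.set_index("sample_id").reindex(gm.sample_ids)["sex"].to_numpy()
    keep = np.isin(sex, ["male", "female"])
    for i in idx:
        keep &= codes[i] >= 0
    names = labels[codes[idx[0]][keep]]
    if len(idx) == 2:
        names = np.char.add(np.char.add(names.astype(str), "|"),
                            labels[codes[idx[1]][keep]].astype(str))
    tab = pd.crosstab(pd.Series(names, name="class"), pd.Series(sex[keep], name="sex"))
    tab = tab.reindex(columns=["male", "female"], fill_value=0)
    out = tab.reset_index().rename(columns={"male": "n_male", "female": "n_female"})
    out["percent_male"] = 100.0 * out["n_male"] / (out["n_male"] + out["n_female"])
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (point-probability method)."""
    obs = np.asarray(table, dtype=np.int64)
    if obs.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("margins must be positive")
    return float(_scipy_fisher(obs, alternative="two-sided")[1])
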