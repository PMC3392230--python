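"""Per-SNP G-test of genetic differentiation between the sexes.

Each called SNP yields a sexes-by-genotypes contingency table (rows male /
female, columns the observed called genotype classes).  Association is
measured by the log-likelihood-ratio goodness-of-fit statistic
G = 2 * sum O * ln(O / E) with expectations from independence of the
margins, referred to a chi-square with (r-1)(c-1) degrees of freedom — no
continuity or Williams correction.  SNPs genotyped in fewer than 20 males or
20 females are removed before testing, and the Benjamini-Hochberg step-up
procedure converts p-values into q-values within each family.  SNPs with
q < 0.001 sit above the "0.1 percent false discovery rate" line of the scan.

An allelic 2x2 mode (alleles rather than genotype classes as columns) is
available for comparison; the genotypic mode is the default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

log = logging.getLogger("radsexscan")


def g_test(table) -> tuple[float, int, float]:
    """Log-likelihood-ratio test of independence for an r x c count table.

    Cells with O = 0 contribute zero (the x*ln(x) limit).  A zero row or
    column margin is an error: such rows/columns must be dropped upstream.
    Returns ``(G, df, p)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("g_test needs an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row/column margin; drop empty classes first")
    expected = np.outer(row, col) / obs.sum()
    g = 2.0 * xlogy(obs, obs / expected).sum()
    g = max(g, 0.0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(g), int(df), float(chi2.sf(g, df))


def g_test_tables(male_counts: np.ndarray, female_counts: np.ndarray):
    """Vectorized 2 x C G-test over many SNPs.

    ``male_counts``/``female_counts`` are (N, C) genotype-class counts.
    Classes with zero total are dropped per SNP (they shrink df).  Returns
    ``(G, df, p)`` arrays; SNPs with an empty sex margin get NaN.
    """
    m = np.asarray(male_counts, dtype=float)
    f = np.asarray(female_counts, dtype=float)
    col = m + f
    row_m = m.sum(axis=1)
    row_f = f.sum(axis=1)
    total = row_m + row_f
    with np.errstate(invalid="ignore", divide="ignore"):
        e_m = row_m[:, None] * col / total[:, None]
        e_f = row_f[:, None] * col / total[:, None]
        g = 2.0 * (_xlogy_ratio(m, e_m) + _xlogy_ratio(f, e_f)).sum(axis=1)
    g = np.clip(g, 0.0, None)
    df = (col > 0).sum(axis=1) - 1
    ok = (row_m > 0) & (row_f > 0) & (df >= 1)
    p = np.full(len(g), np.nan)
    p[ok] = chi2.sf(g[ok], df[ok])
    g[~ok] = np.nan
    return g, df, p


def _xlogy_ratio(o: np.ndarray, e: np.ndarray) -> np.ndarray:
    out = np.zeros_like(o)
    pos = o > 0
    out[pos] = o[pos] * np.log(o[pos] / e[pos])
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending ordering, clipped
    at 1.  Invariant to permutations of the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr: empty p-value list")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def filter_min_per_sex(calls: pd.DataFrame, sheet: pd.DataFrame,
                       min_per_sex: int = 20) -> pd.DataFrame:
    """Keep only SNPs with at least ``min_per_sex`` called males AND females.

    ``calls`` is a call table from :func:`radsexscan.genotyper.call_matrix`;
    individuals of unknown sex never count toward either tally.
    """
    if min_per_sex < 1:
        raise ValueError("min_per_sex must be >= 1")
    sexed = sheet[sheet["sex"].isin(["male", "female"])]
    merged = calls.merge(sexed[["sample_id", "sex"]], on="sample_id", how="inner")
    counts = (merged[merged["called"]]
              .groupby(["marker_id", "sex"])["sample_id"].nunique()
              .unstack(fill_value=0)
              .reindex(columns=["male", "female"], fill_value=0))
    keep = counts.index[(counts["male"] >= min_per_sex) & (counts["female"] >= min_per_sex)]
    return merged[merged["marker_id"].isin(set(keep))].copy()


def run_sexscan(calls: pd.DataFrame, sheet: pd.DataFrame, family: str | None = None,
                min_per_sex: int = 20, fdr: float = 0.001,
                mode: str = "genotypic") -> pd.DataFrame:
    """Genome scan of male/female genetic differentiation over called SNPs.

    Returns one row per surviving SNP: chrom, pos_bp, allele1, allele2,
    per-sex counts of each biallelic genotype class, totals, G, df, p, q,
    neglog10p and the q < ``fdr`` significance flag.  FDR is computed within
    the scanned family only.
    """
    if mode not in ("genotypic", "allelic"):
        raise ValueError("mode must be 'genotypic' or 'allelic'")
    sexed = sheet[sheet["sex"].isin(["male", "female"])]
    if family is not None:
        sexed = sexed[sexed["family"] == family]
    kept = filter_min_per_sex(calls, sexed, min_per_sex=min_per_sex)
    kept = kept[kept["called"]]
    rows = []
    for marker, grp in kept.groupby("marker_id", sort=False):
        tab = pd.crosstab(grp["sex"], grp["genotype"].astype(str))
        tab = tab.reindex(index=["male", "female"], fill_value=0)
        tab = tab.loc[:, tab.sum(axis=0) > 0]
        alleles = pd.Series(
            [a for g in grp["genotype"].astype(str) for a in g.split("/")]
        ).value_counts()
        allele1 = alleles.index[0]
        allele2 = alleles.index[1] if len(alleles) > 1 else allele1
        if mode == "allelic":
            m_counts = [sum(g.split("/").count(a) for g in
                            grp.loc[grp["sex"] == "male", "genotype"].astype(str))
                        for a in (allele1, allele2)]
            f_counts = [sum(g.split("/").count(a) for g in
                            grp.loc[grp["sex"] == "female", "genotype"].astype(str))
                        for a in (allele1, allele2)]
            test_tab = np.array([m_counts, f_counts], dtype=float)
            test_tab = test_tab[:, test_tab.sum(axis=0) > 0]
        else:
            test_tab = tab.to_numpy(dtype=float)
        if test_tab.shape[1] < 2 or (test_tab.sum(axis=1) == 0).any():
            continue  # monomorphic among called fish, or a sex entirely missing
        g, dof, p = g_test(test_tab)
        hom1, het = f"{allele1}/{allele1}", "/".join(sorted([allele1, allele2]))
        hom2 = f"{allele2}/{allele2}"
        def cnt(sex, gt):
            return int(tab.loc[sex, gt]) if gt in tab.columns else 0
        rows.append({
            "marker_id": marker,
            "chrom": grp["chrom"].iloc[0],
            "pos_bp": int(grp["pos_bp"].iloc[0]),
            "allele1": allele1, "allele2": allele2,
            "n_male_hom1": cnt("male", hom1), "n_male_het": cnt("male", het),
            "n_male_hom2": cnt("male", hom2),
            "n_female_hom1": cnt("female", hom1), "n_female_het": cnt("female", het),
            "n_female_hom2": cnt("female", hom2),
            "n_male_called": int(tab.loc["male"].sum()),
            "n_female_called": int(tab.loc["female"].sum()),
            "G": g, "df": dof, "p": p,
        })
    if not rows:
        n_snps = calls["marker_id"].nunique()
        raise ValueError(
            f"no SNP survived scanning ({n_snps} markers seen, "
            f"min {min_per_sex} called per sex required)")
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    with np.errstate(divide="ignore"):
        out["neglog10p"] = -np.log10(out["p"])
    out["significant"] = out["q"] < fdr
    log.info("run_sexscan: %d SNPs tested, %d significant at q < %g",
             len(out), int(out["significant"].sum()), fdr)
    return out
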