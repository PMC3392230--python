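"""Maximum-likelihood diploid genotype calling from nucleotide read counts.

A site's reads are modelled as a multinomial sample over the four
nucleotides.  For a homozygote ii with per-read error rate eps the read
probabilities are 1-eps for base i and eps/3 for each other base; for a
heterozygote ij each genotype base has probability (1-2eps/3)/2 and the
others eps/3.  Instead of fixing eps, each genotype's likelihood is
profiled: maximized over eps within a bounded interval (default
[0.001, 0.1]).  The bound is the point of the method — it stops wildly
uneven read counts at a true heterozygote from being absorbed into an
implausibly large error rate and miscalled homozygous.

The interior profile maximizers are closed form:

* homozygote ii:      eps_hat = (n - n_i) / n
* heterozygote ij:    eps_hat = 3 (n - n_i - n_j) / (2 n)

each clipped to the bound.  The multinomial coefficient is omitted: it is
identical for every genotype at a site and cancels from every likelihood
ratio.

A genotype is called only when the likelihood-ratio statistic between the
two best genotypes, 2*(lnL_best - lnL_second), exceeds the chi-square(1 df)
quantile at 1-alpha (6.6349 for alpha = 0.01).  Zero depth and exact
first-place likelihood ties yield NO_CALL.  No explicit depth filter is
applied: low-coverage sites simply cannot reach a significant ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .iocore import NUCLEOTIDES

GENOTYPE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(4) for j in range(i, 4)
)
GENOTYPE_NAMES: tuple[str, ...] = tuple(
    f"{NUCLEOTIDES[i]}/{NUCLEOTIDES[j]}" for i, j in GENOTYPE_PAIRS
)


@dataclass(frozen=True)
class GenotyperConfig:
    """Bounds of the error-rate profile and the call-significance level."""

    eps_min: float = 0.001
    eps_max: float = 0.1
    alpha: float = 0.01
    min_depth: int = 0  # optional post-hoc filter; 0 disables it

    def __post_init__(self):
        if not 0.0 < self.eps_min < self.eps_max < 0.75:
            raise ValueError("require 0 < eps_min < eps_max < 0.75")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")

    @property
    def lr_critical(self) -> float:
        return float(chi2.ppf(1.0 - self.alpha, df=1))


@dataclass(frozen=True)
class GenotypeCall:
    best_genotype: str | None  # "A/C" style, None = NO_CALL
    lnl_best: float
    lnl_second: float
    eps_hat: float
    lr_stat: float
    called: bool
    depth: int


def _hom_loglik(n: np.ndarray, n_i: np.ndarray, cfg: GenotyperConfig):
    eps = np.clip((n - n_i) / np.maximum(n, 1), cfg.eps_min, cfg.eps_max)
    lnl = n_i * np.log1p(-eps) + (n - n_i) * np.log(eps / 3.0)
    return lnl, eps


def _het_loglik(n: np.ndarray, m: np.ndarray, cfg: GenotyperConfig):
    eps = np.clip(1.5 * (n - m) / np.maximum(n, 1), cfg.eps_min, cfg.eps_max)
    lnl = m * np.log((1.0 - 2.0 * eps / 3.0) / 2.0) + (n - m) * np.log(eps / 3.0)
    return lnl, eps


def loglik_matrix(counts: np.ndarray, config: GenotyperConfig | None = None):
    """Profile log-likelihood of all 10 unordered genotypes per count vector.

    ``counts`` is (N, 4) in A,C,G,T order.  Returns ``(lnl, eps_hat)`` each of
    shape (N, 10) in ``GENOTYPE_PAIRS`` order.  Rows with zero depth get
    -inf likelihoods.
    """
    config = config or GenotyperConfig()
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim == 1:
        counts = counts[None, :]
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    n = counts.sum(axis=1)
    lnl = np.full((len(counts), len(GENOTYPE_PAIRS)), -np.inf)
    eps = np.full_like(lnl, np.nan)
    pos = n > 0
    for g, (i, j) in enumerate(GENOTYPE_PAIRS):
        if i == j:
            l, e = _hom_loglik(n[pos], counts[pos, i], config)
        else:
            l, e = _het_loglik(n[pos], counts[pos, i] + counts[pos, j], config)
        lnl[pos, g] = l
        eps[pos, g] = e
    return lnl, eps


def profile_loglik(genotype: str, counts, config: GenotyperConfig | None = None):
    """Profile log-likelihood and eps_hat of one genotype for one count vector.

    ``genotype`` is an unordered pair like "A/C" (or "C/A").  Depth must be
    positive.
    """
    config = config or GenotyperConfig()
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (4,):
        raise ValueError("counts must be 4 integers (A, C, G, T)")
    if counts.sum() == 0:
        raise ValueError("zero depth: likelihood undefined (emit NO_CALL upstream)")
    a, b = sorted(genotype.split("/"))
    g = GENOTYPE_NAMES.index(f"{a}/{b}")
    lnl, eps = loglik_matrix(counts[None, :], config)
    return float(lnl[0, g]), float(eps[0, g])


def call_genotype(counts, config: GenotyperConfig | None = None) -> GenotypeCall:
    """Call one site in one individual; NO_CALL on zero depth, weak LR or ties."""
    config = config or GenotyperConfig()
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n == 0:
        return GenotypeCall(None, np.nan, np.nan, np.nan, np.nan, False, 0)
    lnl, eps = loglik_matrix(counts[None, :], config)
    lnl, eps = lnl[0], eps[0]
    order = np.argsort(lnl, kind="stable")[::-1]
    best, second = order[0], order[1]
    lr = 2.0 * (lnl[best] - lnl[second])
    tie = lnl[best] == lnl[second]
    called = (not tie) and lr >= config.lr_critical and n >= config.min_depth
    return GenotypeCall(
        best_genotype=GENOTYPE_NAMES[best] if called else None,
        lnl_best=float(lnl[best]),
        lnl_second=float(lnl[second]),
        eps_hat=float(eps[best]),
        lr_stat=float(lr),
        called=bool(called),
        depth=n,
    )


def call_matrix(table: pd.DataFrame, config: GenotyperConfig | None = None,
                sample_sheet: pd.DataFrame | None = None):
    """Call every (marker, individual) row of a read-count table.

    Returns ``(calls, summary)``: per-row calls (marker_id, chrom, pos_bp,
    sample_id, depth, genotype, called, lr_stat, eps_hat) with genotype NA
    when not called, and a per-marker summary of call counts (split by sex
    when a sample sheet is supplied, feeding the scan's >=20-per-sex filter).
    """
    config = config or GenotyperConfig()
    counts = table[["n_A", "n_C", "n_G", "n_T"]].to_numpy(dtype=np.int64)
    n = counts.sum(axis=1)
    lnl, eps = loglik_matrix(counts, config)
    order = np.argsort(lnl, axis=1, kind="stable")[:, ::-1]
    best = order[:, 0]
    second = order[:, 1]
    rows = np.arange(len(counts))
    with np.errstate(invalid="ignore"):  # zero-depth rows are -inf - -inf
        lr = 2.0 * (lnl[rows, best] - lnl[rows, second])
    tie = lnl[rows, best] == lnl[rows, second]
    called = (n > 0) & ~tie & (lr >= config.lr_critical) & (n >= config.min_depth)
    genotype = pd.array([GENOTYPE_NAMES[b] if c else pd.NA
                         for b, c in zip(best, called)], dtype="string")
    calls = pd.DataFrame({
        "marker_id": table["marker_id"].to_numpy(),
        "chrom": table["chrom"].to_numpy(),
        "pos_bp": table["pos_bp"].to_numpy(),
        "sample_id": table["sample_id"].to_numpy(),
        "depth": n,
        "genotype": genotype,
        "called": called,
        "lr_stat": np.where(n > 0, lr, np.nan),
        "eps_hat": np.where(called, eps[rows, best], np.nan),
    })
    if sample_sheet is not None:
        merged = calls.merge(sample_sheet[["sample_id", "sex"]], on="sample_id", how="left")
        summary = (merged[merged["called"]]
                   .pivot_table(index="marker_id", columns="sex", values="sample_id",
                                aggfunc="nunique", fill_value=0)
                   .reindex(columns=["male", "female"], fill_value=0)
                   .rename(columns={"male": "n_male_called", "female": "n_female_called"})
                   .reset_index())
    else:
        summary = (calls[calls["called"]]
                   .groupby("marker_id")["sample_id"].nunique()
                   .rename("n_called").reset_index())
    return calls, summary
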