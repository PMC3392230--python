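"""Observed/expected enrichment of genomic element classes in a region.

Given genome-wide copy numbers of an element class, the expected count in a
target region under uniform placement is n_genome * region_fraction, the
percent-in-region is 100 * observed / n_genome, and an upper-tail binomial
test gives P(X >= observed) with X ~ Binomial(n_genome, region_fraction).
The region fraction (e.g. a heterochromatic arm covering 2.26 % of an
assembly) is an input, not recomputed from assembly sizes.

Display rounding follows the convention of published element tables: one
decimal, half away from zero, except that values of 10 or more are shown as
integers.  Raw values are kept at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import binom


def _round_half_away(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_expected(value: float) -> str:
    """Display string for an expected count: one decimal below 10, else integer."""
    one = _round_half_away(value, 1)
    if one >= 10:
        return str(int(_round_half_away(value, 0)))
    return f"{one:.1f}"


def format_percent(value: float) -> str:
    return f"{_round_half_away(value, 1):.1f}"


@dataclass(frozen=True)
class RegionEnrichment:
    element_class: str
    n_genome: int
    region_fraction: float
    expected: float
    observed: int
    percent_in_region: float
    p_binomial: float

    @property
    def expected_display(self) -> str:
        return format_expected(self.expected)

    @property
    def percent_display(self) -> str:
        return format_percent(self.percent_in_region)


def count_in_region(elements: pd.DataFrame, chrom: str, start: int, end: int,
                    element_class: str | None = None, rule: str = "start") -> int:
    """Number of elements falling in a 0-based half-open region.

    ``rule="start"`` counts an element if its start lies in [start, end)
    (each element counted in exactly one region of a tiling);
    ``rule="overlap"`` counts any overlap.  ``element_class=None`` counts
    all classes.
    """
    if end <= start:
        raise ValueError("region end must exceed start")
    sel = elements[elements["chrom"] == chrom]
    if element_class is not None:
        sel = sel[sel["element_class"] == element_class]
    if rule == "start":
        hit = (sel["start"] >= start) & (sel["start"] < end)
    elif rule == "overlap":
        hit = (sel["start"] < end) & (sel["end"] > start)
    else:
        raise ValueError("rule must be 'start' or 'overlap'")
    return int(hit.sum())


def enrichment_summary(element_class: str, n_genome: int, observed: int,
                       region_fraction: float) -> RegionEnrichment:
    """Expected count, percent-in-region and binomial upper-tail p-value."""
    if not 0.0 < region_fraction <= 1.0:
        raise ValueError("region_fraction must lie in (0, 1]")
    if n_genome < 0 or observed < 0:
        raise ValueError("counts must be non-negative")
    if observed > n_genome:
        raise ValueError("observed cannot exceed the genome-wide count")
    expected = n_genome * region_fraction
    percent = 100.0 * observed / n_genome if n_genome > 0 else 0.0
    p = float(binom.sf(observed - 1, n_genome, region_fraction)) if n_genome > 0 else 1.0
    return RegionEnrichment(element_class=element_class, n_genome=int(n_genome),
                            region_fraction=float(region_fraction),
                            expected=float(expected), observed=int(observed),
                            percent_in_region=float(percent), p_binomial=p)


def enrichment_table(counts: pd.DataFrame, region_fraction: float) -> pd.DataFrame:
    """Summarize many element classes at once.

    ``counts`` needs element_class, n_genome, observed columns.  Returns the
    raw and display-rounded expected/percent plus the binomial p per class.
    """
    rows = []
    for _, r in counts.iterrows():
        e = enrichment_summary(str(r["element_class"]), int(r["n_genome"]),
                               int(r["observed"]), region_fraction)
        rows.append({
            "element_class": e.element_class,
            "n_genome": e.n_genome,
            "expected": e.expected,
            "expected_display": e.expected_display,
            "observed": e.observed,
            "percent_in_region": e.percent_in_region,
            "percent_display": e.percent_display,
            "p_binomial": e.p_binomial,
        })
    return pd.DataFrame(rows)
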