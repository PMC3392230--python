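"""Sex-specific recombination fractions, Kosambi distances, window rates.

In a phase-known F2 design every individual's maternal gamete is a direct
observation of one female meiosis and its paternal gamete of one male
meiosis, so the recombination fraction between adjacent markers is simply
the fraction of gametes whose grandparental origin switches between them,
estimated separately per parent sex.  Fractions convert to map distance
with the Kosambi function d = 25 ln((1+2r)/(1-2r)) cM (inverse
r = tanh(2d)/2 with d in Morgans), and local rates come from a sliding
window of 3 markers moving 1 marker per estimate: window cM span divided by
window Mb span, anchored at the middle marker.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("radsexscan")

RF_CAP = 0.4999  # Kosambi diverges at 0.5; estimates at or above are capped


def kosambi_cm(r) -> np.ndarray | float:
    """Map distance in cM for recombination fraction(s) r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if (r < 0).any() or (r >= 0.5).any():
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse_r(d_cm) -> np.ndarray | float:
    """Recombination fraction for map distance(s) in cM (inverse of kosambi_cm)."""
    d = np.asarray(d_cm, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


def _origin_rows(gm, parent_sex: str) -> np.ndarray:
    if parent_sex == "female":
        return gm.maternal
    if parent_sex == "male":
        return gm.paternal
    raise ValueError("parent_sex must be 'female' or 'male'")


def estimate_rf(gm, marker_a: str, marker_b: str,
                parent_sex: str) -> tuple[float, int]:
    """Recombination fraction between two markers in one parent's meioses.

    Counts origin switches among individuals with both gametic origins
    observed (pairwise deletion of missing entries).  Estimates at or above
    0.5 are capped at 0.4999 so Kosambi conversion stays finite.  Returns
    ``(r_hat, n_informative)``.
    """
    ids = gm.markers["marker_id"]
    ia = int(np.flatnonzero((ids == marker_a).to_numpy())[0])
    ib = int(np.flatnonzero((ids == marker_b).to_numpy())[0])
    origins = _origin_rows(gm, parent_sex)
    a, b = origins[ia], origins[ib]
    informative = (a >= 0) & (b >= 0)
    n = int(informative.sum())
    if n == 0:
        raise ValueError(f"no informative gametes between {marker_a} and {marker_b}")
    r = float((a[informative] != b[informative]).sum()) / n
    if r >= 0.5:
        log.warning("estimate_rf: %s-%s r_hat=%.3f capped at %.4f",
                    marker_a, marker_b, r, RF_CAP)
        r = RF_CAP
    return r, n


def build_sex_map(gm, parent_sex: str) -> pd.DataFrame:
    """Estimate a cumulative cM map from gametes of one parent sex.

    Adjacent-interval recombination fractions along each chromosome (in
    physical order) are Kosambi-converted and summed.  Returns a genetic-map
    table with the estimated cM in ``cM_<parent_sex>`` (the other sex column
    is NaN) plus the per-interval r_hat and informative count.
    """
    rows = []
    for chrom, grp in gm.markers.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp", kind="mergesort")
        ids = grp["marker_id"].tolist()
        cm = 0.0
        rows.append((ids[0], chrom, int(grp["pos_bp"].iloc[0]), cm, np.nan, 0))
        for a, b, pos in zip(ids[:-1], ids[1:], grp["pos_bp"].iloc[1:]):
            r, n = estimate_rf(gm, a, b, parent_sex)
            cm += kosambi_cm(r)
            rows.append((b, chrom, int(pos), cm, r, n))
    out = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp",
                                      f"cM_{parent_sex}", "r_hat", "n_informative"])
    other = "cM_male" if parent_sex == "female" else "cM_female"
    out[other] = np.nan
    return out


def sliding_window_rate(genetic_map: pd.DataFrame, parent_sex: str,
                        window_markers: int = 3, step: int = 1) -> pd.DataFrame:
    """Local recombination rate (cM/Mb) in sliding marker windows.

    For each window of ``window_markers`` consecutive markers (advancing
    ``step`` markers), the rate is (cM of last - cM of first) over the Mb
    span, reported at the middle marker.  Windows with non-positive Mb span
    are skipped with a warning.  The map must be sorted by position within
    each chromosome with non-decreasing cM, else an error is raised.
    """
    col = f"cM_{parent_sex}"
    if col not in genetic_map.columns:
        raise ValueError(f"map lacks column {col}")
    if window_markers < 2 or step < 1:
        raise ValueError("need window_markers >= 2 and step >= 1")
    rows = []
    for chrom, grp in genetic_map.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        cm = grp[col].to_numpy(dtype=float)
        if (np.diff(pos) < 0).any() or (np.diff(cm) < -1e-9).any():
            raise ValueError(f"{chrom}: map must be sorted with non-decreasing cM")
        if len(grp) < window_markers:
            continue
        for w, start in enumerate(range(0, len(grp) - window_markers + 1, step)):
            stop = start + window_markers - 1
            mb = (pos[stop] - pos[start]) / 1e6
            if mb <= 0:
                log.warning("sliding_window_rate: %s window %d has zero Mb span, skipped",
                            chrom, w)
                continue
            span = cm[stop] - cm[start]
            mid = start + window_markers // 2
            rows.append({
                "chrom": chrom, "window": w,
                "marker_first": grp["marker_id"].iloc[start],
                "marker_mid": grp["marker_id"].iloc[mid],
                "marker_last": grp["marker_id"].iloc[stop],
                "pos_bp": int(pos[mid]),
                "cM_span": float(span), "Mb_span": float(mb),
                "rate_cM_per_Mb": float(span / mb),
                "parent_sex": parent_sex,
            })
    return pd.DataFrame(rows, columns=["chrom", "window", "marker_first", "marker_mid",
                                       "marker_last", "pos_bp", "cM_span", "Mb_span",
                                       "rate_cM_per_Mb", "parent_sex"])
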