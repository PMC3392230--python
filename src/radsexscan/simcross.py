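"""Forward simulation of reciprocal F2 intercross families with RAD-style reads.

The generator emulates a cross between two inbred-like founder strains (G1 =
grandsire strain, G2 = granddam strain): F0 fish are opposite homozygotes at
every strain-diagnostic marker, F1 are uniformly heterozygous with known
phase, and each F2 receives one maternal gamete drawn on the female genetic
map and one paternal gamete drawn on the male map.  Crossovers follow a
no-interference process: each inter-marker interval recombines independently
with probability equal to the Kosambi inverse of the parent-sex-specific cM
interval.  Gonadal sex is assigned by a penetrance table at one or two
sex-associated loci, and sequencing is emulated as negative-binomial depth
followed by multinomial read sampling with a per-nucleotide error rate.

Genotypes are stored phase-known: the four-way class of an F2 individual at
a marker is the ordered pair (maternal-gamete origin, paternal-gamete
origin), each G1 or G2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iocore import MAP_COLUMNS, NUCLEOTIDES
from .recomb import kosambi_inverse_r

COLLAPSED_LABELS = ("G1G1", "G1G2", "G2G2")  # het unordered
FOURWAY_LABELS = ("G1|G1", "G1|G2", "G2|G1", "G2|G2")  # maternal|paternal origin


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: physical length, marker count, map lengths.

    Markers are evenly spaced along the chromosome.  The female map is
    piecewise linear in bp with the distal (right) telomeric fraction of the
    chromosome carrying an elevated share of the map, emulating the
    telomere-biased recombination of fish linkage maps; the male map is the
    female map scaled by ``male_scale`` and, where requested, additionally
    suppressed in the terminal region.
    """

    name: str
    length_bp: int
    n_markers: int
    cm_female: float
    cm_male: float | None = None  # None -> male_scale * cm_female

    def __post_init__(self):
        if self.n_markers < 2:
            raise ValueError(f"{self.name}: need at least 2 markers")
        if self.length_bp < self.n_markers:
            raise ValueError(f"{self.name}: length_bp too small")
        if self.cm_female < 0 or (self.cm_male is not None and self.cm_male < 0):
            raise ValueError(f"{self.name}: negative map length")


@dataclass(frozen=True)
class SexModel:
    """Penetrance-based sex determination at one or two loci.

    ``loci`` lists (chrom, pos_bp) of simulated markers.  ``table`` maps a
    collapsed genotype label ("G1G1"/"G1G2"/"G2G2") — or, for two loci, a
    tuple of two such labels ordered as ``loci`` — to the probability that the
    individual develops as male.  Sex draws are independent given genotype.
    """

    loci: tuple[tuple[str, int], ...]
    table: dict

    def __post_init__(self):
        if not 1 <= len(self.loci) <= 2:
            raise ValueError("SexModel supports 1 or 2 loci")
        for v in self.table.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("penetrance values must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a simulated family.

    Defaults mirror the mapped Family-A design: 145 F2 individuals, a
    Fig-2A-like single sex-associated locus near the distal end of the last
    chromosome (grandsire-homozygotes always male, heterozygotes male with
    probability 0.16, granddam-homozygotes never male), negative-binomial
    depth with mean 30 and dispersion 5, sequencing error rate 0.01.
    """

    n_f2: int = 145
    chromosomes: tuple[ChromosomeSpec, ...] = (
        ChromosomeSpec("chr1", 50_000_000, 40, 90.0),
        ChromosomeSpec("chr2", 50_000_000, 40, 90.0),
        ChromosomeSpec("chr3", 50_000_000, 40, 90.0),
        ChromosomeSpec("chr4", 62_000_000, 50, 100.0),
    )
    sex_model: SexModel | None = None  # None -> default Fig-2A-style locus on last chromosome
    diagnostic_fraction: float = 1.0
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.01
    p_missing: float = 0.02
    male_scale: float = 0.6
    terminal_fraction: float = 0.10
    terminal_cm_share: float = 0.20
    suppression_factor: float = 5.0
    suppressed_chroms: tuple[str, ...] | None = None  # None -> last chromosome
    cm_maps: dict | None = None  # chrom -> (cM_female array, cM_male array), overrides the shape above
    family: str = "A"

    def __post_init__(self):
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be positive")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if not 0.0 <= self.p_missing <= 1.0:
            raise ValueError("p_missing must lie in [0, 1]")
        if not 0.0 <= self.diagnostic_fraction <= 1.0:
            raise ValueError("diagnostic_fraction must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not 0.0 < self.terminal_fraction < 1.0:
            raise ValueError("terminal_fraction must lie in (0, 1)")
        if self.suppression_factor < 1.0:
            raise ValueError("suppression_factor must be >= 1")

    def resolved_sex_model(self) -> SexModel:
        if self.sex_model is not None:
            return self.sex_model
        chrom = self.chromosomes[-1]
        pos = _marker_positions(chrom)[-2]  # penultimate marker, near the distal telomere
        return SexModel(loci=((chrom.name, int(pos)),),
                        table={"G1G1": 1.0, "G1G2": 0.16, "G2G2": 0.0})


@dataclass
class GenotypeMatrix:
    """Phase-known four-way genotypes of the F2 panel.

    ``maternal``/``paternal`` are (n_markers, n_individuals) int8 arrays of
    gamete origins: 0 = G1 (grandsire strain), 1 = G2 (granddam strain),
    -1 = missing/unobservable.  ``markers`` carries the true map (marker_id,
    chrom, pos_bp, cM_female, cM_male) plus the founder alleles and the
    strain-diagnostic flag.
    """

    markers: pd.DataFrame
    sample_ids: list[str]
    maternal: np.ndarray
    paternal: np.ndarray

    def classes(self) -> np.ndarray:
        """Four-way class 2*maternal + paternal in 0..3; -1 where missing."""
        out = 2 * self.maternal + self.paternal
        out[(self.maternal < 0) | (self.paternal < 0)] = -1
        return out.astype(np.int8)

    def collapsed(self) -> np.ndarray:
        """Number of G2 alleles (0, 1, 2); -1 where missing."""
        out = self.maternal + self.paternal
        out[(self.maternal < 0) | (self.paternal < 0)] = -1
        return out.astype(np.int8)

    def genetic_map(self) -> pd.DataFrame:
        return self.markers[MAP_COLUMNS].copy()

    def marker_index(self, chrom: str, pos_bp: int) -> int:
        hit = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy()
                             & (self.markers["pos_bp"] == pos_bp).to_numpy())
        if hit.size != 1:
            raise KeyError(f"no unique marker at {chrom}:{pos_bp}")
        return int(hit[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table (marker_id, sample_id, maternal, paternal)."""
        m, n = self.maternal.shape
        return pd.DataFrame({
            "marker_id": np.repeat(self.markers["marker_id"].to_numpy(), n),
            "sample_id": np.tile(np.asarray(self.sample_ids, dtype=object), m),
            "maternal": self.maternal.ravel(),
            "paternal": self.paternal.ravel(),
        })


def _marker_positions(chrom: ChromosomeSpec) -> np.ndarray:
    return np.linspace(chrom.length_bp / chrom.n_markers, chrom.length_bp,
                       chrom.n_markers).round().astype(np.int64)


def _chrom_cm_maps(chrom: ChromosomeSpec, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative female and male cM at each marker of one chromosome."""
    if config.cm_maps is not None and chrom.name in config.cm_maps:
        f, m = config.cm_maps[chrom.name]
        f, m = np.asarray(f, float), np.asarray(m, float)
        if len(f) != chrom.n_markers or len(m) != chrom.n_markers:
            raise ValueError(f"{chrom.name}: explicit cM map length mismatch")
        if (np.diff(f) < 0).any() or (np.diff(m) < 0).any():
            raise ValueError(f"{chrom.name}: cM maps must be non-decreasing")
        return f, m
    pos = _marker_positions(chrom).astype(float)
    split = (1.0 - config.terminal_fraction) * chrom.length_bp
    frac = np.where(
        pos <= split,
        (pos / split) * (1.0 - config.terminal_cm_share),
        (1.0 - config.terminal_cm_share)
        + (pos - split) / (chrom.length_bp - split) * config.terminal_cm_share,
    )
    cm_f = chrom.cm_female * frac
    cm_m_total = chrom.cm_male if chrom.cm_male is not None else config.male_scale * chrom.cm_female
    cm_m = cm_m_total * frac
    suppressed = config.suppressed_chroms
    if suppressed is None:
        suppressed = (config.chromosomes[-1].name,)
    if chrom.name in suppressed and config.suppression_factor > 1.0:
        d = np.diff(cm_m, prepend=0.0)
        d[pos > split] /= config.suppression_factor
        cm_m = np.cumsum(d)
    return cm_f, cm_m


def _simulate_gametes(cm: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n_markers, n) gamete origins for one chromosome under one parent's map."""
    d = np.diff(cm)
    if (d < 0).any():
        raise ValueError("cM map must be non-decreasing")
    r = kosambi_inverse_r(d)
    if (r >= 0.5).any():
        raise ValueError("interval recombination fraction >= 0.5")
    start = rng.integers(0, 2, size=n)
    switches = rng.random((len(d), n)) < r[:, None]
    return (np.vstack([start[None, :], switches]).cumsum(axis=0) % 2).astype(np.int8)


def simulate_pedigree_genotypes(config: SimulationConfig,
                                rng: np.random.Generator | int) -> GenotypeMatrix:
    """Simulate the F2 genotype matrix and return it with its true map.

    F0 founders are opposite homozygotes at strain-diagnostic markers, F1 are
    phase-known heterozygotes, and each F2 draws a maternal gamete on the
    female map and a paternal gamete on the male map via the no-interference
    crossover process.  Non-diagnostic markers (probability
    ``1 - diagnostic_fraction``) carry identical founder alleles; gametic
    origins are unobservable there and stored as missing.
    """
    rng = np.random.default_rng(rng)
    sample_ids = [f"F2_{i:04d}" for i in range(config.n_f2)]
    marker_rows, mat_blocks, pat_blocks = [], [], []
    for chrom in config.chromosomes:
        pos = _marker_positions(chrom)
        cm_f, cm_m = _chrom_cm_maps(chrom, config)
        diagnostic = rng.random(chrom.n_markers) < config.diagnostic_fraction
        a1 = rng.integers(0, 4, chrom.n_markers)
        shift = rng.integers(1, 4, chrom.n_markers)
        a2 = np.where(diagnostic, (a1 + shift) % 4, a1)
        mat = _simulate_gametes(cm_f, config.n_f2, rng)
        pat = _simulate_gametes(cm_m, config.n_f2, rng)
        mat[~diagnostic, :] = -1
        pat[~diagnostic, :] = -1
        mat_blocks.append(mat)
        pat_blocks.append(pat)
        for i in range(chrom.n_markers):
            marker_rows.append((f"{chrom.name}_m{i:03d}", chrom.name, int(pos[i]),
                                float(cm_f[i]), float(cm_m[i]),
                                NUCLEOTIDES[a1[i]], NUCLEOTIDES[a2[i]], bool(diagnostic[i])))
    markers = pd.DataFrame(marker_rows, columns=[
        "marker_id", "chrom", "pos_bp", "cM_female", "cM_male",
        "allele1", "allele2", "diagnostic"])
    return GenotypeMatrix(markers=markers, sample_ids=sample_ids,
                          maternal=np.vstack(mat_blocks), paternal=np.vstack(pat_blocks))


def assign_sex(gm: GenotypeMatrix, sex_model: SexModel,
               rng: np.random.Generator | int, family: str = "A") -> pd.DataFrame:
    """Draw each F2 individual's sex from the penetrance table and return a sample sheet."""
    rng = np.random.default_rng(rng)
    collapsed = gm.collapsed()
    keys = []
    for chrom, pos in sex_model.loci:
        idx = gm.marker_index(chrom, pos)
        cls = collapsed[idx]
        if (cls < 0).any():
            raise ValueError(f"sex locus {chrom}:{pos} has unobservable genotypes")
        keys.append(np.asarray(COLLAPSED_LABELS)[cls])
    if len(keys) == 1:
        lookup = keys[0]
        p_male = np.empty(len(lookup))
        for i, k in enumerate(lookup):
            if k not in sex_model.table:
                raise KeyError(f"genotype class {k!r} absent from penetrance table")
            p_male[i] = sex_model.table[k]
    else:
        p_male = np.empty(len(keys[0]))
        for i, k in enumerate(zip(keys[0], keys[1])):
            if k not in sex_model.table:
                raise KeyError(f"genotype class {k!r} absent from penetrance table")
            p_male[i] = sex_model.table[k]
    is_male = rng.random(len(p_male)) < p_male
    return pd.DataFrame({
        "sample_id": gm.sample_ids,
        "family": family,
        "generation": "F2",
        "sex": np.where(is_male, "male", "female"),
    })


def simulate_read_counts(gm: GenotypeMatrix, config: SimulationConfig,
                         rng: np.random.Generator | int) -> pd.DataFrame:
    """Emulate RAD sequencing of every (marker, individual) cell.

    Depth is negative-binomial (mean ``depth_mean``, dispersion
    ``depth_dispersion``), zeroed with probability ``p_missing``.  Given depth
    n, true genotype and error rate eps, read counts are multinomial with
    per-read probabilities 1-eps (the homozygous base) and eps/3 elsewhere,
    or (1-2eps/3)/2 for each heterozygous base and eps/3 for the others.
    """
    rng = np.random.default_rng(rng)
    eps = config.error_rate
    m_markers, n_ind = gm.maternal.shape
    k = config.depth_dispersion
    p_nb = k / (k + config.depth_mean)
    depth = rng.negative_binomial(k, p_nb, size=(m_markers, n_ind)).astype(np.int64)
    depth[rng.random((m_markers, n_ind)) < config.p_missing] = 0

    a1 = np.array([NUCLEOTIDES.index(a) for a in gm.markers["allele1"]])
    a2 = np.array([NUCLEOTIDES.index(a) for a in gm.markers["allele2"]])
    # gamete origin -> founder nucleotide; unobservable origins (non-diagnostic
    # markers) have allele1 == allele2, so treat them as G1/G1
    mat = np.where(gm.maternal >= 0, gm.maternal, 0)
    pat = np.where(gm.paternal >= 0, gm.paternal, 0)
    g1 = np.where(mat == 0, a1[:, None], a2[:, None])
    g2 = np.where(pat == 0, a1[:, None], a2[:, None])

    d = depth.ravel()
    g1f, g2f = g1.ravel(), g2.ravel()
    counts = np.zeros((d.size, 4), dtype=np.int64)
    het = g1f != g2f
    # homozygotes: errors total Binom(n, eps), split evenly among the 3 others
    for a in range(4):
        sel = ~het & (g1f == a)
        if not sel.any():
            continue
        n = d[sel]
        e = rng.binomial(n, eps)
        e1 = rng.binomial(e, 1.0 / 3.0)
        e2 = rng.binomial(e - e1, 0.5)
        others = [b for b in range(4) if b != a]
        counts[sel, a] = n - e
        counts[sel, others[0]] = e1
        counts[sel, others[1]] = e2
        counts[sel, others[2]] = e - e1 - e2
    # heterozygotes: off-genotype bases total Binom(n, 2eps/3); remainder
    # splits evenly between the two genotype bases
    for a in range(4):
        for b in range(a + 1, 4):
            sel = het & (np.minimum(g1f, g2f) == a) & (np.maximum(g1f, g2f) == b)
            if not sel.any():
                continue
            n = d[sel]
            e = rng.binomial(n, 2.0 * eps / 3.0)
            e1 = rng.binomial(e, 0.5)
            na = rng.binomial(n - e, 0.5)
            others = [c for c in range(4) if c not in (a, b)]
            counts[sel, a] = na
            counts[sel, b] = n - e - na
            counts[sel, others[0]] = e1
            counts[sel, others[1]] = e - e1
    out = pd.DataFrame({
        "marker_id": np.repeat(gm.markers["marker_id"].to_numpy(), n_ind),
        "chrom": np.repeat(gm.markers["chrom"].to_numpy(), n_ind),
        "pos_bp": np.repeat(gm.markers["pos_bp"].to_numpy(), n_ind),
        "sample_id": np.tile(np.asarray(gm.sample_ids, dtype=object), m_markers),
        "n_A": counts[:, 0], "n_C": counts[:, 1],
        "n_G": counts[:, 2], "n_T": counts[:, 3],
    })
    return out


@dataclass
class SimulatedCross:
    genotypes: GenotypeMatrix
    sample_sheet: pd.DataFrame
    read_counts: pd.DataFrame
    config: SimulationConfig


def simulate_cross(config: SimulationConfig,
                   rng: np.random.Generator | int) -> SimulatedCross:
    """Run the three generator stages under one RNG stream."""
    rng = np.random.default_rng(rng)
    gm = simulate_pedigree_genotypes(config, rng)
    sheet = assign_sex(gm, config.resolved_sex_model(), rng, family=config.family)
    counts = simulate_read_counts(gm, config, rng)
    return SimulatedCross(gm, sheet, counts, config)
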