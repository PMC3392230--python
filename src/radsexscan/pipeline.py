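"""End-to-end orchestration: simulate -> genotype -> scan -> qtl -> recomb -> report.

Each stage draws from its own RNG stream spawned from the master seed by a
fixed key, so e.g. changing the permutation count never perturbs the
simulation draws.  All stage outputs are deterministic functions of
(config, seed) and are written as TSV next to a plain-text report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, enrich, iocore, qtlscan, recomb, sexscan
from .genotyper import GenotyperConfig, call_matrix
from .simcross import SimulationConfig, simulate_cross

log = logging.getLogger("radsexscan")

_STAGE_KEYS = {"simulate": 0, "genotype": 1, "sexscan": 2, "qtlscan": 3, "recomb": 4}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],)))


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    genotyper: GenotyperConfig = field(default_factory=GenotyperConfig)
    min_per_sex: int = 20
    fdr: float = 0.001
    n_perm: int = 1000
    lod_drop: float = 1.5
    window_markers: int = 3
    region_fraction: float = datasets.CHR4_HETEROCHROMATIN_FRACTION


@dataclass(frozen=True)
class FamilySummary:
    family: str
    n_male: int
    n_female: int
    sex_ratio: float | None  # male/female, one-decimal display; None if no females
    n_markers_polymorphic: int = 0
    n_markers_scanned: int = 0

    @property
    def ratio_display(self) -> str:
        if self.sex_ratio is None:
            return "undefined"
        return f"{self.sex_ratio:.1f}:1"


def summarize_family(sheet: pd.DataFrame, family: str,
                     n_markers_polymorphic: int = 0,
                     n_markers_scanned: int = 0) -> FamilySummary:
    """Sex bookkeeping for one family (F2 individuals of known sex)."""
    sub = sheet[(sheet["family"] == family) & (sheet["generation"] == "F2")]
    if sub.empty:
        raise ValueError(f"family {family!r} not present")
    n_male = int((sub["sex"] == "male").sum())
    n_female = int((sub["sex"] == "female").sum())
    ratio = round(n_male / n_female, 1) if n_female > 0 else None
    return FamilySummary(family, n_male, n_female, ratio,
                         n_markers_polymorphic, n_markers_scanned)


def load_genotype_matrix(genotypes_path, map_path):
    """Build a GenotypeMatrix from long-format truth genotypes + a map TSV.

    The genotype file needs marker_id, sample_id, maternal, paternal columns
    (origins 0 = G1, 1 = G2, -1/empty = missing); the map is a standard
    genetic-map table.  This is the drop-in entry point for externally
    produced phase-known genotypes.
    """
    from .simcross import GenotypeMatrix

    truth = pd.read_csv(genotypes_path, sep="\t",
                        dtype={"marker_id": str, "sample_id": str})
    gmap = iocore.read_genetic_map(map_path)
    samples = sorted(truth["sample_id"].unique())
    mat = (truth.pivot(index="marker_id", columns="sample_id", values="maternal")
           .reindex(index=gmap["marker_id"], columns=samples).to_numpy())
    pat = (truth.pivot(index="marker_id", columns="sample_id", values="paternal")
           .reindex(index=gmap["marker_id"], columns=samples).to_numpy())
    markers = gmap.copy()
    markers["allele1"] = "A"
    markers["allele2"] = "C"
    markers["diagnostic"] = True
    return GenotypeMatrix(markers=markers, sample_ids=samples,
                          maternal=np.nan_to_num(mat, nan=-1).astype("int8"),
                          paternal=np.nan_to_num(pat, nan=-1).astype("int8"))


def run_all(config: PipelineConfig, seed: int, outdir,
            counts_path=None, samples_path=None,
            genotypes_path=None, map_path=None) -> Path:
    """Run every stage and write all outputs.

    By default the family is simulated; externally produced inputs drop in
    via ``counts_path``/``samples_path`` (read counts + sample sheet) and
    ``genotypes_path``/``map_path`` (phase-known truth genotypes + map).
    Writes counts/sheet/map/truth TSVs, the genotype calls, the G-test scan,
    the LOD scan with thresholds and support intervals, sex-specific window
    rates, the element-enrichment table and a text report.  Byte-identical
    across runs with the same (config, seed, inputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run_all: seed=%d outdir=%s", seed, outdir)

    # --- simulate or load ---------------------------------------------------
    external = counts_path is not None
    if external:
        if samples_path is None or genotypes_path is None or map_path is None:
            raise ValueError("external inputs need counts, samples, genotypes and map paths")
        for p in (counts_path, samples_path, genotypes_path, map_path):
            log.info("input %s sha256=%s", p, iocore.file_sha256(p))
        counts = iocore.read_counts_table(counts_path)
        sheet = iocore.read_sample_sheet(samples_path)
        gm = load_genotype_matrix(genotypes_path, map_path)
    else:
        sim = simulate_cross(config.simulation, stage_rng(seed, "simulate"))
        gm, sheet, counts = sim.genotypes, sim.sample_sheet, sim.read_counts
    family = (config.simulation.family if not external
              else str(sheet.loc[sheet["generation"] == "F2", "family"].iloc[0]))
    iocore.write_counts_table(counts, outdir / "read_counts.tsv")
    iocore.write_sample_sheet(sheet, outdir / "samples.tsv")
    iocore.write_genetic_map(gm.genetic_map(), outdir / "true_map.tsv")
    gm.to_frame().to_csv(outdir / "true_genotypes.tsv", sep="\t", index=False)

    # --- genotype -----------------------------------------------------------
    calls, call_summary = call_matrix(counts, config.genotyper, sample_sheet=sheet)
    calls.to_csv(outdir / "genotype_calls.tsv", sep="\t", index=False, float_format="%.6g")
    call_summary.to_csv(outdir / "call_summary.tsv", sep="\t", index=False)

    # --- sex scan -----------------------------------------------------------
    scan = sexscan.run_sexscan(calls, sheet, family=family,
                               min_per_sex=config.min_per_sex, fdr=config.fdr)
    iocore.write_scan_results(scan, outdir / "sexscan.tsv")

    # --- LOD scan -----------------------------------------------------------
    lod = qtlscan.lod_scan(gm, sheet)
    thresholds = qtlscan.permutation_threshold(
        gm, sheet, n_perm=config.n_perm,
        seed=np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS["qtlscan"],)))
    intervals = qtlscan.lod_support_interval(lod, thresholds[0.95], drop=config.lod_drop)
    iocore.write_scan_results(lod, outdir / "lodscan.tsv")
    pd.DataFrame([{"quantile": q, "threshold": t} for q, t in sorted(thresholds.items())]) \
        .to_csv(outdir / "lod_thresholds.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame([vars(iv) for iv in intervals]) \
        .to_csv(outdir / "lod_intervals.tsv", sep="\t", index=False, float_format="%.6g")

    # --- recombination ------------------------------------------------------
    windows = []
    for parent_sex in ("female", "male"):
        est_map = recomb.build_sex_map(gm, parent_sex)
        windows.append(recomb.sliding_window_rate(est_map, parent_sex,
                                                  window_markers=config.window_markers))
    windows = pd.concat(windows, ignore_index=True)
    windows.to_csv(outdir / "recomb_windows.tsv", sep="\t", index=False, float_format="%.6g")

    # --- enrichment ---------------------------------------------------------
    enr = enrich.enrichment_table(datasets.chr4q_element_counts(), config.region_fraction)
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    # --- report -------------------------------------------------------------
    fam = summarize_family(sheet, family,
                           n_markers_polymorphic=int(gm.markers["diagnostic"].sum()),
                           n_markers_scanned=len(scan))
    top = scan.nsmallest(5, "p")
    lines = [
        "radsexscan pipeline report",
        f"seed: {seed}",
        f"family: {fam.family}  males: {fam.n_male}  females: {fam.n_female}  "
        f"sex ratio {fam.ratio_display}",
        f"markers polymorphic: {fam.n_markers_polymorphic}  SNPs scanned: {fam.n_markers_scanned}",
        "",
        "top SNPs (G-test):",
    ]
    for _, r in top.iterrows():
        lines.append(f"  {r['marker_id']}  {r['chrom']}:{r['pos_bp']}  G={r['G']:.2f}  "
                     f"p={r['p']:.3g}  q={r['q']:.3g}")
    peak = lod.loc[lod["LOD"].idxmax()]
    lines += [
        "",
        f"LOD peak: {peak['marker_id']}  {peak['chrom']}:{int(peak['pos_bp'])}  "
        f"LOD={peak['LOD']:.2f}",
        f"genome-wide thresholds: 5% {thresholds[0.95]:.2f}  10% {thresholds[0.90]:.2f}",
    ]
    for iv in intervals:
        lines.append(f"support interval {iv.chrom}: {iv.cm_lo:.1f}-{iv.cm_hi:.1f} cM "
                     f"({iv.bp_lo}-{iv.bp_hi} bp), peak {iv.peak_marker} LOD {iv.peak_lod:.2f}")
    mean_rates = windows.groupby("parent_sex")["rate_cM_per_Mb"].mean()
    lines += ["", "mean recombination rate (cM/Mb): "
              + "  ".join(f"{s}={mean_rates[s]:.2f}" for s in ("female", "male"))]
    lines += ["", "element enrichment (top 3 by expected excess):"]
    enr_top = enr.assign(excess=enr["observed"] - enr["expected"]).nlargest(3, "excess")
    for _, r in enr_top.iterrows():
        lines.append(f"  {r['element_class']}: observed {r['observed']} vs expected "
                     f"{r['expected_display']} ({r['percent_display']}% in region)")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return outdir
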