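"""Tabular I/O shared by every pipeline stage.

All flat files are tab-separated UTF-8 with a mandatory header row and no
quoting dialect, so write-then-read round trips are bit-stable.  Marker
tables use 1-based genome positions; genomic element intervals use 0-based
half-open BED coordinates, each matching its ecosystem's convention.

The domain tables are plain :class:`pandas.DataFrame` objects with fixed
column sets; the reader functions validate the type invariants and raise
``ValueError`` with the offending 1-based file line number.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("radsexscan")

NUCLEOTIDES = ("A", "C", "G", "T")
SEX_TOKENS = ("male", "female", "unknown")
GENERATION_TOKENS = ("F0", "F1", "F2")

COUNT_COLUMNS = ["marker_id", "chrom", "pos_bp", "sample_id", "n_A", "n_C", "n_G", "n_T"]
SAMPLE_COLUMNS = ["sample_id", "family", "generation", "sex"]
MAP_COLUMNS = ["marker_id", "chrom", "pos_bp", "cM_female", "cM_male"]
BED_COLUMNS = ["chrom", "start", "end", "element_class"]


def _require_header(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header must name {columns}")


def _line(idx: int) -> int:
    # data row idx -> 1-based file line (header is line 1)
    return int(idx) + 2


def _first_bad(mask: pd.Series) -> int:
    return _line(mask[mask].index[0])


def read_counts_table(path) -> pd.DataFrame:
    """Read a per-(marker, individual) nucleotide read-count table.

    Columns: marker_id, chrom, pos_bp (1-based), sample_id, n_A, n_C, n_G, n_T.
    Raises ``ValueError`` naming the file line for negative counts, non-integer
    fields, positions < 1, or duplicated (marker_id, sample_id) keys.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str, "sample_id": str})
    _require_header(df, COUNT_COLUMNS, path)
    df = df[COUNT_COLUMNS].copy()
    for col in ["pos_bp", "n_A", "n_C", "n_G", "n_T"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise ValueError(f"{path}: line {_first_bad(bad)}: column {col!r} is not an integer")
        df[col] = vals.astype(np.int64)
    for col in ["n_A", "n_C", "n_G", "n_T"]:
        bad = df[col] < 0
        if bad.any():
            raise ValueError(f"{path}: line {_first_bad(bad)}: negative read count in {col!r}")
    bad = df["pos_bp"] < 1
    if bad.any():
        raise ValueError(f"{path}: line {_first_bad(bad)}: pos_bp must be >= 1")
    dup = df.duplicated(subset=["marker_id", "sample_id"])
    if dup.any():
        raise ValueError(f"{path}: line {_first_bad(dup)}: duplicate (marker_id, sample_id) pair")
    log.info("read_counts_table: %d rows from %s", len(df), path)
    return df


def write_counts_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet (sample_id, family, generation, sex).

    Sex tokens must be spelled out as male/female/unknown; generation is
    F0/F1/F2.  Duplicate sample ids are an error.  Rows with sex=unknown are
    kept here (association stages exclude them themselves).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_header(df, SAMPLE_COLUMNS, path)
    df = df[SAMPLE_COLUMNS].copy()
    if df.empty:
        log.warning("read_sample_sheet: %s is empty (header only)", path)
        return df
    bad = ~df["sex"].isin(SEX_TOKENS)
    if bad.any():
        tok = df.loc[bad, "sex"].iloc[0]
        raise ValueError(
            f"{path}: line {_first_bad(bad)}: unknown sex token {tok!r} (use {'/'.join(SEX_TOKENS)})"
        )
    bad = ~df["generation"].isin(GENERATION_TOKENS)
    if bad.any():
        raise ValueError(f"{path}: line {_first_bad(bad)}: generation must be one of {GENERATION_TOKENS}")
    dup = df.duplicated(subset=["sample_id"])
    if dup.any():
        raise ValueError(f"{path}: line {_first_bad(dup)}: duplicate sample_id")
    for (family, sex), grp in df[df["generation"] == "F2"].groupby(["family", "sex"]):
        log.info("read_sample_sheet: family %s: %d F2 %s", family, len(grp), sex)
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_genetic_map(path) -> pd.DataFrame:
    """Read a genetic/physical marker map.

    Columns: marker_id, chrom, pos_bp (1-based), cM_female, cM_male.  Within a
    chromosome the cM columns must be non-decreasing once markers are sorted
    by physical position (map order follows the assembly here).
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    _require_header(df, MAP_COLUMNS, path)
    df = df[MAP_COLUMNS].copy()
    df["pos_bp"] = pd.to_numeric(df["pos_bp"]).astype(np.int64)
    for col in ["cM_female", "cM_male"]:
        df[col] = pd.to_numeric(df[col]).astype(float)
        if (df[col] < 0).any():
            raise ValueError(f"{path}: line {_first_bad(df[col] < 0)}: negative {col}")
    if (df["pos_bp"] < 1).any():
        raise ValueError(f"{path}: line {_first_bad(df['pos_bp'] < 1)}: pos_bp must be >= 1")
    for chrom, grp in df.groupby("chrom", sort=False):
        srt = grp.sort_values("pos_bp")
        for col in ["cM_female", "cM_male"]:
            if (np.diff(srt[col].to_numpy()) < -1e-9).any():
                raise ValueError(f"{path}: {col} not non-decreasing along {chrom}")
    return df


def write_genetic_map(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[MAP_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_bed(path) -> pd.DataFrame:
    """Read genomic element intervals from a BED file (0-based, half-open).

    The BED name column (column 4) is the element class.  Intervals with
    start >= end are rejected.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BED_COLUMNS, usecols=[0, 1, 2, 3],
                     dtype={0: str, 3: str})
    df["start"] = pd.to_numeric(df["start"]).astype(np.int64)
    df["end"] = pd.to_numeric(df["end"]).astype(np.int64)
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        raise ValueError(f"{path}: line {int(bad[bad].index[0]) + 1}: requires 0 <= start < end")
    return df


def write_bed(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)
    return path


def write_scan_results(df: pd.DataFrame, path) -> Path:
    """Write a per-marker scan-result table.

    Tab-separated with a header, rows sorted by (chrom, pos_bp), floats at six
    significant digits, so output is deterministic for a given result.
    """
    if df.empty:
        raise ValueError("write_scan_results: refusing to write an empty result table")
    out = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_genotype_vcf(calls: pd.DataFrame, markers: pd.DataFrame, path) -> Path:
    """Export called genotypes as VCFv4.2 (GT + DP) via pysam.

    ``calls`` needs marker_id, sample_id, genotype (like "A/C" or NA), depth;
    ``markers`` needs marker_id, chrom, pos_bp.  The reference allele is the
    alphabetically first nucleotide observed among calls at the site (the true
    reference base is unknown to a de novo RAD analysis).
    """
    import pysam

    path = Path(path)
    samples = sorted(calls["sample_id"].unique())
    header = pysam.VariantHeader()
    header.add_meta("source", "radsexscan")
    for chrom, grp in markers.groupby("chrom", sort=True):
        header.contigs.add(str(chrom), length=int(grp["pos_bp"].max()) + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s)

    minfo = markers.set_index("marker_id")
    by_marker = {m: g for m, g in calls.groupby("marker_id")}
    order = markers.sort_values(["chrom", "pos_bp"], kind="mergesort")["marker_id"]
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for marker in order:
            grp = by_marker.get(marker)
            if grp is None:
                continue
            called = grp[grp["genotype"].notna()]
            alleles_here = sorted({a for g in called["genotype"] for a in g.split("/")})
            if not alleles_here:
                continue
            ref, alts = alleles_here[0], alleles_here[1:]
            rec = vcf.new_record(
                contig=str(minfo.loc[marker, "chrom"]),
                start=int(minfo.loc[marker, "pos_bp"]) - 1,
                alleles=tuple([ref] + (alts or ["."])) if alts else (ref, "."),
                id=str(marker),
            )
            idx = {a: i for i, a in enumerate(alleles_here)}
            rows = grp.set_index("sample_id")
            for s in samples:
                if s in rows.index and pd.notna(rows.loc[s, "genotype"]):
                    a, b = rows.loc[s, "genotype"].split("/")
                    rec.samples[s]["GT"] = (idx[a], idx[b])
                else:
                    rec.samples[s]["GT"] = (None, None)
                if s in rows.index:
                    rec.samples[s]["DP"] = int(rows.loc[s, "depth"])
            vcf.write(rec)
    return path


def file_sha256(path) -> str:
    """Checksum used when logging pipeline inputs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
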