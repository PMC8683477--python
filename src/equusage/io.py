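"""Readers and writers for the pipeline's on-disk formats.

Conventions: beta matrices are stored sites-as-rows on disk (the usual
array-export orientation) and held samples-x-sites in memory; VCF positions
are 1-based inclusive; ROH BED output is 0-based half-open.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .clock import ClockModel
from .types import (
    MISSING_DOSAGE,
    AnnotationTable,
    BetaMatrix,
    GenotypeTable,
    ROHSegment,
    SampleSheet,
    ValidationError,
)

log = logging.getLogger("equusage")

INFO_FIELDS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")


# ---------------------------------------------------------------- sample sheet

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str})
    sheet = SampleSheet(df)
    log.info("read sample sheet %s: %d samples", path, len(sheet))
    return sheet


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, index=False)


# ----------------------------------------------------------------- beta matrix

def read_beta_matrix(path, sites_as_rows: bool = True, sep: str = ",") -> BetaMatrix:
    """Read a beta-value CSV/TSV into the canonical samples x sites form.

    The first column holds site ids (default, ``sites_as_rows=True``) or
    sample ids; "NA"/empty cells become missing (NaN) and are counted in the
    log. Finite values outside [0, 1] are rejected with coordinates.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if sites_as_rows:
        df = df.T  # now samples x sites
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        log.info("beta matrix %s: %d missing entries", path, n_missing)
    matrix = BetaMatrix.from_frame(df)
    log.info(
        "read beta matrix %s: %d samples x %d sites",
        path, matrix.n_samples, matrix.n_sites,
    )
    return matrix


def write_beta_matrix(matrix: BetaMatrix, path, sites_as_rows: bool = True) -> None:
    df = matrix.to_frame()
    if sites_as_rows:
        df = df.T
    df.to_csv(path)


# ----------------------------------------------------------------- annotation

def read_annotation(path) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, dtype={"site_id": str}))


def write_annotation(annotation: AnnotationTable, path) -> None:
    annotation.frame.to_csv(path, index=False)


# ---------------------------------------------------------------- clock model

_CLOCK_META = ("intercept", "transform", "offset", "alpha", "lambda")


def write_clock(model: ClockModel, path) -> None:
    """Write a clock as CSV: '# key: value' metadata then (site_id, coefficient)."""
    if not np.isfinite(model.intercept) or not all(
        np.isfinite(v) for v in model.coefficients.values()
    ):
        raise ValidationError("clock has non-finite coefficients")
    with open(path, "w") as fh:
        fh.write(f"# intercept: {model.intercept!r}\n")
        fh.write(f"# transform: {model.transform}\n")
        fh.write(f"# offset: {model.offset!r}\n")
        fh.write(f"# alpha: {model.alpha!r}\n")
        fh.write(f"# lambda: {model.lam!r}\n")
        if model.n_train is not None:
            fh.write(f"# n_train: {model.n_train}\n")
        if model.tissue is not None:
            fh.write(f"# tissue: {model.tissue}\n")
        fh.write("site_id,coefficient\n")
        for site, coef in model.coefficients.items():
            fh.write(f"{site},{coef!r}\n")


def read_clock(path) -> ClockModel:
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            elif line.startswith("site_id"):
                continue
            else:
                site, _, coef = line.partition(",")
                rows.append((site, float(coef)))
    missing = [k for k in _CLOCK_META if k not in meta]
    if missing:
        raise ValidationError(f"clock file {path} missing metadata field(s): {missing}")
    return ClockModel(
        transform=meta["transform"],
        offset=float(meta["offset"]),
        intercept=float(meta["intercept"]),
        coefficients=dict(rows),
        alpha=float(meta["alpha"]),
        lam=float(meta["lambda"]),
        n_train=int(meta["n_train"]) if "n_train" in meta else None,
        tissue=meta.get("tissue"),
    )


# ------------------------------------------------------------------------ VCF

def read_vcf_minimal(path) -> GenotypeTable:
    """Load biallelic SNPs from a VCF into a dosage grid.

    Multiallelic and indel records are skipped (counts logged); missing
    genotypes keep the missing code. INFO fields used by the hard filters
    are carried along when present.
    """
    vcf = pysam.VariantFile(str(path))
    individuals = list(vcf.header.samples)
    rows = []
    dosage_cols = []
    n_skipped_multi = 0
    n_skipped_indel = 0
    for line_no, rec in enumerate(vcf, start=1):
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped_multi += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or alt == "*":
            n_skipped_indel += 1
            continue
        col = np.full(len(individuals), MISSING_DOSAGE, dtype=np.int8)
        for i, sample in enumerate(individuals):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            if any(a not in (0, 1) for a in gt):
                raise ValidationError(
                    f"malformed GT {gt} at record {line_no} ({rec.chrom}:{rec.pos})"
                )
            col[i] = sum(gt)
        row = {"chrom": rec.chrom, "pos": rec.pos, "ref": ref, "alt": alt}
        for key in INFO_FIELDS:
            if key in rec.info:
                value = rec.info[key]
                row[key] = float(value[0] if isinstance(value, tuple) else value)
        rows.append(row)
        dosage_cols.append(col)
    vcf.close()
    if n_skipped_multi or n_skipped_indel:
        log.info(
            "VCF %s: skipped %d multiallelic and %d indel/symbolic records",
            path, n_skipped_multi, n_skipped_indel,
        )
    sites = pd.DataFrame(rows)
    dosages = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    table = GenotypeTable(individuals, sites, dosages)
    table.n_skipped_multiallelic = n_skipped_multi  # type: ignore[attr-defined]
    table.n_skipped_indel = n_skipped_indel  # type: ignore[attr-defined]
    return table


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    for key in INFO_FIELDS:
        header.info.add(key, 1, "Float", f"{key} annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    chrom_order = list(dict.fromkeys(table.sites["chrom"]))
    for chrom in chrom_order:
        max_pos = int(table.sites.loc[table.sites["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=max_pos + 1)
    for ind in table.individuals:
        header.add_sample(ind)
    out = pysam.VariantFile(str(path), "w", header=header)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING_DOSAGE: (None, None)}
    for j, site in table.sites.iterrows():
        rec = out.new_record(
            contig=str(site["chrom"]),
            start=int(site["pos"]) - 1,
            stop=int(site["pos"]),
            alleles=(site["ref"], site["alt"]),
        )
        for key in INFO_FIELDS:
            if key in site.index and pd.notna(site[key]):
                rec.info[key] = float(site[key])
        for i, ind in enumerate(table.individuals):
            rec.samples[ind]["GT"] = gt_codes[int(table.dosages[i, j])]
        out.write(rec)
    out.close()


# ------------------------------------------------------------------------ BED

def write_roh_bed(segments: list[ROHSegment], path) -> None:
    """ROH segments as BED6-ish rows (name = individual id, score = n_snps)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.individual}\t{seg.n_snps}\t.\n"
            )


def read_roh_bed(path) -> list[ROHSegment]:
    segments = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, score, _ = line.rstrip("\n").split("\t")
            segments.append(
                ROHSegment(
                    individual=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    n_snps=int(score),
                )
            )
    return segments
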