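"""Genotype-based inbreeding: hard filters, method-of-moments F, runs of
homozygosity, F_ROH, Mendelian-error audit, and imputation-quality metrics.

F is the excess-homozygosity estimator (O_hom - E_hom) / (L - E_hom); F_ROH
divides each individual's total ROH length by the genome length screened.
ROH detection is a PLINK-style sliding scan: fixed-size SNP windows are
called homozygous when they contain at most ``window_het`` heterozygotes
and ``window_missing`` missing calls, each SNP is scored by the fraction of
overlapping windows called homozygous, and stretches of qualifying SNPs
become runs subject to minimum SNP-count and physical-length rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FilterConfig, ROHConfig
from .types import (
    MISSING_DOSAGE,
    GenotypeTable,
    InbreedingEstimate,
    ROHSegment,
    ValidationError,
)


# ----------------------------------------------------------------- hard filter

@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_by: dict[str, int] = field(default_factory=dict)
    missing_info: dict[str, int] = field(default_factory=dict)


def hard_filter(
    table: GenotypeTable, config: FilterConfig | None = None
) -> tuple[GenotypeTable, FilterReport]:
    """Remove sites violating any GATK-style INFO threshold or the MAF/MAC
    floor; a site missing an INFO field passes that criterion (logged in
    the report). A site failing several criteria is counted under each.
    """
    cfg = config or FilterConfig()
    if table.n_sites == 0:
        raise ValidationError("empty genotype table")
    sites = table.sites
    n = table.n_sites

    def info(col):
        if col in sites.columns:
            return sites[col].to_numpy(float)
        return np.full(n, np.nan)

    rules = {
        "QD": info("QD") < cfg.qd_min,
        "FS": info("FS") > cfg.fs_max,
        "SOR": info("SOR") > cfg.sor_max,
        "MQ": info("MQ") < cfg.mq_min,
        "MQRankSum": info("MQRankSum") < cfg.mq_rank_sum_min,
        "ReadPosRankSum": info("ReadPosRankSum") < cfg.read_pos_rank_sum_min,
    }
    missing_info = {
        key: int(np.isnan(info(key)).sum())
        for key in rules
        if np.isnan(info(key)).any()
    }
    # NaN comparisons are False: a missing INFO field passes its criterion
    p = table.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1 - p)
    rules["MAF"] = maf < cfg.maf_min  # strict <: MAF exactly at floor is retained
    if cfg.min_mac > 0:
        alleles = np.where(table.dosages == MISSING_DOSAGE, np.nan, table.dosages)
        alt = np.nansum(alleles, axis=0)
        tot = 2 * np.sum(~np.isnan(alleles), axis=0)
        mac = np.fmin(alt, tot - alt)
        rules["MAC"] = mac < cfg.min_mac
    removed = np.zeros(n, dtype=bool)
    removed_by = {}
    for key, viol in rules.items():
        viol = np.asarray(viol, bool)
        removed_by[key] = int(viol.sum())
        removed |= viol
    report = FilterReport(
        n_input=n,
        n_retained=int((~removed).sum()),
        removed_by=removed_by,
        missing_info=missing_info,
    )
    return table.subset_sites(~removed), report


# ------------------------------------------------------------ method of moments

def f_moments(
    table: GenotypeTable, small_sample_correction: bool = False
) -> dict[str, float | None]:
    """Per-individual excess-homozygosity F-hat.

    Allele frequencies come from the same table; monomorphic loci are
    excluded. An individual with no usable loci gets None. With the
    optional correction the expected homozygosity term uses
    2*p*q * L/(L-1) with L the individual's observed locus count.
    """
    p = table.allele_freq()
    usable_site = np.isfinite(p) & (p > 0) & (p < 1)
    out: dict[str, float | None] = {}
    for i, ind in enumerate(table.individuals):
        d = table.dosages[i]
        mask = usable_site & (d != MISSING_DOSAGE)
        L = int(mask.sum())
        if L == 0:
            out[ind] = None
            continue
        o_hom = int(np.sum((d[mask] == 0) | (d[mask] == 2)))
        het_exp = 2 * p[mask] * (1 - p[mask])
        if small_sample_correction and L > 1:
            het_exp = het_exp * L / (L - 1)
        e_hom = float(np.sum(1 - het_exp))
        denom = L - e_hom
        out[ind] = (o_hom - e_hom) / denom if denom != 0 else None
    return out


# --------------------------------------------------------------- ROH detection

def _roh_one_chrom(genos: np.ndarray, pos: np.ndarray, cfg: ROHConfig):
    """Qualifying-SNP runs on one sorted chromosome; yields (i0, i1) index
    ranges (inclusive) of candidate runs before the size thresholds."""
    L = genos.size
    W = cfg.window_snps
    if L < W:
        return []
    het = (genos == 1).astype(np.int64)
    mis = (genos == MISSING_DOSAGE).astype(np.int64)
    csum_het = np.concatenate(([0], np.cumsum(het)))
    csum_mis = np.concatenate(([0], np.cumsum(mis)))
    starts = np.arange(L - W + 1)
    hom_win = (
        (csum_het[starts + W] - csum_het[starts] <= cfg.window_het)
        & (csum_mis[starts + W] - csum_mis[starts] <= cfg.window_missing)
    ).astype(np.int64)
    csum_hom = np.concatenate(([0], np.cumsum(hom_win)))
    j = np.arange(L)
    lo = np.maximum(j - W + 1, 0)
    hi = np.minimum(j, L - W)
    n_win = hi - lo + 1
    n_hom = csum_hom[hi + 1] - csum_hom[lo]
    qualifies = n_hom / n_win >= cfg.hit_frac
    runs = []
    i = 0
    while i < L:
        if qualifies[i]:
            j0 = i
            while i + 1 < L and qualifies[i + 1]:
                i += 1
            runs.append((j0, i))
        i += 1
    return runs


def detect_roh(
    table: GenotypeTable, config: ROHConfig | None = None
) -> list[ROHSegment]:
    """Sliding-window ROH calls for every individual in the table.

    A candidate run becomes a segment iff it has >= ``min_snps`` qualifying
    SNPs and spans >= ``min_length_kb`` kb first-to-last SNP. BED-style
    coordinates: start = first SNP position - 1, end = last SNP position.
    """
    cfg = config or ROHConfig()
    min_len_bp = cfg.min_length_kb * 1000.0
    segments: list[ROHSegment] = []
    chrom_col = table.sites["chrom"].to_numpy()
    pos_col = table.sites["pos"].to_numpy()
    for i, ind in enumerate(table.individuals):
        for chrom in dict.fromkeys(chrom_col):
            sel = chrom_col == chrom
            pos = pos_col[sel]
            genos = table.dosages[i, sel]
            for j0, j1 in _roh_one_chrom(genos, pos, cfg):
                n_snps = j1 - j0 + 1
                start = int(pos[j0]) - 1
                end = int(pos[j1])
                if n_snps >= cfg.min_snps and end - start >= min_len_bp:
                    segments.append(
                        ROHSegment(
                            individual=ind,
                            chrom=str(chrom),
                            start=start,
                            end=end,
                            n_snps=n_snps,
                        )
                    )
    return segments


def froh(
    segments: list[ROHSegment],
    screened_length_bp: int,
    individuals=None,
) -> dict[str, float]:
    """F_ROH = total ROH length / screened genome length, per individual.

    ``individuals`` (optional) forces zero entries for run-free individuals.
    """
    if screened_length_bp <= 0:
        raise ValidationError("screened_length_bp must be > 0")
    totals: dict[str, int] = {ind: 0 for ind in (individuals or [])}
    for seg in segments:
        totals[seg.individual] = totals.get(seg.individual, 0) + seg.length
    return {ind: total / screened_length_bp for ind, total in totals.items()}


def inbreeding_estimates(
    table: GenotypeTable,
    segments: list[ROHSegment],
    screened_length_bp: int,
) -> list[InbreedingEstimate]:
    """Combine F-hat and F_ROH into one record per individual."""
    f_hat = f_moments(table)
    f_roh = froh(segments, screened_length_bp, individuals=table.individuals)
    per_ind: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        per_ind.setdefault(seg.individual, []).append(seg)
    return [
        InbreedingEstimate(
            individual=ind,
            f_hat=f_hat.get(ind),
            f_roh=f_roh.get(ind, 0.0),
            total_roh_bp=sum(s.length for s in per_ind.get(ind, [])),
            n_segments=len(per_ind.get(ind, [])),
        )
        for ind in table.individuals
    ]


# ------------------------------------------------------------- Mendelian audit

_IMPOSSIBLE = {
    (0, 0): {1, 2},
    (0, 1): {2},
    (1, 0): {2},
    (0, 2): {0, 2},
    (2, 0): {0, 2},
    (1, 1): set(),
    (1, 2): {0},
    (2, 1): {0},
    (2, 2): {0, 1},
}


def mendelian_error_rate(table: GenotypeTable, trios):
    """Per-locus and mean Mendelian error rate over (child, sire, dam) trios.

    A trio-locus is evaluable when all three dosages are non-missing; an
    error is a child dosage impossible under biallelic transmission.
    Returns (per_locus_rates, mean_rate, sd_rate); loci with no evaluable
    trio get NaN and are excluded from the mean.
    """
    index = {ind: i for i, ind in enumerate(table.individuals)}
    for trio in trios:
        for ind in trio:
            if ind not in index:
                raise ValidationError(f"unknown individual {ind!r} in trio")
    n_sites = table.n_sites
    errors = np.zeros(n_sites)
    evaluable = np.zeros(n_sites)
    for child, sire, dam in trios:
        c = table.dosages[index[child]].astype(int)
        s = table.dosages[index[sire]].astype(int)
        d = table.dosages[index[dam]].astype(int)
        ok = (c != MISSING_DOSAGE) & (s != MISSING_DOSAGE) & (d != MISSING_DOSAGE)
        evaluable += ok
        idx = np.nonzero(ok)[0]
        for j in idx:
            if c[j] in _IMPOSSIBLE[(s[j], d[j])]:
                errors[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(evaluable > 0, errors / evaluable, np.nan)
    valid = per_locus[~np.isnan(per_locus)]
    mean = float(valid.mean()) if valid.size else np.nan
    sd = float(valid.std()) if valid.size else np.nan
    return per_locus, mean, sd


# ------------------------------------------------------- imputation evaluation

def imputation_metrics(truth: GenotypeTable, imputed: GenotypeTable):
    """Concordance and dosage r^2 of imputed vs true genotypes.

    Returns a DataFrame (individual, concordance, dosage_r2) plus the means;
    r^2 is NaN for an individual with constant dosages on either side.
    """
    common = [ind for ind in truth.individuals if ind in set(imputed.individuals)]
    if not common:
        raise ValidationError("no shared individuals")
    t_sites = list(zip(truth.sites["chrom"], truth.sites["pos"]))
    i_sites = list(zip(imputed.sites["chrom"], imputed.sites["pos"]))
    shared = sorted(set(t_sites) & set(i_sites), key=lambda x: (str(x[0]), x[1]))
    if not shared:
        raise ValidationError("no overlapping sites between truth and imputed")
    t_idx = [t_sites.index(s) for s in shared]
    i_idx = [i_sites.index(s) for s in shared]
    rows = []
    for ind in common:
        td = truth.dosages[truth.individuals.index(ind)][t_idx].astype(float)
        im = imputed.dosages[imputed.individuals.index(ind)][i_idx].astype(float)
        ok = (td != MISSING_DOSAGE) & (im != MISSING_DOSAGE)
        if not ok.any():
            rows.append((ind, np.nan, np.nan))
            continue
        conc = float(np.mean(td[ok] == im[ok]))
        if np.std(td[ok]) == 0 or np.std(im[ok]) == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(td[ok], im[ok])[0, 1] ** 2)
        rows.append((ind, conc, r2))
    frame = pd.DataFrame(rows, columns=["individual", "concordance", "dosage_r2"])
    return frame, float(frame["concordance"].mean()), float(frame["dosage_r2"].mean())
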