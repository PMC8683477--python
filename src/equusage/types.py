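"""Shared domain containers for the pipeline.

Methylation is carried as *beta values*: the fraction of molecules
methylated at a CpG site, always in [0, 1] (missing entries are NaN).
Genotypes are alt-allele dosages coded 0/1/2 with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("blood", "biopsy")
SEXES = ("F", "M", "unknown")
TSS_CLASSES = (
    "promoter",
    "5'UTR",
    "exon",
    "intron",
    "3'UTR",
    "downstream",
    "intergenic",
)

MISSING_DOSAGE = -1


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


@dataclass
class SampleSheet:
    """Cohort phenotype table: one row per sample.

    Columns: sample_id (unique), species, tissue (blood/biopsy),
    sex (F/M/unknown), age in years (finite, >= 0).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "species", "tissue", "sex", "age"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = self.frame.reset_index(drop=True)
        if df["age"].isna().any():
            rows = df.index[df["age"].isna()].tolist()
            raise ValidationError(f"missing age in rows {rows}")
        ages = df["age"].astype(float)
        if not np.isfinite(ages).all() or (ages < 0).any():
            bad = df.index[~np.isfinite(ages) | (ages < 0)].tolist()
            raise ValidationError(f"age must be finite and >= 0; bad rows {bad}")
        dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample ids: {dup}")
        bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise ValidationError(f"unknown tissue tokens: {bad_tissue}")
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise ValidationError(f"unknown sex tokens: {bad_sex}")
        df["age"] = ages
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(float)

    def subset(self, sample_ids) -> "SampleSheet":
        keep = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep.copy())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class BetaMatrix:
    """Samples x CpG-sites grid of methylation fractions.

    ``values[i, j]`` is the beta value of sample ``sample_ids[i]`` at site
    ``site_ids[j]``; NaN marks missing. All finite entries lie in [0, 1].
    """

    sample_ids: list[str]
    site_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValidationError(
                f"beta grid shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.site_ids)} sites"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("site_ids not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids not unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            i, j = np.argwhere(
                np.isfinite(self.values) & ((self.values < 0) | (self.values > 1))
            )[0]
            raise ValidationError(
                f"beta value {self.values[i, j]} out of [0,1] at "
                f"sample {self.sample_ids[i]!r}, site {self.site_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.site_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            sample_ids=[str(s) for s in frame.index],
            site_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(float),
        )

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return BetaMatrix(list(sample_ids), list(self.site_ids), self.values[rows])

    def subset_sites(self, site_ids) -> "BetaMatrix":
        index = {s: j for j, s in enumerate(self.site_ids)}
        cols = [index[s] for s in site_ids]
        return BetaMatrix(list(self.sample_ids), list(site_ids), self.values[:, cols])

    def drop_missing_sites(self) -> tuple["BetaMatrix", int]:
        """Drop sites with any missing value; returns (matrix, n_dropped)."""
        keep = ~np.isnan(self.values).any(axis=0)
        dropped = int((~keep).sum())
        if dropped == 0:
            return self, 0
        sites = [s for s, k in zip(self.site_ids, keep) if k]
        return BetaMatrix(list(self.sample_ids), sites, self.values[:, keep]), dropped


@dataclass
class AnnotationTable:
    """Per-site genomic context: TSS-distance class and CpG-island flag."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["site_id", "tss_class", "island_flag"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        df = self.frame.reset_index(drop=True)
        dup = df["site_id"][df["site_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate annotation rows for sites: {dup}")
        bad = sorted(set(df["tss_class"]) - set(TSS_CLASSES))
        if bad:
            raise ValidationError(f"unknown TSS classes: {bad}")
        df["island_flag"] = df["island_flag"].astype(bool)
        self.frame = df


@dataclass
class GenotypeTable:
    """Biallelic SNP panel: individuals x sites alt-dosage grid.

    ``dosages`` is int8 with codes {0, 1, 2} and -1 for missing. ``sites``
    has columns chrom, pos (1-based), ref, alt plus any INFO fields
    (QD, FS, SOR, MQ, MQRankSum, ReadPosRankSum when available).
    """

    individuals: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individuals), len(self.sites)):
            raise ValidationError(
                f"dosage grid {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        legal = np.isin(self.dosages, (0, 1, 2, MISSING_DOSAGE))
        if not legal.all():
            raise ValidationError("dosages outside {0,1,2,missing}")
        sites = self.sites.reset_index(drop=True)
        for chrom, grp in sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError(f"positions not strictly increasing on {chrom}")
        self.sites = sites

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per site from non-missing dosages (NaN if none)."""
        d = self.dosages.astype(float)
        d[d == MISSING_DOSAGE] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset_sites(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeTable(
            list(self.individuals),
            self.sites.loc[mask].reset_index(drop=True),
            self.dosages[:, mask],
        )


@dataclass
class ROHSegment:
    """One run of homozygosity; start/end are 0-based half-open bp."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InbreedingEstimate:
    individual: str
    f_hat: float | None = None
    f_roh: float | None = None
    total_roh_bp: int = 0
    n_segments: int = 0


@dataclass
class MethylTruth:
    """Ground truth behind a simulated beta matrix.

    ``role`` per site: 'clock_linear' (mean beta = m0 + r*sqrt(age)),
    'pacemaker_shared' (mean beta = m0 + r*s(age), one shared state curve),
    or 'null'. Sufficient to score recovery of any downstream estimate.
    """

    site_ids: list[str]
    role: np.ndarray
    rate: np.ndarray
    intercept: np.ndarray
    state: np.ndarray
    ages: np.ndarray
    noise_sd: float
    curve_a: float
    curve_c: float
    tissue_offsets: np.ndarray | None = None
    sex_offsets: np.ndarray | None = None


@dataclass
class GenoTruth:
    """Planted-ROH ground truth for a simulated genotype panel."""

    individuals: list[str]
    planted: dict[str, list[tuple[str, int, int]]]
    target_froh: dict[str, float]
    allele_freq: np.ndarray
    screened_length_bp: int

    def planted_froh(self, individual: str) -> float:
        runs = self.planted.get(individual, [])
        return sum(e - s for _, s, e in runs) / self.screened_length_bp
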