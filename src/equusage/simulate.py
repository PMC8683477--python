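"""Synthetic cohorts with known truth for every downstream analysis.

The generators emulate the statistical structure the pipeline assumes:

* methylation beta values with three site classes — sites linear in
  sqrt(age) (clock-like), sites following one shared nonlinear state
  trajectory s(age) = a*ln(age + c) (pacemaker-like), and age-independent
  null sites — plus small tissue/sex offsets and i.i.d. Gaussian noise,
  clipped to [0, 1];
* a "related species" variant that perturbs the intercepts of a fraction
  of sites, for cross-species transfer experiments;
* genotype panels with Hardy-Weinberg background and planted homozygous
  runs whose total length realizes a known F_ROH per individual;
* age-acceleration phenotypes with a configurable age x inbreeding
  interaction and optionally age-growing noise.

Every generator is deterministic under its seed, and returns a truth
record sufficient to score recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulateConfig
from .types import (
    AnnotationTable,
    BetaMatrix,
    GenotypeTable,
    GenoTruth,
    MethylTruth,
    SampleSheet,
    ValidationError,
    TSS_CLASSES,
)

MIN_ROH_BP = 1_500_000
MAX_ROH_BP = 60_000_000


def gen_ages(n: int, min_age: float = 0.15, max_age: float = 25.0, seed: int = 0):
    """Right-skewed (log-uniform) ages in [min_age, max_age], years."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    if not 0 <= min_age < max_age:
        raise ValidationError("need 0 <= min_age < max_age")
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(min_age + 1e-12), np.log(max_age)
    return np.exp(rng.uniform(lo, hi, size=n))


def state_curve(age, a: float = 5.0, c: float = 1.0):
    """Shared pacemaker state trajectory s(age) = a*ln(age + c)."""
    return a * np.log(np.asarray(age, float) + c)


def _safe_intercepts(rng, effect_lo, effect_hi, margin=0.02):
    """Intercept uniform over the sub-interval keeping mean betas in [0,1]."""
    lo = np.maximum(margin - np.minimum(effect_lo, 0.0), 0.05)
    hi = np.minimum(1.0 - margin - np.maximum(effect_hi, 0.0), 0.95)
    hi = np.maximum(hi, lo + 1e-6)
    return rng.uniform(lo, hi)


def gen_methylation(
    ages,
    n_sites: int = 2000,
    frac_clock: float = 0.025,
    frac_pacemaker: float = 0.15,
    noise_sd: float = 0.01,
    tissue_labels=None,
    sex_labels=None,
    curve_a: float = 5.0,
    curve_c: float = 1.0,
    clock_slope: float = 0.02,
    pacemaker_rate_range: tuple[float, float] = (0.01, 0.03),
    tissue_effect_sd: float = 0.0,
    sex_effect_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BetaMatrix, MethylTruth]:
    """Simulate a samples x sites beta matrix with planted age signal.

    Clock sites: mean beta = m0 + r*sqrt(age), r = +/- clock_slope.
    Pacemaker sites: mean beta = m0 + r*s(age), one shared s(age).
    Null sites: constant mean. All betas get N(0, noise_sd) noise and are
    clipped to [0, 1].
    """
    ages = np.asarray(ages, float)
    if not (0 <= frac_clock <= 1 and 0 <= frac_pacemaker <= 1):
        raise ValidationError("fractions must be in [0,1]")
    if frac_clock + frac_pacemaker > 1:
        raise ValidationError("fractions sum above 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = ages.size
    n_clock = int(round(frac_clock * n_sites))
    n_pace = int(round(frac_pacemaker * n_sites))
    role = np.array(
        ["clock_linear"] * n_clock
        + ["pacemaker_shared"] * n_pace
        + ["null"] * (n_sites - n_clock - n_pace)
    )

    sqrt_age = np.sqrt(ages)
    state = state_curve(ages, curve_a, curve_c)
    rate = np.zeros(n_sites)
    sign = rng.choice((-1.0, 1.0), size=n_sites)
    rate[:n_clock] = sign[:n_clock] * clock_slope
    rate[n_clock : n_clock + n_pace] = sign[n_clock : n_clock + n_pace] * rng.uniform(
        *pacemaker_rate_range, size=n_pace
    )

    # per-site predictor range -> intercepts that keep mean betas inside [0,1]
    pred = np.zeros((n, n_sites))
    pred[:, :n_clock] = sqrt_age[:, None]
    pred[:, n_clock : n_clock + n_pace] = state[:, None]
    effect = pred * rate
    m0 = _safe_intercepts(rng, effect.min(axis=0), effect.max(axis=0))

    mean = m0 + effect
    tissue_off = np.zeros(n_sites)
    sex_off = np.zeros(n_sites)
    if tissue_labels is not None and tissue_effect_sd > 0:
        tissue_off = rng.normal(0.0, tissue_effect_sd, size=n_sites)
        is_biopsy = np.asarray([t == "biopsy" for t in tissue_labels])
        mean = mean + np.outer(is_biopsy, tissue_off)
    if sex_labels is not None and sex_effect_sd > 0:
        sex_off = rng.normal(0.0, sex_effect_sd, size=n_sites)
        is_male = np.asarray([s == "M" for s in sex_labels])
        mean = mean + np.outer(is_male, sex_off)

    betas = mean + rng.normal(0.0, noise_sd, size=mean.shape) if noise_sd > 0 else mean
    betas = np.clip(betas, 0.0, 1.0)
    width = max(3, len(str(n_sites)))
    site_ids = [f"cg{j:0{width}d}" for j in range(n_sites)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    truth = MethylTruth(
        site_ids=site_ids,
        role=role,
        rate=rate,
        intercept=m0,
        state=state,
        ages=ages.copy(),
        noise_sd=noise_sd,
        curve_a=curve_a,
        curve_c=curve_c,
        tissue_offsets=tissue_off,
        sex_offsets=sex_off,
    )
    return BetaMatrix(sample_ids, site_ids, betas), truth


def gen_related_species(
    truth: MethylTruth,
    conserved_frac: float = 0.9,
    shift_sd: float = 0.1,
    ages=None,
    seed: int = 0,
) -> tuple[BetaMatrix, MethylTruth]:
    """Draw a sister-species cohort from perturbed truth.

    Conserved sites keep their (m0, r); the rest get intercept shifts
    ~ N(0, shift_sd). Noise is redrawn at the base noise level and betas
    re-clipped, emulating applying a clock across an evolutionary divergence.
    """
    if not 0 <= conserved_frac <= 1:
        raise ValidationError("conserved_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    ages = truth.ages if ages is None else np.asarray(ages, float)
    n_sites = len(truth.site_ids)
    conserved = rng.random(n_sites) < conserved_frac
    m0 = truth.intercept.copy()
    m0[~conserved] += rng.normal(0.0, shift_sd, size=int((~conserved).sum()))

    n = ages.size
    pred = np.zeros((n, n_sites))
    clock = truth.role == "clock_linear"
    pace = truth.role == "pacemaker_shared"
    pred[:, clock] = np.sqrt(ages)[:, None]
    pred[:, pace] = state_curve(ages, truth.curve_a, truth.curve_c)[:, None]
    mean = m0 + pred * truth.rate
    betas = (
        mean + rng.normal(0.0, truth.noise_sd, size=mean.shape)
        if truth.noise_sd > 0
        else mean.copy()
    )
    betas = np.clip(betas, 0.0, 1.0)
    sample_ids = [f"rs{i:03d}" for i in range(n)]
    new_truth = MethylTruth(
        site_ids=list(truth.site_ids),
        role=truth.role.copy(),
        rate=truth.rate.copy(),
        intercept=m0,
        state=state_curve(ages, truth.curve_a, truth.curve_c),
        ages=ages.copy(),
        noise_sd=truth.noise_sd,
        curve_a=truth.curve_a,
        curve_c=truth.curve_c,
    )
    return BetaMatrix(sample_ids, list(truth.site_ids), betas), new_truth


# ------------------------------------------------------------------ genotypes

def _draw_run_lengths(target_bp: float, rng) -> list[float]:
    """Run lengths in [1.5, 60] Mb summing exactly to target_bp."""
    if target_bp == 0:
        return []
    if target_bp < MIN_ROH_BP:
        raise ValidationError(
            f"target ROH total {target_bp:.0f} bp below the minimum run of "
            f"{MIN_ROH_BP} bp; cannot plant runs"
        )
    lengths = []
    remaining = float(target_bp)
    while remaining > MAX_ROH_BP:
        upper = min(MAX_ROH_BP, remaining - MIN_ROH_BP)
        length = rng.uniform(MIN_ROH_BP, upper)
        lengths.append(length)
        remaining -= length
    lengths.append(remaining)
    return lengths


def gen_genotypes(
    n_ind: int,
    n_snps: int,
    chrom_map: dict[str, int],
    target_froh,
    seed: int = 0,
    contamination: float = 0.0,
    alt_freq_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[GenotypeTable, GenoTruth]:
    """Simulate a biallelic SNP panel with planted runs of homozygosity.

    Outside planted runs genotypes follow Hardy-Weinberg at each site's
    alt frequency; inside runs they are homozygous (alt with probability
    p_l) except for a per-SNP ``contamination`` rate of ordinary draws.
    Planted run lengths sum exactly to target_froh * screened length.
    """
    target_froh = np.asarray(target_froh, float)
    if target_froh.size != n_ind:
        raise ValidationError("target_froh must have one entry per individual")
    if np.any((target_froh < 0) | (target_froh > 0.5)):
        raise ValidationError("target_froh entries must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_map)
    lengths = np.array([chrom_map[c] for c in chroms], float)
    screened = int(lengths.sum())
    individuals = [f"ind{i:03d}" for i in range(n_ind)]

    # SNP positions: allocate per chromosome proportional to length
    alloc = np.maximum(np.round(n_snps * lengths / lengths.sum()).astype(int), 1)
    site_rows = []
    for c, chrom in enumerate(chroms):
        k = int(alloc[c])
        pos = np.sort(rng.choice(int(lengths[c]), size=k, replace=False)) + 1
        for p in pos:
            site_rows.append((chrom, int(p)))
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos"])
    sites["ref"] = "A"
    sites["alt"] = "G"
    n_sites = len(sites)
    p_alt = rng.uniform(*alt_freq_range, size=n_sites)

    planted: dict[str, list[tuple[str, int, int]]] = {}
    for i, ind in enumerate(individuals):
        runs: list[tuple[str, int, int]] = []
        for length in _draw_run_lengths(target_froh[i] * screened, rng):
            length = int(round(length))
            eligible = [c for c in range(len(chroms)) if lengths[c] >= length]
            if not eligible:
                raise ValidationError(
                    f"planted run of {length} bp exceeds every chromosome length"
                )
            placed = False
            for _ in range(1000):
                c = rng.choice(eligible, p=lengths[eligible] / lengths[eligible].sum())
                start = int(rng.integers(0, int(lengths[c]) - length + 1))
                end = start + length
                chrom = chroms[c]
                if all(
                    not (chrom == rc and start < re and rs < end)
                    for rc, rs, re in runs
                ):
                    runs.append((chrom, start, end))
                    placed = True
                    break
            if not placed:
                raise ValidationError("could not place planted runs without overlap")
        planted[ind] = runs

    hw = rng.random((n_ind, n_sites, 2))  # two allele draws per genotype
    dosages = (hw[:, :, 0] < p_alt).astype(np.int8) + (hw[:, :, 1] < p_alt).astype(
        np.int8
    )
    chrom_col = sites["chrom"].to_numpy()
    pos_col = sites["pos"].to_numpy()
    hom_alt = rng.random((n_ind, n_sites)) < p_alt  # allele choice inside runs
    keep_hw = rng.random((n_ind, n_sites)) < contamination
    for i, ind in enumerate(individuals):
        in_run = np.zeros(n_sites, dtype=bool)
        for chrom, start, end in planted[ind]:
            in_run |= (chrom_col == chrom) & (pos_col > start) & (pos_col <= end)
        forced = in_run & ~keep_hw[i]
        dosages[i, forced] = np.where(hom_alt[i, forced], 2, 0)

    table = GenotypeTable(individuals, sites, dosages)
    truth = GenoTruth(
        individuals=individuals,
        planted=planted,
        target_froh={ind: float(target_froh[i]) for i, ind in enumerate(individuals)},
        allele_freq=p_alt,
        screened_length_bp=screened,
    )
    return table, truth


# ----------------------------------------------------------------- phenotypes

def gen_accel_phenotypes(
    ages,
    inbreeding,
    sex,
    beta_interaction: float,
    noise_sd: float,
    seed: int = 0,
    beta_age: float = 0.0,
    beta_inbreeding: float = 0.0,
    beta_sex: float = 0.0,
    intercept: float = 0.0,
    hetero_rate: float = 0.1,
):
    """Age-acceleration phenotypes with a planted age x inbreeding interaction.

    accel_i = b0 + b_sex*sex + b_age*age + b_F*F + b3*age*F + eps_i, with
    eps ~ N(0, sd_i) and sd_i = noise_sd * (1 + hetero_rate * age/10): the
    noise grows by ``hetero_rate`` per decade (default 10%/decade), so the
    robust-SE step downstream has something to be robust to.
    """
    ages = np.asarray(ages, float)
    inbreeding = np.asarray(inbreeding, float)
    sex = np.asarray(sex, float)
    if not (ages.size == inbreeding.size == sex.size):
        raise ValidationError("ages, inbreeding, and sex must have equal length")
    rng = np.random.default_rng(seed)
    sd = noise_sd * (1.0 + hetero_rate * ages / 10.0)
    eps = rng.normal(0.0, 1.0, size=ages.size) * sd if noise_sd > 0 else 0.0
    return (
        intercept
        + beta_sex * sex
        + beta_age * ages
        + beta_inbreeding * inbreeding
        + beta_interaction * ages * inbreeding
        + eps
    )


# ------------------------------------------------------------------ utilities

def gen_sample_sheet(
    ages, tissue_frac_blood: float = 0.8, species: str = "base", seed: int = 0
) -> SampleSheet:
    """Sample sheet with random tissue (blood-heavy) and sex assignments."""
    ages = np.asarray(ages, float)
    rng = np.random.default_rng(seed)
    n = ages.size
    tissue = np.where(rng.random(n) < tissue_frac_blood, "blood", "biopsy")
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"s{i:03d}" for i in range(n)],
                "species": species,
                "tissue": tissue,
                "sex": sex,
                "age": ages,
            }
        )
    )


def gen_annotation(site_ids, island_frac: float = 0.3, seed: int = 0) -> AnnotationTable:
    """Random genomic-context annotation for EWAS summaries."""
    rng = np.random.default_rng(seed)
    classes = rng.choice(TSS_CLASSES, size=len(site_ids))
    island = rng.random(len(site_ids)) < island_frac
    return AnnotationTable(
        pd.DataFrame(
            {"site_id": list(site_ids), "tss_class": classes, "island_flag": island}
        )
    )


def gen_cohort(cfg: SimulateConfig) -> tuple[SampleSheet, BetaMatrix, MethylTruth]:
    """One call producing a coherent cohort (sheet + betas + truth)."""
    ages = gen_ages(cfg.n_samples, cfg.min_age, cfg.max_age, seed=cfg.seed)
    sheet = gen_sample_sheet(ages, seed=cfg.seed + 1)
    beta, truth = gen_methylation(
        ages,
        n_sites=cfg.n_sites,
        frac_clock=cfg.frac_clock,
        frac_pacemaker=cfg.frac_pacemaker,
        noise_sd=cfg.noise_sd,
        tissue_labels=sheet.frame["tissue"].tolist(),
        sex_labels=sheet.frame["sex"].tolist(),
        curve_a=cfg.curve_a,
        curve_c=cfg.curve_c,
        tissue_effect_sd=cfg.tissue_effect_sd,
        sex_effect_sd=cfg.sex_effect_sd,
        seed=cfg.seed + 2,
    )
    return sheet, beta, truth
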