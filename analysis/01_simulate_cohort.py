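"""Simulate the study cohort: methylation betas for a two-tissue cohort and
a genotype panel with planted runs of homozygosity.

Writes results/data/{sample_sheet.csv, betas.csv, genotypes.vcf,
annotation.csv, truth.json}. Genotyped individuals reuse the first blood
sample ids so the acceleration-vs-inbreeding join in a later step has an
explicit key.
"""

import json
from pathlib import Path

import numpy as np

from equusage import io
from equusage.config import SimulateConfig
from equusage.simulate import gen_annotation, gen_cohort, gen_genotypes

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2026

cfg = SimulateConfig(n_samples=96, n_sites=2000, seed=SEED)
sheet, beta, truth = gen_cohort(cfg)
io.write_sample_sheet(sheet, OUT / "sample_sheet.csv")
io.write_beta_matrix(beta, OUT / "betas.csv")
io.write_annotation(gen_annotation(beta.site_ids, seed=SEED + 3), OUT / "annotation.csv")

n_blood = (sheet.frame["tissue"] == "blood").sum()
print(f"cohort: {len(sheet)} samples ({n_blood} blood), {beta.n_sites} sites")
print(f"age range: {sheet.ages.min():.2f}-{sheet.ages.max():.2f} years")

# genotype panel for 70 of the samples, F_ROH spanning the plausible range
chroms = {f"chr{i + 1}": 120_000_000 for i in range(4)}
rng = np.random.default_rng(SEED + 4)
targets = np.round(rng.uniform(0.0, 0.37, 70), 3)
targets[targets * sum(chroms.values()) < 1_500_000] = 0.0
table, geno_truth = gen_genotypes(70, 30_000, chroms, targets, seed=SEED + 5)
genotyped_ids = sheet.sample_ids[:70]
geno_truth.planted = dict(zip(genotyped_ids, geno_truth.planted.values()))
geno_truth.target_froh = dict(zip(genotyped_ids, geno_truth.target_froh.values()))
table.individuals = genotyped_ids
io.write_vcf(table, OUT / "genotypes.vcf")

(OUT / "truth.json").write_text(
    json.dumps(
        {
            "seed": SEED,
            "screened_length_bp": geno_truth.screened_length_bp,
            "target_froh": geno_truth.target_froh,
            "curve": {"a": truth.curve_a, "c": truth.curve_c},
            "noise_sd": truth.noise_sd,
        },
        indent=2,
        sort_keys=True,
    )
)
print(
    f"genotypes: {table.n_individuals} individuals x {table.n_sites} SNPs, "
    f"planted F_ROH 0-{max(targets):.2f}"
)
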