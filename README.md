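# equusage

Epigenetic-aging and inbreeding analyses for wildlife methylation +
reduced-representation sequencing cohorts, written for studies like a
plains-zebra pedigree: small two-tissue cohorts (tens of blood and biopsy
samples), mammalian methylation-array beta values, and genotype panels
deep enough to call runs of homozygosity but far from reference-grade.

The package implements five analysis stages as a reusable library with a
CLI, plus a synthetic-data module that generates cohorts with known truth
so every stage is testable without any external download:

1. **Elastic-net epigenetic clocks** (`equusage.clock`). A clock is a
   sparse linear model √age = β₀ + Σⱼ wⱼ·βⱼ over CpG beta values βⱼ ∈
   [0, 1], fit by cyclic coordinate descent on the objective
   (1/2n)‖y − Xw‖² + λ(α‖w‖₁ + (1−α)/2·‖w‖₂²) with λ chosen by
   cross-validation. Evaluation is leave-one-sample-out with full λ
   re-selection per held-out sample; a trained clock can be applied to a
   related species' profiles.
2. **Epigenetic pacemaker** (`equusage.pacemaker`). The bilinear model
   m_ij = m0ⱼ + rⱼ·s_i + ε assigns every sample a latent epigenetic state
   s_i and every age-correlated site a rate rⱼ and baseline m0ⱼ, fit by
   alternating least squares; a shifted-log trend s = a·ln(age + c) + d
   translates states back to years.
3. **Inbreeding** (`equusage.inbreeding`). GATK-style hard filters on VCF
   INFO fields, the excess-homozygosity estimator
   F̂ = (O_hom − E_hom)/(L − E_hom), PLINK-style sliding-window ROH
   detection, F_ROH = ΣROH/genome screened, plus Mendelian-error and
   imputation-concordance audits.
4. **Age-acceleration models** (`equusage.accel`). Acceleration (the
   residual of predicted on chronological age) regressed on sex, age,
   inbreeding, and age×inbreeding, with Huber-White (HC0/HC1/HC3)
   sandwich standard errors.
5. **EWAS + meta-analysis** (`equusage.ewas`). Per-site Pearson screening
   of methylation against age (t on n−2 df, inverted to signed z),
   Stouffer combination across tissues z_meta = Σw_k z_k/√(Σw_k²), top-k
   selection, and TSS-class/CpG-island summaries.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (96 samples, 2000 CpGs, 70 genotyped individuals with planted
runs of homozygosity) and write tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_train_clocks.py
...
python analysis/06_run_ewas.py
```

Representative output (fixed seed inside the scripts):

```
blood clock: 88 CpGs, LOO r=0.997, MAE=0.17 years
combined clock: 93 CpGs, LOO r=0.996, MAE=0.18 years
EPM: 350 sites, state-age r=0.928, translated MAE=0.02 years
160 ROH segments; F_ROH range 0.000-0.361; mean |F_ROH - planted| = 0.0012; r(F, F_ROH) = 0.998
planted interaction (beta3 = 1.5 on EPM accel):
  EPM~F: estimate=+1.395, robust p=0.0000
```

Reading: the clock predicts chronological age from held-out methylation
with a median absolute error of about 0.17 years on clean synthetic data;
ROH detection recovers the planted genomic inbreeding almost exactly, and
the two inbreeding estimators agree (r = 0.998); the interaction test
recovers a planted age×F effect on pacemaker acceleration while leaving
the clock-acceleration models null.

The same stages are exposed as a CLI:

```sh
equusage simulate --seed 7 --out data/
equusage train-clock --betas data/betas.csv --sheet data/sample_sheet.csv --out clock/
equusage roh --vcf data/genotypes.vcf --screened-length 480000000 --out roh/
```

## Layout

```
src/equusage/     library: types, io, config, simulate, clock, pacemaker,
                  inbreeding, accel, ewas, cli
analysis/         numbered narrative drivers writing results/ tables
tests/            pytest suite (unit, property, and study-scale checks)
scripts/          acceptance script
docs/methods.md   model assumptions, parameter defaults, design choices
```
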