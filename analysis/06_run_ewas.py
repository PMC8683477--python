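"""Epigenome-wide association of methylation with age, per tissue, with
cross-tissue Stouffer meta-analysis and genomic-context summaries.

Writes results/ewas/{ewas_results.csv, significant_counts.csv,
top_sites.csv, tss_classes.csv} and prints the counts that the study-style
figures would display.
"""

from pathlib import Path

import pandas as pd

from equusage import io
from equusage.config import EWASConfig
from equusage.ewas import annotate_summary, ewas_analysis, significant_sites, top_k_by_z

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "ewas"
OUT.mkdir(parents=True, exist_ok=True)

beta = io.read_beta_matrix(ROOT / "data" / "betas.csv")
sheet = io.read_sample_sheet(ROOT / "data" / "sample_sheet.csv")
annotation = io.read_annotation(ROOT / "data" / "annotation.csv")

cfg = EWASConfig(top_k=100)  # 2000 simulated sites; keep the top set selective
results = ewas_analysis(beta, sheet, cfg)
results.to_csv(OUT / "ewas_results.csv", index=False)

summary = significant_sites(results, cfg.alpha)
summary.per_tissue.to_csv(OUT / "significant_counts.csv", index=False)
print(f"significant sites at p < {cfg.alpha:g}:")
print(summary.per_tissue.to_string(index=False))
print(f"cross-tissue overlap: {summary.overlap}")
print(summary.sectors["sector"].value_counts().to_string())

top = top_k_by_z(results, cfg.top_k, "meta_z")
pd.Series(top, name="site_id").to_csv(OUT / "top_sites.csv", index=False)
sel = results[results["site_id"].isin(top)][["site_id", "meta_z"]]
asum = annotate_summary(sel, annotation, "meta_z")
asum.tss_counts.to_csv(OUT / "tss_classes.csv")
print(
    f"top {len(top)} sites; island vs non-island z: rank-sum p = "
    f"{asum.island_p:.3g}, median difference = {asum.island_median_diff:.3f}"
)
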