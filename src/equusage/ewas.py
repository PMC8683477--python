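"""Correlation-based EWAS of age with cross-tissue Stouffer meta-analysis.

Each CpG site is screened by the Pearson correlation of its beta values
with chronological age; the correlation's t statistic gives a two-sided p,
which is inverted to a signed z-score. Per-tissue z-scores are combined
with Stouffer's method (weights sqrt(n) by default), and the paper-style
summaries — significance counts by direction, tissue overlap and sector
classes, top-k selection, TSS-class/island breakdowns — operate on the
resulting table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import EWASConfig
from .types import AnnotationTable, BetaMatrix, SampleSheet, ValidationError

log = logging.getLogger("equusage")


def site_age_screen(beta: BetaMatrix, ages, z_cap: float = 40.0) -> pd.DataFrame:
    """Per-site (r, t, p, z) for the correlation of methylation with age.

    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df, two-sided; z = sign(r) *
    Phi^-1(1 - p/2), capped at ``z_cap`` (flagged) so perfectly correlated
    sites stay ordered and finite. Zero-variance sites get NaN statistics.
    """
    ages = np.asarray(ages, float)
    n = ages.size
    if n < 4:
        raise ValidationError("need n >= 4 for the age screen")
    vals = beta.values
    ac = ages - ages.mean()
    vc = vals - vals.mean(axis=0)
    ss_site = (vc**2).sum(axis=0)
    denom = np.sqrt(ss_site) * np.sqrt((ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, vc.T @ ac / denom, np.nan)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.sign(r) * stats.norm.isf(p / 2)
        z = np.where(p <= 1e-300, np.sign(r) * np.inf, z)  # p underflow
    capped = np.abs(z) > z_cap
    capped &= ~np.isnan(z)
    z = np.where(capped, np.sign(z) * z_cap, z)
    p = np.where(p <= 1e-300, 1e-300, p)  # keep reported p in (0, 1]
    n_const = int(np.isnan(r).sum())
    if n_const:
        log.info("age screen: %d zero-variance site(s) skipped", n_const)
    return pd.DataFrame(
        {
            "site_id": beta.site_ids,
            "n": n,
            "r": r,
            "t": t,
            "p": p,
            "z": z,
            "z_capped": capped,
        }
    )


def stouffer_meta(z_rows, weights=None):
    """Stouffer combination z_meta = sum(w_k z_k) / sqrt(sum(w_k^2)).

    ``z_rows``: array-like (n_studies, n_sites) of signed z-scores;
    ``weights`` one per study (default equal). Sites with any missing study
    z get a missing meta value. Returns (z_meta, p_meta) with p two-sided
    from the normal.
    """
    Z = np.atleast_2d(np.asarray(z_rows, float))
    k = Z.shape[0]
    w = np.ones(k) if weights is None else np.asarray(weights, float)
    if w.size != k:
        raise ValidationError("one weight per study required")
    z_meta = (w @ Z) / np.sqrt((w**2).sum())
    z_meta = np.where(np.isnan(Z).any(axis=0), np.nan, z_meta)
    p_meta = 2 * stats.norm.sf(np.abs(z_meta))
    return z_meta, p_meta


def ewas_analysis(
    beta: BetaMatrix, sheet: SampleSheet, config: EWASConfig | None = None
) -> pd.DataFrame:
    """Per-tissue screens plus the cross-tissue meta-analysis, one row per site.

    Columns: per tissue ``{tissue}_{n,r,t,p,z}``, then meta_z / meta_p for
    sites scored in at least two tissues (Stouffer weights sqrt(n_k) when
    the config says weighted).
    """
    cfg = config or EWASConfig()
    out = pd.DataFrame({"site_id": beta.site_ids})
    z_rows, weights = [], []
    for tissue in sorted(sheet.frame["tissue"].unique()):
        ids = sheet.frame.loc[sheet.frame["tissue"] == tissue, "sample_id"]
        ages = sheet.frame.loc[sheet.frame["tissue"] == tissue, "age"].to_numpy(float)
        if len(ids) < 4:
            log.info("tissue %s has <4 samples; skipped", tissue)
            continue
        screen = site_age_screen(beta.subset_samples(ids.tolist()), ages, cfg.z_cap)
        for col in ("n", "r", "t", "p", "z"):
            out[f"{tissue}_{col}"] = screen[col].to_numpy()
        z_rows.append(screen["z"].to_numpy())
        weights.append(np.sqrt(len(ids)) if cfg.weighted else 1.0)
    if len(z_rows) >= 2:
        out["meta_z"], out["meta_p"] = stouffer_meta(np.vstack(z_rows), weights)
    return out


# ------------------------------------------------------------------ summaries

@dataclass
class SignificanceSummary:
    per_tissue: pd.DataFrame  # tissue, n_significant, n_positive, n_negative
    overlap: int  # sites significant in both tissues
    sectors: pd.DataFrame  # site_id, sector for two-tissue comparisons


def significant_sites(
    results: pd.DataFrame, alpha: float = 1e-4
) -> SignificanceSummary:
    """Counts of age-associated sites at p < alpha, split by direction.

    For two-tissue tables, also the cross-tissue overlap and sector
    classes: 'shared' (p < alpha in both, same sign), 'divergent'
    (p < alpha in both, opposite signs), '{tissue}_specific' (p < alpha in
    one, p > 0.05 in the other).
    """
    tissues = sorted(c[: -len("_p")] for c in results.columns if c.endswith("_p") and c != "meta_p")
    rows = []
    for tissue in tissues:
        p = results[f"{tissue}_p"]
        r = results[f"{tissue}_r"]
        sig = p < alpha
        rows.append(
            {
                "tissue": tissue,
                "n_significant": int(sig.sum()),
                "n_positive": int((sig & (r > 0)).sum()),
                "n_negative": int((sig & (r < 0)).sum()),
            }
        )
    per_tissue = pd.DataFrame(rows)
    overlap = 0
    sectors = pd.DataFrame(columns=["site_id", "sector"])
    if len(tissues) == 2:
        t1, t2 = tissues
        p1, p2 = results[f"{t1}_p"], results[f"{t2}_p"]
        z1, z2 = results[f"{t1}_z"], results[f"{t2}_z"]
        sig1, sig2 = p1 < alpha, p2 < alpha
        overlap = int((sig1 & sig2).sum())
        sector = pd.Series("none", index=results.index)
        sector[sig1 & sig2 & (np.sign(z1) == np.sign(z2))] = "shared"
        sector[sig1 & sig2 & (np.sign(z1) != np.sign(z2))] = "divergent"
        sector[sig1 & ~sig2 & (p2 > 0.05)] = f"{t1}_specific"
        sector[sig2 & ~sig1 & (p1 > 0.05)] = f"{t2}_specific"
        sectors = pd.DataFrame({"site_id": results["site_id"], "sector": sector})
    return SignificanceSummary(per_tissue=per_tissue, overlap=overlap, sectors=sectors)


def top_k_by_z(results: pd.DataFrame, k: int = 500, z_col: str = "meta_z") -> list[str]:
    """The k most-positive plus k most-negative z sites.

    Ties break lexicographically on site_id for determinism; if fewer than
    2k scored sites exist, all are returned (logged).
    """
    scored = results.dropna(subset=[z_col])
    if len(scored) < 2 * k:
        log.info("top_k_by_z: only %d scored sites for 2k=%d; taking all", len(scored), 2 * k)
        warnings.warn(f"fewer than {2 * k} scored sites; returning all", stacklevel=2)
        ordered = scored.sort_values([z_col, "site_id"], ascending=[False, True])
        return ordered["site_id"].tolist()
    pos = scored.sort_values([z_col, "site_id"], ascending=[False, True]).head(k)
    neg = scored.sort_values([z_col, "site_id"], ascending=[True, True]).head(k)
    return pos["site_id"].tolist() + neg["site_id"].tolist()


@dataclass
class AnnotationSummary:
    tss_counts: pd.DataFrame  # tss_class x (n_positive, n_negative)
    island_statistic: float
    island_p: float
    island_median_diff: float


def annotate_summary(
    selected: pd.DataFrame, annotation: AnnotationTable, z_col: str = "meta_z"
) -> AnnotationSummary:
    """Genomic-context breakdown of the selected age-related CpGs.

    ``selected`` needs site_id and a z column. Counts selected CpGs per
    TSS-distance class split by z sign, and compares island vs non-island
    z by a two-sided Wilcoxon rank-sum test.
    """
    if selected.empty:
        raise ValidationError("empty selection")
    ann = annotation.frame.set_index("site_id")
    covered = selected["site_id"].isin(ann.index)
    if covered.mean() < 0.95:
        warnings.warn(
            f"annotation covers only {covered.mean():.1%} of selected sites",
            stacklevel=2,
        )
    merged = selected[covered].merge(
        annotation.frame, on="site_id", how="left", validate="one_to_one"
    )
    merged["direction"] = np.where(merged[z_col] > 0, "n_positive", "n_negative")
    tss = (
        merged.pivot_table(
            index="tss_class", columns="direction", values="site_id", aggfunc="count"
        )
        .reindex(columns=["n_positive", "n_negative"])
        .fillna(0)
        .astype(int)
    )
    z_island = merged.loc[merged["island_flag"], z_col].to_numpy(float)
    z_other = merged.loc[~merged["island_flag"], z_col].to_numpy(float)
    if z_island.size == 0 or z_other.size == 0:
        stat, p, med = np.nan, np.nan, np.nan
    else:
        res = stats.ranksums(z_island, z_other)
        stat, p = float(res.statistic), float(res.pvalue)
        med = float(np.median(z_island) - np.median(z_other))
    return AnnotationSummary(
        tss_counts=tss, island_statistic=stat, island_p=p, island_median_diff=med
    )
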