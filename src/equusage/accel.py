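"""Epigenetic age acceleration and its association with inbreeding.

Acceleration is the discrepancy between epigenetically predicted and
chronological age; the default definition is the residual of predicted age
regressed on chronological age, which is exactly uncorrelated with
chronological age by construction. The association models are OLS of
acceleration on sex, age, inbreeding, and the age x inbreeding interaction,
with Huber-White (sandwich) heteroskedasticity-robust standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import AccelConfig
from .types import ValidationError

log = logging.getLogger("equusage")

ACCEL_METHODS = ("difference", "residual", "residual_methods_literal")


def compute_accel(predicted, chronological, method: str = "residual") -> np.ndarray:
    """Age acceleration per sample, in years.

    'difference': predicted - chronological. 'residual' (default): residual
    of OLS of predicted on chronological. 'residual_methods_literal': the
    reversed regression (chronological on predicted), sign-flipped so that
    positive still means epigenetically older than expected.
    """
    predicted = np.asarray(predicted, float)
    chronological = np.asarray(chronological, float)
    if predicted.shape != chronological.shape:
        raise ValidationError("predicted/chronological length mismatch")
    if method == "difference":
        return predicted - chronological
    if method not in ACCEL_METHODS:
        raise ValidationError(f"unknown accel method {method!r}")
    if predicted.size < 3:
        raise ValidationError("need n >= 3 for the residual method")
    if method == "residual":
        x, y = chronological, predicted
    else:
        x, y = predicted, chronological
    if np.std(x) == 0:
        raise ValidationError("zero-variance regressor in residual method")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return resid if method == "residual" else -resid


def accel_table(
    sample_ids, chronological, predicted, method: str = "residual"
) -> pd.DataFrame:
    """Tidy per-sample acceleration table (both definitions included)."""
    frame = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "age": np.asarray(chronological, float),
            "predicted_age": np.asarray(predicted, float),
        }
    )
    frame["accel_diff"] = compute_accel(predicted, chronological, "difference")
    frame["accel_resid"] = compute_accel(predicted, chronological, "residual")
    frame["accel"] = compute_accel(predicted, chronological, method)
    return frame


# ------------------------------------------------------------------------ OLS

@dataclass
class RegressionFit:
    names: list[str]
    params: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    vcov_flavor: str
    residuals: np.ndarray
    df_resid: int
    X: np.ndarray
    y: np.ndarray

    def summary_frame(self, model: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": model,
                "term": self.names,
                "estimate": self.params,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "vcov": self.vcov_flavor,
            }
        )


def _tests(params, vcov, df_resid):
    se = np.sqrt(np.diag(vcov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = params / se
    p = 2 * stats.t.sf(np.abs(t), df_resid)
    return se, t, p


def ols_fit(y, X, names=None) -> RegressionFit:
    """OLS via QR decomposition, with classical sigma^2 (X'X)^-1 covariance.

    Raises on rank deficiency, naming the collinear columns (those whose
    R-diagonal is numerically zero).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k:
        raise ValidationError(f"n={n} too small for {k} coefficients")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = np.finfo(float).eps * max(n, k) * (diag.max() if diag.size else 1.0)
    bad = diag <= tol
    if bad.any():
        cols = [names[j] for j in np.nonzero(bad)[0]]
        raise ValidationError(f"rank-deficient design; collinear column(s): {cols}")
    params = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ params
    df_resid = n - k
    sigma2 = float(resid @ resid) / df_resid
    R_inv = np.linalg.inv(R)
    xtx_inv = R_inv @ R_inv.T
    vcov = sigma2 * xtx_inv
    se, t, p = _tests(params, vcov, df_resid)
    return RegressionFit(
        names=list(names),
        params=params,
        vcov=vcov,
        se=se,
        t=t,
        p=p,
        vcov_flavor="classical",
        residuals=resid,
        df_resid=df_resid,
        X=X,
        y=y,
    )


def robust_vcov(fit: RegressionFit, flavor: str = "HC3") -> RegressionFit:
    """Huber-White sandwich covariance (X'X)^-1 X' diag(w) X (X'X)^-1.

    Weights: HC0 w=e^2; HC1 w=e^2 * n/(n-k); HC3 w=e^2/(1-h)^2 with h the
    leverage. Returns a new fit with robust SEs and t/p on n-k df.
    """
    if flavor not in ("HC0", "HC1", "HC3"):
        raise ValidationError(f"unknown HC flavor {flavor!r}")
    X, e = fit.X, fit.residuals
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    w = e**2
    if flavor == "HC1":
        w = w * n / (n - k)
    elif flavor == "HC3":
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        if np.any(h >= 1 - 1e-12):
            raise ValidationError("leverage of 1 encountered; HC3 undefined")
        w = w / (1 - h) ** 2
    meat = (X * w[:, None]).T @ X
    vcov = xtx_inv @ meat @ xtx_inv
    se, t, p = _tests(fit.params, vcov, fit.df_resid)
    return replace(fit, vcov=vcov, se=se, t=t, p=p, vcov_flavor=flavor)


# ------------------------------------------------------------ the 2x2 analysis

MODEL_TERMS = ("intercept", "sex", "age", "inbreeding", "age_x_inbreeding")


def _design(frame: pd.DataFrame, inbreeding_col: str) -> np.ndarray:
    sex = frame["sex"].map({"F": 0.0, "M": 1.0, 0: 0.0, 1: 1.0, 0.0: 0.0, 1.0: 1.0})
    if sex.isna().any():
        raise ValidationError("sex must be F/M (or 0/1) in the association models")
    age = frame["age"].to_numpy(float)
    inb = frame[inbreeding_col].to_numpy(float)
    return np.column_stack(
        [np.ones(len(frame)), sex.to_numpy(float), age, inb, age * inb]
    )


def run_inbreeding_analysis(
    samples: pd.DataFrame, config: AccelConfig | None = None
) -> tuple[dict[str, RegressionFit], pd.DataFrame]:
    """The 2x2 grid of models: {EC, EPM} acceleration x {F, F_ROH}.

    ``samples`` needs columns sample_id, age, sex, accel_ec, accel_epm,
    f_hat, f_roh. Rows with any missing variable are dropped (count
    logged), as are explicitly excluded ids. Each model is OLS of
    acceleration on intercept + sex + age + inbreeding + age x inbreeding
    with robust standard errors.
    """
    cfg = config or AccelConfig()
    needed = ["sample_id", "age", "sex", "accel_ec", "accel_epm", "f_hat", "f_roh"]
    missing_cols = [c for c in needed if c not in samples.columns]
    if missing_cols:
        raise ValidationError(f"samples table missing columns: {missing_cols}")
    frame = samples[~samples["sample_id"].isin(set(cfg.exclude_ids))]
    before = len(frame)
    frame = frame.dropna(subset=needed)
    if before - len(frame):
        log.info("dropped %d samples with missing variables", before - len(frame))
    if len(frame) < 10:
        raise ValidationError(f"refusing to fit on {len(frame)} joined samples (<10)")
    fits: dict[str, RegressionFit] = {}
    tidy = []
    for accel_col, accel_name in (("accel_ec", "EC"), ("accel_epm", "EPM")):
        for inb_col, inb_name in (("f_hat", "F"), ("f_roh", "F_ROH")):
            X = _design(frame, inb_col)
            fit = ols_fit(frame[accel_col].to_numpy(float), X, list(MODEL_TERMS))
            fit = robust_vcov(fit, cfg.hc_flavor)
            key = f"{accel_name}~{inb_name}"
            fits[key] = fit
            tidy.append(fit.summary_frame(model=key))
    return fits, pd.concat(tidy, ignore_index=True)
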