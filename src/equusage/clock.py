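"""Elastic-net epigenetic clocks on transformed chronological age.

A clock is a sparse linear model from CpG beta values to sqrt-transformed
age, trained with an L1/L2 penalty whose strength is chosen by
cross-validation; predictions are squared back to years. The same trained
model can be applied to methylation profiles of a related species
(cross-species transfer), with missing model sites handled by policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._cd import cd_path, cd_solve, kkt_residual
from .config import ClockConfig
from .types import BetaMatrix, SampleSheet, ValidationError

log = logging.getLogger("equusage")


# ------------------------------------------------------------- age transform

def transform_age(age, mode: str = "sqrt", offset: float = 0.0):
    """Map age in years to the model's response scale (sqrt(age+offset))."""
    age = np.asarray(age, dtype=float)
    if mode == "identity":
        return age + 0.0
    if mode != "sqrt":
        raise ValidationError(f"unknown transform mode {mode!r}")
    shifted = age + offset
    if np.any(shifted < 0):
        raise ValidationError("age + offset < 0 under sqrt transform")
    return np.sqrt(shifted)


def inverse_transform_age(t, mode: str = "sqrt", offset: float = 0.0):
    """Inverse of :func:`transform_age`; negative sqrt-scale predictions are
    clamped to 0 years. Returns (ages_years, clamped_mask)."""
    t = np.asarray(t, dtype=float)
    if mode == "identity":
        years = t - 0.0
        clamped = np.zeros_like(years, dtype=bool)
        return years, clamped
    clamped = t < 0
    years = np.where(clamped, 0.0, t) ** 2 - offset
    years = np.where(clamped, 0.0, np.maximum(years, 0.0))
    return years, clamped


# ---------------------------------------------------------------- elastic net

@dataclass
class ElasticNetFit:
    intercept: float
    coef: np.ndarray
    alpha: float
    lam: float
    n_iter: int
    kkt: float
    objective_trace: np.ndarray | None = None
    excluded: np.ndarray | None = None  # constant columns dropped pre-fit

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coef


def _prepare(X, y, standardize, fit_intercept):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in elastic-net input")
    n = X.shape[0]
    x_mean = X.mean(axis=0) if fit_intercept else np.zeros(X.shape[1])
    y_mean = float(y.mean()) if fit_intercept else 0.0
    Xc = X - x_mean
    sd = np.sqrt(np.einsum("ij,ij->j", Xc, Xc) / n)
    constant = sd == 0
    if standardize:
        scale = np.where(constant, 1.0, sd)
        Xs = Xc / scale
    else:
        scale = np.ones(X.shape[1])
        Xs = Xc
    Xs = np.asfortranarray(Xs)
    cnorm = np.einsum("ij,ij->j", Xs, Xs) / n
    cnorm[constant] = 0.0  # excluded from updates
    return Xs, y - y_mean, x_mean, y_mean, scale, cnorm, constant


def fit_elastic_net(
    X,
    y,
    alpha: float,
    lam: float,
    *,
    standardize: bool = True,
    fit_intercept: bool = True,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    record_objective: bool = False,
) -> ElasticNetFit:
    """Fit one elastic-net problem by cyclic coordinate descent.

    Objective: (1/2n)*RSS + lam*(alpha*||w||_1 + (1-alpha)/2*||w||_2^2),
    with predictors standardized internally by default and weights
    back-transformed to the original scale. Convergence: max coefficient
    change per sweep < ``tol``; the returned ``kkt`` field is the residual
    of the stationarity conditions on the solver's scale.
    """
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must be in [0,1]")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    Xs, yc, x_mean, y_mean, scale, cnorm, constant = _prepare(
        X, y, standardize, fit_intercept
    )
    n, p = Xs.shape
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-variance column(s) excluded from fit",
            stacklevel=2,
        )
    w = np.zeros(p)
    trace = np.full(max_iter, np.nan) if record_objective else np.empty(0)
    n_iter = cd_solve(Xs, yc, float(alpha), float(lam), w, cnorm, tol, max_iter, trace)
    kkt = kkt_residual(Xs, yc, w, alpha, lam, cnorm=cnorm)
    coef = w / scale
    intercept = y_mean - float(coef @ x_mean)
    return ElasticNetFit(
        intercept=intercept,
        coef=coef,
        alpha=alpha,
        lam=lam,
        n_iter=int(n_iter),
        kkt=kkt,
        objective_trace=trace[~np.isnan(trace)] if record_objective else None,
        excluded=constant,
    )


def lambda_path(
    X, y, alpha: float, n_lambdas: int = 100, lambda_min_ratio: float = 1e-3
) -> np.ndarray:
    """Decreasing log-spaced lambda grid from lambda_max (all-zero solution)."""
    Xs, yc, *_ = _prepare(X, y, standardize=True, fit_intercept=True)
    n = Xs.shape[0]
    # below alpha ~ 0 the all-zero lambda is unbounded; use glmnet's 1e-3 floor
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas
    )


@dataclass
class LambdaSelection:
    lam: float
    path: np.ndarray
    cv_mse: np.ndarray
    cv_se: np.ndarray | None = None


def _cv_folds(n: int, folds, seed: int) -> list[np.ndarray]:
    if folds == "loo":
        return [np.array([i]) for i in range(n)]
    k = int(folds)
    if k < 2:
        raise ValidationError("cv_folds must be 'loo' or an int >= 2")
    if n < k:
        raise ValidationError(f"n={n} smaller than {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def select_lambda(
    X,
    y,
    alpha: float,
    folds="loo",
    *,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-5,
    max_iter: int = 20_000,
    seed: int = 0,
    rule: str = "1se",
) -> LambdaSelection:
    """Pick lambda by cross-validated MSE over a warm-started path.

    Ties on the CV curve break toward the larger lambda (sparser model).
    The default ``rule='1se'`` treats every lambda whose CV MSE is within
    one standard error of the minimum as tied with it and takes the
    largest — the resolution at which the CV estimate can distinguish
    curve points. ``rule='min'`` takes the exact minimizer, breaking exact
    ties toward the larger lambda (first minimum on the descending path).
    """
    if rule not in ("min", "1se"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < (2 if folds == "loo" else int(folds)):
        raise ValidationError("too few samples for the requested folds")
    lams = lambda_path(X, y, alpha, n_lambdas, lambda_min_ratio)
    all_sq = np.zeros((n, lams.size))
    for test_idx in _cv_folds(n, folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xs, yc, x_mean, y_mean, scale, cnorm, _ = _prepare(
            X[mask], y[mask], standardize=True, fit_intercept=True
        )
        W = cd_path(Xs, yc, float(alpha), lams, cnorm, tol, max_iter)
        Xte = (X[test_idx] - x_mean) / scale
        pred = y_mean + Xte @ W.T  # (n_test, n_lambda)
        all_sq[test_idx] = (y[test_idx][:, None] - pred) ** 2
    cv_mse = all_sq.mean(axis=0)
    cv_se = all_sq.std(axis=0, ddof=1) / np.sqrt(n)
    best = int(np.argmin(cv_mse))
    if rule == "1se":
        within = np.nonzero(cv_mse <= cv_mse[best] + cv_se[best])[0]
        best = int(within[0])  # path is descending: first index = largest lambda
    return LambdaSelection(lam=float(lams[best]), path=lams, cv_mse=cv_mse, cv_se=cv_se)


# -------------------------------------------------------------------- clocks

@dataclass
class ClockModel:
    """Portable elastic-net clock: sparse site weights on transformed age."""

    transform: str
    offset: float
    intercept: float
    coefficients: dict[str, float]
    alpha: float
    lam: float
    n_train: int | None = None
    tissue: str | None = None

    @property
    def n_sites(self) -> int:
        return len(self.coefficients)


@dataclass
class ClockPredictions:
    sample_ids: list[str]
    ages: np.ndarray  # years
    transformed: np.ndarray
    clamped: np.ndarray
    n_missing_sites: np.ndarray


@dataclass
class ClockEvaluation:
    pearson_r: float | None
    mae: float  # median absolute error, years
    predictions: np.ndarray
    mae_below_split: float | None = None
    mae_at_or_above_split: float | None = None
    age_split: float | None = None


def _training_arrays(beta: BetaMatrix, sheet: SampleSheet, tissue: str | None):
    missing = set(sheet.sample_ids) - set(beta.sample_ids)
    if missing:
        raise ValidationError(f"samples absent from beta matrix: {sorted(missing)}")
    frame = sheet.frame
    if tissue is not None:
        frame = frame[frame["tissue"] == tissue]
        if frame.empty:
            raise ValidationError(f"no samples after filter tissue={tissue!r}")
    ids = frame["sample_id"].tolist()
    sub, n_dropped = beta.subset_samples(ids).drop_missing_sites()
    if n_dropped:
        log.info("dropped %d sites with missing betas before fitting", n_dropped)
    return sub, ids, frame["age"].to_numpy(float)


def train_clock(
    beta: BetaMatrix, sheet: SampleSheet, config: ClockConfig | None = None
) -> ClockModel:
    """Train a clock on the full (tissue-filtered) cohort.

    Lambda is chosen by cross-validated MSE, then the final model is refit
    on all training samples at that lambda; the sparse nonzero-site map is
    what gets serialized.
    """
    cfg = config or ClockConfig()
    sub, ids, ages = _training_arrays(beta, sheet, cfg.tissue)
    if len(ids) < 10:
        raise ValidationError(
            f"refusing to train a clock on {len(ids)} samples (<10; underdetermined)"
        )
    if len(np.unique(sub.values, axis=0)) < len(ids):
        warnings.warn("duplicate methylation profiles in training set", stacklevel=2)
    y = transform_age(ages, cfg.transform, cfg.offset)
    sel = select_lambda(
        sub.values,
        y,
        cfg.alpha,
        folds=cfg.cv_folds,
        n_lambdas=cfg.n_lambdas,
        lambda_min_ratio=cfg.lambda_min_ratio,
        tol=cfg.cv_tol,
        seed=cfg.seed,
        rule=cfg.lambda_rule,
    )
    fit = fit_elastic_net(
        sub.values, y, cfg.alpha, sel.lam, tol=cfg.tol, max_iter=cfg.max_iter
    )
    nz = np.nonzero(fit.coef)[0]
    coefficients = {sub.site_ids[j]: float(fit.coef[j]) for j in nz}
    log.info("trained clock: lambda=%.4g, %d nonzero sites", sel.lam, len(nz))
    return ClockModel(
        transform=cfg.transform,
        offset=cfg.offset,
        intercept=float(fit.intercept),
        coefficients=coefficients,
        alpha=cfg.alpha,
        lam=sel.lam,
        n_train=len(ids),
        tissue=cfg.tissue,
    )


def loo_predict(
    beta: BetaMatrix, sheet: SampleSheet, config: ClockConfig | None = None
) -> ClockPredictions:
    """Leave-one-sample-out age predictions in years.

    For every sample the whole pipeline — lambda selection and final fit —
    is re-run without that sample, so each prediction is out-of-sample with
    no leakage through the penalty choice.
    """
    cfg = config or ClockConfig()
    sub, ids, ages = _training_arrays(beta, sheet, cfg.tissue)
    n = len(ids)
    if n < 3:
        raise ValidationError("need at least 3 samples for leave-one-out evaluation")
    y = transform_age(ages, cfg.transform, cfg.offset)
    X = sub.values
    pred_t = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sel = select_lambda(
            X[mask],
            y[mask],
            cfg.alpha,
            folds=cfg.cv_folds,
            n_lambdas=cfg.n_lambdas,
            lambda_min_ratio=cfg.lambda_min_ratio,
            tol=cfg.cv_tol,
            seed=cfg.seed,
            rule=cfg.lambda_rule,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_elastic_net(
                X[mask], y[mask], cfg.alpha, sel.lam, tol=cfg.tol, max_iter=cfg.max_iter
            )
        pred_t[i] = fit.predict(X[i : i + 1])[0]
    years, clamped = inverse_transform_age(pred_t, cfg.transform, cfg.offset)
    return ClockPredictions(
        sample_ids=ids,
        ages=years,
        transformed=pred_t,
        clamped=clamped,
        n_missing_sites=np.zeros(n, dtype=int),
    )


def apply_clock(
    model: ClockModel, beta: BetaMatrix, missing_policy: str = "error"
) -> ClockPredictions:
    """Apply a trained clock to (possibly cross-species) methylation data.

    ``missing_policy='zero_contribution'`` lets model sites absent from the
    input contribute nothing (their weight is skipped); 'error' refuses and
    lists the absent sites.
    """
    if missing_policy not in ("error", "zero_contribution"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    sites = list(model.coefficients)
    present = [s for s in sites if s in set(beta.site_ids)]
    absent = [s for s in sites if s not in set(beta.site_ids)]
    if absent and missing_policy == "error":
        raise ValidationError(f"model sites absent from input: {absent}")
    n = beta.n_samples
    pred_t = np.full(n, model.intercept, dtype=float)
    n_missing = np.full(n, len(absent), dtype=int)
    if present:
        sub = beta.subset_sites(present)
        weights = np.array([model.coefficients[s] for s in present])
        vals = sub.values.copy()
        site_missing = np.isnan(vals)
        vals[site_missing] = 0.0  # zero contribution for missing entries
        n_missing = n_missing + site_missing.sum(axis=1).astype(int)
        if site_missing.any() and missing_policy == "error":
            raise ValidationError("missing beta values at model sites")
        pred_t += vals @ weights
    years, clamped = inverse_transform_age(pred_t, model.transform, model.offset)
    return ClockPredictions(
        sample_ids=list(beta.sample_ids),
        ages=years,
        transformed=pred_t,
        clamped=clamped,
        n_missing_sites=n_missing,
    )


def evaluate_predictions(
    pred, true, age_split: float | None = None
) -> ClockEvaluation:
    """Pearson r and median absolute error (years), optionally stratified
    at a cut age (MAE for true age < split and >= split)."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValidationError("pred/true must be equal-length with n >= 2")
    if np.std(pred) == 0 or np.std(true) == 0:
        r = None
    else:
        r = float(np.corrcoef(pred, true)[0, 1])
    err = np.abs(pred - true)
    mae = float(np.median(err))
    below = above = None
    if age_split is not None:
        young = true < age_split
        below = float(np.median(err[young])) if young.any() else None
        above = float(np.median(err[~young])) if (~young).any() else None
    return ClockEvaluation(
        pearson_r=r,
        mae=mae,
        predictions=pred,
        mae_below_split=below,
        mae_at_or_above_split=above,
        age_split=age_split,
    )
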