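"""Epigenetic pacemaker (EPM): latent epigenetic states by alternating
least squares.

Model: m_ij = m0_j + r_j * s_i + eps_ij, where site j has rate r_j and
baseline m0_j and sample i has a latent epigenetic state s_i. Fitting
alternates (a) per-site simple regression of betas on the current states
and (b) the per-sample state update s_i = sum_j r_j (beta_ij - m0_j) /
sum_j r_j^2; each half-step minimizes the total squared error given the
other block, so the error trace is non-increasing. States are anchored by
initializing at chronological age and are identified only up to an affine
gauge; a shifted-log trend curve s = a*ln(age + c) + d translates states
back to years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import EPMConfig
from .types import BetaMatrix, ValidationError


def select_sites(beta: BetaMatrix, ages, r_threshold: float) -> list[str]:
    """Sites whose beta values correlate with age at |Pearson r| >= threshold.

    Zero-variance sites are excluded (their correlation is undefined).
    """
    if not 0 < r_threshold <= 1:
        raise ValidationError("r_threshold must be in (0,1]")
    ages = np.asarray(ages, float)
    if ages.size < 3:
        raise ValidationError("need at least 3 samples to screen sites")
    vals = beta.values
    ac = ages - ages.mean()
    vc = vals - vals.mean(axis=0)
    denom = np.sqrt((vc**2).sum(axis=0)) * np.sqrt((ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, vc.T @ ac / denom, np.nan)
    keep = np.abs(r) >= r_threshold
    keep &= ~np.isnan(r)
    return [s for s, k in zip(beta.site_ids, keep) if k]


@dataclass
class EPMModel:
    site_ids: list[str]
    sample_ids: list[str]
    rates: np.ndarray  # beta units per state unit
    intercepts: np.ndarray  # beta units
    states: np.ndarray  # state units, one per sample
    error_trace: np.ndarray  # total squared error per iteration
    converged: bool

    def predict_states(self, betas: np.ndarray) -> np.ndarray:
        """State update formula applied to new samples' betas at the
        trained (rates, intercepts)."""
        denom = float(self.rates @ self.rates)
        if denom == 0:
            raise ValidationError("degenerate model: all site rates are zero")
        return (betas - self.intercepts) @ self.rates / denom


def _site_update(vals: np.ndarray, s: np.ndarray):
    sc = s - s.mean()
    var = float(sc @ sc)
    if var == 0:
        raise ValidationError("states collapsed to a constant; cannot regress sites")
    rates = vals.T @ sc / var  # per-site slope on states
    intercepts = vals.mean(axis=0) - rates * s.mean()
    return rates, intercepts


def fit_epm(
    beta_selected: BetaMatrix, ages, config: EPMConfig | None = None
) -> EPMModel:
    """Alternating least squares for the pacemaker model.

    States initialize at chronological ages; iteration stops when the
    relative improvement of the total squared error falls below ``tol``
    (default 1e-6) or at ``max_iter`` (default 100).
    """
    cfg = config or EPMConfig()
    return _fit_epm_arrays(
        beta_selected.values, np.asarray(ages, float), cfg,
        list(beta_selected.site_ids), list(beta_selected.sample_ids), min_n=3,
    )


def _fit_epm_arrays(vals, ages, cfg, site_ids, sample_ids, min_n=3) -> EPMModel:
    n, m = vals.shape
    if m < 2:
        raise ValidationError("need at least 2 selected sites")
    if n < min_n:
        raise ValidationError(f"need at least {min_n} samples")
    if ages.size != n:
        raise ValidationError("ages length does not match samples")
    s = ages.astype(float).copy()
    trace = []
    prev = np.inf
    converged = False
    rates = intercepts = None
    for _ in range(cfg.max_iter):
        rates, intercepts = _site_update(vals, s)
        denom = float(rates @ rates)
        if denom == 0:
            raise ValidationError("degenerate model: all site rates are zero")
        s = (vals - intercepts) @ rates / denom
        resid = vals - (intercepts + np.outer(s, rates))
        err = float((resid**2).sum())
        trace.append(err)
        if prev - err <= cfg.tol * max(prev, 1e-300) and np.isfinite(prev):
            converged = True
            break
        prev = err
    return EPMModel(
        site_ids=site_ids,
        sample_ids=sample_ids,
        rates=rates,
        intercepts=intercepts,
        states=s,
        error_trace=np.asarray(trace),
        converged=converged,
    )


def loo_states(
    beta_selected: BetaMatrix, ages, config: EPMConfig | None = None
) -> np.ndarray:
    """Leave-one-out epigenetic states.

    Each sample's state comes from the state-update formula under the model
    trained without that sample, so states are out-of-sample.
    """
    cfg = config or EPMConfig()
    ages = np.asarray(ages, float)
    vals = beta_selected.values
    n = vals.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples for leave-one-out states")
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ids = [s for k, s in enumerate(beta_selected.sample_ids) if k != i]
        # the n=3 minimum case leaves two training samples, which still
        # identifies the per-site regressions
        model = _fit_epm_arrays(
            vals[mask], ages[mask], cfg,
            list(beta_selected.site_ids), ids, min_n=2,
        )
        out[i] = model.predict_states(vals[i])
    return out


# ----------------------------------------------------------------- trend curve

@dataclass
class TrendFit:
    a: float
    c: float
    d: float
    translated_ages: np.ndarray  # years
    pearson_r: float  # r(state, age)
    mae: float  # median |translated - chronological|, years


def _curve(age, a, c, d):
    return a * np.log(age + c) + d


def translate_states(states, a: float, c: float, d: float) -> np.ndarray:
    """Invert the trend curve: age = exp((s - d)/a) - c, clamped at 0."""
    if abs(a) < 1e-12:
        raise ValidationError("trend slope a ~ 0; translation undefined")
    return np.maximum(np.exp((np.asarray(states, float) - d) / a) - c, 0.0)


def fit_trend(states, ages) -> TrendFit:
    """Nonlinear least squares of state = a*ln(age + c) + d (c > 0).

    Five multi-starts over the curvature parameter c; non-convergence of
    all starts raises with the per-start errors.
    """
    states = np.asarray(states, float)
    ages = np.asarray(ages, float)
    if states.size != ages.size or states.size < 4:
        raise ValidationError("need matched states/ages with n >= 4")
    if np.any(ages < 0):
        raise ValidationError("ages must be >= 0")
    if np.std(states) == 0:
        raise ValidationError("constant states; trend fit is degenerate")
    best = None
    failures = []
    for c0 in (0.1, 0.5, 1.0, 2.0, 5.0):
        la = np.log(ages + c0)
        a0 = float(np.polyfit(la, states, 1)[0]) or 1.0
        d0 = float(states.mean() - a0 * la.mean())
        try:
            popt, _ = curve_fit(
                _curve,
                ages,
                states,
                p0=(a0, c0, d0),
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20_000,
                xtol=1e-14,
                ftol=1e-14,
            )
        except (RuntimeError, ValueError) as exc:  # no convergence from this start
            failures.append(f"c0={c0}: {exc}")
            continue
        sse = float(((states - _curve(ages, *popt)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise ValidationError(
            "trend curve did not converge from any start:\n" + "\n".join(failures)
        )
    a, c, d = (float(v) for v in best[1])
    if abs(a) < 1e-12:
        raise ValidationError("trend slope a ~ 0; state-age relationship degenerate")
    translated = translate_states(states, a, c, d)
    r = float(np.corrcoef(states, ages)[0, 1]) if np.std(ages) > 0 else np.nan
    mae = float(np.median(np.abs(translated - ages)))
    return TrendFit(a=a, c=c, d=d, translated_ages=translated, pearson_r=r, mae=mae)


def epm_age_acceleration(states, ages, trend: TrendFit):
    """EPM age acceleration in both exposed forms.

    Returns (state_residual, years_difference): the residual of the state
    from the trend curve at the sample's age (state units), and translated
    age minus chronological age (years).
    """
    states = np.asarray(states, float)
    ages = np.asarray(ages, float)
    state_resid = states - _curve(ages, trend.a, trend.c, trend.d)
    years_diff = translate_states(states, trend.a, trend.c, trend.d) - ages
    return state_resid, years_diff
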