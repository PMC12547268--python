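"""Negative-binomial mixed model of stress-phase effects on per-minute counts.

Counts (movements/min or hens per litter area) are modelled as
NB2(mu, k) with variance mu + mu^2 / k on a log link:

    log mu_ij = beta_0 + beta_phase(ij) + b_week(ij),   b_w ~ N(0, sigma^2)

with the pre-stress phase as reference, experimental groups entering as
replicate observations, and week as a random intercept.  The marginal
likelihood is maximized under a Laplace approximation of the week-intercept
integrals (one-dimensional Newton inner solves per week).  Reported phase
means are response-scale exp(intercept + contrast) with delta-method
standard errors and Wald p-values for during/after versus before.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .geometry_io import CountRecord, records_to_frame, clock_to_seconds

__all__ = [
    "PHASES",
    "WindowSpec",
    "default_window_spec",
    "select_windows",
    "NBGLMMFit",
    "fit_nb_glmm",
    "phase_report",
]

PHASES = ("before", "during", "after")

STRESS_DURATIONS_MIN = {"visual": 6, "auditory": 1}
FRUSTRATION_DELAY_MIN = 60


@dataclass(frozen=True)
class WindowSpec:
    """Before/during/after windows in minutes relative to stress onset."""

    stressor: str  # visual | auditory | frustrative
    horizon: str  # short | long
    windows: dict[str, tuple[int, int]]  # phase -> (offset_min, duration_min)
    frustration_anchor: Optional[str] = None  # early | late

    def __post_init__(self) -> None:
        if set(self.windows) != set(PHASES):
            raise ValueError("windows must cover before/during/after")
        spans = sorted(
            (off, off + dur) for off, dur in self.windows.values()
        )
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("phase windows must not overlap")


def default_window_spec(
    stressor: str,
    horizon: str = "short",
    frustration_anchor: Optional[str] = None,
) -> WindowSpec:
    """Study window layouts.

    Visual/auditory: before/after of 5 min (short) or 25 min (long) around
    the full stress duration (6 min visual, 1 min auditory).  Frustrative:
    the stress period is the 60-min feed delay; ``during`` is its first or
    last 5 min (short) / 30 min (long) depending on the anchor, with
    matching 5- or 30-min before/after windows.
    """
    if horizon not in ("short", "long"):
        raise ValueError(f"unknown horizon {horizon!r}")
    if stressor in STRESS_DURATIONS_MIN:
        dur = STRESS_DURATIONS_MIN[stressor]
        flank = 5 if horizon == "short" else 25
        windows = {
            "before": (-flank, flank),
            "during": (0, dur),
            "after": (dur, flank),
        }
        return WindowSpec(stressor=stressor, horizon=horizon, windows=windows)
    if stressor == "frustrative":
        if frustration_anchor not in ("early", "late"):
            raise ValueError(
                "frustrative stress requires frustration_anchor 'early' or 'late'"
            )
        span = 5 if horizon == "short" else 30
        if frustration_anchor == "early":
            during = (0, span)
        else:
            during = (FRUSTRATION_DELAY_MIN - span, span)
        windows = {
            "before": (-span, span),
            "during": during,
            "after": (FRUSTRATION_DELAY_MIN, span),
        }
        return WindowSpec(
            stressor=stressor,
            horizon=horizon,
            windows=windows,
            frustration_anchor=frustration_anchor,
        )
    raise ValueError(f"unknown stressor {stressor!r}")


def select_windows(
    records: Sequence[CountRecord] | pd.DataFrame,
    spec: WindowSpec,
    onset_clock: int,
) -> pd.DataFrame:
    """Label per-minute records with their stress phase; drop the rest.

    Raises if any (group, week) series does not cover every minute of every
    window, listing the missing minutes.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if df["clock_time"].dtype == object:
            df["clock_time"] = df["clock_time"].map(clock_to_seconds)
    else:
        df = records_to_frame(records)
        df["clock_time"] = df["clock_time"].map(clock_to_seconds)

    phase_col = np.full(len(df), "", dtype=object)
    for phase, (off, dur) in spec.windows.items():
        lo = onset_clock + 60 * off
        hi = lo + 60 * dur
        in_window = (df["clock_time"] >= lo) & (df["clock_time"] < hi)
        phase_col[in_window.to_numpy()] = phase
    df = df.assign(phase=phase_col)
    df = df[df["phase"] != ""].copy()

    expected_minutes = {
        phase: [
            onset_clock + 60 * off + 60 * m
            for m in range(dur)
        ]
        for phase, (off, dur) in spec.windows.items()
    }
    missing: list[str] = []
    for (group, week), sub in df.groupby(["group_id", "week"]):
        have = set(sub["clock_time"])
        for phase, minutes in expected_minutes.items():
            for minute in minutes:
                if minute not in have:
                    missing.append(
                        f"group {group} week {week} {phase} minute "
                        f"{minute // 3600:02d}:{minute % 3600 // 60:02d}"
                    )
    if missing:
        raise ValueError(
            "incomplete window coverage; missing minutes: "
            + "; ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )
    df["phase"] = pd.Categorical(df["phase"], categories=list(PHASES), ordered=True)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# NB2 GLMM with Laplace-approximated week random intercept
# ---------------------------------------------------------------------------


@dataclass
class NBGLMMFit:
    phases: list[str]
    coefficients: dict[str, float]  # intercept + phase contrasts (log scale)
    coef_se: dict[str, float]
    dispersion: float  # NB2 k
    week_sd: float
    week_intercepts: dict[object, float]  # empirical Bayes modes
    phase_means: dict[str, float]  # response scale
    phase_ses: dict[str, float]
    observed_phase_means: dict[str, float]
    contrast_p: dict[str, float]  # during/after vs before (Wald)
    log_likelihood: float
    converged: bool
    gradient_norm: float
    n_obs: int
    cov: np.ndarray = field(repr=False, default=None)

    def week_effect_summary(self) -> tuple[float, float]:
        """Mean and SD of the predicted week-intercept deviations."""
        b = np.array(list(self.week_intercepts.values()), dtype=float)
        if b.size == 0:
            return 0.0, 0.0
        return float(b.mean()), float(b.std(ddof=0))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1)
        + k * np.log(k / (k + mu))
        + y * np.log(mu / (k + mu))
    )


def _inner_modes(
    y: np.ndarray,
    eta0: np.ndarray,
    widx: np.ndarray,
    n_weeks: int,
    k: float,
    sigma2: float,
    b0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve of the per-week conditional modes b_hat (vectorized over
    weeks).  Returns (b_hat, curvature = -h'' per week)."""
    b = b0.copy()
    for _ in range(max_iter):
        mu = np.exp(eta0 + b[widx])
        grad_i = y - (y + k) * mu / (k + mu)
        hess_i = (y + k) * k * mu / (k + mu) ** 2
        g = np.bincount(widx, weights=grad_i, minlength=n_weeks) - b / sigma2
        h = np.bincount(widx, weights=hess_i, minlength=n_weeks) + 1.0 / sigma2
        step = g / h
        # dampen huge steps for stability
        step = np.clip(step, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(g)) < tol * (1.0 + np.max(np.abs(b))):
            break
    mu = np.exp(eta0 + b[widx])
    hess_i = (y + k) * k * mu / (k + mu) ** 2
    curvature = np.bincount(widx, weights=hess_i, minlength=n_weeks) + 1.0 / sigma2
    return b, curvature


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def fit_nb_glmm(
    data: pd.DataFrame,
    response: str = "value",
    phase_col: str = "phase",
    week_col: str = "week",
    week_sd: Optional[float] = None,
    phases: Sequence[str] = PHASES,
) -> NBGLMMFit:
    """Fit the NB2 mixed model by Laplace-approximated maximum likelihood.

    ``week_sd=None`` estimates the random-intercept SD; ``week_sd=0`` fixes
    it at zero, reducing the model to a plain NB regression.  Counts must be
    nonnegative integers.  Non-convergence is flagged on the result, never
    silently ignored.
    """
    df = data.copy()
    present = [p for p in phases if p in set(df[phase_col].astype(str))]
    if len(present) < 2:
        raise ValueError("need at least 2 phases present")
    weeks = np.sort(df[week_col].unique())
    if len(weeks) < 2 and (week_sd is None or week_sd != 0):
        raise ValueError("need at least 2 weeks to estimate a week effect")
    y = df[response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    y = y.astype(float)

    phase_arr = df[phase_col].astype(str).to_numpy()
    ref = present[0]
    contrasts = present[1:]
    n = len(y)
    p = 1 + len(contrasts)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for c, phase in enumerate(contrasts, start=1):
        X[:, c] = phase_arr == phase

    week_map = {w: i for i, w in enumerate(weeks)}
    widx = df[week_col].map(week_map).to_numpy(dtype=int)
    n_weeks = len(weeks)

    estimate_sigma = week_sd is None
    fixed_sigma = 0.0 if week_sd == 0 else (week_sd or 0.0)

    # starting values from observed phase means and moment dispersion
    obs_means = {
        phase: float(y[phase_arr == phase].mean()) for phase in present
    }
    beta0 = np.zeros(p)
    beta0[0] = math.log(max(obs_means[ref], 1e-3))
    for c, phase in enumerate(contrasts, start=1):
        beta0[c] = math.log(max(obs_means[phase], 1e-3)) - beta0[0]
    resid_var = float(
        np.mean(
            [
                y[phase_arr == phase].var(ddof=1) if (phase_arr == phase).sum() > 1 else 0.0
                for phase in present
            ]
        )
    )
    mean_all = float(y.mean())
    excess = max(resid_var - mean_all, 1e-3)
    k0 = float(np.clip(mean_all**2 / excess, 0.05, 1e4))

    LOG_SIGMA_FLOOR = math.log(1e-4)

    warm_b = {"b": np.zeros(n_weeks)}

    def nll(theta: np.ndarray) -> float:
        beta = theta[:p]
        log_k = theta[p]
        k = math.exp(log_k)
        eta0 = X @ beta
        if estimate_sigma:
            sigma = math.exp(theta[p + 1])
        else:
            sigma = fixed_sigma
        if sigma <= 1e-8:
            ll = float(np.sum(_nb_loglik(y, np.exp(eta0), k)))
            return -ll
        sigma2 = sigma * sigma
        b_hat, curvature = _inner_modes(
            y, eta0, widx, n_weeks, k, sigma2, warm_b["b"]
        )
        warm_b["b"] = b_hat
        mu = np.exp(eta0 + b_hat[widx])
        ll = float(np.sum(_nb_loglik(y, mu, k)))
        ll -= float(np.sum(b_hat**2) / (2.0 * sigma2))
        ll -= 0.5 * float(np.sum(np.log(sigma2 * curvature)))
        return -ll

    x0 = np.concatenate(
        [beta0, [math.log(k0)], [math.log(0.1)] if estimate_sigma else []]
    )
    bounds = [(None, None)] * p + [(math.log(1e-3), math.log(1e7))]
    if estimate_sigma:
        bounds.append((LOG_SIGMA_FLOOR, math.log(10.0)))

    result = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    xhat = result.x
    converged = bool(result.success)
    grad_norm = float(np.max(np.abs(result.jac))) if result.jac is not None else float("nan")
    if not converged:
        warnings.warn(
            f"NB GLMM did not converge: {result.message} "
            f"(gradient norm {grad_norm:.2e})"
        )

    beta_hat = xhat[:p]
    k_hat = float(math.exp(xhat[p]))
    sigma_hat = float(math.exp(xhat[p + 1])) if estimate_sigma else fixed_sigma
    if estimate_sigma and xhat[p + 1] <= LOG_SIGMA_FLOOR + 1e-9:
        sigma_hat = 0.0

    # covariance of the estimated parameters from the numeric Hessian
    hess = _numeric_hessian(nll, xhat)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    ses = np.sqrt(diag)

    if sigma_hat > 1e-8:
        b_hat, _ = _inner_modes(
            y, X @ beta_hat, widx, n_weeks, k_hat, sigma_hat**2,
            np.zeros(n_weeks),
        )
    else:
        b_hat = np.zeros(n_weeks)

    coef_names = ["intercept"] + [f"{phase}_vs_{ref}" for phase in contrasts]
    coefficients = dict(zip(coef_names, beta_hat.tolist()))
    coef_se = dict(zip(coef_names, ses[:p].tolist()))

    phase_means = {}
    phase_ses = {}
    contrast_p = {}
    for idx, phase in enumerate(present):
        a = np.zeros(len(xhat))
        a[0] = 1.0
        if idx > 0:
            a[idx] = 1.0
        eta = float(beta_hat[0] + (beta_hat[idx] if idx > 0 else 0.0))
        mean = math.exp(eta)
        var = float(a @ cov @ a)
        phase_means[phase] = mean
        phase_ses[phase] = mean * math.sqrt(var) if var >= 0 else float("nan")
        if idx > 0:
            se_c = ses[idx]
            z = beta_hat[idx] / se_c if se_c > 0 else float("nan")
            contrast_p[phase] = float(2.0 * stats.norm.sf(abs(z)))

    return NBGLMMFit(
        phases=list(present),
        coefficients=coefficients,
        coef_se=coef_se,
        dispersion=k_hat,
        week_sd=sigma_hat,
        week_intercepts={w: float(b_hat[week_map[w]]) for w in weeks},
        phase_means=phase_means,
        phase_ses=phase_ses,
        observed_phase_means=obs_means,
        contrast_p=contrast_p,
        log_likelihood=float(-result.fun),
        converged=converged,
        gradient_norm=grad_norm,
        n_obs=n,
        cov=cov,
    )


def phase_report(
    fit: NBGLMMFit,
    durations_min: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Tabulate response-scale phase means, SEs and Wald p-values plus the
    week-effect summary (mean +- SD of predicted week deviations)."""
    wmean, wsd = fit.week_effect_summary()
    rows = []
    for phase in fit.phases:
        rows.append(
            {
                "phase": phase,
                "duration_min": (durations_min or {}).get(phase),
                "mean": fit.phase_means[phase],
                "se": fit.phase_ses[phase],
                "p_vs_before": fit.contrast_p.get(phase),
                "week_effect_mean": wmean,
                "week_effect_sd": wsd,
            }
        )
    return pd.DataFrame(rows)
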