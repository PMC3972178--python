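"""Probe-level moderated t-statistics (empirical Bayes variance shrinkage).

For each probe the two-group comparison (case minus control mean of the
log2 MeDIP/input ratios) uses a pooled-variance linear model.  Per-probe
sample variances s_g^2 with d residual degrees of freedom are shrunk
toward a common prior via the scaled inverse chi-square hierarchy

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chi^2_d / d
    1 / sigma_g^2      ~  chi^2_{d0} / (d0 * s0^2)

so the posterior variance is (d0*s0^2 + d*s_g^2) / (d0 + d) and the
moderated t follows a t distribution with d0 + d degrees of freedom.
The hyperparameters (d0, s0^2) are estimated by method of moments on
log s_g^2, whose marginal is a location-shifted log-F: matching its mean
and variance to digamma/trigamma expressions yields the estimates
(Smyth-style empirical Bayes).  d0 = inf is returned when the observed
dispersion of log s_g^2 does not exceed the theoretical minimum
trigamma(d/2), i.e. the variances are consistent with a single shared
value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import AnalysisConfig
from .matrix import GROUP_CASE, GROUP_CONTROL, MethylationMatrix

__all__ = [
    "EBayesPrior",
    "fit_probe_models",
    "estimate_prior",
    "trigamma_inverse",
    "moderated_t",
    "call_probes",
    "probe_pipeline",
]

#: Sample variances at or below this are treated as exactly zero:
#: floored before taking logs and excluded from prior estimation.
VARIANCE_FLOOR = 1e-12

CALL_UP = "up_in_cpa"
CALL_DOWN = "down_in_cpa"
CALL_NONE = "none"


@dataclass(frozen=True)
class EBayesPrior:
    """Prior degrees of freedom d0 (possibly inf) and prior variance s0^2."""

    prior_df: float
    prior_variance: float

    def __post_init__(self) -> None:
        if not self.prior_df > 0:
            raise ValueError("prior_df must be positive")
        if not self.prior_variance > 0 or not math.isfinite(self.prior_variance):
            raise ValueError("prior_variance must be positive and finite")


def fit_probe_models(matrix: MethylationMatrix) -> pd.DataFrame:
    """Per-probe group-difference fits under the pooled-variance model.

    Returns a DataFrame with columns ``probe_id, log2fc,
    residual_variance, residual_df`` where ``log2fc`` is the case-minus-
    control difference of group means and ``residual_variance`` the
    pooled within-group variance on ``n1 + n2 - 2`` degrees of freedom.
    """
    case = matrix.group_mask(GROUP_CASE)
    ctrl = matrix.group_mask(GROUP_CONTROL)
    n1, n2 = int(case.sum()), int(ctrl.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2 for a pooled variance")
    x1 = matrix.values[:, case]
    x2 = matrix.values[:, ctrl]
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    return pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "log2fc": log2fc,
            "residual_variance": (ss1 + ss2) / df,
            "residual_df": df,
        }
    )


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Falls back to bisection steps whenever a Newton update leaves the
    positive half-line or fails to reduce the residual.
    """
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    # Near-asymptotic guesses: trigamma(y) ~ 1/y + 1/(2y^2) for large y.
    y = 0.5 + 1.0 / x
    lo, hi = 1e-12, None
    for _ in range(max_iter):
        f = special.polygamma(1, y) - x
        if abs(f) < tol * x:
            return float(y)
        if f > 0:  # trigamma decreasing: y too small
            lo = max(lo, y)
        else:
            hi = y if hi is None else min(hi, y)
        fprime = special.polygamma(2, y)
        step = f / fprime
        candidate = y - step
        if candidate <= lo or (hi is not None and candidate >= hi):
            candidate = (lo + hi) / 2 if hi is not None else y * 2
        y = candidate
    return float(y)


def estimate_prior(
    residual_variances: np.ndarray, residual_df: float | np.ndarray
) -> EBayesPrior:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Requires at least 10 probes with positive variance.  All-equal
    variances (zero dispersion of log s^2 beyond trigamma(d/2)) give
    d0 = inf with s0^2 at the common value.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    df = np.asarray(residual_df, dtype=float)
    if df.ndim == 0:
        df = np.full(s2.shape, float(df))
    if np.unique(df).size != 1:
        raise ValueError("estimate_prior assumes a common residual df")
    d = float(df[0])
    if d <= 0:
        raise ValueError("residual_df must be positive")
    positive = s2 > VARIANCE_FLOOR
    if not positive.any():
        raise ValueError("all residual variances are zero; prior undefined")
    s2 = s2[positive]
    if s2.size < 10:
        raise ValueError(f"need >= 10 probes with positive variance, got {s2.size}")
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = float(e.mean())
    # Unbiased sample variance of e, less the within-probe log-chi^2 noise.
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2))
    if e_var <= 0:
        # No excess dispersion: a single shared variance explains the data.
        return EBayesPrior(math.inf, float(s2.mean()))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + special.digamma(d0 / 2) - math.log(d0 / 2)
    )
    return EBayesPrior(d0, s0_sq)


def moderated_t(
    fits: pd.DataFrame, prior: EBayesPrior, n_case: int, n_control: int
) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values for per-probe fits.

    The posterior variance interpolates between the probe's own sample
    variance and the prior; the statistic is referred to a t distribution
    with ``prior_df + residual_df`` degrees of freedom (standard normal
    when the prior df is infinite).
    """
    out = fits.copy()
    s2 = out["residual_variance"].to_numpy(dtype=float)
    df = out["residual_df"].to_numpy(dtype=float)
    d0 = prior.prior_df
    if math.isinf(d0):
        post = np.full_like(s2, prior.prior_variance)
    else:
        post = (d0 * prior.prior_variance + df * s2) / (d0 + df)
    se = np.sqrt(post * (1.0 / n_case + 1.0 / n_control))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = out["log2fc"].to_numpy(dtype=float) / se
    t = np.where(se == 0, 0.0, t)  # zero effect over zero variance
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + df)
    out["posterior_variance"] = post
    out["moderated_t"] = t
    out["p_value"] = p
    return out


def call_probes(results: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Flag probes meeting the probe-level calling rule.

    A probe is called (directionally) when its p-value is at most
    ``probe_p_threshold`` — uncorrected, by design — and the absolute
    log2 fold difference is at least ``min_abs_log2fc``.
    """
    out = results.copy()
    passing = (out["p_value"] <= config.probe_p_threshold) & (
        out["log2fc"].abs() >= config.min_abs_log2fc
    )
    call = np.where(
        passing & (out["log2fc"] > 0),
        CALL_UP,
        np.where(passing & (out["log2fc"] < 0), CALL_DOWN, CALL_NONE),
    )
    out["probe_call"] = call
    return out


def probe_pipeline(
    matrix: MethylationMatrix, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Fit, shrink, test and call every probe of a matrix in one step."""
    config = config or AnalysisConfig()
    fits = fit_probe_models(matrix)
    prior = estimate_prior(
        fits["residual_variance"].to_numpy(), fits["residual_df"].iloc[0]
    )
    n_case, n_control = matrix.group_counts()
    results = moderated_t(fits, prior, n_case, n_control)
    return call_probes(results, config), prior
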