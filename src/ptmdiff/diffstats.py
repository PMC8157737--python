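"""Two-group differential abundance with an empirical-Bayes moderated t-test.

Model
-----
Per feature *g* the observed values (log2 intensities or M-values) are
Gaussian within each of two groups with a common variance sigma_g^2. The
usual pooled estimate s_g^2 has df_g = n_a + n_b - 2 residual degrees of
freedom and, given sigma_g^2, follows sigma_g^2 * chi^2_{df_g} / df_g. A
scaled inverse-chi-square prior sigma_g^2 ~ s0^2 * d0 / chi^2_{d0} is
shared across features; its hyperparameters (d0, s0^2) are estimated by
the method of moments on log s_g^2, and the posterior-mean variance

    s_tilde_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

replaces s_g^2 in the t-statistic, which then has d0 + df_g degrees of
freedom. Shrinking the per-feature variances toward the common prior
stabilises the test at the small replicate counts typical of MS
experiments (n = 3 per group); d0 -> 0 recovers the classical pooled
t-test and d0 -> infinity a common-variance z-like test.

Hyperparameter estimation
-------------------------
With z_g = log s_g^2, E[z_g] = log sigma_g^2 + psi(df_g/2) - log(df_g/2)
and Var[z_g] = psi'(df_g/2) (psi, psi' digamma/trigamma). Removing the
df-dependent bias, e_g = z_g - psi(df_g/2) + log(df_g/2), gives a sample
whose excess dispersion over the chi-square sampling noise estimates the
prior spread:

    psi'(d0/2) = mean_g[ (e_g - e_bar)^2 * n/(n-1) - psi'(df_g/2) ]
    s0^2       = exp( e_bar + psi(d0/2) - log(d0/2) )

d0 comes from inverting the (strictly decreasing) trigamma function by
bracketed Newton iteration. A non-positive right-hand side means the
observed spread is no larger than sampling noise; the prior is then
degenerate (d0 = +inf, all variances shrunk fully to exp(e_bar)).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_FC_THRESHOLD = 2.0


@dataclass(frozen=True)
class FeatureFit:
    """Per-feature two-group summary on the log2 / M scale."""

    feature: str
    mean_a: float      # treatment-arm mean
    mean_b: float      # control-arm mean
    log2fc: float      # mean_a - mean_b (treatment minus control)
    s2: float          # pooled residual variance
    df: float          # residual degrees of freedom (effective n - 2)
    n_a: int
    n_b: int


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled inverse-chi-square variance-prior hyperparameters."""

    d0: float    # prior degrees of freedom; 0 = no shrinkage, may be math.inf
    s0sq: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("prior df d0 must be non-negative")
        if not self.s0sq >= 0:
            raise ValueError("prior variance s0sq must be non-negative")


# ---------------------------------------------------------------------------
# per-feature fits
# ---------------------------------------------------------------------------

def fit_features(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Group means, log2 fold changes and pooled variances per feature.

    ``values`` is features x samples on the log2 (or M) scale; ``group_a``
    is the treatment arm, ``group_b`` the control, so ``log2fc`` is
    treatment minus control. Missing values reduce the feature's effective
    df; features unmeasurable in a whole group keep their row with missing
    statistics rather than being dropped.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = values[group_a].to_numpy(float)
    b = values[group_b].to_numpy(float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN groups kept
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        ss_a = np.nansum((a - mean_a[:, None]) ** 2, axis=1)
        ss_b = np.nansum((b - mean_b[:, None]) ** 2, axis=1)
    mean_a = np.where(na >= 1, mean_a, np.nan)
    mean_b = np.where(nb >= 1, mean_b, np.nan)
    df = np.maximum(na - 1, 0) + np.maximum(nb - 1, 0)
    df = np.where((na >= 1) & (nb >= 1), df, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, (ss_a + ss_b) / df, np.nan)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_a - mean_b,
            "s2": s2,
            "df": df,
            "n_a": na,
            "n_b": nb,
        },
        index=values.index,
    )
    n_zero_df = int(((out["df"] == 0) | out["df"].isna()).sum())
    if n_zero_df:
        logger.info(
            "%d feature(s) with df = 0 or missing excluded from prior estimation",
            n_zero_df,
        )
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes prior
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve psi'(x) = y for x > 0 by bracketed Newton iteration.

    psi' is strictly decreasing on (0, inf) with range (0, inf), so the
    root is unique. Newton on x uses d psi'(x)/dx = psi''(x) < 0; the
    asymptotic start x ~ 1/y (from psi'(x) ~ 1/x for large x) converges in
    a handful of steps.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:           # psi'(x) ~ 1/x^2 as x -> 0
        return 1.0 / math.sqrt(y)
    if y < 1e-6:          # psi'(x) ~ 1/x as x -> inf
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = max(x + dif, 1e-12)
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(
    s2: np.ndarray | pd.Series, df: np.ndarray | pd.Series
) -> EBayesPrior:
    """Method-of-moments fit of (d0, s0^2) from per-feature variances.

    Zero-variance and df < 1 features are excluded (count logged); fewer
    than two usable features is a hard error because the moment equations
    are then meaningless.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    usable = np.isfinite(s2) & np.isfinite(df) & (df >= 1) & (s2 > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("estimate_prior: %d unusable feature(s) excluded", n_dropped)
    s2, df = s2[usable], df[usable]
    n = len(s2)
    if n < 2:
        raise ValueError(
            "need >= 2 features with df >= 1 and s2 > 0 to estimate the "
            "variance prior (moderated shrinkage is imprecise for very few "
            "features)"
        )
    if n < 10:
        logger.warning(
            "estimate_prior: only %d usable features; prior is imprecise", n
        )
    half_df = df / 2.0
    e = np.log(s2) - special.digamma(half_df) + np.log(half_df)
    e_bar = e.mean()
    target = float(
        np.mean((e - e_bar) ** 2 * n / (n - 1) - special.polygamma(1, half_df))
    )
    if target <= 0:
        return EBayesPrior(d0=math.inf, s0sq=float(np.exp(e_bar)))
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    s0sq = float(np.exp(e_bar + special.digamma(half_d0) - np.log(half_d0)))
    return EBayesPrior(d0=d0, s0sq=s0sq)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def moderated_t(fits: pd.DataFrame, prior: EBayesPrior) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values.

    Posterior variance s_tilde^2 = (d0 s0^2 + df s^2)/(d0 + df);
    t = log2fc / (s_tilde * sqrt(1/n_a + 1/n_b)) on d0 + df degrees of
    freedom (standard normal in the d0 = inf limit). Features with df = 0
    receive the prior variance and df = d0, and are flagged.

    A degenerate s_tilde = 0 (both s^2 = 0 and s0^2 = 0) yields p = 0 for
    a nonzero fold change and p = 1 otherwise, flagged.
    """
    log2fc = fits["log2fc"].to_numpy(float)
    s2 = fits["s2"].to_numpy(float)
    df = fits["df"].to_numpy(float)
    na = fits["n_a"].to_numpy(float)
    nb = fits["n_b"].to_numpy(float)

    df_eff = np.where(np.isfinite(df) & (df > 0), df, 0.0)
    zero_df = (~np.isfinite(df)) | (df <= 0)
    s2_eff = np.where(zero_df, 0.0, np.nan_to_num(s2))
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2_eff, prior.s0sq)
        df_total = np.full_like(s2_eff, math.inf)
    else:
        s2_post = (prior.d0 * prior.s0sq + df_eff * s2_eff) / (prior.d0 + df_eff)
        df_total = prior.d0 + df_eff

    measurable = (na >= 1) & (nb >= 1) & np.isfinite(log2fc)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        t = log2fc / se
    degenerate = measurable & (se == 0)
    if degenerate.any():
        repl = np.where(np.nan_to_num(log2fc) != 0,
                        np.inf * np.sign(np.nan_to_num(log2fc)), 0.0)
        t = np.where(degenerate, repl, t)
    p = np.full_like(t, np.nan)
    finite_df = np.isfinite(df_total)
    p[measurable & finite_df] = 2.0 * stats.t.sf(
        np.abs(t[measurable & finite_df]), df_total[measurable & finite_df]
    )
    inf_mask = measurable & ~finite_df
    p[inf_mask] = 2.0 * stats.norm.sf(np.abs(t[inf_mask]))
    p[degenerate] = np.where(log2fc[degenerate] != 0, 0.0, 1.0)
    t = np.where(measurable, t, np.nan)

    out = fits.copy()
    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["t_mod"] = t
    out["p"] = p
    out["shrunk_to_prior"] = zero_df
    out["degenerate_se"] = degenerate
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up FDR adjustment.

    Missing p-values are propagated and do not count toward m. Output is
    monotone along the sorted raw-p order, elementwise >= the raw p, and
    capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if np.nanmin(arr, initial=0.5) < 0 or np.nanmax(arr, initial=0.5) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ok.sum():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="p_adj")
    return out


def call_significant(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Flag features with FDR-adjusted p < alpha AND |log2fc| > log2(fc).

    The fold-change gate is two-sided: "fold change > 2" means
    |log2fc| > 1, matching the symmetric volcano threshold lines.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    out = results.copy()
    lfc_gate = np.abs(out["log2fc"].to_numpy(float)) > np.log2(fc_threshold)
    p_gate = out["p_adj"].to_numpy(float) < alpha
    out["significant"] = lfc_gate & p_gate & ~out["p_adj"].isna().to_numpy()
    return out


def differential_analysis(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    prior: EBayesPrior | None = None,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Full pipeline: fit, shrink, test, adjust, flag.

    Returns the per-feature result table (log2fc, t_mod, p, p_adj,
    significant, ...) and the estimated (or supplied) prior.
    """
    fits = fit_features(values, group_a, group_b)
    if prior is None:
        prior = estimate_prior(fits["s2"], fits["df"])
    res = moderated_t(fits, prior)
    res["p_adj"] = bh_adjust(res["p"])
    res = call_significant(res, alpha=alpha, fc_threshold=fc_threshold)
    return res, prior
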