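"""Intensity transforms: log2, total-intensity proportions, beta / M values,
peptide-family percentages, and row z-scores.

The relative-abundance model mirrors the one used for DNA-methylation
arrays. For modification *i* in peptide family *F* of sample *s*,

    beta_i = x_i / (sum_{j in F} x_j + offset)

with ``offset`` (default 100, on the raw intensity scale) regularising the
ratio when the whole family is weakly observed; beta is therefore bounded
in [0, 1) and the family's betas sum to strictly less than one. Because the
beta is bounded it violates the Gaussian assumptions of linear-model
statistics, so testing is done on its logit,

    M = log2( beta / (1 - beta) ),

which is symmetric around beta = 0.5 and unbounded. The log2 base matches
the methylation M-value convention; a natural-log logit would differ only
by a constant factor but the base is fixed for reproducibility.

With ``offset > 0`` betas are intentionally scale-dependent: downscaling a
family's intensities by a common factor strictly decreases every nonzero
beta. Offset 0 recovers the plain percent-of-family normalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptmdiff.io_tables import PTMTable, ProteinMatrix

logger = logging.getLogger(__name__)

DEFAULT_OFFSET = 100.0
DEFAULT_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class BetaConfig:
    """Parameters of the beta-value transform.

    ``family_key_rule`` names the annotation columns whose combination
    defines a co-normalised peptide family; the default groups all
    modification states of the same site-bearing peptide on the same
    histone.
    """

    offset: float = DEFAULT_OFFSET
    family_key_rule: tuple[str, ...] = ("histone_protein", "site")
    clamp_eps: float = DEFAULT_CLAMP_EPS

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if not 0 < self.clamp_eps < 0.5:
            raise ValueError("clamp_eps must lie in (0, 0.5)")


def family_keys(ptm: PTMTable, cfg: BetaConfig) -> pd.Series:
    """Family labels per feature under the configured grouping rule."""
    ann = ptm.annotations
    missing = [c for c in cfg.family_key_rule if c not in ann.columns]
    if missing:
        raise ValueError(f"family key columns not in annotations: {missing}")
    key = ann[cfg.family_key_rule[0]].astype(str)
    for c in cfg.family_key_rule[1:]:
        key = key + ":" + ann[c].astype(str)
    return key


def log2_transform(
    matrix: pd.DataFrame | ProteinMatrix, zero_policy: str = "missing"
) -> pd.DataFrame:
    """log2 of a non-negative intensity matrix.

    ``zero_policy='missing'`` (default) maps zeros to NaN — a zero MS
    intensity is below the dynamic range, not a measured log-abundance.
    ``zero_policy='pseudocount'`` adds 1 to every value first.
    """
    x = matrix.intensities if isinstance(matrix, ProteinMatrix) else matrix
    vals = x.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative intensities cannot be log-transformed")
    if zero_policy == "pseudocount":
        vals = vals + 1.0
    elif zero_policy == "missing":
        vals = np.where(vals == 0, np.nan, vals)
    else:
        raise ValueError(f"unknown zero_policy: {zero_policy!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(vals)
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def total_intensity_normalize(ptm: PTMTable, sample: str) -> pd.Series:
    """Each modification's share of the sample-wide modification total.

    Unlike the family-percent method, the denominator is the sum over *all*
    modifications in the sample, not just those in the peptide family.
    """
    if sample not in ptm.intensities.columns:
        raise KeyError(f"sample not in table: {sample!r}")
    x = ptm.intensities[sample].astype(float)
    total = x.sum(skipna=True)
    if not total > 0:
        raise ValueError(f"sample {sample!r} has zero total intensity")
    return x / total


def compute_beta(ptm: PTMTable, cfg: BetaConfig | None = None) -> PTMTable:
    """Fill beta and M columns from intensities.

    beta = x / (family sum + offset) per sample; an all-zero family yields
    all-zero betas (the offset keeps the denominator positive).
    """
    cfg = cfg or BetaConfig()
    fam = family_keys(ptm, cfg)
    x = ptm.intensities.astype(float)
    denom = x.groupby(fam.to_numpy()).transform("sum") + cfg.offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = x / denom
    beta = beta.where(denom.ne(0), 0.0)  # offset 0 + all-zero family
    if (beta.to_numpy(float) >= 1).any():  # offset-0 single-member boundary
        warnings.warn(
            "beta value(s) at 1 clamped below 1 to preserve the [0, 1) bound",
            stacklevel=2,
        )
        beta = beta.clip(upper=1 - cfg.clamp_eps)
    m = beta_to_m(beta, eps=cfg.clamp_eps)
    return PTMTable(
        ptm.annotations, ptm.intensities, beta=beta, m_value=m, family_key=fam
    )


def beta_to_m(
    beta: float | np.ndarray | pd.DataFrame | pd.Series,
    eps: float = DEFAULT_CLAMP_EPS,
):
    """Logit (base 2) of a beta value: M = log2(beta / (1 - beta)).

    Values at exactly 0 or 1 are clamped to ``eps`` / ``1 - eps`` with a
    warning so the logit stays finite; the transform is strictly
    increasing on (0, 1).
    """
    arr = np.asarray(beta, dtype=float)
    if np.nanmin(arr, initial=0.5) < 0 or np.nanmax(arr, initial=0.5) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    at_bound = (arr == 0) | (arr == 1)
    if at_bound.any():
        warnings.warn(
            f"{int(at_bound.sum())} beta value(s) at 0 or 1 clamped to "
            f"[{eps}, {1 - eps}] before logit",
            stacklevel=2,
        )
        arr = np.clip(arr, eps, 1 - eps)
    m = np.log2(arr / (1 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (1 + 2**M)."""
    arr = np.asarray(m, dtype=float)
    p = np.exp2(arr)
    beta = p / (1.0 + p)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(beta)
    return beta


def family_percent(ptm: PTMTable, cfg: BetaConfig | None = None) -> pd.DataFrame:
    """Percent-of-peptide-family normalisation (the offset-free beta).

    Sums to 1 per family per sample; all-zero families yield zeros.
    """
    cfg = cfg or BetaConfig()
    fam = family_keys(ptm, cfg)
    x = ptm.intensities.astype(float)
    denom = x.groupby(fam.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = x / denom
    return out.where(denom.ne(0), 0.0)


def zscore_rows(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardisation: (x - row mean) / row sd, sd with the n-1
    denominator. Constant rows become all-zero with a warning."""
    x = log2_matrix.astype(float)
    n_obs = x.notna().sum(axis=1)
    if (n_obs < 2).any():
        raise ValueError("z-scoring needs >= 2 non-missing values per row")
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) z-scored to all zeros",
            stacklevel=2,
        )
        sd = sd.mask(constant, 1.0)
    z = x.sub(mu, axis=0).div(sd, axis=0)
    return z.mask(pd.DataFrame(np.tile(constant.to_numpy()[:, None], (1, x.shape[1])),
                               index=x.index, columns=x.columns), 0.0)
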