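"""Matrix-level transforms and filters applied between normalization and association.

Beta matrices are pandas DataFrames with CpG ids on the row index and sample
ids on the columns, values in [0, 1]. M-value matrices share the same axes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "filter_low_variability",
    "exclude_blacklist",
    "estimate_surrogate_variables",
    "vif",
]


def _check_beta(beta: pd.DataFrame) -> None:
    vals = beta.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("beta matrix contains missing values")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("beta values outside [0, 1]")


def beta_to_m(beta: pd.DataFrame, offset: float = 1e-6) -> pd.DataFrame:
    """log2 odds transform M = log2((beta + offset) / (1 - beta + offset)).

    The offset keeps boundary beta values (0 or 1) finite; it must be a small
    fraction in [0, 0.01]. The transform is strictly increasing in beta.
    """
    if not 0 <= offset <= 0.01:
        raise ValueError(f"offset must be in [0, 0.01], got {offset}")
    _check_beta(beta)
    vals = beta.to_numpy(dtype=float)
    m = np.log2((vals + offset) / (1.0 - vals + offset))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` at the same offset."""
    r = np.exp2(m.to_numpy(dtype=float))
    beta = (r * (1.0 + offset) - offset) / (1.0 + r)
    return pd.DataFrame(beta, index=m.index, columns=m.columns)


def filter_low_variability(
    beta: pd.DataFrame, sd_threshold: float = 0.01
) -> tuple[pd.DataFrame, list[str]]:
    """Drop CpG rows whose across-sample SD falls below ``sd_threshold``.

    Returns the retained matrix and the list of removed CpG ids. The union of
    retained and removed ids is exactly the input ids, so the filter is
    idempotent and conserving.
    """
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be >= 0")
    if beta.shape[1] < 2:
        raise ValueError("SD is undefined with fewer than two samples")
    sd = beta.std(axis=1, ddof=1)
    keep = sd >= sd_threshold
    removed = list(beta.index[~keep])
    return beta.loc[keep], removed


def exclude_blacklist(beta: pd.DataFrame, blacklist) -> pd.DataFrame:
    """Remove CpG rows whose id appears in ``blacklist`` (e.g. SNP-overlap sites).

    Ids absent from the matrix are ignored with a log message; row order of the
    survivors is preserved.
    """
    black = set(blacklist)
    absent = black - set(beta.index)
    if absent:
        log.info("%d blacklist ids not present in matrix", len(absent))
    keep = ~beta.index.isin(black)
    out = beta.loc[keep]
    if out.shape[0] == 0:
        log.warning("blacklist removed every CpG row")
    return out


def estimate_surrogate_variables(
    m: pd.DataFrame, primary, k: int = 5
) -> pd.DataFrame:
    """Estimate latent batch covariates by residual PCA with rescoring.

    The latent directions are learned from the residuals after removing the
    primary-variable group mean from every CpG row (so the learned structure
    is batch, not the effect of interest), but the returned surrogate
    variables are the scores of the *original* data along those CpG-space
    directions. Rescoring matters: scores confined to the residual space are
    orthogonal to the group indicator by construction and therefore cannot
    remove chance batch/group confounding — they would only shrink standard
    errors and inflate test statistics.

    Returns a sample x k DataFrame; columns are mutually orthogonal, scaled
    to unit sample variance, with a deterministic sign convention.
    """
    n = m.shape[1]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n - 2:
        raise ValueError(f"k={k} too large for {n} samples (need k < n - 2)")
    groups = pd.Series(np.asarray(primary), index=m.columns)
    vals = m.to_numpy(dtype=float)
    resid = vals.copy()
    for g in groups.unique():
        cols = (groups == g).to_numpy()
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    # CpG-space latent directions from the residuals
    u, _, _ = np.linalg.svd(resid, full_matrices=False)
    directions = u[:, :k]
    # score the original (row-centered) data on those directions
    centered = vals - vals.mean(axis=1, keepdims=True)
    scores = centered.T @ directions
    # orthonormalize within the score span, fix signs, scale to unit variance
    sv, _ = np.linalg.qr(scores - scores.mean(axis=0, keepdims=True))
    flip = np.sign(sv[np.argmax(np.abs(sv), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    sv = sv * flip
    sv = sv / sv.std(axis=0, ddof=1)
    return pd.DataFrame(sv, index=m.columns, columns=[f"SV{i + 1}" for i in range(k)])


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from regressing predictor j on all other predictors (with an
    intercept). Exactly collinear predictors are reported as ``inf`` rather
    than raising, so callers can flag them.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF needs more samples than predictors")
    x = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        others = np.column_stack(
            [np.ones(x.shape[0]), np.delete(x, j, axis=1)]
        )
        y = x[:, j]
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
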