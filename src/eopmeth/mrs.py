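"""Threshold-stratified methylation risk score (MRS).

CpGs are stratified by EWAS p-value cutoffs; per sample and cutoff the raw
score is the sum over selected CpGs of M-value times the EWAS Z (effect/SE),
then standardized to z-scores across samples. Associations between the
z-scored MRS and phenotypes use linear regression for continuous responses
and logistic regression (with a Firth penalized-likelihood fallback under
separation) for binary ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

DEFAULT_THRESHOLDS = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)

__all__ = [
    "ThresholdSet",
    "MrsProfile",
    "DEFAULT_THRESHOLDS",
    "stratify_cpgs",
    "compute_mrs",
    "zscore_mrs",
    "build_profile",
    "associate_mrs",
]


@dataclass(frozen=True)
class ThresholdSet:
    """CpGs selected from an EWAS at p < threshold."""

    threshold: float
    cpg_ids: frozenset


@dataclass
class MrsProfile:
    """Raw and z-scored risk scores per sample at each p-value threshold.

    ``raw`` and ``z`` are sample x threshold DataFrames (threshold columns are
    floats); ``n_cpgs`` maps threshold -> number of CpGs used. Thresholds that
    select no CpG have all-zero raw scores and NaN z-scores, and are listed in
    ``empty_thresholds``.
    """

    raw: pd.DataFrame
    z: pd.DataFrame
    n_cpgs: dict
    empty_thresholds: list


def stratify_cpgs(result: pd.DataFrame, thresholds=None) -> list[ThresholdSet]:
    """Select CpG sets at each p-value cutoff (strict inequality p < t).

    Defaults to the six canonical cutoffs 1e-6 ... 1e-1. Sets are nested:
    the set at a smaller threshold is contained in every larger one.
    """
    if len(result) == 0:
        raise ValueError("empty EWAS result")
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = list(thresholds)
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    p = result["p"]
    return [
        ThresholdSet(t, frozenset(result.index[p < t])) for t in thresholds
    ]


def compute_mrs(m: pd.DataFrame, result: pd.DataFrame, tset: ThresholdSet) -> pd.Series:
    """Raw MRS per sample: sum over the set's CpGs of M-value x Z, where
    Z = effect/SE from the EWAS."""
    ids = sorted(tset.cpg_ids)
    missing = [i for i in ids if i not in m.index]
    if missing:
        raise ValueError(f"CpGs missing from M matrix: {missing[:5]}")
    missing_r = [i for i in ids if i not in result.index]
    if missing_r:
        raise ValueError(f"CpGs missing from EWAS result: {missing_r[:5]}")
    if not ids:
        return pd.Series(0.0, index=m.columns, name=tset.threshold)
    z = (result.loc[ids, "effect"] / result.loc[ids, "se"]).to_numpy()
    score = z @ m.loc[ids].to_numpy(dtype=float)
    return pd.Series(score, index=m.columns, name=tset.threshold)


def zscore_mrs(raw: pd.Series) -> pd.Series:
    """Standardize raw scores: (x - mean)/SD with the n-1 SD. The result has
    mean 0 and SD 1."""
    if len(raw) < 2:
        raise ValueError("need at least two samples")
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero-variance MRS at threshold {raw.name}")
    return (raw - raw.mean()) / sd


def build_profile(m: pd.DataFrame, result: pd.DataFrame, thresholds=None) -> MrsProfile:
    """Compute raw and z-scored MRS at every threshold."""
    sets = stratify_cpgs(result, thresholds)
    raw = pd.DataFrame(index=m.columns)
    zdf = pd.DataFrame(index=m.columns)
    n_cpgs, empty = {}, []
    for ts in sets:
        r = compute_mrs(m, result, ts)
        raw[ts.threshold] = r
        n_cpgs[ts.threshold] = len(ts.cpg_ids)
        if len(ts.cpg_ids) == 0 or r.std(ddof=1) == 0:
            empty.append(ts.threshold)
            zdf[ts.threshold] = np.nan
        else:
            zdf[ts.threshold] = zscore_mrs(r)
    return MrsProfile(raw=raw, z=zdf, n_cpgs=n_cpgs, empty_thresholds=empty)


def _firth_logit(y: np.ndarray, x: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Finite estimates exist even under complete separation. Returns
    (coefficients, standard errors from the penalized Fisher information).
    """
    n, k = x.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        xw = x * np.sqrt(w)[:, None]
        info = xw.T @ xw
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", xw, info_inv, xw)
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = x @ beta
    w = expit(eta) * (1.0 - expit(eta))
    info = (x * w[:, None]).T @ x
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


def _is_binary(v: pd.Series) -> bool:
    vals = pd.unique(v.dropna())
    return len(vals) == 2


def associate_mrs(
    profile: MrsProfile,
    sheet: pd.DataFrame,
    phenotype: str,
    family: str = "auto",
) -> pd.DataFrame:
    """Regress a phenotype on the z-scored MRS, per threshold.

    The phenotype is the response and the MRS the predictor. ``auto`` picks
    logistic for binary phenotypes and linear otherwise. Logistic models with
    complete or quasi-complete separation (frequent in small cohorts) fall
    back to Firth penalized likelihood and are flagged, never silently.

    Returns one row per threshold: beta, ci_low, ci_high, p, family, flag,
    significant (p < 0.05).
    """
    if phenotype not in sheet.columns:
        raise ValueError(f"phenotype {phenotype!r} not in sample sheet")
    pheno = sheet.loc[profile.z.index, phenotype]
    ok = pheno.notna()
    if ok.sum() < 8:
        raise ValueError("need at least 8 samples with phenotype values")
    y_all = pheno[ok].to_numpy(dtype=float)
    if family == "auto":
        family = "logistic" if _is_binary(pheno) else "linear"
    if family == "logistic":
        classes = np.unique(y_all)
        if len(classes) < 2:
            raise ValueError("binary phenotype has a single class")
        y_all = (y_all == classes.max()).astype(float)

    rows = []
    for t in profile.z.columns:
        zcol = profile.z[t][ok]
        if zcol.isna().all():
            rows.append((t, np.nan, np.nan, np.nan, np.nan, family, "empty_set", False))
            continue
        x = np.column_stack([np.ones(len(zcol)), zcol.to_numpy(dtype=float)])
        flag = ""
        if family == "linear":
            fit = sm.OLS(y_all, x).fit()
            beta, se = fit.params[1], fit.bse[1]
            p = fit.pvalues[1]
            lo, hi = fit.conf_int(alpha=0.05)[1]
        else:
            separated = _separation(y_all, x[:, 1])
            fitted = None
            if not separated:
                try:
                    fitted = sm.Logit(y_all, x).fit(disp=0, maxiter=200)
                    if (np.abs(fitted.params) > 15).any() or not np.isfinite(
                        fitted.bse
                    ).all():
                        fitted = None
                except Exception:
                    fitted = None
            if fitted is not None:
                beta, se = fitted.params[1], fitted.bse[1]
            else:
                coef, ses = _firth_logit(y_all, x)
                beta, se = coef[1], ses[1]
                flag = "separation_firth" if separated else "firth"
            zstat = beta / se
            p = 2 * stats.norm.sf(abs(zstat))
            lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
        rows.append((t, float(beta), float(lo), float(hi), float(p), family,
                     flag, bool(p < 0.05)))
    return pd.DataFrame(
        rows,
        columns=["threshold", "beta", "ci_low", "ci_high", "p", "family",
                 "flag", "significant"],
    )


def _separation(y: np.ndarray, x: np.ndarray) -> bool:
    # complete separation: some cut of the predictor splits the classes
    x1, x0 = x[y == 1], x[y == 0]
    if x1.size == 0 or x0.size == 0:
        return False
    return bool(x1.min() >= x0.max() or x0.min() >= x1.max())
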