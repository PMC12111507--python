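"""Per-CpG association of methylation with case status.

The default model regresses methylation (one CpG at a time) on the group
indicator plus covariates by ordinary least squares and reports the group
coefficient — a methylation-scale difference between groups. A logistic mode
(group as the response, the CpG as predictor of interest) is available behind
the ``mode`` flag. Both report effect, SE, the Wald statistic t = effect/SE
and a two-sided p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import vif

__all__ = [
    "fit_cpg_association",
    "genomic_inflation_lambda",
    "qq_data",
    "annotate_hits",
    "manhattan_data",
]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


def _design(outcome: np.ndarray, covariates: pd.DataFrame | None, n: int):
    cols = [np.ones(n), outcome.astype(float)]
    names = ["intercept", "group"]
    if covariates is not None:
        if covariates.shape[1] >= 2:
            v = vif(covariates)
            if np.isinf(v).any():
                bad = list(v.index[np.isinf(v)])
                raise ValueError(f"collinear covariates: {bad}")
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


def fit_cpg_association(
    meth: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    mode: str = "methylation_as_outcome",
) -> pd.DataFrame:
    """Fit one association model per CpG row of ``meth``.

    Parameters
    ----------
    meth
        CpG x sample matrix (beta or M values).
    outcome
        Binary group labels, one per sample column.
    covariates
        Optional sample x p DataFrame (age, sex, surrogate variables, ...);
        screened for multicollinearity before fitting.
    mode
        ``methylation_as_outcome`` (default): OLS of methylation on
        group + covariates, reporting the group coefficient with a Student-t
        reference at df = n - #coefficients. ``logistic``: maximum-likelihood
        logit of group on CpG + covariates, reporting the CpG coefficient
        with a normal (z) reference.

    Returns a DataFrame indexed by CpG with columns effect, se, t, p, df and
    a boolean ``skipped`` flag for constant CpG rows (which cannot be fitted).
    """
    y = np.asarray(outcome)
    n = meth.shape[1]
    if len(y) != n:
        raise ValueError("outcome length does not match sample count")
    if pd.isna(y.astype(float)).any():
        raise ValueError("missing outcome labels")
    if covariates is not None and list(covariates.index) != list(meth.columns):
        covariates = covariates.loc[meth.columns]
    x, names = _design(y, covariates, n)
    p_params = x.shape[1]
    if n < p_params + 2:
        raise ValueError(f"too few samples ({n}) for {p_params} coefficients")

    vals = meth.to_numpy(dtype=float)
    constant = vals.std(axis=1) == 0

    if mode == "methylation_as_outcome":
        df_resid = n - p_params
        xtx_inv = np.linalg.inv(x.T @ x)
        h = xtx_inv @ x.T                      # p x n solve operator
        coefs = vals @ h.T                     # cpg x p
        resid = vals - coefs @ x.T
        sigma2 = (resid**2).sum(axis=1) / df_resid
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        effect = coefs[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
        out = pd.DataFrame(
            dict(effect=effect, se=se, t=t, p=pvals, df=df_resid),
            index=meth.index,
        )
    elif mode == "logistic":
        rows = []
        base = x[:, [0] + list(range(2, p_params))]  # intercept + covariates
        for i in range(vals.shape[0]):
            if constant[i]:
                rows.append((np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            xi = np.column_stack([base[:, :1], vals[i], base[:, 1:]])
            try:
                fit = sm.Logit(y.astype(float), xi).fit(disp=0, maxiter=200)
                eff, se_i = fit.params[1], fit.bse[1]
                z = eff / se_i
                rows.append((eff, se_i, z, 2 * stats.norm.sf(abs(z)),
                             n - xi.shape[1]))
            except Exception:
                rows.append((np.nan, np.nan, np.nan, np.nan, np.nan))
        out = pd.DataFrame(
            rows, index=meth.index, columns=["effect", "se", "t", "p", "df"]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out["skipped"] = constant
    out.loc[constant, ["effect", "se", "t", "p"]] = np.nan
    out["p"] = out["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
    out.loc[out["effect"].isna(), "p"] = np.nan
    out.index.name = "cpg"
    return out


def genomic_inflation_lambda(p_values) -> float:
    """Genomic inflation factor: median observed chi-square (1 df, from the
    p-values) divided by the null chi-square median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a QQ plot.

    Observed p-values are sorted ascending; expected quantile i (1-based) is
    (i - 0.5)/n. Duplicate p-values each keep their own point.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = p.size
    exp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"expected": -np.log10(exp), "observed": -np.log10(obs)}
    )


def annotate_hits(
    result: pd.DataFrame, annotation: pd.DataFrame, p_threshold: float = 1e-5
) -> pd.DataFrame:
    """Report CpGs with p < ``p_threshold`` joined to their annotation,
    ordered by ascending p. CpGs without annotation get blank gene/feature
    fields rather than being dropped."""
    if not 0 < p_threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hits = result[result["p"] < p_threshold].sort_values("p")
    ann = annotation.reindex(hits.index)
    out = pd.concat([ann, hits[["effect", "se", "t", "p"]]], axis=1)
    for col in ("gene", "feature", "island_relation"):
        if col in out.columns:
            out[col] = out[col].fillna("")
    out.index.name = "cpg"
    return out


def manhattan_data(result: pd.DataFrame, annotation: pd.DataFrame,
                   label_threshold: float = 1e-5) -> pd.DataFrame:
    """Plot-ready Manhattan table: chromosome, cumulative genome coordinate,
    -log10 p, and a gene label wherever p < ``label_threshold``.

    Chromosome blocks are laid out 1..22; within a chromosome the cumulative
    coordinate is the raw position plus the summed spans of the preceding
    chromosomes. Every CpG in ``result`` must be annotated.
    """
    missing = result.index.difference(annotation.index)
    if len(missing) > 0:
        raise ValueError(f"unannotated CpGs: {sorted(missing)[:10]}")
    ann = annotation.loc[result.index]
    df = pd.DataFrame(
        {
            "chr": ann["chr"].astype(int),
            "pos": ann["pos"].astype(int),
            "neglog10p": -np.log10(result["p"]),
            "gene": ann.get("gene", pd.Series("", index=ann.index)).fillna(""),
            "p": result["p"],
        }
    )
    df = df.sort_values(["chr", "pos"])
    offset, offsets = 0, {}
    for c in sorted(df["chr"].unique()):
        offsets[c] = offset
        offset += int(df.loc[df["chr"] == c, "pos"].max())
    df["cum_pos"] = df["pos"] + df["chr"].map(offsets)
    df["label"] = np.where(df["p"] < label_threshold, df["gene"], "")
    df.index.name = "cpg"
    return df.drop(columns="p")
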