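"""Linear epigenetic clocks, age acceleration and clock/trait analyses.

A clock is a named linear model over CpG beta values: raw = intercept +
sum(w_i * beta_i), optionally passed through the inverse Horvath age
transform. Output units may be years (age clocks), kilobases (DNAm telomere
length) or a unitless rate (pace-of-aging clocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ClockModel",
    "horvath_forward",
    "horvath_inverse",
    "apply_clock",
    "age_acceleration",
    "clock_trait_matrix",
    "stepwise_clock_regression",
]


@dataclass
class ClockModel:
    """A linear epigenetic clock.

    transform is "identity" or "horvath:<adult_age>"; the Horvath transform
    maps raw model output back to years via :func:`horvath_inverse`.
    """

    name: str
    intercept: float
    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    transform: str = "identity"
    units: str = "years"

    def __post_init__(self):
        kind, adult = _parse_transform(self.transform)
        if kind == "horvath" and adult <= 0:
            raise ValueError("horvath adult_age must be positive")
        if self.weights.index.has_duplicates:
            raise ValueError("duplicate CpG ids in clock weights")


def _parse_transform(spec: str) -> tuple[str, float]:
    if spec == "identity":
        return "identity", 0.0
    if spec.startswith("horvath:"):
        return "horvath", float(spec.split(":", 1)[1])
    raise ValueError(f"unknown transform spec {spec!r}")


def horvath_forward(age, adult_age: float = 20.0):
    """Horvath's age transform: log((age+1)/(adult_age+1)) below adult_age,
    linear (age - adult_age)/(adult_age + 1) above. Continuous and strictly
    increasing."""
    age = np.asarray(age, dtype=float)
    out = np.where(
        age <= adult_age,
        np.log((age + 1.0) / (adult_age + 1.0)),
        (age - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def horvath_inverse(x, adult_age: float = 20.0):
    """Inverse of :func:`horvath_forward`: (adult_age+1)*exp(x) - 1 for x < 0,
    x*(adult_age+1) + adult_age for x >= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < 0,
        (adult_age + 1.0) * np.exp(x) - 1.0,
        x * (adult_age + 1.0) + adult_age,
    )
    return out if out.ndim else float(out)


def apply_clock(
    beta: pd.DataFrame, model: ClockModel, missing_policy: str = "error"
) -> pd.Series:
    """Apply a clock to a beta matrix, returning one value per sample.

    Under the ``error`` policy every clock CpG must be present; under
    ``mean_impute`` a missing CpG's beta is imputed per sample with the mean
    beta of the clock CpGs that are present.
    """
    if missing_policy not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    kind, adult = _parse_transform(model.transform)
    if len(model.weights) == 0:
        raw = pd.Series(model.intercept, index=beta.columns, dtype=float)
    else:
        present = model.weights.index.intersection(beta.index)
        missing = model.weights.index.difference(beta.index)
        if len(missing) > 0 and missing_policy == "error":
            raise ValueError(
                f"clock {model.name!r}: {len(missing)} CpGs missing from "
                f"matrix, e.g. {sorted(missing)[:5]}"
            )
        sub = beta.loc[present].to_numpy(dtype=float)
        raw_vals = model.intercept + model.weights.loc[present].to_numpy() @ sub
        if len(missing) > 0:
            fill = sub.mean(axis=0) if len(present) else np.full(beta.shape[1], 0.5)
            raw_vals = raw_vals + float(model.weights.loc[missing].sum()) * fill
        raw = pd.Series(raw_vals, index=beta.columns)
    if kind == "horvath":
        raw = pd.Series(horvath_inverse(raw.to_numpy(), adult), index=raw.index)
    raw.name = model.name
    return raw


def age_acceleration(epiage: pd.Series, chronage: pd.Series) -> pd.Series:
    """Age acceleration: residuals of epigenetic age regressed (OLS, with
    intercept) on chronological age. Residuals have mean zero and are
    invariant to adding a constant to the epigenetic ages."""
    epiage, chronage = epiage.align(chronage, join="inner")
    if len(epiage) < 3:
        raise ValueError("need at least 3 samples")
    x = chronage.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant; acceleration undefined")
    design = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(design, epiage.to_numpy(dtype=float), rcond=None)
    resid = epiage.to_numpy(dtype=float) - design @ coef
    return pd.Series(resid, index=epiage.index, name="age_acceleration")


def _normalish(x: np.ndarray) -> bool:
    # Shapiro-Wilk at alpha = 0.05; degenerate inputs are never "normal"
    if np.unique(x).size < 3:
        return False
    return stats.shapiro(x).pvalue > 0.05


def clock_trait_matrix(
    ages: pd.DataFrame, sheet: pd.DataFrame, traits
) -> pd.DataFrame:
    """Correlate every clock's age estimate with every numeric trait.

    Pearson when both variables pass a Shapiro-Wilk normality screen
    (alpha = 0.05), Spearman otherwise; the method used is recorded per cell.
    Constant traits are flagged (method="constant") instead of raising.
    Returns a long DataFrame: clock, trait, r, p, method, n.
    """
    rows = []
    for clock in ages.columns:
        for trait in traits:
            pair = pd.concat([ages[clock], sheet[trait]], axis=1).dropna()
            if len(pair) < 4:
                raise ValueError(f"fewer than 4 complete pairs for {trait!r}")
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                rows.append((clock, trait, np.nan, np.nan, "constant", len(pair)))
                continue
            if _normalish(x) and _normalish(y):
                r, p = stats.pearsonr(x, y)
                method = "pearson"
            else:
                r, p = stats.spearmanr(x, y)
                method = "spearman"
            rows.append((clock, trait, float(r), float(p), method, len(pair)))
    return pd.DataFrame(rows, columns=["clock", "trait", "r", "p", "method", "n"])


def stepwise_clock_regression(
    epiage: pd.Series,
    sheet: pd.DataFrame,
    candidates,
    criterion: str = "aic",
) -> pd.DataFrame:
    """Bidirectional stepwise linear regression of epigenetic age on
    candidate phenotypes.

    Starts from the intercept-only model and, at each step, applies the
    single addition or removal that most improves the information criterion
    (AIC by default, BIC selectable), stopping when no move improves it.
    Returns the retained terms (including the intercept) with coefficient,
    SE, Wald 95% CI and p-value.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    data = pd.concat([epiage.rename("__y__"), sheet[candidates]], axis=1).dropna()
    n = len(data)
    if n <= len(candidates) + 2:
        raise ValueError("too few samples for the candidate set")
    x_all = data[candidates].to_numpy(dtype=float)
    if len(candidates) >= 2 and np.linalg.matrix_rank(
        np.column_stack([np.ones(n), x_all])
    ) < len(candidates) + 1:
        raise ValueError("perfect collinearity among candidates")
    ic = (lambda f: f.aic) if criterion == "aic" else (lambda f: f.bic)
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")

    y = data["__y__"].to_numpy(dtype=float)

    def fit(terms):
        x = sm.add_constant(data[list(terms)], has_constant="add")
        return sm.OLS(y, x).fit()

    current: list[str] = []
    best_fit = fit(current)
    best_ic = ic(best_fit)
    improved = True
    while improved:
        improved = False
        moves = [("add", t) for t in candidates if t not in current]
        moves += [("drop", t) for t in current]
        best_move = None
        for kind, term in moves:
            trial = current + [term] if kind == "add" else [t for t in current if t != term]
            try:
                f = fit(trial)
            except Exception:
                continue
            if ic(f) < best_ic - 1e-10:
                best_ic, best_move, best_fit_trial = ic(f), (kind, term, trial), f
        if best_move is not None:
            current = best_move[2]
            best_fit = best_fit_trial
            improved = True

    ci = best_fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "term": best_fit.params.index,
            "coef": best_fit.params.to_numpy(),
            "se": best_fit.bse.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": best_fit.pvalues.to_numpy(),
        }
    )
    return out.reset_index(drop=True)
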