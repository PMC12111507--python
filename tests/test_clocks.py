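"""Clock application, Horvath transform, acceleration, trait analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eopmeth.clocks import (ClockModel, age_acceleration, apply_clock,
                            clock_trait_matrix, horvath_forward,
                            horvath_inverse, stepwise_clock_regression)


def beta_frame(vals, cpgs, samples=None):
    samples = samples or [f"S{i}" for i in range(np.shape(vals)[1])]
    return pd.DataFrame(vals, index=cpgs, columns=samples)


def test_intercept_only_clock_is_constant():
    model = ClockModel("const", intercept=7.5)
    beta = beta_frame(np.random.default_rng(0).uniform(0, 1, (3, 5)),
                      ["a", "b", "c"])
    assert (apply_clock(beta, model) == 7.5).all()


def test_horvath_transform_reference_points():
    assert horvath_inverse(0.0, 20.0) == pytest.approx(20.0)
    assert horvath_inverse(-np.log(21.0), 20.0) == pytest.approx(0.0, abs=1e-12)
    for x in (-2.0, -0.5, 0.0, 1.3):
        assert horvath_forward(horvath_inverse(x, 20.0), 20.0) == pytest.approx(x)
    # continuity and monotonicity across the adult-age knee
    grid = np.linspace(-3, 3, 301)
    ages = horvath_inverse(grid, 20.0)
    assert (np.diff(ages) > 0).all()


def test_horvath_clock_output_at_zero_raw():
    model = ClockModel("h", intercept=0.0, transform="horvath:20")
    beta = beta_frame([[0.2, 0.8]], ["cg1"])
    model = ClockModel("h", intercept=0.0,
                       weights=pd.Series({"cg1": 0.0}), transform="horvath:20")
    assert (apply_clock(beta, model) == 20.0).all()


def test_apply_clock_linear_in_weights():
    rng = np.random.default_rng(1)
    beta = beta_frame(rng.uniform(0.1, 0.9, (4, 6)), list("abcd"))
    w = pd.Series(rng.normal(size=4), index=list("abcd"))
    m1 = ClockModel("c1", intercept=3.0, weights=w)
    m2 = ClockModel("c2", intercept=3.0, weights=2 * w)
    r1 = apply_clock(beta, m1) - 3.0
    r2 = apply_clock(beta, m2) - 3.0
    assert np.allclose(r2, 2 * r1)


def test_apply_clock_missing_policy():
    beta = beta_frame([[0.5, 0.6], [0.3, 0.4]], ["a", "b"])
    model = ClockModel("c", intercept=0.0,
                       weights=pd.Series({"a": 1.0, "zzz": 1.0}))
    with pytest.raises(ValueError, match="zzz"):
        apply_clock(beta, model, missing_policy="error")
    imputed = apply_clock(beta, model, missing_policy="mean_impute")
    # missing CpG imputed with mean beta of present clock CpGs per sample
    assert np.allclose(imputed, [0.5 + 0.5, 0.6 + 0.6])


def test_age_acceleration_residual_properties():
    chron = pd.Series([10.0, 12, 14, 16, 18], index=list("abcde"))
    assert np.allclose(age_acceleration(chron, chron), 0.0, atol=1e-12)
    assert np.allclose(age_acceleration(chron + 5.0, chron), 0.0, atol=1e-12)
    rng = np.random.default_rng(2)
    chron50 = pd.Series(rng.uniform(10, 18, 50),
                        index=[f"S{i}" for i in range(50)])
    epi = chron50 + rng.normal(0, 0.5, 50)
    epi.iloc[13] += 10.0  # planted fast ager
    resid = age_acceleration(epi, chron50)
    assert resid.idxmax() == "S13"
    assert abs(resid.mean()) < 1e-10
    with pytest.raises(ValueError):
        age_acceleration(epi, pd.Series(12.0, index=epi.index))


def test_clock_trait_matrix_methods_and_values():
    rng = np.random.default_rng(3)
    n = 100
    ages = pd.DataFrame({"clockA": rng.normal(14, 2, n)},
                        index=[f"S{i}" for i in range(n)])
    sheet = pd.DataFrame(
        {
            "linear": 2.0 * ages["clockA"] + 1.0,
            "independent": rng.normal(size=n),
            "binary": rng.integers(0, 2, n),
            "flat": 1.0,
        },
        index=ages.index,
    )
    out = clock_trait_matrix(ages, sheet, ["linear", "independent", "binary", "flat"])
    row = out.set_index("trait")
    assert row.loc["linear", "r"] == pytest.approx(1.0)
    assert row.loc["linear", "p"] < 1e-10
    assert abs(row.loc["independent", "r"]) < 0.25
    assert row.loc["binary", "method"] == "spearman"
    assert row.loc["flat", "method"] == "constant"
    # symmetry of the correlation under variable swap
    r_swap = clock_trait_matrix(
        pd.DataFrame({"clockA": sheet["independent"]}),
        pd.DataFrame({"t": ages["clockA"]}), ["t"],
    )["r"].iloc[0]
    assert r_swap == pytest.approx(row.loc["independent", "r"])


def test_stepwise_retains_strong_predictor_bic():
    # R^2 ~ 0.9 single predictor among 4 noise candidates, BIC criterion:
    # the strong predictor survives in every replicate; the exact model
    # {a} is selected at the rate binomial theory allows (each noise
    # candidate clears the BIC bar with prob ~0.034 at n=100, so
    # P(exact) ~ 0.966^4 ~ 0.87; 75 is ~3.5 sigma below 100*0.87)
    exact, kept = 0, 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        y = pd.Series(3.0 * x["a"] + rng.normal(0, 1, 100))
        sel = stepwise_clock_regression(y, x, list("abcde"), criterion="bic")
        terms = set(sel["term"]) - {"const"}
        kept += "a" in terms
        exact += terms == {"a"}
    assert kept == 100
    assert exact >= 75


def test_stepwise_pure_noise_keeps_intercept_only_bic():
    kept_empty = 0
    for seed in range(60):
        rng = np.random.default_rng(1000 + seed)
        x = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = pd.Series(rng.normal(size=100))
        sel = stepwise_clock_regression(y, x, list("abcd"), criterion="bic")
        kept_empty += set(sel["term"]) == {"const"}
    assert kept_empty > 30  # majority of replicates


def test_stepwise_ci_identity_and_errors():
    rng = np.random.default_rng(4)
    x = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
    y = pd.Series(2.0 * x["a"] - x["b"] + rng.normal(0, 0.5, 60))
    sel = stepwise_clock_regression(y, x, list("abc"))
    retained = sel[sel["term"] != "const"]
    assert len(retained) >= 2
    df = 60 - len(sel)
    tcrit = stats.t.ppf(0.975, df)
    assert np.allclose(retained["ci_low"], retained["coef"] - tcrit * retained["se"])
    assert np.allclose(retained["ci_high"], retained["coef"] + tcrit * retained["se"])

    x["dup"] = x["a"]
    with pytest.raises(ValueError, match="collinear"):
        stepwise_clock_regression(y, x, ["a", "b", "c", "dup"])
    with pytest.raises(ValueError):
        stepwise_clock_regression(y, x, [])
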