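"""Synthetic DNA-methylation cohort generator with known ground truth.

The generator emulates a small psychiatric case/control cohort profiled on a
methylation array: a CpG x sample beta matrix, a sample sheet of phenotypes,
and the ground truth used to plant the signal. Betas are built on the logit
scale (Gaussian effects pushed through the logistic function), which keeps
every value strictly inside (0, 1) without clipping and makes the M-value
transform exact.

Structure of a simulated beta value, on the logit scale:

    logit(beta_ij) = baseline_i + group effect (causal CpGs only)
                     + age slope (clock CpGs only)
                     + latent batch loadings . sample scores
                     + residual noise

Clock CpGs carry a dedicated id prefix (``ck``) so a clock fixture generated
from the same seed can be applied to the cohort and recover the true ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clocks import ClockModel, horvath_forward

__all__ = ["SimConfig", "GroundTruth", "generate_cohort",
           "generate_clock_fixture", "generate_annotation"]

_DEF_AGE_RANGE = (10.0, 18.0)

# logit-scale slope range of clock CpGs per unit normalized age, and the
# baseline band keeping clock betas mid-range where the logistic is steep
_CLOCK_B_RANGE = (0.6, 1.0)
_CLOCK_A_RANGE = (-0.5, 0.5)

# documented group -> phenotype coefficients (see docs/methods.md)
_PHENO_LOGIT = {
    "mood": (1.0, 0.8),
    "anxiety_stress": (-0.6, 1.9),
    "conduct": (-0.2, 0.0),
    "neurodev": (-1.0, -0.8),
    "eating": (-2.5, 1.5),
    "panic": (-2.0, 2.2),
    "auditory_hallucinations": (-2.2, 2.6),
    "visual_hallucinations": (-2.2, 2.4),
    "tactile_hallucinations": (-2.6, 2.2),
    "negative_symptoms": (-2.0, 2.3),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a 12-case / 11-control adolescent cohort with eight
    planted differentially methylated CpGs of beta-scale effect 0.15,
    ten thousand CpGs, two latent batch components and an age-responsive
    clock CpG panel.
    """

    n_cases: int = 12
    n_controls: int = 11
    n_cpgs: int = 10_000
    n_causal: int = 8
    effect_delta: float = 0.15
    n_latent: int = 2
    latent_sd: float = 0.3
    age_range: tuple = _DEF_AGE_RANGE
    clock_cpg_count: int = 50
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cases, self.n_controls, self.n_cpgs) <= 0:
            raise ValueError("sample and CpG counts must be positive")
        if self.n_causal < 0 or self.n_latent < 0 or self.clock_cpg_count < 0:
            raise ValueError("n_causal, n_latent, clock_cpg_count must be >= 0")
        if self.n_causal + self.clock_cpg_count > self.n_cpgs:
            raise ValueError("n_causal + clock_cpg_count exceeds n_cpgs")
        if not 0 <= self.effect_delta <= 0.4:
            # baselines are drawn in [0.3, 0.7]; delta/2 <= 0.2 keeps group
            # means inside (0.1, 0.9) so the logit construction never saturates
            raise ValueError("effect_delta must be in [0, 0.4]")
        if self.noise_sd < 0 or self.latent_sd < 0:
            raise ValueError("dispersions must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be (min, max) with min < max")


@dataclass
class GroundTruth:
    """What was planted: causal CpGs and their signed beta-scale effects,
    latent loadings, true ages and the clock CpG panel."""

    causal_cpg_ids: list
    effects: pd.Series
    latent_loadings: pd.DataFrame
    true_ages: pd.Series
    clock_cpg_ids: list = field(default_factory=list)


def _streams(seed: int):
    cohort, clock, pheno = np.random.SeedSequence(seed).spawn(3)
    return (np.random.default_rng(cohort), np.random.default_rng(clock),
            np.random.default_rng(pheno))


def _clock_params(n: int, rng: np.random.Generator):
    a = rng.uniform(*_CLOCK_A_RANGE, n)
    sgn = rng.choice([-1.0, 1.0], n)
    b = sgn * rng.uniform(*_CLOCK_B_RANGE, n)
    return a, b


def _noise_sd_logit(p0: np.ndarray, noise_sd: float) -> np.ndarray:
    # beta-scale residual SD mapped to the logit scale via d(beta)/d(logit)
    # = p(1-p); capped so near-boundary CpGs do not explode
    return np.minimum(noise_sd / (p0 * (1.0 - p0)), 0.8)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a beta matrix, sample sheet and ground truth.

    Cases and controls differ in expectation by ``effect_delta`` (randomly
    signed) at the causal CpGs only; clock CpGs respond linearly (on the
    logit scale) to age; all CpGs receive latent batch structure and residual
    noise. Identical config (same seed) gives identical output.
    """
    rng, rng_clock, rng_pheno = _streams(config.seed)
    n = config.n_cases + config.n_controls
    group = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    n_bg = config.n_cpgs - config.clock_cpg_count
    cpg_ids = [f"cg{i:08d}" for i in range(n_bg)] + [
        f"ck{i:05d}" for i in range(config.clock_cpg_count)
    ]

    # phenotypes
    lo, hi = config.age_range
    age = rng_pheno.uniform(lo, hi, n)
    sex = rng_pheno.integers(0, 2, n).astype(int)
    gaf = np.clip(np.rint(75 - 30 * group + rng_pheno.normal(0, 8, n)), 1, 100)
    admissions = rng_pheno.poisson(0.2 + 1.0 * group)
    schooling = np.clip(np.rint(age - 6 + rng_pheno.normal(0, 1.2, n)), 0, 14)
    comorbidity = 1 + rng_pheno.poisson(0.6 + 0.6 * group)
    bmi_z = 0.4 * group + rng_pheno.normal(0.6, 1.2, n)
    sheet = pd.DataFrame(
        {
            "group": group.astype(int),
            "age": age,
            "sex": sex,
            "schooling": schooling.astype(int),
            "bmi_z": bmi_z,
            "gaf": gaf.astype(int),
            "admissions": admissions.astype(int),
            "admissions_flag": (admissions > 0).astype(int),
            "comorbidity_count": comorbidity.astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for name, (b0, b1) in _PHENO_LOGIT.items():
        sheet[name] = rng_pheno.binomial(1, expit(b0 + b1 * group))

    # baseline methylation and planted effects
    p0 = rng.uniform(0.1, 0.9, config.n_cpgs)
    causal_idx = (
        rng.choice(n_bg, config.n_causal, replace=False)
        if config.n_causal
        else np.array([], dtype=int)
    )
    p0[causal_idx] = rng.uniform(0.3, 0.7, config.n_causal)
    signs = rng.choice([-1.0, 1.0], config.n_causal)
    effects = signs * config.effect_delta

    mu = np.tile(logit(p0)[:, None], (1, n))
    for j, idx in enumerate(causal_idx):
        mu[idx] = np.where(
            group == 1,
            logit(p0[idx] + effects[j] / 2.0),
            logit(p0[idx] - effects[j] / 2.0),
        )

    # age-responsive clock CpGs (same parameters as generate_clock_fixture)
    if config.clock_cpg_count:
        a, b = _clock_params(config.clock_cpg_count, rng_clock)
        s = (age - (lo + hi) / 2.0) / ((hi - lo) / 2.0)
        mu[n_bg:] = a[:, None] + b[:, None] * s[None, :]
        p0[n_bg:] = expit(a)

    loadings = rng.normal(0.0, config.latent_sd, (config.n_cpgs, config.n_latent))
    scores = rng.normal(0.0, 1.0, (config.n_latent, n))
    noise = rng.normal(0.0, 1.0, (config.n_cpgs, n)) * _noise_sd_logit(
        p0, config.noise_sd
    )[:, None]

    beta = expit(mu + loadings @ scores + noise)
    beta_df = pd.DataFrame(beta, index=pd.Index(cpg_ids, name="cpg"),
                           columns=sample_ids)

    truth = GroundTruth(
        causal_cpg_ids=[cpg_ids[i] for i in causal_idx],
        effects=pd.Series(effects, index=[cpg_ids[i] for i in causal_idx],
                          name="effect", dtype=float),
        latent_loadings=pd.DataFrame(
            loadings, index=beta_df.index,
            columns=[f"LC{i + 1}" for i in range(config.n_latent)],
        ),
        true_ages=pd.Series(age, index=sample_ids, name="age"),
        clock_cpg_ids=cpg_ids[n_bg:],
    )
    return beta_df, sheet, truth


def generate_clock_fixture(
    n_cpgs: int,
    transform: str = "identity",
    seed: int = 0,
    age_range: tuple = _DEF_AGE_RANGE,
    adult_age: float = 20.0,
) -> ClockModel:
    """Build a clock whose weights invert the cohort's planted age signal.

    Sharing ``seed`` with :func:`generate_cohort` reproduces the clock CpG
    parameters, so applying the fixture to that cohort recovers the true ages
    (up to noise). With ``n_cpgs`` = 0 the clock is the constant intercept at
    the mid-range age. Each clock CpG contributes an unbiased linear read-out
    of normalized age obtained from the local slope of the logistic curve.
    """
    lo, hi = age_range
    mid, hw = (lo + hi) / 2.0, (hi - lo) / 2.0
    if transform == "identity":
        slope, center = hw, mid
    elif transform.startswith("horvath:") or transform == "horvath":
        if transform == "horvath":
            transform = f"horvath:{adult_age:g}"
        adult_age = float(transform.split(":", 1)[1])
        f_lo = horvath_forward(lo, adult_age)
        f_hi = horvath_forward(hi, adult_age)
        slope, center = (f_hi - f_lo) / 2.0, (f_hi + f_lo) / 2.0
    else:
        raise ValueError(f"unknown transform spec {transform!r}")

    if n_cpgs == 0:
        return ClockModel(name=f"fixture_{transform}", intercept=center,
                          weights=pd.Series(dtype=float), transform=transform)

    _, rng_clock, _ = _streams(seed)
    a, b = _clock_params(n_cpgs, rng_clock)
    p = expit(a)
    deriv = p * (1.0 - p)
    ids = [f"ck{i:05d}" for i in range(n_cpgs)]
    w = slope / (n_cpgs * deriv * b)
    intercept = center - float(np.sum(w * p))
    return ClockModel(
        name=f"fixture_{transform}",
        intercept=intercept,
        weights=pd.Series(w, index=ids),
        transform=transform,
    )


def generate_annotation(cpg_ids, seed: int = 0) -> pd.DataFrame:
    """Synthetic CpG annotation: chromosome 1-22, positive 1-based position,
    gene symbol (blank for ~15% of sites), feature class and island relation.
    One row per id; duplicate ids are an error."""
    ids = list(cpg_ids)
    if not ids:
        raise ValueError("empty CpG id list")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate CpG ids")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA110)))
    df = pd.DataFrame(
        {
            "gene": [
                "" if rng.random() < 0.15 else f"GENE{rng.integers(1, 5000):04d}"
                for _ in ids
            ],
            "chr": rng.integers(1, 23, len(ids)),
            "pos": rng.integers(10_000, 100_000_000, len(ids)),
            "feature": rng.choice(["Body", "Exon", "TSS200", "intergenic"], len(ids)),
            "island_relation": rng.choice(
                ["Island", "N Shore", "S Shore", "Open Sea"], len(ids)
            ),
        },
        index=pd.Index(ids, name="cpg"),
    )
    # unique positions within a chromosome (the Manhattan layout assumes it)
    df["pos"] = df["pos"] + df.groupby(["chr", "pos"]).cumcount()
    return df
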