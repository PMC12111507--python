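"""Pipeline driver: preprocess -> EWAS -> MRS -> clocks -> cohort stats.

A :class:`PipelineConfig` names the input files and stage parameters; the
driver runs every stage, writes each stage's outputs under ``out_dir`` and
appends a row-count entry per stage to a run manifest. Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as eio
from .clocks import (age_acceleration, apply_clock, clock_trait_matrix,
                     stepwise_clock_regression)
from .ewas import (annotate_hits, fit_cpg_association,
                   genomic_inflation_lambda, manhattan_data, qq_data)
from .mrs import DEFAULT_THRESHOLDS, associate_mrs, build_profile
from .preprocess import (beta_to_m, estimate_surrogate_variables,
                         exclude_blacklist, filter_low_variability)

__all__ = ["PipelineConfig", "run_pipeline"]

_DEFAULT_TABLE1 = [
    ["age", "continuous"],
    ["schooling", "continuous"],
    ["bmi_z", "continuous"],
    ["gaf", "continuous"],
    ["admissions", "count"],
    ["sex", "categorical"],
    ["admissions_flag", "categorical"],
    ["anxiety_stress", "categorical"],
    ["mood", "categorical"],
    ["eating", "categorical"],
]

_DEFAULT_PHENOTYPES = [
    "panic", "auditory_hallucinations", "visual_hallucinations",
    "tactile_hallucinations", "negative_symptoms", "gaf",
]


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    beta: str
    samples: str
    annotation: str
    out_dir: str
    blacklist: str | None = None
    clock_files: list = field(default_factory=list)
    seed: int = 0
    sd_threshold: float = 0.01
    m_offset: float = 1e-6
    sv_k: int = 5
    ewas_mode: str = "methylation_as_outcome"
    hit_threshold: float = 1e-5
    mrs_thresholds: list = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    mrs_phenotypes: list = field(default_factory=lambda: list(_DEFAULT_PHENOTYPES))
    clock_traits: list = field(default_factory=lambda: ["age", "gaf", "admissions"])
    stepwise_candidates: list = field(
        default_factory=lambda: ["age", "sex", "schooling", "comorbidity_count",
                                 "admissions_flag"]
    )
    table1_spec: list = field(default_factory=lambda: [list(r) for r in _DEFAULT_TABLE1])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``out_dir/manifest.json``). On a stage failure the manifest accumulated so
    far is still written before the error propagates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "version": __version__,
        "stages": [],
        "warnings": [],
    }

    def stage(name, **counts):
        manifest["stages"].append({"stage": name, **counts})

    def flush():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    try:
        beta = eio.read_beta_matrix(config.beta)
        sheet = eio.read_sample_sheet(config.samples)
        sheet = sheet.loc[beta.columns]
        annotation = eio.read_annotation(config.annotation)
        stage("load", cpgs=int(beta.shape[0]), samples=int(beta.shape[1]))

        # --- preprocess -----------------------------------------------------
        filtered, removed = filter_low_variability(beta, config.sd_threshold)
        if config.blacklist:
            filtered = exclude_blacklist(filtered, eio.read_blacklist(config.blacklist))
        m = beta_to_m(filtered, config.m_offset)
        sv = estimate_surrogate_variables(m, sheet["group"], k=config.sv_k)
        sv.to_csv(out / "surrogate_variables.csv", float_format=eio.FLOAT_FMT)
        stage("preprocess", cpgs_in=int(beta.shape[0]),
              low_variability_removed=len(removed), cpgs_out=int(m.shape[0]))

        # --- EWAS -----------------------------------------------------------
        covariates = pd.concat([sheet[["age", "sex"]], sv], axis=1)
        result = fit_cpg_association(
            filtered, sheet["group"], covariates, mode=config.ewas_mode
        )
        lam = genomic_inflation_lambda(result["p"].dropna())
        full = annotation.reindex(result.index).join(result)
        full.to_csv(out / "ewas.tsv", sep="\t", float_format=eio.FLOAT_FMT)
        qq_data(result["p"].dropna()).to_csv(
            out / "qq.csv", index=False, float_format=eio.FLOAT_FMT
        )
        manhattan_data(result.dropna(subset=["p"]), annotation,
                       config.hit_threshold).to_csv(
            out / "manhattan.csv", float_format=eio.FLOAT_FMT
        )
        hits = annotate_hits(result, annotation, config.hit_threshold)
        hits.to_csv(out / "hits.tsv", sep="\t", float_format=eio.FLOAT_FMT)
        stage("ewas", cpgs=int(result.shape[0]), hits=int(hits.shape[0]),
              genomic_inflation_lambda=round(lam, 6))

        # --- MRS ------------------------------------------------------------
        profile = build_profile(m, result.dropna(subset=["p"]),
                                config.mrs_thresholds)
        scores = pd.concat(
            {"raw": profile.raw, "z": profile.z}, axis=1
        )
        scores.columns = [f"{kind}_{thr:g}" for kind, thr in scores.columns]
        scores.to_csv(out / "mrs_scores.csv", float_format=eio.FLOAT_FMT)
        assoc_frames = []
        for pheno in config.mrs_phenotypes:
            if pheno not in sheet.columns:
                manifest["warnings"].append(f"mrs: phenotype {pheno!r} missing")
                continue
            a = associate_mrs(profile, sheet, pheno)
            a.insert(0, "phenotype", pheno)
            assoc_frames.append(a)
        if assoc_frames:
            pd.concat(assoc_frames, ignore_index=True).to_csv(
                out / "mrs_assoc.csv", index=False, float_format=eio.FLOAT_FMT
            )
        stage("mrs", thresholds=len(config.mrs_thresholds),
              n_cpgs_per_threshold={f"{k:g}": v for k, v in profile.n_cpgs.items()})

        # --- clocks ---------------------------------------------------------
        if config.clock_files:
            ages = pd.DataFrame(index=beta.columns)
            accel = pd.DataFrame(index=beta.columns)
            for path in config.clock_files:
                model = eio.read_clock_model(path)
                est = apply_clock(beta, model, missing_policy="mean_impute")
                ages[model.name] = est
                accel[model.name] = age_acceleration(est, sheet["age"])
            ages.to_csv(out / "ages.csv", float_format=eio.FLOAT_FMT)
            accel.to_csv(out / "age_acceleration.csv", float_format=eio.FLOAT_FMT)
            traits = [t for t in config.clock_traits if t in sheet.columns]
            clock_trait_matrix(ages, sheet, traits).to_csv(
                out / "table2.csv", index=False, float_format=eio.FLOAT_FMT
            )
            table3 = []
            for clock in ages.columns:
                sel = stepwise_clock_regression(
                    ages[clock], sheet,
                    [c for c in config.stepwise_candidates if c in sheet.columns],
                )
                sel.insert(0, "clock", clock)
                table3.append(sel)
            pd.concat(table3, ignore_index=True).to_csv(
                out / "table3.csv", index=False, float_format=eio.FLOAT_FMT
            )
            stage("clocks", clocks=len(config.clock_files))

        # --- cohort statistics ----------------------------------------------
        from .cohortstats import table1_report

        spec = [tuple(r) for r in config.table1_spec if r[0] in sheet.columns]
        table1_report(sheet, spec).to_csv(
            out / "table1.csv", index=False, float_format=eio.FLOAT_FMT
        )
        stage("stats", variables=len(spec))
    except Exception:
        flush()
        raise
    flush()
    return manifest
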