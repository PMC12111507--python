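"""Readers and writers for the plain-text interchange formats.

Beta/M matrices travel as TSV or CSV (CpG ids in the first column, sample ids
in the header), transparently gzipped when the path ends in ``.gz``. Clock
models use a small CSV dialect with ``#key=value`` header directives followed
by ``cpg,weight`` records.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ClockModel

__all__ = [
    "read_beta_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_blacklist",
    "read_clock_model",
    "write_clock_model",
]

FLOAT_FMT = "%.10g"


def _sep(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_beta_matrix(path) -> pd.DataFrame:
    """Read and validate a CpG x sample beta matrix.

    Duplicate CpG ids, non-numeric cells and values outside [0, 1] are
    errors; the offending cell is named in the message.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "cpg"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate CpG ids: {dups[:5]}")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as e:
        raise ValueError(f"non-numeric value in beta matrix: {e}") from None
    bad = np.argwhere(np.isnan(vals) | (vals < 0) | (vals > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"beta value out of range at CpG {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {vals[i, j]}"
        )
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a beta or M matrix (TSV/CSV by extension, gzip by suffix)."""
    df.to_csv(path, sep=_sep(path), float_format=FLOAT_FMT)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV: first column is the sample id."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample sheet")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, float_format=FLOAT_FMT)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "cpg"
    if df.index.has_duplicates:
        raise ValueError("duplicate CpG ids in annotation")
    return df


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep=_sep(path))


def read_blacklist(path) -> list[str]:
    """One CpG id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_clock_model(path) -> ClockModel:
    """Parse a clock coefficient file.

    Format: ``#name=``, ``#intercept=``, ``#transform=identity|horvath:20``,
    ``#units=`` directives, then a ``cpg,weight`` header and records.
    """
    meta: dict[str, str] = {}
    records: list[tuple[str, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif line.lower().startswith("cpg,"):
            continue
        else:
            cpg, _, w = line.partition(",")
            records.append((cpg.strip(), float(w)))
    if "intercept" not in meta:
        raise ValueError(f"{path}: missing #intercept= directive")
    ids = [c for c, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate CpG weight rows")
    weights = pd.Series(dict(records), dtype=float).reindex(ids)
    return ClockModel(
        name=meta.get("name", Path(path).stem),
        intercept=float(meta["intercept"]),
        weights=weights,
        transform=meta.get("transform", "identity"),
        units=meta.get("units", "years"),
    )


def write_clock_model(model: ClockModel, path) -> None:
    lines = [
        f"#name={model.name}",
        f"#intercept={model.intercept!r}",
        f"#transform={model.transform}",
        f"#units={model.units}",
        "cpg,weight",
    ]
    lines += [f"{c},{w!r}" for c, w in model.weights.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth, path) -> None:
    """Serialize a GroundTruth to JSON (loadings included column-wise)."""
    payload = {
        "causal_cpg_ids": list(truth.causal_cpg_ids),
        "effects": {k: float(v) for k, v in truth.effects.items()},
        "true_ages": {k: float(v) for k, v in truth.true_ages.items()},
        "clock_cpg_ids": list(truth.clock_cpg_ids),
        "latent_loadings": {
            col: truth.latent_loadings[col].round(10).tolist()
            for col in truth.latent_loadings.columns
        },
        "latent_cpg_order": list(truth.latent_loadings.index),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
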