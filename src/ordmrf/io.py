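"""Data ingestion, parameter serialization, and run artifacts.

Ordinal data arrive as delimited text with a header row of variable names
and integer category cells. Rows with any missing value are dropped
(listwise deletion) and the count is logged. Input may be 0- or 1-based
(e.g. Likert 1–5); by default the base is auto-detected from the global
minimum and recoded to 0-based scores.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParams, OrdinalData
from .sampler import PosteriorSamples

logger = logging.getLogger("ordmrf")

__all__ = [
    "read_ordinal_csv",
    "write_ordinal_csv",
    "params_to_json",
    "params_from_json",
    "samples_to_frame",
    "write_samples_csv",
    "write_manifest",
]


def read_ordinal_csv(
    path,
    missing_token: str = "NA",
    recode: str = "auto",
    n_categories=None,
) -> OrdinalData:
    """Read an ordinal data matrix from CSV/TSV.

    ``recode`` is one of ``"auto"`` (subtract the global minimum if it is
    positive), ``"none"``, or an integer-like string giving the code of the
    lowest category. Columns where a single category is observed are a hard
    error: they carry no information about their interactions.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=None, engine="python", na_values=[missing_token]
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path} contains no data rows")
    n_raw = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("%d row(s) with missing responses dropped", n_dropped)
    if len(df) == 0:
        raise ValueError(f"{path}: every row has missing responses")
    values = df.to_numpy()
    as_float = values.astype(float)
    if not np.all(as_float == np.round(as_float)):
        bad = np.argwhere(as_float != np.round(as_float))[0]
        raise ValueError(
            f"{path}: non-integer cell at row {bad[0]}, "
            f"column {df.columns[bad[1]]!r}"
        )
    values = as_float.astype(np.int64)
    if recode == "auto":
        base = int(values.min())
        if base > 0:
            logger.info("auto-recoding categories: subtracting base %d", base)
            values = values - base
    elif recode == "none":
        pass
    else:
        values = values - int(recode)
    if values.min() < 0:
        raise ValueError(f"{path}: negative category codes after recoding")
    for c, name in enumerate(df.columns):
        observed = np.unique(values[:, c])
        if observed.size < 2:
            raise ValueError(
                f"{path}: column {name!r} has a single observed category"
            )
    data = OrdinalData.from_values(values, n_categories)
    data.variable_names = list(df.columns)  # type: ignore[attr-defined]
    return data


def write_ordinal_csv(path, data: OrdinalData, variable_names=None) -> None:
    names = variable_names or getattr(
        data, "variable_names", [f"V{i+1}" for i in range(data.p)]
    )
    pd.DataFrame(data.values, columns=names).to_csv(path, index=False)


def params_to_json(params: ModelParams) -> str:
    return json.dumps(
        {
            "thresholds": [t.tolist() for t in params.thresholds],
            "interactions": params.interactions.tolist(),
        },
        indent=2,
    )


def params_from_json(text: str) -> ModelParams:
    d = json.loads(text)
    return ModelParams(
        [np.asarray(t, dtype=float) for t in d["thresholds"]],
        np.asarray(d["interactions"], dtype=float),
    )


def samples_to_frame(samples: PosteriorSamples) -> pd.DataFrame:
    """One row per retained draw; columns var[i].mu[h], edge[i.j].sigma/.gamma."""
    cols = {}
    for idx, (i, h) in enumerate(samples.threshold_labels):
        cols[f"var[{i}].mu[{h}]"] = samples.thresholds[:, idx]
    for k, (i, j) in enumerate(samples.pairs):
        cols[f"edge[{i}.{j}].sigma"] = samples.interactions[:, k]
        cols[f"edge[{i}.{j}].gamma"] = samples.gamma[:, k]
    return pd.DataFrame(cols)


def write_samples_csv(path, samples: PosteriorSamples) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def write_manifest(path, samples: PosteriorSamples, extra: dict | None = None):
    manifest = {
        "config": samples.config,
        "prior": samples.prior.to_dict(),
        "acceptance_rates": samples.acceptance,
        "n_retained_draws": samples.n_draws,
        "n_visited_structures": len(samples.visited_structures),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
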