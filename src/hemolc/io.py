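"""CSV dataset ingestion, configuration and fit artifacts.

The dataset schema requires ``id``, ``rbc_units_24h`` (positive, >= 1 unit
by the study inclusion criterion) and ``death_24h`` (0/1).  Covariate roles
are declared in a YAML/JSON config: ``membership`` columns form the
class-membership design v, ``class_specific`` columns the marker and
mortality designs (or separate ``marker``/``death`` lists), and
``ratio_covariates`` are 24-h blood-product ratios expanded to two
reference-coded indicators (level 0 reference, levels (0, 1] and > 1) and
appended to both class-specific designs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ModelParameters, TraumaData

__all__ = [
    "default_study_config",
    "simulation_config",
    "load_config",
    "read_dataset",
    "write_simulated_dataset",
    "provenance",
    "save_fit",
    "load_fit",
]

logger = logging.getLogger("hemolc")

REQUIRED_COLUMNS = ("id", "rbc_units_24h", "death_24h")


def default_study_config() -> dict:
    """Covariate roles for the retrospective trauma analysis layout:
    four binary admission vitals drive class membership, and the class-
    specific models add the categorized 24-h blood-product ratios."""
    return {
        "membership": ["sbp_lt90", "hr_ge120", "ph_lt725", "hgb_lt9"],
        "class_specific": ["sbp_lt90", "hr_ge120", "ph_lt725", "hgb_lt9"],
        "ratio_covariates": ["plasma_rbc_ratio_24h", "platelet_rbc_ratio_24h"],
    }


def simulation_config() -> dict:
    """Covariate roles matching the synthetic benchmark datasets."""
    return {"membership": ["v"], "marker": ["v", "x"], "death": ["x"]}


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _expand_ratio(series: pd.Series, name: str) -> pd.DataFrame:
    """Reference-code a ratio column into (0,1] and >1 indicators."""
    vals = series.astype(float)
    if (vals < 0).any():
        raise ValueError(f"negative values in ratio column {name!r}")
    return pd.DataFrame(
        {
            f"{name}_0to1": ((vals > 0) & (vals <= 1)).astype(float),
            f"{name}_gt1": (vals > 1).astype(float),
        }
    )


def read_dataset(path, config: dict | None = None, min_units: float | None = 1.0) -> TraumaData:
    """Read and validate a patient-level CSV into a TraumaData.

    Rows with missing declared covariates are dropped with a logged count
    (complete-case analysis); rows with units below ``min_units`` (default
    1, the study inclusion criterion) or non-numeric cells raise a
    line-numbered error.  Pass ``min_units=None`` (or 0) for simulated
    datasets whose censored markers may fall below one unit.
    """
    config = config or default_study_config()
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")

    membership = list(config.get("membership", []))
    marker = list(config.get("marker", config.get("class_specific", [])))
    death = list(config.get("death", config.get("class_specific", [])))
    ratios = list(config.get("ratio_covariates", []))
    declared = sorted(set(membership + marker + death + ratios))
    for col in declared:
        if col not in df.columns:
            raise ValueError(f"declared covariate column {col!r} not in {path}")

    # file line numbers: header is line 1
    lines = df.index.to_numpy() + 2

    numeric_cols = ["rbc_units_24h", "death_24h", *declared]
    bad_lines = []
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            bad_lines.extend((col, int(l)) for l in lines[bad.to_numpy()])
        df[col] = coerced
    if bad_lines:
        detail = ", ".join(f"{c} at line {l}" for c, l in bad_lines[:10])
        raise ValueError(f"non-numeric cells in {path}: {detail}")

    complete = df[declared].notna().all(axis=1) & df["rbc_units_24h"].notna() & df[
        "death_24h"
    ].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "dropped %d incomplete record(s) of %d (complete-case analysis)",
            n_dropped, len(df),
        )
    df = df[complete]
    lines = lines[complete.to_numpy()]
    if df.empty:
        raise ValueError(f"no complete records in {path}")

    units = df["rbc_units_24h"].to_numpy(dtype=float)
    if np.any(units <= 0):
        bad = lines[units <= 0]
        raise ValueError(
            f"non-positive rbc_units_24h at line(s) {bad[:10].tolist()} in {path}"
        )
    if min_units:
        below = units < min_units
        if below.any():
            raise ValueError(
                f"rbc_units_24h below {min_units} (study inclusion criterion) "
                f"at line(s) {lines[below][:10].tolist()} in {path}"
            )
    died = df["death_24h"].to_numpy()
    if not np.isin(died, (0, 1)).all():
        bad = lines[~np.isin(died, (0, 1))]
        raise ValueError(f"death_24h must be 0/1; offending line(s) {bad[:10].tolist()}")

    extra = pd.concat(
        [_expand_ratio(df[c], c) for c in ratios], axis=1
    ) if ratios else pd.DataFrame(index=df.index)

    def design(cols, with_ratios):
        parts = [np.ones(len(df))]
        parts += [df[c].to_numpy(dtype=float) for c in cols]
        if with_ratios and len(extra.columns):
            parts += [extra[c].to_numpy(dtype=float) for c in extra.columns]
        return np.column_stack(parts)

    return TraumaData(
        y_obs=np.log(units),
        died=died.astype(int),
        V=design(membership, with_ratios=False),
        X_marker=design(marker, with_ratios=True),
        X_death=design(death, with_ratios=True),
        ids=df["id"].to_numpy(),
        rbc_units=units,
    )


def write_simulated_dataset(data: TraumaData, labels, path) -> None:
    """Write a simulated dataset in the readable CSV schema.

    Columns: id, rbc_units_24h, death_24h, v, x, plus the simulation-only
    ground-truth column ``true_class_sim``.  Floats carry 12 significant
    digits so a read round-trips to within formatting precision.
    """
    df = pd.DataFrame(
        {
            "id": data.ids,
            "rbc_units_24h": np.exp(data.y_obs),
            "death_24h": data.died,
            "v": data.V[:, 1],
            "x": data.X_marker[:, 2],
            "true_class_sim": np.asarray(labels, dtype=int),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def provenance(seed, config: dict | None = None) -> dict:
    """Machine-readable provenance block for output artifacts."""
    blob = json.dumps(config or {}, sort_keys=True).encode()
    try:
        ver = _pkg_version("hemolc")
    except Exception:  # pragma: no cover - not installed
        ver = "unknown"
    return {
        "package": "hemolc",
        "version": ver,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }


def save_fit(results, path, seed=None, config: dict | None = None) -> None:
    """Serialize a fitted model (parameters, SEs, trace metadata) to JSON."""
    p = results.mle.params
    payload = {
        "K": p.K,
        "alpha": p.alpha.tolist(),
        "betas": p.betas.tolist(),
        "gammas": p.gammas.tolist(),
        "sigma": p.sigma,
        "loglik": results.llf,
        "bic": results.bic,
        "n_params": results.mle.n_params,
        "n_obs": results.mle.n_obs,
        "converged": bool(results.mle.converged),
        "n_iter": int(results.mle.n_iter),
        "start_index": int(results.mle.start_index),
        "param_names": p.param_names(),
        "se": None if results.inference is None else results.inference.se.tolist(),
        "provenance": provenance(seed, config),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_fit(path) -> ModelParameters:
    d = json.loads(Path(path).read_text())
    alpha = np.asarray(d["alpha"], dtype=float)
    if d["K"] == 1:
        alpha = np.zeros((0, 1))
    return ModelParameters(
        alpha=alpha,
        betas=np.asarray(d["betas"], dtype=float),
        gammas=np.asarray(d["gammas"], dtype=float),
        sigma=float(d["sigma"]),
    )
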