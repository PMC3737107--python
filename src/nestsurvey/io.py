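"""Reading and writing the package's file formats.

Observation CSV columns (exact names): transect_id, visit, year,
distance_m, habitat, optionally x_utm / y_utm (planar metres) and is_new
(0/1 marked-nest flag).  Transect CSV: transect_id, length_km, one column
per habitat holding that habitat's length in km.  Run configuration is
YAML or JSON.  Schema violations raise :class:`SchemaError` naming file,
row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .density import TransectLayout
from .errors import SchemaError

OBS_REQUIRED = ["transect_id", "visit", "year", "distance_m", "habitat"]
OBS_OPTIONAL = ["x_utm", "y_utm", "is_new"]


def read_observations(path) -> pd.DataFrame:
    path = Path(path)
    try:
        obs = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: no observations") from exc
    missing = [c for c in OBS_REQUIRED if c not in obs.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(obs) == 0:
        raise SchemaError(f"{path}: no observations")
    dist = pd.to_numeric(obs["distance_m"], errors="coerce")
    bad = np.nonzero(~np.isfinite(dist.to_numpy()) | (dist.to_numpy() < 0))[0]
    if bad.size:
        raise SchemaError(
            f"{path}: row {int(bad[0]) + 2}, column 'distance_m': "
            "must be a nonnegative number"
        )
    if "is_new" in obs.columns:
        flags = set(pd.unique(obs["is_new"].dropna()))
        if not flags <= {0, 1}:
            raise SchemaError(f"{path}: column 'is_new' must be 0/1")
    obs["distance_m"] = dist
    return obs


def read_transects(path) -> TransectLayout:
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty transect table") from exc
    try:
        return TransectLayout(table)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg


def write_density_report(path, estimates) -> None:
    """Tidy results CSV: one row per stratum estimate."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "stratum": est.stratum,
                "n": est.n,
                "effort_km": est.effort_km,
                "estimate": est.value,
                "cv": est.cv,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "estimator": est.estimator,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def write_json(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
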