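"""CSV/JSON input-output for fitness records, designs and reports.

CSV dialect: comma-separated, UTF-8, header required, "." decimal, ``NA``
for missing.  The record schema is one row per assayed individual:
``line_id, sex (M/F), block, individual, fitness, infected (optional
0/1/NA)``.  Reports are JSON with stable key order and reproducibility
metadata (package version, seed, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .scenarios import ScenarioConfig
from .synthetic import IsolineDesign

logger = logging.getLogger("cibias")

__all__ = [
    "read_fitness_csv",
    "write_fitness_csv",
    "write_report_json",
    "read_report_json",
    "scenario_config_from_json",
    "isoline_design_from_json",
]

_CSV_REQUIRED = ("line_id", "sex", "block", "individual", "fitness")


def read_fitness_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate individual-level fitness records.

    Returns a data frame with columns ``line_id, sex, block, individual,
    fitness_raw`` (+ ``infected`` if present).  Rows with missing fitness
    are dropped with a log entry.  Errors name the offending data row
    (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")

    sex = df["sex"].astype(str).str.strip().str.upper()
    bad = df.index[~sex.isin(["M", "F"])]
    if len(bad):
        row = int(bad[0]) + 1
        raise ValueError(
            f"{path.name}: unknown sex code {df['sex'].iloc[bad[0]]!r} on row {row}"
        )
    fitness = pd.to_numeric(df["fitness"], errors="coerce")
    bad = df.index[fitness.isna() & df["fitness"].notna()]
    if len(bad):
        row = int(bad[0]) + 1
        raise ValueError(
            f"{path.name}: non-numeric fitness {df['fitness'].iloc[bad[0]]!r} "
            f"on row {row}"
        )

    out = pd.DataFrame(
        {
            "line_id": df["line_id"].astype(str),
            "sex": sex,
            "block": df["block"].astype(str),
            "individual": df["individual"],
            "fitness_raw": fitness,
        }
    )
    if "infected" in df.columns:
        inf = pd.to_numeric(df["infected"], errors="coerce")
        bad_inf = df.index[~inf.isin([0, 1]) & inf.notna()]
        if len(bad_inf):
            row = int(bad_inf[0]) + 1
            raise ValueError(
                f"{path.name}: infected must be 0/1/NA, got "
                f"{df['infected'].iloc[bad_inf[0]]!r} on row {row}"
            )
        out["infected"] = inf
    n_missing = int(out["fitness_raw"].isna().sum())
    if n_missing:
        logger.info("%s: dropped %d record(s) with missing fitness", path.name, n_missing)
        out = out.loc[out["fitness_raw"].notna()].reset_index(drop=True)
    return out


def write_fitness_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the input CSV schema (``fitness_raw`` -> ``fitness``)."""
    cols = {"line_id", "sex", "block", "individual", "fitness_raw"}
    missing = cols - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    out = records.rename(columns={"fitness_raw": "fitness"})
    keep = ["line_id", "sex", "block", "individual", "fitness"]
    if "infected" in out.columns:
        keep.append("infected")
    out[keep].to_csv(path, index=False, na_rep="NA")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def config_hash(config: Any) -> str:
    """Stable sha256 of a configuration object's JSON form."""
    payload = json.dumps(_jsonify(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_report_json(
    report: dict,
    path: str | Path,
    *,
    seed: int | None = None,
    config: Any = None,
) -> None:
    """Write an analysis report as JSON with reproducibility metadata.

    Keys are sorted; floats keep full double precision.  The header block
    records the package version, the seed, and a hash of the configuration
    so identical runs produce byte-identical files.
    """
    from . import __version__

    doc = {
        "cibias_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "report": _jsonify(report),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _from_json(path: str | Path, cls):
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a JSON object")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(
            f"{Path(path).name}: unknown key(s) {unknown}; valid keys: {sorted(valid)}"
        )
    if "ci_lines" in data and isinstance(data["ci_lines"], list):
        data["ci_lines"] = tuple(data["ci_lines"])
    obj = cls(**data)
    obj.validate()
    return obj


def scenario_config_from_json(path: str | Path) -> ScenarioConfig:
    """Load a :class:`ScenarioConfig` from JSON, rejecting unknown keys."""
    return _from_json(path, ScenarioConfig)


def isoline_design_from_json(path: str | Path) -> IsolineDesign:
    """Load an :class:`IsolineDesign` from JSON, rejecting unknown keys."""
    return _from_json(path, IsolineDesign)
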