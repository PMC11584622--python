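"""CSV / JSON / YAML round-trips for cohorts, residual pools and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aft import ResidualSeries
from .cohort import PARSONNET_MAX, CohortConfig, PatientRecord
from .exceptions import DataError
from .runlength import ResidualPool

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_residual_pool",
    "write_residual_pool",
    "load_config",
    "dump_config",
]

COHORT_COLUMNS = ["patient_id", "parsonnet", "time_days", "censored", "group"]


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write a cohort CSV (UTF-8, '.' decimal separator, censored in {0,1})."""
    df = pd.DataFrame(
        {
            "patient_id": np.arange(1, len(records) + 1),
            "parsonnet": [r.parsonnet for r in records],
            "time_days": [repr(float(r.time_days)) for r in records],
            "censored": [int(r.censored) for r in records],
            "group": [r.group if r.group is not None else "" for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; errors name the offending data row."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: file is empty (expected header {COHORT_COLUMNS})")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            parsonnet = int(row.parsonnet)
            time_days = float(row.time_days)
            censored_raw = int(row.censored)
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path}: row {i}: non-numeric field ({exc})") from None
        if not 0 <= parsonnet <= PARSONNET_MAX:
            raise DataError(
                f"{path}: row {i}: parsonnet {parsonnet} outside [0, {PARSONNET_MAX}]"
            )
        if censored_raw not in (0, 1):
            raise DataError(f"{path}: row {i}: censored must be 0 or 1")
        if not time_days > 0:
            raise DataError(f"{path}: row {i}: non-positive time_days {time_days}")
        group = getattr(row, "group", "") or None
        records.append(
            PatientRecord(
                parsonnet=parsonnet,
                time_days=time_days,
                censored=bool(censored_raw),
                group=group,
            )
        )
    return records


def write_residual_pool(pool: ResidualPool | ResidualSeries, path) -> None:
    values = pool.values
    source = pool.source
    pd.DataFrame({"residual": [repr(float(v)) for v in values]}).to_csv(path, index=False)
    # source travels in a sidecar so the CSV stays a plain one-column table
    Path(str(path) + ".meta.json").write_text(json.dumps({"source": source}))


def read_residual_pool(path) -> ResidualPool:
    df = pd.read_csv(path)
    if "residual" not in df.columns:
        raise DataError(f"{path}: missing 'residual' column")
    source = "SR_SVM"
    meta = Path(str(path) + ".meta.json")
    if meta.exists():
        source = json.loads(meta.read_text()).get("source", source)
    return ResidualPool(values=df["residual"].to_numpy(dtype=float), source=source)


def load_config(path) -> dict:
    """Load a flat JSON or YAML config document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise DataError(f"{path}: config must be a mapping")
    return out


def dump_config(cfg: CohortConfig | dict, path) -> None:
    d = cfg.to_dict() if isinstance(cfg, CohortConfig) else dict(cfg)
    text = json.dumps(d, indent=2) if str(path).endswith(".json") else yaml.safe_dump(d)
    Path(path).write_text(text)
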