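"""Readers/writers for the tabular artifacts and the trial config file.

All tables are comma-delimited UTF-8 with one header row, preceded by
``#``-prefixed metadata lines carrying the schema version and, where
relevant, the seed and a config hash so every artifact can be reproduced.
Readers reject unknown major schema versions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import ElectricalConstants
from .device import DeviceGeometry
from .simulate import (
    DowntimeModel,
    IrrigationEvent,
    IrrigationSchedule,
    RootContactModel,
    SoilParams,
    TreatmentSpec,
    TrialConfig,
    deep_depth_profile,
    shallow_depth_profile,
)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "SchemaError",
    "write_table",
    "read_table",
    "read_measurements",
    "write_measurements",
    "read_field_map",
    "load_trial_config",
    "config_hash",
]

SCHEMA_MAJOR = 1

MEASUREMENT_COLUMNS = [
    "timestamp",
    "device_id",
    "paddle_index",
    "depth_index",
    "V1_volts",
    "V2_volts",
    "TC_seconds",
    "Vs_volts",
    "ResVD_ohms",
]

_NUMERIC_MEASUREMENT_COLUMNS = [
    "paddle_index",
    "depth_index",
    "V1_volts",
    "V2_volts",
    "TC_seconds",
    "Vs_volts",
    "ResVD_ohms",
]


class SchemaError(ValueError):
    """Missing required column or incompatible schema version."""


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
    **extra_meta: object,
) -> None:
    """Write a CSV artifact with a versioned metadata header."""
    meta = {"schema": f"v{SCHEMA_MAJOR}"}
    if seed is not None:
        meta["seed"] = seed
    if config_digest is not None:
        meta["config_hash"] = config_digest
    meta.update(extra_meta)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(
            "# rhizosense-table "
            + " ".join(f"{k}={v}" for k, v in meta.items())
            + "\n"
        )
        df.to_csv(fh, index=False)


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line.lstrip("#").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    return meta


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV artifact, checking the schema version; metadata in attrs."""
    path = Path(path)
    meta = _read_meta(path)
    schema = meta.get("schema", f"v{SCHEMA_MAJOR}")
    major = int(schema.lstrip("v").split(".")[0])
    if major != SCHEMA_MAJOR:
        raise SchemaError(
            f"{path}: schema {schema} not supported (reader is v{SCHEMA_MAJOR})"
        )
    df = pd.read_csv(path, comment="#")
    df.attrs["meta"] = meta
    return df


def write_measurements(
    stream: pd.DataFrame, path: str | Path, seed: int | None = None,
    config_digest: str | None = None, geometry: DeviceGeometry | None = None,
) -> None:
    """Write a raw measurement stream in the canonical column order.

    When ``geometry`` is given its fields go into the metadata header so
    that :func:`geometry_from_meta` can re-grid the stream on read.
    """
    extra = geometry_meta(geometry) if geometry is not None else {}
    write_table(stream[MEASUREMENT_COLUMNS], path, seed=seed,
                config_digest=config_digest, **extra)


def read_measurements(path: str | Path, lenient: bool = False) -> pd.DataFrame:
    """Read and validate a raw measurement stream.

    Every schema column must be present (a missing column raises
    :class:`SchemaError` naming it).  Rows with an unparseable timestamp
    or non-numeric measurement fields are errors by default; under
    ``lenient=True`` they are skipped and counted in
    ``df.attrs['n_malformed']``.
    """
    df = read_table(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    for col in _NUMERIC_MEASUREMENT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        # nan voltages are legal (masked readings); other columns must parse
        if col in ("V1_volts", "V2_volts"):
            bad |= vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        else:
            bad |= vals.isna()
        df[col] = vals
    n_bad = int(bad.sum())
    if n_bad and not lenient:
        raise SchemaError(f"{path}: {n_bad} malformed row(s); use lenient=True to skip")
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    meta = df.attrs.get("meta", {})
    df.attrs["meta"] = meta
    df.attrs["n_malformed"] = n_bad
    return df.reset_index(drop=True)


def geometry_meta(geometry: DeviceGeometry) -> dict[str, object]:
    """Geometry fields embedded in stream headers so readers can re-grid."""
    return {
        "n_paddles": geometry.n_paddles,
        "electrodes_per_paddle": geometry.electrodes_per_paddle,
        "depth_shallow_cm": geometry.depth_shallow_cm,
        "depth_deep_cm": geometry.depth_deep_cm,
        "cadence_minutes": geometry.cadence_minutes,
    }


def geometry_from_meta(meta: dict[str, str]) -> DeviceGeometry:
    """Rebuild the device geometry from stream metadata (default if absent)."""
    if "n_paddles" not in meta:
        return DeviceGeometry()
    return DeviceGeometry(
        n_paddles=int(meta["n_paddles"]),
        electrodes_per_paddle=int(meta["electrodes_per_paddle"]),
        depth_shallow_cm=float(meta["depth_shallow_cm"]),
        depth_deep_cm=float(meta["depth_deep_cm"]),
        cadence_minutes=float(meta["cadence_minutes"]),
    )


def read_field_map(path: str | Path) -> pd.DataFrame:
    """Read a field map (device_id, row, position, genotype, treatment, status)."""
    df = pd.read_csv(path, comment="#", dtype={"device_id": str})
    required = ["device_id", "genotype", "treatment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: field map missing column(s) {missing}")
    if "status" not in df.columns:
        df["status"] = ""
    return df


# ---------------------------------------------------------------------------
# Trial configuration


def _depth_profile_from(value, geometry: DeviceGeometry):
    if value is None:
        return None
    if isinstance(value, str):
        if value == "shallow":
            return shallow_depth_profile(geometry)
        if value == "deep":
            return deep_depth_profile(geometry)
        raise ValueError(f"unknown depth profile {value!r}")
    arr = np.asarray(value, dtype=float)
    return arr / arr.sum()


def _schedule_from(value, n_days: int) -> IrrigationSchedule:
    if value is None:
        return IrrigationSchedule()
    if "weekly" in value:
        return IrrigationSchedule.weekly(n_days=n_days, **value["weekly"])
    events = tuple(
        IrrigationEvent(
            start_minutes=float(e["start_minutes"]),
            duration_hours=float(e["duration_hours"]),
            depth_reach_cm=float(e.get("depth_reach_cm", 30.0)),
        )
        for e in value.get("events", [])
    )
    return IrrigationSchedule(events)


def load_trial_config(path: str | Path, seed: int | None = None) -> TrialConfig:
    """Build a :class:`TrialConfig` from a YAML file.

    Top-level keys mirror the dataclass fields: ``n_days``, ``seed``,
    ``geometry``, ``soil``, ``contact``, ``constants``, ``downtime`` (each
    a mapping of dataclass fields), ``genotypes``, ``start``,
    ``n_devices`` (treatment -> count) and ``treatments`` (treatment ->
    {schedule, root_arrival_rate, rate_multipliers, depth_profile,
    depth_profile_windows}).  ``seed`` passed here overrides the file.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    n_days = int(raw.get("n_days", 30))
    geometry = DeviceGeometry(**raw.get("geometry", {}))
    treatments = {}
    for name, tr in (raw.get("treatments") or {"well_watered": {}}).items():
        tr = tr or {}
        treatments[name] = TreatmentSpec(
            schedule=_schedule_from(tr.get("schedule"), n_days),
            root_arrival_rate=float(tr.get("root_arrival_rate", 2.0)),
            rate_multipliers=tuple(
                (float(a), float(b), float(f))
                for a, b, f in tr.get("rate_multipliers", [])
            ),
            depth_profile=_depth_profile_from(tr.get("depth_profile"), geometry),
            depth_profile_windows=tuple(
                (float(a), float(b), _depth_profile_from(p, geometry))
                for a, b, p in tr.get("depth_profile_windows", [])
            ),
        )
    return TrialConfig(
        n_days=n_days,
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        geometry=geometry,
        soil=SoilParams(**raw.get("soil", {})),
        contact=RootContactModel(**raw.get("contact", {})),
        constants=ElectricalConstants(**raw.get("constants", {})),
        treatments=treatments,
        n_devices={k: int(v) for k, v in raw.get("n_devices", {}).items()}
        or {name: 2 for name in treatments},
        genotypes=tuple(raw.get("genotypes", ("HYB001",))),
        downtime=DowntimeModel(**raw.get("downtime", {})),
        start=str(raw.get("start", "2021-05-01")),
    )


def config_hash(config: TrialConfig) -> str:
    """Short stable digest of a trial config (for artifact provenance)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict("records")
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    text = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
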