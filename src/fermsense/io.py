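"""File formats and persistence: probe logs, offline tables, model JSON,
run bundles, and YAML configuration.

Everything is vendor-neutral plain text: CSV for time series and reference
tables (``.`` decimal separator, times in hours as floats), JSON for model
artifacts and manifests, YAML for run/control configuration. A simulated
run is published as a *bundle* directory whose manifest (seed + config
hash) makes it bit-reproducible from one command.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import MODEL_SCHEMA_VERSION, ODModelSpec
from .control import ControlConfig
from .exceptions import ModelVersionError, ParseError, SchemaError
from .signals import PROBE_LOG_COLUMNS
from .simulate import NoiseModel, ProbeModel, SimConfig, SimRun

OFFLINE_COLUMNS = ("run_id", "probe_id", "time_h", "od600")
BUNDLE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# CSV time series / tables


def _read_csv_checked(path, required: tuple[str, ...], numeric: tuple[str, ...]):
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    out = df.copy()
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: empty cell in column {col!r}", row=row)
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r}", row=row)
        out[col] = vals
    return out


def read_probe_log(path) -> pd.DataFrame:
    """Read and validate a probe log CSV.

    Columns (any order, keyed by name):
    ``time_h,transmission,reflection,do_pct,volume_ml,antifoam_cum_ml``.
    Times must be strictly increasing; violations are reported with their
    file line number.
    """
    df = _read_csv_checked(path, PROBE_LOG_COLUMNS, PROBE_LOG_COLUMNS)
    t = df["time_h"].to_numpy(dtype=float)
    if t.size > 1:
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise ParseError(
                f"{path}: non-increasing time_h", row=int(bad[0]) + 3)
    if (df["volume_ml"] <= 0).any():
        row = int(df.index[df["volume_ml"] <= 0][0]) + 2
        raise ParseError(f"{path}: volume_ml must be > 0", row=row)
    af = df["antifoam_cum_ml"].to_numpy(dtype=float)
    if af.size > 1 and np.any(np.diff(af) < 0):
        row = int(np.where(np.diff(af) < 0)[0][0]) + 3
        raise ParseError(f"{path}: antifoam_cum_ml must be non-decreasing", row=row)
    return df.loc[:, list(PROBE_LOG_COLUMNS)]


def write_probe_log(records: pd.DataFrame, path) -> None:
    records.loc[:, list(PROBE_LOG_COLUMNS)].to_csv(path, index=False)


def read_offline_table(path) -> pd.DataFrame:
    """Offline OD600 reference table: ``run_id,probe_id,time_h,od600``."""
    df = _read_csv_checked(path, OFFLINE_COLUMNS, ("time_h", "od600"))
    if (df["od600"] < 0).any():
        row = int(df.index[df["od600"] < 0][0]) + 2
        raise ParseError(f"{path}: od600 must be >= 0", row=row)
    return df.loc[:, list(OFFLINE_COLUMNS)]


def write_offline_table(table: pd.DataFrame, path) -> None:
    table.loc[:, list(OFFLINE_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model artifact


def write_model(spec: ODModelSpec, path) -> None:
    """Persist a fitted calibration as JSON (full float precision)."""
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n")


def read_model(path) -> ODModelSpec:
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(d, dict) or "schema_version" not in d:
        raise ParseError(f"{path}: not a model artifact (no schema_version)")
    if int(d["schema_version"]) != MODEL_SCHEMA_VERSION:
        raise ModelVersionError(
            f"{path}: model schema version {d['schema_version']} "
            f"incompatible with supported version {MODEL_SCHEMA_VERSION}")
    try:
        return ODModelSpec.from_dict(d)
    except (KeyError, TypeError, ValueError) as e:
        raise ParseError(f"{path}: malformed model artifact ({e})") from e


# ---------------------------------------------------------------------------
# configuration


def _nested_dataclass_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "probe" in d and isinstance(d["probe"], dict):
        d["probe"] = ProbeModel(**d["probe"])
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = NoiseModel(**d["noise"])
    if "antifoam_schedule" in d and d["antifoam_schedule"] is not None:
        d["antifoam_schedule"] = [tuple(x) for x in d["antifoam_schedule"]]
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown SimConfig keys: {sorted(unknown)}")
    return SimConfig(**d)


def load_sim_config(path) -> SimConfig:
    """Load a :class:`SimConfig` from YAML (keys mirror the field names;
    ``probe:`` and ``noise:`` are nested mappings)."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return _nested_dataclass_from_dict(d)


def save_sim_config(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["antifoam_schedule"] = [list(x) for x in config.antifoam_schedule]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_control_config(path) -> ControlConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ControlConfig)}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown ControlConfig keys: {sorted(unknown)}")
    return ControlConfig(**d)


def config_hash(config: SimConfig) -> str:
    """SHA-256 over the canonical JSON form of a config (reproducibility
    stamp carried in run-bundle manifests)."""
    d = dataclasses.asdict(config)
    d["antifoam_schedule"] = [list(map(float, x)) for x in config.antifoam_schedule]
    blob = json.dumps(d, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# run bundles


@dataclass
class RunBundle:
    """Paths and manifest of one published run directory."""

    root: Path
    probe_log: Path
    truth: Path | None
    offline: Path | None
    events: Path | None
    manifest: dict


def write_run_bundle(run: SimRun, out_dir) -> RunBundle:
    """Publish a simulated run as ``probe_log.csv``, ``truth.csv``,
    ``offline.csv``, ``events.csv`` and ``manifest.json``."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    probe_log = root / "probe_log.csv"
    write_probe_log(run.records, probe_log)
    truth = root / "truth.csv"
    run.truth.to_csv(truth, index=False)
    offline = root / "offline.csv"
    run.offline.to_csv(offline, index=False)
    events_path = root / "events.csv"
    run.events_frame().to_csv(events_path, index=False)
    manifest = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "seed": int(run.config.seed),
        "config_hash": config_hash(run.config),
        "n_records": int(len(run.records)),
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    save_sim_config(run.config, root / "sim_config.yaml")
    return RunBundle(root=root, probe_log=probe_log, truth=truth,
                     offline=offline, events=events_path, manifest=manifest)


def build_calibration_table(probe_logs_dir, offline: pd.DataFrame,
                            window: float | None = None) -> pd.DataFrame:
    """Pair an offline reference table with per-run probe logs.

    ``probe_logs_dir`` must contain one ``<run_id>.csv`` probe log per run
    appearing in ``offline``. Each offline row is matched to the
    nearest-in-time smoothed record of its run's log and the model features
    are attached, yielding the calibration table consumed by
    :class:`~fermsense.calibration.InlineODModel`.
    """
    from .signals import DEFAULT_MA_WINDOW, FEATURE_NAMES, featurize_log

    window = DEFAULT_MA_WINDOW if window is None else window
    root = Path(probe_logs_dir)
    rows = []
    for run_id, grp in offline.groupby("run_id", sort=True):
        log_path = root / f"{run_id}.csv"
        if not log_path.exists():
            raise ParseError(f"no probe log for run {run_id!r} at {log_path}")
        feats = featurize_log(read_probe_log(log_path), window=window)
        t_rec = feats["time_h"].to_numpy()
        for _, r in grp.iterrows():
            i = int(np.argmin(np.abs(t_rec - float(r["time_h"]))))
            frow = feats.iloc[i]
            rows.append({
                "run_id": run_id,
                "probe_id": r.get("probe_id", ""),
                "time_h": float(r["time_h"]),
                **{name: float(frow[name]) for name in FEATURE_NAMES},
                "offline_od": float(r["od600"]),
            })
    return pd.DataFrame(rows)


def read_run_bundle(path) -> dict:
    """Load a run bundle directory back into DataFrames + manifest."""
    root = Path(path)
    out = {
        "probe_log": read_probe_log(root / "probe_log.csv"),
        "manifest": json.loads((root / "manifest.json").read_text()),
    }
    for name in ("truth", "offline", "events"):
        p = root / f"{name}.csv"
        out[name] = pd.read_csv(p) if p.exists() else None
    return out
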