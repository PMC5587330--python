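"""File interchange: retention CSVs, experiment tables, configs, manifests.

All tabular interchange is plain CSV with versioned schemas; numeric output
is written with 6 significant digits (documented round-trip precision).
Run configuration is a YAML mapping; every command writes a manifest (config
snapshot + seed + package version) next to its outputs so any artifact can
be regenerated from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import RetentionRecord
from .exceptions import ConfigurationError, DataError
from .gases import GasPanel
from .inversion import PerfusionDistribution

FLOAT_FORMAT = "%.6g"

RETENTION_COLUMNS = (
    "sample_id",
    "setting_id",
    "perfusate",
    "gas",
    "upstream_pressure",
    "downstream_pressure",
    "retention",
)

#: default column mapping for an exported bench spreadsheet (deposited data);
#: override via config key ``s1_mapping`` to match the actual export layout
DEFAULT_S1_MAPPING = {
    "perfusate": "perfusate",
    "setting_id": "setting_id",
    "duplicate": "duplicate",
    "ivlm_shunt": "ivlm_shunt",
    "mm_shunt": "mm_shunt",
}


def write_retention_csv(records: list[RetentionRecord], path) -> None:
    if not records:
        raise DataError("no retention records to write")
    df = pd.concat([r.to_frame() for r in records], ignore_index=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_retention_csv(path) -> list[RetentionRecord]:
    """Read a retention table; malformed rows are reported with line numbers."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse retention CSV {path}: {exc}") from exc
    missing = [c for c in RETENTION_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise DataError(f"retention CSV {path} missing columns {missing}")
    if df.empty:
        raise DataError(f"retention CSV {path} has no rows")
    records = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        bad = grp[
            ~np.isfinite(grp["upstream_pressure"].astype(float))
            | (grp["upstream_pressure"].astype(float) <= 0)
        ]
        if not bad.empty:
            lines = [int(i) + 2 for i in bad.index]  # header + 0-based
            raise DataError(
                f"non-positive upstream pressure in {path} at line(s) {lines}"
            )
        records.append(
            RetentionRecord(
                tuple(grp["gas"].astype(str)),
                grp["upstream_pressure"].to_numpy(dtype=float),
                grp["downstream_pressure"].to_numpy(dtype=float),
                sample_id=str(sample_id),
                setting_id=str(grp["setting_id"].iloc[0]),
                perfusate=str(grp["perfusate"].iloc[0]),
            )
        )
    return records


def write_experiment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_experiment_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse experiment table {path}: {exc}") from exc
    if df.empty:
        raise DataError(f"experiment table {path} has no rows")
    return df


def read_s1_csv(path, mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an exported bench-data spreadsheet (CSV) into an experiment table.

    ``mapping`` translates our canonical column names to the columns of the
    export; unmapped optional columns (``rss``) are carried through if
    present.
    """
    colmap = dict(DEFAULT_S1_MAPPING)
    if mapping:
        colmap.update(mapping)
    df = read_experiment_table(path)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise DataError(
            f"S1 export {path} lacks mapped columns {missing}; "
            "adjust the s1_mapping config"
        )
    out = pd.DataFrame({canon: df[src] for canon, src in colmap.items()})
    if "rss" in df.columns and "rss" not in out.columns:
        out["rss"] = df["rss"]
    return out


def write_distribution_csv(dists: Mapping[str, PerfusionDistribution], path) -> None:
    frames = []
    for sample_id, dist in dists.items():
        f = dist.to_frame()
        f.insert(0, "sample_id", sample_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# run configuration


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "panel": None,  # path to a panel CSV overriding the built-in defaults
    "grid": {"n_compartments": 50, "vq_min": 0.005, "vq_max": 100.0},
    "smoothing_weight": 40.0,
    "design": {
        "settings": [0.0, 0.2, 0.4, 0.6, 0.8],
        "duplicates_per_setting": 2,
        "perfusates": ["blood", "saline"],
        "flow_error_rel": 0.01,
        "retention_noise_rel": 0.02,
    },
    "s1_mapping": {},
}


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Load a YAML run config, layered over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        try:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(user, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, dict(overrides))
    return cfg


def _deep_update(base: dict, update: Mapping) -> None:
    for key, val in update.items():
        if isinstance(val, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


def write_manifest(out_dir, config: Mapping, command: str) -> Path:
    """Write the reproducibility manifest next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package": "migetsim",
        "version": __version__,
        "config": json.loads(json.dumps(config)),
    }
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def panel_from_config(cfg: Mapping, perfusate: str) -> GasPanel:
    from .gases import default_panel

    if cfg.get("panel"):
        panel = GasPanel.from_csv(cfg["panel"])
        if panel.perfusate_label != perfusate:
            raise ConfigurationError(
                f"panel file is for {panel.perfusate_label!r}, need {perfusate!r}"
            )
        return panel
    return default_panel(perfusate)
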