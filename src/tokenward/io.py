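"""Scenario loading, event-log serialization, and run manifests.

Scenario files are YAML or JSON with a strict schema (unknown keys are
rejected, absent keys take the shipped defaults).  Event logs are written as
JSON-lines — one event per line, keys sorted — so that two runs with the same
seed and config produce byte-identical files, plus a tidy CSV export.  Every
output directory carries a ``manifest.json`` with the config hash, the seed,
and the package version: enough to reproduce the run exactly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .config import ConfigurationError, ScenarioConfig, validate_config
from .market import EventLog, SessionResult

__all__ = [
    "load_scenario",
    "scenario_to_dict",
    "save_scenario",
    "bundled_scenario_path",
    "write_events",
    "read_events",
    "write_schedule",
    "read_schedule",
    "config_hash",
    "write_run_outputs",
]

_DATA_DIR = Path(__file__).parent / "data"


def bundled_scenario_path(name: str = "paper_default") -> Path:
    """Path of a scenario shipped with the package (e.g. 'paper_default')."""
    p = _DATA_DIR / f"{name}.yaml"
    if not p.exists():
        available = sorted(q.stem for q in _DATA_DIR.glob("*.yaml"))
        raise FileNotFoundError(f"no bundled scenario {name!r}; available: {available}")
    return p


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Parse and validate a YAML/JSON scenario file, filling defaults."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return validate_config(raw)


def scenario_to_dict(config: ScenarioConfig) -> dict[str, Any]:
    d = config.model_dump(mode="json")
    # drop keys still at their defaults? keep everything: explicit is reproducible
    return d


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    d = scenario_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def write_events(log: EventLog, path: str | Path) -> None:
    Path(path).write_text(log.to_jsonl())


def read_events(path: str | Path) -> EventLog:
    return EventLog.from_jsonl(Path(path).read_text())


def write_schedule(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Save a replayable price schedule (day, ward, illness, severity, price)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)


def read_schedule(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def config_hash(config: ScenarioConfig) -> str:
    canon = json.dumps(scenario_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_run_outputs(
    result: SessionResult,
    outdir: str | Path,
    plots: bool = False,
    extra_files: Optional[dict[str, Any]] = None,
) -> Path:
    """Write the standard artifact set for one session run.

    events.jsonl, events.csv, snapshots.csv, summary tables, the resolved
    scenario, and a manifest sufficient to reproduce the run.
    """
    from .analysis import extract_pairs, plot_price_workload, summarize_session

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    def _note(name: str):
        files.append(name)
        return outdir / name

    write_events(result.log, _note("events.jsonl"))
    result.log.to_frame().to_csv(_note("events.csv"), index=False)
    result.snapshots.to_csv(_note("snapshots.csv"), index=False)
    save_scenario(result.config, _note("scenario.yaml"))
    pairs = extract_pairs(result.log)
    pairs.to_csv(_note("pairs.csv"), index=False)
    summary = summarize_session(result)
    summary["wards"].to_csv(_note("summary_wards.csv"), index=False)
    summary["hospital"].to_csv(_note("summary_hospital.csv"), index=False)
    if plots and len(pairs):
        plot_price_workload(pairs, severities=result.config.severities,
                            path=str(_note("price_workload.png")))
    manifest = {
        "artifact": "tokenward",
        "version": __version__,
        "seed": result.config.seed,
        "config_hash": config_hash(result.config),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "n_events": len(result.log),
        "files": sorted(files),
    }
    if extra_files:
        manifest.update(extra_files)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
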