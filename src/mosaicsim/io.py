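"""Configuration, event-log and contact-list I/O, and fixture generation.

Formats are deliberately plain: YAML (or JSON) configs, tab-separated event
logs and contact lists, JSON manifests.  Times are floating point in each
model's own units (hours for the germinal-center model, minutes for the
transcription model, data ticks for temporal networks).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .engine import EventRecord, MosaicError
from .metrics import ContactLog

__all__ = [
    "ConfigError", "RunConfig", "load_config",
    "write_event_log", "read_event_log",
    "write_contact_tsv", "read_contact_tsv", "write_sociopatterns",
    "generate_fixture", "write_manifest",
]

_MODEL_SCHEMAS = {
    # model -> (required keys, optional keys)
    "bcell": ({"n_b", "n_t"}, {"beta", "lam_bt", "lam_unbind", "lam_apop",
                               "lam_div", "competition", "record_every"}),
    "hes1": ({"beta"}, {"gamma", "h", "tau0", "alpha_elong", "lam_trans",
                        "lam_degM", "lam_degP", "strict", "record_grid"}),
    "tn": ({"n_nodes"}, {"alpha_activity", "rate_activity", "alpha_term",
                         "rate_term", "w", "kernel", "preference"}),
}


class ConfigError(MosaicError, ValueError):
    """Schema violation in a run configuration; names the offending field."""


@dataclass
class RunConfig:
    model: str
    params: dict
    t_end: float
    seed: int
    lambda_max: Optional[float] = None
    out_dir: Optional[str] = None


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run configuration and validate its schema."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in ("model", "t_end", "seed"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required field '{key}'")
    model = raw["model"]
    if model not in _MODEL_SCHEMAS:
        raise ConfigError(
            f"{path}: unknown model '{model}' (choose from "
            f"{sorted(_MODEL_SCHEMAS)})")
    params = raw.get("params", {})
    if not isinstance(params, dict):
        raise ConfigError(f"{path}: field 'params' must be a mapping")
    required, optional = _MODEL_SCHEMAS[model]
    missing = required - params.keys()
    if missing:
        raise ConfigError(
            f"{path}: model '{model}' missing parameter(s) "
            f"{sorted(missing)}")
    unknown = params.keys() - required - optional
    if unknown:
        raise ConfigError(
            f"{path}: model '{model}' got unknown parameter(s) "
            f"{sorted(unknown)}")
    t_end = raw["t_end"]
    if not isinstance(t_end, (int, float)) or t_end <= 0:
        raise ConfigError(f"{path}: field 't_end' must be a positive number")
    if not isinstance(raw["seed"], int):
        raise ConfigError(f"{path}: field 'seed' must be an integer")
    return RunConfig(model=model, params=dict(params), t_end=float(t_end),
                     seed=raw["seed"], lambda_max=raw.get("lambda_max"),
                     out_dir=raw.get("out_dir"))


def write_event_log(records: list[EventRecord], path: str | Path) -> None:
    """TSV event log: time, channel, kind, accepted, payload."""
    with open(path, "w") as fh:
        fh.write("time\tchannel\tkind\taccepted\tpayload\n")
        for r in records:
            payload = "" if r.payload is None else json.dumps(r.payload)
            fh.write(f"{r.time!r}\t{r.channel_id}\t{r.kind}\t"
                     f"{int(r.accepted)}\t{payload}\n")


def read_event_log(path: str | Path) -> list[EventRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("time\t"):
            raise ConfigError(f"{path}: not an event log (bad header)")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ConfigError(
                    f"{path}: line {ln}: expected 5 columns, got {len(parts)}")
            try:
                rec = EventRecord(float(parts[0]), int(parts[1]), parts[2],
                                  bool(int(parts[3])),
                                  json.loads(parts[4]) if parts[4] else None)
            except ValueError as exc:
                raise ConfigError(f"{path}: line {ln}: {exc}") from exc
            records.append(rec)
    return records


def write_contact_tsv(log: ContactLog, path: str | Path) -> None:
    """Contact list TSV: t_start, t_end, i, j (+ header comment with size)."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={log.n_nodes} horizon={log.horizon!r}\n")
        fh.write("t_start\tt_end\ti\tj\n")
        for t0, t1, i, j in log.events:
            fh.write(f"{t0!r}\t{t1!r}\t{i}\t{j}\n")


def read_contact_tsv(path: str | Path) -> ContactLog:
    path = Path(path)
    events = []
    n_nodes = None
    horizon = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            for token in first[1:].split():
                key, _, val = token.partition("=")
                if key == "n_nodes":
                    n_nodes = int(val)
                elif key == "horizon":
                    horizon = float(val)
            header = fh.readline().strip()
        else:
            header = first
        if header.split("\t") != ["t_start", "t_end", "i", "j"]:
            raise ConfigError(f"{path}: bad contact-list header {header!r}")
        for ln, line in enumerate(fh, start=3 if first.startswith("#") else 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ConfigError(
                    f"{path}: line {ln}: expected 4 columns, got {len(parts)}")
            try:
                events.append((float(parts[0]), float(parts[1]),
                               int(parts[2]), int(parts[3])))
            except ValueError as exc:
                raise ConfigError(f"{path}: line {ln}: {exc}") from exc
    if n_nodes is None:
        n_nodes = 1 + max((max(i, j) for _, _, i, j in events), default=0)
    if horizon is None:
        horizon = max((t1 for _, t1, _, _ in events), default=0.0)
    return ContactLog(events=events, n_nodes=n_nodes, horizon=horizon)


def write_sociopatterns(log: ContactLog, path: str | Path,
                        interval: float = 1.0) -> None:
    """Instantaneous 't i j' export: one row per tick a contact is active."""
    with open(path, "w") as fh:
        for t0, t1, i, j in log.events:
            t = math.ceil(t0 / interval) * interval
            while t < t1:
                fh.write(f"{t!r}\t{i}\t{j}\n")
                t += interval


def generate_fixture(kind: str, params: dict, seed: int):
    """Small synthetic inputs for tests: deterministic given the seed.

    Kinds: ``ied-sample`` (oracle waiting-time draws), ``gc-small`` (a tiny
    germinal-center run), ``contact-log`` (a synthetic contact list with
    Poissonian starts and exponential durations -- a stand-in shaped like
    SocioPatterns data, not derived from any real recording).
    """
    rng = np.random.default_rng(seed)
    if kind == "ied-sample":
        from . import hazards
        family = params.get("family", "exponential")
        if family == "exponential":
            ied = hazards.ExponentialIED(params.get("rate", 1.0))
        elif family == "gamma":
            ied = hazards.GammaIED(params.get("shape", 3.0),
                                   params.get("rate_scale", 0.05))
        elif family == "pareto":
            ied = hazards.ParetoIED(params.get("t_min", 1.0),
                                    params.get("alpha", 1.5))
        else:
            raise ConfigError(f"unknown IED fixture family '{family}'")
        return ied.sample(params.get("n", 1000), rng)
    if kind == "gc-small":
        from .bcell import run_gc
        return run_gc(n_b=params.get("n_b", 50), n_t=params.get("n_t", 2),
                      t_end=params.get("t_end", 48.0), seed=seed)
    if kind == "contact-log":
        n = params.get("n_nodes", 10)
        horizon = params.get("horizon", 100.0)
        rate = params.get("rate", 0.02)        # contacts per pair per tick
        mean_dur = params.get("mean_duration", 3.0)
        events = []
        for i in range(n):
            for j in range(i + 1, n):
                t = rng.exponential(1.0 / rate)
                while t < horizon:
                    dur = rng.exponential(mean_dur)
                    end = min(t + max(dur, 1e-6), horizon)
                    events.append((t, end, i, j))
                    t = end + rng.exponential(1.0 / rate)
        return ContactLog(events=sorted(events), n_nodes=n, horizon=horizon)
    raise ConfigError(f"unknown fixture kind '{kind}'")


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Record everything needed to reproduce a run alongside its outputs."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config, "seed": seed, "version": __version__}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
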