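"""CSV/JSON/YAML plumbing: event tables, insight tables, configs, reports.

Formats are deliberately plain:

* event table — CSV with header ``session_id,time_s,inscription_id,is_new``,
  one row per attention-shift event, times strictly increasing per session;
* insight table — CSV with header ``session_id,time_s``;
* trajectory table — CSV with header ``session_id,time,u,gamma``;
* analysis report — versioned JSON with a config echo and all statistics;
* run config — YAML or JSON mirroring every module default; unknown keys
  are rejected.

An import adapter (``column_map``) renames arbitrary external column names
onto the canonical event-table header, so third-party corpora can be loaded
without rewriting files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import LatentTrajectory
from .observation import Event, EventSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_events",
    "write_events",
    "read_insights",
    "write_insights",
    "write_trajectories",
    "write_report",
    "read_report",
]

EVENT_COLUMNS = ["session_id", "time_s", "inscription_id", "is_new"]
INSIGHT_COLUMNS = ["session_id", "time_s"]
REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline defaults in one declarative bundle.

    Field names match the CLI flags; unknown keys in a config file are a
    hard error so typos cannot silently fall back to defaults.
    """

    # simulation
    n_sessions: int = 24
    n_symbols: int = 25
    gamma_start: float = 0.1
    gamma_end: float = 0.3
    n_steps: int = 2000
    dt: float = 1.0
    noise_sigma: float = 0.02
    u0: float = 0.1
    concentration: float = 0.005
    seed: int = 0
    # surprisal
    delta: float = 40.0
    smoothing_k: float = 0.0
    backoff: str = "marginal"
    # epochs / inference
    w_pre: float = 200.0
    w_post: float = 200.0
    n_bins: int = 15
    n_permutations: int = 500
    time_scale: float = 60.0
    # io adapter
    column_map: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty and df.columns.size == 0:
        raise ValueError(f"{path}: empty file")
    return df


def read_events(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[EventSeries]:
    """Load an event table into per-session EventSeries.

    ``column_map`` maps external column names onto the canonical header
    (e.g. ``{"subject": "session_id"}``), supporting third-party corpora.
    is_new is recomputed from first occurrences and cross-checked against
    the file's column; on mismatch a warning is logged and the recomputed
    (invariant-consistent) value is kept.  Non-monotone or duplicate times
    within a session are hard errors naming the offending row.
    """
    df = _read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in EVENT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no event rows")

    out = []
    for sid, grp in df.groupby("session_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        rows = grp.index.to_numpy()
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            r = int(rows[bad[0] + 1])
            raise ValueError(
                f"{path}: session {sid!r} has non-increasing time_s at row {r + 2} "
                "(1-based, counting the header)"
            )
        labels = grp["inscription_id"].astype(str).tolist()
        seen: set[str] = set()
        events = []
        mismatches = 0
        file_is_new = grp["is_new"].to_numpy() if "is_new" in grp.columns else None
        for i, (t, lab) in enumerate(zip(times, labels)):
            is_new = lab not in seen
            if file_is_new is not None and bool(int(file_is_new[i])) != is_new:
                mismatches += 1
            seen.add(lab)
            events.append(Event(time=float(t), inscription=lab, is_new=is_new))
        if mismatches:
            logger.warning(
                "%s: session %s: %d is_new flags disagree with first occurrences; "
                "recomputed values kept",
                path, sid, mismatches,
            )
        out.append(EventSeries(session_id=str(sid), events=tuple(events)))
    return out


def write_events(series_list: Sequence[EventSeries], path: str | Path) -> None:
    rows = [
        {
            "session_id": s.session_id,
            "time_s": e.time,
            "inscription_id": e.inscription,
            "is_new": int(e.is_new),
        }
        for s in series_list
        for e in s.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_insights(
    path: str | Path,
    sessions: Optional[Sequence[str]] = None,
) -> dict[str, list[float]]:
    """Load insight timestamps keyed by session id.

    When ``sessions`` is given, every insight's session must appear in it.
    """
    df = _read_table(path)
    missing = [c for c in INSIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: dict[str, list[float]] = {}
    for sid, grp in df.groupby("session_id", sort=True):
        out[str(sid)] = sorted(float(t) for t in grp["time_s"])
    if sessions is not None:
        unknown = set(out) - set(map(str, sessions))
        if unknown:
            raise ValueError(f"{path}: insight sessions not in event table: {sorted(unknown)}")
    return out


def write_insights(insights: Mapping[str, Sequence[float]], path: str | Path) -> None:
    rows = [
        {"session_id": sid, "time_s": t}
        for sid in sorted(insights)
        for t in insights[sid]
    ]
    pd.DataFrame(rows, columns=INSIGHT_COLUMNS).to_csv(path, index=False)


def write_trajectories(
    trajectories: Mapping[str, LatentTrajectory], path: str | Path
) -> None:
    rows = []
    for sid in sorted(trajectories):
        tr = trajectories[sid]
        for t, u, g in zip(tr.times, tr.u, tr.gamma):
            rows.append({"session_id": sid, "time": t, "u": u, "gamma": g})
    pd.DataFrame(rows, columns=["session_id", "time", "u", "gamma"]).to_csv(path, index=False)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.reset_index().to_dict(orient="list"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_report(results: Mapping[str, Any], path: str | Path) -> dict:
    """Write a versioned, machine-readable JSON analysis report.

    ``results`` should include the resolved config and seeds alongside the
    statistics; numpy scalars/arrays and dataclasses are converted, NaNs
    become JSON null.  Returns the serialised payload.
    """
    payload = {"schema_version": REPORT_SCHEMA_VERSION}
    payload.update(_jsonify(dict(results)))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
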