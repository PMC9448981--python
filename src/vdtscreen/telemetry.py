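"""Replay-file telemetry: parsing, derived channels, and the feature matrix.

A virtual driving test (VDT) session is recorded as a *replay file*: a 10 Hz
multichannel time series (speed, posted speed, lane offset, signed distance
from road centre, heading, road heading, steering) with a per-sample route-zone
label and a list of discrete higher-order error events. From each session the
module derives kinematic channels (forward acceleration and jerk, speed
relative to the posted limit, lane deviation, heading misalignment,
below-limit indicators), then summarizes every channel with min / max / mean /
median / SD both globally (whole drive) and within each route zone, adds
per-type error counts and the composite VDT Error Score, and assembles a
zero-variance-filtered participants × variables feature matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ERROR_TYPES",
    "DEFAULT_ERROR_WEIGHTS",
    "OUT_OF_ZONE",
    "ReplayError",
    "ReplayEvent",
    "ReplaySession",
    "ErrorCounts",
    "FeatureMatrix",
    "parse_replay",
    "write_replay",
    "derive_channels",
    "summarize_variables",
    "vdt_error_score",
]


class ReplayError(ValueError):
    """Raised for malformed replay files or invalid telemetry requests."""


#: The eight higher-order error types recorded during a session.
ERROR_TYPES: tuple[str, ...] = (
    "vehicle_collision_front",
    "vehicle_collision_side_rear",
    "static_object_collision",
    "pedestrian_collision",
    "red_light_error",
    "stop_sign_error",
    "navigation_error",
    "teleport",
)

#: Stand-in weights for the composite VDT Error Score (the production weights
#: are proprietary and unpublished). Collisions are weighted heaviest;
#: override via the ``weights`` argument / pipeline config.
DEFAULT_ERROR_WEIGHTS: dict[str, float] = {
    "vehicle_collision_front": 5.0,
    "vehicle_collision_side_rear": 5.0,
    "static_object_collision": 3.0,
    "pedestrian_collision": 10.0,
    "red_light_error": 2.0,
    "stop_sign_error": 2.0,
    "navigation_error": 1.0,
    "teleport": 4.0,
}

#: Zone id used for samples outside every declared route zone.
OUT_OF_ZONE = -1

#: Channels every replay file must carry, in canonical serialization order.
REQUIRED_CHANNELS: tuple[str, ...] = (
    "speed_mph",
    "posted_speed_mph",
    "lane_offset_m",
    "center_offset_m",
    "heading_deg",
    "road_heading_deg",
    "steering_frac",
)

SUMMARY_STATS: tuple[str, ...] = ("min", "max", "mean", "median", "sd")

#: Thresholds (mph below the posted limit) for the %-time indicator channels.
BELOW_LIMIT_THRESHOLDS: tuple[float, ...] = (10.0, 15.0)


@dataclass(frozen=True)
class ReplayEvent:
    t_sec: float
    type: str
    zone_id: int

    def __post_init__(self) -> None:
        if self.type not in ERROR_TYPES:
            raise ReplayError(f"unknown error type {self.type!r}")


@dataclass
class ReplaySession:
    """One participant's session: channel samples, zone track, error events."""

    session_id: str
    sample_rate: float
    channels: dict[str, np.ndarray]
    zone_track: np.ndarray
    events: list[ReplayEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {name: len(v) for name, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ReplayError(f"channels differ in length: {lengths}")
        for name in REQUIRED_CHANNELS:
            if name not in self.channels:
                raise ReplayError(f"missing required channel {name!r}")
        if len(self.zone_track) != self.n_samples:
            raise ReplayError("zone_track length does not match channel length")
        duration = self.n_samples / self.sample_rate
        for ev in self.events:
            if not 0.0 <= ev.t_sec <= duration:
                raise ReplayError(
                    f"event at t={ev.t_sec} s outside session duration {duration} s"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def zone_ids(self) -> list[int]:
        """Distinct zonal ids present in this session (out-of-zone excluded)."""
        return sorted(z for z in np.unique(self.zone_track) if z != OUT_OF_ZONE)

    def error_counts(self) -> "ErrorCounts":
        counts = dict.fromkeys(ERROR_TYPES, 0)
        for ev in self.events:
            counts[ev.type] += 1
        return ErrorCounts(counts)


@dataclass
class ErrorCounts:
    """Counts per higher-order error type (all eight types always present)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {t: int(self.counts.get(t, 0)) for t in ERROR_TYPES}
        bad = {t: c for t, c in self.counts.items() if c < 0}
        if bad:
            raise ReplayError(f"negative error counts: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[t] for t in ERROR_TYPES], dtype=float)


def vdt_error_score(counts: ErrorCounts, weights: dict[str, float] | None = None) -> float:
    """Composite VDT Error Score: weighted linear combination of error counts."""
    weights = DEFAULT_ERROR_WEIGHTS if weights is None else weights
    missing = [t for t in ERROR_TYPES if t not in weights]
    if missing:
        raise ReplayError(f"weight vector missing error type(s): {missing}")
    w = np.array([float(weights[t]) for t in ERROR_TYPES])
    if len(weights) != len(ERROR_TYPES):
        raise ReplayError("weight vector must have exactly 8 entries")
    if (w < 0).any():
        raise ReplayError("error-score weights must be non-negative")
    return float(counts.as_array() @ w)


# ---------------------------------------------------------------------------
# Replay JSON dialect
# ---------------------------------------------------------------------------


def _session_to_obj(session: ReplaySession) -> dict:
    extras = sorted(set(session.channels) - set(REQUIRED_CHANNELS))
    order = list(REQUIRED_CHANNELS) + extras
    samples = []
    rate = session.sample_rate
    for i in range(session.n_samples):
        s: dict[str, object] = {"t_sec": i / rate}
        for name in order:
            s[name] = float(session.channels[name][i])
        s["zone_id"] = int(session.zone_track[i])
        samples.append(s)
    events = [
        {"t_sec": ev.t_sec, "type": ev.type, "zone_id": ev.zone_id} for ev in session.events
    ]
    return {
        "session_id": session.session_id,
        "sample_rate_hz": session.sample_rate,
        "samples": samples,
        "events": events,
    }


def write_replay(session: ReplaySession, path=None) -> str:
    """Serialize a session to the canonical replay JSON dialect.

    The serialization is deterministic (fixed key order, repr-round-trip
    floats), so write → parse → write is byte-identical.
    """
    text = json.dumps(_session_to_obj(session), separators=(",", ":"))
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_replay(source) -> ReplaySession:
    """Parse a replay file (path or JSON string) into a :class:`ReplaySession`."""
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if len(text) < 4096 and "{" not in text:
            try:
                if Path(text).exists():
                    text = Path(text).read_text()
            except OSError:
                pass
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ReplayError(f"malformed replay JSON: {exc}") from exc
    for key in ("session_id", "sample_rate_hz", "samples", "events"):
        if key not in obj:
            raise ReplayError(f"replay file missing top-level field {key!r}")
    samples = obj["samples"]
    if not samples:
        raise ReplayError("replay file has no samples")
    rate = float(obj["sample_rate_hz"])
    if rate <= 0:
        raise ReplayError("sample_rate_hz must be positive")
    channel_names = [k for k in samples[0] if k not in ("t_sec", "zone_id")]
    for name in REQUIRED_CHANNELS:
        if name not in channel_names:
            raise ReplayError(f"replay file missing required channel {name!r}")
    n = len(samples)
    channels = {name: np.empty(n) for name in channel_names}
    zone_track = np.empty(n, dtype=int)
    times = np.empty(n)
    for i, s in enumerate(samples):
        for name in channel_names:
            if name not in s:
                raise ReplayError(f"sample {i} missing channel {name!r}")
            channels[name][i] = s[name]
        if "zone_id" not in s:
            raise ReplayError(f"sample {i} missing field 'zone_id'")
        zone_track[i] = s["zone_id"]
        times[i] = s["t_sec"]
    expected = np.arange(n) / rate
    if not np.allclose(times, expected, atol=1e-9):
        raise ReplayError("non-uniform timestamps: field 't_sec' must step by 1/sample_rate_hz")
    events = [
        ReplayEvent(float(e["t_sec"]), str(e["type"]), int(e["zone_id"])) for e in obj["events"]
    ]
    return ReplaySession(str(obj["session_id"]), rate, channels, zone_track, events)


# ---------------------------------------------------------------------------
# Derived channels
# ---------------------------------------------------------------------------


def _wrap_angle_deg(delta: np.ndarray) -> np.ndarray:
    return np.abs((delta + 180.0) % 360.0 - 180.0)


def derive_channels(session: ReplaySession) -> dict[str, np.ndarray]:
    """Kinematic channels derived from the raw telemetry.

    Forward acceleration is the first difference of speed × sample rate
    (mph/sec, length n−1, aligned to the trailing sample of each step); jerk
    is the first difference of acceleration × sample rate (mph/sec², length
    n−2). The remaining derived channels are full length. Below-limit
    indicators are 1 when the vehicle is driving at least the threshold below
    the posted limit.
    """
    if session.n_samples < 3:
        raise ReplayError("session shorter than 3 samples: jerk is undefined")
    rate = session.sample_rate
    speed = session.channels["speed_mph"]
    posted = session.channels["posted_speed_mph"]
    accel = np.diff(speed) * rate
    jerk = np.diff(accel) * rate
    derived = {
        "forward_accel": accel,
        "forward_jerk": jerk,
        "speed_vs_limit": speed - posted,
        "lane_deviation": np.abs(session.channels["lane_offset_m"]),
        "heading_misalignment": _wrap_angle_deg(
            session.channels["heading_deg"] - session.channels["road_heading_deg"]
        ),
    }
    for thr in BELOW_LIMIT_THRESHOLDS:
        derived[f"below_limit_{int(thr)}"] = (posted - speed >= thr).astype(float)
    return derived


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Participants × variables with per-variable provenance metadata.

    ``meta`` has one row per retained column (variable id, source channel,
    summary statistic, scope, original column index before filtering); column
    order is stable across runs and is what the ranking tie-break refers to.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    removed: list[str] = field(default_factory=list)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, index_label="participant_id")
        payload = {
            "variables": self.meta.to_dict(orient="records"),
            "removed_zero_variance": self.removed,
        }
        Path(meta_path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, values_path, meta_path) -> "FeatureMatrix":
        values = pd.read_csv(values_path, index_col="participant_id")
        payload = json.loads(Path(meta_path).read_text())
        meta = pd.DataFrame(payload["variables"])
        return cls(values, meta, payload["removed_zero_variance"])


def _scope_labels(zone_ids: list[int]) -> list[str]:
    return ["global"] + [f"zone:{z}" for z in zone_ids]


def _stat_row(values: np.ndarray) -> list[float]:
    """min/max/mean/median/sd of finite values (sd with n−1 denominator)."""
    v = values[np.isfinite(values)]
    if v.size == 0:
        return [np.nan] * len(SUMMARY_STATS)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return [float(v.min()), float(v.max()), float(v.mean()), float(np.median(v)), sd]


def summarize_variables(
    sessions: list[ReplaySession],
    *,
    error_weights: dict[str, float] | None = None,
    missing_zone: str = "error",
    drop_zero_variance: bool = True,
) -> FeatureMatrix:
    """Assemble the feature matrix for a cohort of sessions.

    Every raw and derived channel contributes min/max/mean/median/sd at global
    scope and within each route zone; below-limit indicator channels contribute
    a %-time variable per scope instead; per-type error counts are tallied per
    scope and combined into the global VDT Error Score. Zero-variance columns
    (constant across participants) are removed and recorded.

    ``missing_zone``: ``"error"`` (default — the synthetic route guarantees
    every participant traverses every zone) or ``"nan"`` to record a missing
    zonal value.
    """
    if missing_zone not in ("error", "nan"):
        raise ReplayError(f"unknown missing-zone policy {missing_zone!r}")
    if not sessions:
        raise ReplayError("no sessions supplied")
    zone_ids = sorted({z for s in sessions for z in s.zone_ids})
    scopes = _scope_labels(zone_ids)

    rows = []
    columns: list[tuple[str, str, str]] | None = None  # (channel, stat, scope)
    for session in sessions:
        derived = derive_channels(session)
        extras = sorted(set(session.channels) - set(REQUIRED_CHANNELS))
        stat_channels = {name: session.channels[name] for name in REQUIRED_CHANNELS}
        stat_channels.update({name: session.channels[name] for name in extras})
        stat_channels.update(
            {k: v for k, v in derived.items() if not k.startswith("below_limit_")}
        )
        pct_channels = {k: v for k, v in derived.items() if k.startswith("below_limit_")}

        n = session.n_samples
        # Derived channels are shorter; align to trailing raw samples via
        # leading-NaN padding so the zone track applies unchanged.
        aligned = {
            name: np.concatenate([np.full(n - len(v), np.nan), v])
            for name, v in {**stat_channels, **pct_channels}.items()
        }
        zone_masks = {"global": np.ones(n, dtype=bool)}
        for z in zone_ids:
            mask = session.zone_track == z
            if not mask.any():
                if missing_zone == "error":
                    raise ReplayError(
                        f"session {session.session_id} has no samples in zone {z}"
                    )
            zone_masks[f"zone:{z}"] = mask

        row: list[float] = []
        cols: list[tuple[str, str, str]] = []
        for name in stat_channels:
            v = aligned[name]
            for scope in scopes:
                mask = zone_masks[scope]
                stats = _stat_row(v[mask]) if mask.any() else [np.nan] * 5
                row.extend(stats)
                cols.extend((name, stat, scope) for stat in SUMMARY_STATS)
        for name in pct_channels:
            v = aligned[name]
            for scope in scopes:
                mask = zone_masks[scope]
                vv = v[mask]
                vv = vv[np.isfinite(vv)]
                row.append(float(vv.mean()) if vv.size else np.nan)
                cols.append((name, "pct_time", scope))
        # Per-type error counts by scope, then the composite score.
        for etype in ERROR_TYPES:
            for scope in scopes:
                if scope == "global":
                    c = sum(1 for ev in session.events if ev.type == etype)
                else:
                    z = int(scope.split(":")[1])
                    c = sum(1 for ev in session.events if ev.type == etype and ev.zone_id == z)
                row.append(float(c))
                cols.append((f"error:{etype}", "count", scope))
        row.append(vdt_error_score(session.error_counts(), error_weights))
        cols.append(("vdt_error_score", "score", "global"))

        if columns is None:
            columns = cols
        elif cols != columns:
            raise ReplayError(
                f"session {session.session_id} yields a different variable layout "
                "(sessions must share channels and the route's zone set)"
            )
        rows.append(row)

    assert columns is not None
    ids = [f"{ch}|{stat}|{scope}" for ch, stat, scope in columns]
    values = pd.DataFrame(rows, index=[s.session_id for s in sessions], columns=ids)
    values.index.name = "participant_id"
    meta = pd.DataFrame(
        {
            "variable": ids,
            "channel": [c[0] for c in columns],
            "statistic": [c[1] for c in columns],
            "scope": [c[2] for c in columns],
            "column_index": range(len(ids)),
        }
    )
    removed: list[str] = []
    if drop_zero_variance:
        nun = values.nunique(dropna=False)
        removed = list(values.columns[nun <= 1])
        values = values.drop(columns=removed)
        meta = meta[~meta["variable"].isin(removed)].reset_index(drop=True)
    return FeatureMatrix(values, meta, removed)
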