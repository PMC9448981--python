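"""Synthetic cohort generator: replay files + CNPA tables + ground truth.

The clinical dataset behind this analysis is not publicly available, so the
generator produces cohorts with the statistical structure the analysis
assumes: a fixed driving route (every participant traverses the same zones),
10 Hz multichannel telemetry with participant-level random effects, optional
planted HAND-group location shifts on chosen (channel, zone) cells,
overdispersed higher-order error counts with group-specific means, and CNPA
T-scores drawn conditional on the HAND label so that GDS scoring recovers the
labels exactly (configurable misclassification rate).

A planted location shift on a (channel, zone) cell translates that cell's
min / max / mean / median summary variables by the same amount (SD is
unaffected), so informative variables come in blocks of four; the generator
plants ``ceil(n_informative_variables / 4)`` cells and records the realized
variable ids in :class:`GroundTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vdtscreen import scoring
from vdtscreen.telemetry import (
    ERROR_TYPES,
    OUT_OF_ZONE,
    REQUIRED_CHANNELS,
    ReplayEvent,
    ReplaySession,
)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "ParticipantParams",
    "CohortConfigError",
    "generate_cohort",
    "generate_replay",
    "write_cohort",
]


class CohortConfigError(ValueError):
    """Raised when a cohort specification is invalid."""


#: Mean error-event counts per type as (HAND-absent, HAND-present) pairs.
#: Chosen so the weighted VDT Error Score has a clearly higher median in the
#: HAND group with a long right tail, matching the published score's skew.
DEFAULT_ERROR_RATES: dict[str, tuple[float, float]] = {
    "vehicle_collision_front": (1.0, 2.0),
    "vehicle_collision_side_rear": (0.8, 1.6),
    "static_object_collision": (1.0, 2.2),
    "pedestrian_collision": (0.1, 0.3),
    "red_light_error": (1.0, 2.0),
    "stop_sign_error": (0.8, 1.5),
    "navigation_error": (1.0, 1.8),
    "teleport": (0.4, 1.0),
}

#: Per-channel (between-participant SD tau, within-session noise SD sigma).
#: tau is the "scale parameter" that effect_size is expressed in.
_CHANNEL_SCALES: dict[str, tuple[float, float]] = {
    "speed_mph": (4.0, 6.0),
    "lane_offset_m": (0.15, 0.30),
    "center_offset_m": (0.5, 1.0),
    "heading_deg": (1.0, 2.0),
    "steering_frac": (0.01, 0.02),
}
_EXTRA_SCALE = (1.0, 1.0)

#: Posted-limit menu cycled across zones (mph); out-of-zone limit is 35.
_POSTED_MENU = (25.0, 35.0, 45.0)

#: Channels eligible for planted effects: additive location-scale channels
#: whose summary statistics reflect a location shift exactly (heading and the
#: track-like channels are excluded because of wrapping / determinism).
def _plantable_channels(extra_names: list[str]) -> list[str]:
    return ["speed_mph", "lane_offset_m", "center_offset_m", "steering_frac"] + extra_names


@dataclass
class CohortSpec:
    """Stated world for one synthetic cohort."""

    n_participants: int = 62
    hand_prevalence: float = 0.57
    n_channels: int = 10
    n_zones: int = 5
    sample_rate: float = 10.0
    session_duration: float = 600.0
    n_informative_variables: int = 0
    effect_size: float = 0.0
    error_rate_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_RATES)
    )
    misclassification_rate: float = 0.0
    ar_coefficient: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_participants < 2:
            errors.append("n_participants must be >= 2")
        if not 0.0 < self.hand_prevalence < 1.0:
            errors.append("hand_prevalence must be in (0, 1)")
        if self.effect_size < 0:
            errors.append("effect_size must be >= 0")
        if self.sample_rate <= 0:
            errors.append("sample_rate must be positive")
        if self.session_duration <= 0:
            errors.append("session_duration must be positive")
        if self.n_channels < len(REQUIRED_CHANNELS):
            errors.append(f"n_channels must be >= {len(REQUIRED_CHANNELS)}")
        if self.n_zones < 1:
            errors.append("n_zones must be >= 1")
        if self.n_informative_variables < 0:
            errors.append("n_informative_variables must be >= 0")
        if not 0.0 <= self.misclassification_rate <= 1.0:
            errors.append("misclassification_rate must be in [0, 1]")
        if not -1.0 < self.ar_coefficient < 1.0:
            errors.append("ar_coefficient must be in (-1, 1)")
        missing = [t for t in ERROR_TYPES if t not in self.error_rate_by_group]
        if missing:
            errors.append(f"error_rate_by_group missing type(s): {missing}")
        if errors:
            raise CohortConfigError("; ".join(errors))

    @property
    def n_samples(self) -> int:
        return int(round(self.session_duration * self.sample_rate))

    @property
    def extra_channel_names(self) -> list[str]:
        return [f"extra_{i:02d}" for i in range(1, self.n_channels - len(REQUIRED_CHANNELS) + 1)]


@dataclass
class GroundTruth:
    """Oracle bookkeeping for parameter-recovery tests."""

    hand_labels: np.ndarray
    informative_variable_ids: list[str]
    planted_shift: dict[str, float]

    def to_json(self, path=None) -> str:
        obj = {
            "hand_labels": [int(v) for v in self.hand_labels],
            "informative_variable_ids": self.informative_variable_ids,
            "planted_shift": self.planted_shift,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        obj = json.loads(source)
        return cls(
            np.array(obj["hand_labels"], dtype=int),
            list(obj["informative_variable_ids"]),
            {k: float(v) for k, v in obj["planted_shift"].items()},
        )


@dataclass
class ParticipantParams:
    """Everything :func:`generate_replay` needs for one participant."""

    participant_id: str
    hand: bool
    # channel -> per-scope location offset, indexed [zone 0..Z-1, out-of-zone]
    channel_offsets: dict[str, np.ndarray]
    event_counts: dict[str, int]
    noise_seed: int


def _route_zone_track(spec: CohortSpec) -> np.ndarray:
    """Fixed route: alternate out-of-zone and zonal blocks of equal length."""
    n, z = spec.n_samples, spec.n_zones
    blocks = 2 * z + 1
    edges = np.linspace(0, n, blocks + 1).round().astype(int)
    track = np.full(n, OUT_OF_ZONE, dtype=int)
    for i in range(z):
        start, end = edges[2 * i + 1], edges[2 * i + 2]
        track[start:end] = i
    return track


def _posted_track(spec: CohortSpec, zone_track: np.ndarray) -> np.ndarray:
    posted = np.full(spec.n_samples, 35.0)
    for z in range(spec.n_zones):
        posted[zone_track == z] = _POSTED_MENU[z % len(_POSTED_MENU)]
    return posted


def _road_heading_track(spec: CohortSpec, zone_track: np.ndarray) -> np.ndarray:
    heading = np.full(spec.n_samples, 90.0)
    for z in range(spec.n_zones):
        heading[zone_track == z] = float((90 + 73 * (z + 1)) % 360)
    return heading


def _channel_scale(name: str) -> tuple[float, float]:
    return _CHANNEL_SCALES.get(name, _EXTRA_SCALE)


def _ar1_noise(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    white = rng.normal(0.0, sigma, size=n)
    if phi == 0.0:
        return white
    # innovations scaled to keep the marginal SD at sigma
    out = np.empty(n)
    out[0] = white[0]
    innov_scale = math.sqrt(1.0 - phi * phi)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov_scale * white[i]
    return out


def generate_replay(params: ParticipantParams, spec: CohortSpec) -> ReplaySession:
    """Generate one participant's replay session from drawn parameters."""
    spec.validate()
    rng = np.random.default_rng(params.noise_seed)
    n = spec.n_samples
    zone_track = _route_zone_track(spec)
    posted = _posted_track(spec, zone_track)
    road_heading = _road_heading_track(spec, zone_track)
    # scope index per sample: zone id for zonal samples, Z for out-of-zone
    scope_idx = np.where(zone_track == OUT_OF_ZONE, spec.n_zones, zone_track)

    phi = spec.ar_coefficient
    channels: dict[str, np.ndarray] = {}
    for name in ["speed_mph", "lane_offset_m", "center_offset_m", "steering_frac"] + list(
        spec.extra_channel_names
    ):
        _, sigma = _channel_scale(name)
        offsets = params.channel_offsets[name]
        base = offsets[scope_idx] + _ar1_noise(rng, n, sigma, phi)
        channels[name] = base
    channels["speed_mph"] = channels["speed_mph"] + posted
    channels["posted_speed_mph"] = posted
    _, mis_sigma = _channel_scale("heading_deg")
    mis = params.channel_offsets["heading_deg"][scope_idx] + _ar1_noise(rng, n, mis_sigma * 2, phi)
    channels["heading_deg"] = (road_heading + mis) % 360.0
    channels["road_heading_deg"] = road_heading

    duration = n / spec.sample_rate
    events = []
    for etype in ERROR_TYPES:
        count = params.event_counts[etype]
        times = np.sort(rng.uniform(0.0, duration, size=count))
        for t in times:
            idx = min(int(t * spec.sample_rate), n - 1)
            events.append(ReplayEvent(float(round(t, 3)), etype, int(zone_track[idx])))
    events.sort(key=lambda e: (e.t_sec, e.type))
    return ReplaySession(params.participant_id, spec.sample_rate, channels, zone_track, events)


def _draw_t_scores(rng: np.random.Generator, impaired: bool) -> dict[str, float]:
    """T-scores for one participant conditional on intended HAND status.

    Unimpaired: every test in the normal range (deficit 0 → GDS 0).
    Impaired: 2–5 randomly chosen domains get all tests in the 25–35 band
    (domain deficit ≥ 2 → GDS ≥ 4/7 ≥ 0.5), the rest stay normal.
    """
    scores: dict[str, float] = {}
    domains = list(scoring.CNPA_BATTERY)
    impaired_domains: set[str] = set()
    if impaired:
        m = int(rng.integers(2, 6))
        impaired_domains = set(rng.choice(domains, size=m, replace=False))
    for domain, tests in scoring.CNPA_BATTERY.items():
        for test in tests:
            if domain in impaired_domains:
                scores[test] = float(round(rng.uniform(25.0, 34.99), 1))
            else:
                scores[test] = float(round(np.clip(rng.normal(52.0, 5.0), 40.0, 75.0), 1))
    return scores


def _nbinom_counts(rng: np.random.Generator, mean: float, size_r: float = 2.0) -> int:
    """Overdispersed count draw (negative binomial, dispersion r=2)."""
    if mean <= 0:
        return 0
    p = size_r / (size_r + mean)
    return int(rng.negative_binomial(size_r, p))


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ReplaySession], pd.DataFrame, GroundTruth]:
    """Generate a full cohort: replay sessions, CNPA table, ground truth.

    Deterministic for a fixed spec (including seed). HAND labels are drawn
    first; CNPA T-scores are sampled conditional on the label so GDS scoring
    reproduces the labels (up to ``misclassification_rate``); telemetry channel
    locations are shifted by ``effect_size`` × the channel's between-participant
    SD on the planted (channel, zone) cells for HAND participants only.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    pids = [f"P{i + 1:03d}" for i in range(n)]

    n_pos = int(round(n * spec.hand_prevalence))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1

    # ---- planted effects -------------------------------------------------
    extra_names = spec.extra_channel_names
    plantable = _plantable_channels(extra_names)
    cells = [(ch, z) for ch in plantable for z in range(spec.n_zones)]
    n_cells = math.ceil(spec.n_informative_variables / 4)
    if spec.n_informative_variables > 0 and spec.effect_size > 0:
        if n_cells > len(cells):
            raise CohortConfigError(
                f"requested {spec.n_informative_variables} informative variables but only "
                f"{len(cells)} plantable (channel, zone) cells exist"
            )
        chosen = [cells[i] for i in rng.choice(len(cells), size=n_cells, replace=False)]
    else:
        chosen = []
    signs = {cell: float(rng.choice((-1.0, 1.0))) for cell in chosen}
    informative_ids: list[str] = []
    planted_shift: dict[str, float] = {}
    for ch, z in chosen:
        tau, _ = _channel_scale(ch)
        delta = signs[(ch, z)] * spec.effect_size * tau
        for stat in ("min", "max", "mean", "median"):
            vid = f"{ch}|{stat}|zone:{z}"
            informative_ids.append(vid)
            planted_shift[vid] = delta

    # ---- per-participant parameters --------------------------------------
    offset_channels = ["speed_mph", "lane_offset_m", "center_offset_m", "steering_frac",
                       "heading_deg"] + extra_names
    sessions: list[ReplaySession] = []
    cnpa_rows: list[dict[str, float]] = []
    for i, pid in enumerate(pids):
        hand = bool(labels[i])
        channel_offsets: dict[str, np.ndarray] = {}
        for name in offset_channels:
            tau, _ = _channel_scale(name)
            offsets = rng.normal(0.0, tau, size=spec.n_zones + 1)
            if hand:
                for (ch, z), sign in signs.items():
                    if ch == name:
                        offsets[z] += sign * spec.effect_size * tau
            channel_offsets[name] = offsets
        group_idx = 1 if hand else 0
        event_counts = {
            etype: _nbinom_counts(rng, spec.error_rate_by_group[etype][group_idx])
            for etype in ERROR_TYPES
        }
        noise_seed = int(rng.integers(0, 2**31 - 1))
        params = ParticipantParams(pid, hand, channel_offsets, event_counts, noise_seed)
        sessions.append(generate_replay(params, spec))

        score_as_impaired = hand
        if spec.misclassification_rate > 0 and rng.random() < spec.misclassification_rate:
            score_as_impaired = not score_as_impaired
        cnpa_rows.append(_draw_t_scores(rng, score_as_impaired))

    cnpa = pd.DataFrame(cnpa_rows, index=pids, columns=list(scoring.ALL_TESTS))
    cnpa.index.name = "participant_id"
    truth = GroundTruth(labels, informative_ids, planted_shift)
    return sessions, cnpa, truth


def write_cohort(
    sessions: list[ReplaySession],
    cnpa: pd.DataFrame,
    truth: GroundTruth,
    out_dir,
) -> None:
    """Persist a cohort: replay JSONs, CNPA CSV, ground-truth sidecar."""
    from vdtscreen.telemetry import write_replay

    out = Path(out_dir)
    (out / "replays").mkdir(parents=True, exist_ok=True)
    for s in sessions:
        write_replay(s, out / "replays" / f"{s.session_id}.json")
    scoring.write_cnpa_csv(cnpa, out / "cnpa.csv")
    truth.to_json(out / "ground_truth.json")
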