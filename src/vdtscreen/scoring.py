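"""Neuropsychological scoring: T-scores → deficit scores → GDS → HAND labels.

A comprehensive neuropsychological assessment (CNPA) yields one demographically
adjusted T-score (mean 50, SD 10 in a seronegative reference population) per
component test, grouped into seven cognitive domains. Each T-score is graded on
a 0–5 deficit scale, test deficits are averaged within a domain, and the Global
Deficit Score (GDS) is the mean of the seven domain deficits. GDS ≥ 0.5 flags
HAND; a domain deficit ≥ 1 flags impairment within that domain. Both cutoffs
are inclusive and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CNPA_BATTERY",
    "DOMAINS",
    "CnpaProfile",
    "DeficitSummary",
    "ScoringError",
    "t_to_deficit",
    "summarize_deficits",
    "score_cohort",
    "read_cnpa_csv",
    "write_cnpa_csv",
    "write_deficit_summaries",
    "prevalence_rows",
]


class ScoringError(ValueError):
    """Raised for invalid CNPA profiles or scoring configuration."""


#: Component tests per cognitive domain (standard HAND battery layout:
#: seven domains, at least two measures per domain).
CNPA_BATTERY: dict[str, tuple[str, ...]] = {
    "processing_speed": (
        "waisiv_coding",
        "trail_making_a",
        "stroop_word",
        "stroop_color",
    ),
    "attention_working_memory": (
        "digit_span_forward",
        "digit_span_backward",
        "digit_span_sequencing",
    ),
    "motor_function": ("pegboard_dominant", "pegboard_nondominant"),
    "executive_function": ("trail_making_b", "stroop_color_word", "mwcst_errors"),
    "language": ("letter_fluency", "animal_fluency", "boston_naming"),
    "verbal_memory": ("hvlt_immediate", "hvlt_delayed", "hvlt_recognition"),
    "visuospatial_memory": ("bvmt_immediate", "bvmt_delayed", "bvmt_recognition"),
}

DOMAINS: tuple[str, ...] = tuple(CNPA_BATTERY)

ALL_TESTS: tuple[str, ...] = tuple(t for tests in CNPA_BATTERY.values() for t in tests)

#: Deficit-score bin edges: T ≥ 40 is unimpaired (0), then one deficit point
#: per 5-point band down to T < 20 (5). Exposed so alternative conventions can
#: be configured; these are the standard GDS bins.
DEFICIT_CUTOFF_T = 40.0
DEFICIT_BAND_WIDTH = 5.0
MAX_DEFICIT = 5

GDS_HAND_CUTOFF = 0.5
DOMAIN_IMPAIRMENT_CUTOFF = 1.0
#: GDS at or above which the three-level category reads "dementia". The source
#: analyses defer the three-level scheme to the cited GDS literature and do not
#: use it in the primary pipeline; the value is a configurable convention.
GDS_DEMENTIA_CUTOFF = 1.5


@dataclass
class CnpaProfile:
    """Per-participant T-scores for the component tests of the battery."""

    participant_id: str
    t_scores: dict[str, float]
    battery: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(CNPA_BATTERY))

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for domain, tests in self.battery.items():
            if len(tests) < 2:
                raise ScoringError(
                    f"domain {domain!r} has {len(tests)} test(s); at least two are required"
                )
            for t in tests:
                if t in seen:
                    raise ScoringError(f"test {t!r} appears in both {seen[t]!r} and {domain!r}")
                seen[t] = domain


@dataclass
class DeficitSummary:
    participant_id: str
    per_test_deficit: dict[str, int]
    domain_deficit: dict[str, float]
    gds: float
    hand: bool
    domain_impaired: dict[str, bool]
    hand_category: str  # none | asymptomatic_or_mild | dementia


def t_to_deficit(t: float) -> int:
    """Grade a T-score on the 0–5 deficit scale.

    Monotone non-increasing step function: 0 for T ≥ 40, one point per
    5-point band below that, capped at 5 (T < 20).
    """
    if not math.isfinite(t):
        raise ScoringError(f"T-score must be finite, got {t!r}")
    if t >= DEFICIT_CUTOFF_T:
        return 0
    return min(MAX_DEFICIT, math.ceil((DEFICIT_CUTOFF_T - t) / DEFICIT_BAND_WIDTH))


def summarize_deficits(
    profile: CnpaProfile,
    *,
    missing: str = "error",
    gds_cutoff: float = GDS_HAND_CUTOFF,
    domain_cutoff: float = DOMAIN_IMPAIRMENT_CUTOFF,
) -> DeficitSummary:
    """Score one participant: per-test deficits, domain deficits, GDS, flags.

    Parameters
    ----------
    missing
        ``"error"`` (default) requires every configured test; ``"available"``
        averages each domain over the tests that are present (a domain with no
        scored test is always an error — no imputation is performed).
    """
    if missing not in ("error", "available"):
        raise ScoringError(f"unknown missing-data policy {missing!r}")
    per_test: dict[str, int] = {}
    domain_deficit: dict[str, float] = {}
    for domain, tests in profile.battery.items():
        scored = []
        for test in tests:
            t = profile.t_scores.get(test)
            if t is None or (isinstance(t, float) and math.isnan(t)):
                if missing == "error":
                    raise ScoringError(
                        f"participant {profile.participant_id}: missing T-score for {test!r}"
                    )
                continue
            d = t_to_deficit(float(t))
            per_test[test] = d
            scored.append(d)
        if not scored:
            raise ScoringError(
                f"participant {profile.participant_id}: domain {domain!r} has no scored tests"
            )
        domain_deficit[domain] = float(np.mean(scored))
    gds = float(np.mean(list(domain_deficit.values())))
    hand = gds >= gds_cutoff
    if not hand:
        category = "none"
    elif gds >= GDS_DEMENTIA_CUTOFF:
        category = "dementia"
    else:
        category = "asymptomatic_or_mild"
    return DeficitSummary(
        participant_id=profile.participant_id,
        per_test_deficit=per_test,
        domain_deficit=domain_deficit,
        gds=gds,
        hand=hand,
        domain_impaired={d: v >= domain_cutoff for d, v in domain_deficit.items()},
        hand_category=category,
    )


def score_cohort(cnpa: pd.DataFrame, **kwargs) -> list[DeficitSummary]:
    """Score every row of a CNPA table (index = participant id, columns = tests)."""
    out = []
    for pid, row in cnpa.iterrows():
        profile = CnpaProfile(str(pid), {t: float(v) for t, v in row.items()})
        out.append(summarize_deficits(profile, **kwargs))
    return out


def read_cnpa_csv(path) -> pd.DataFrame:
    """Read a CNPA table: one row per participant, one column per test."""
    df = pd.read_csv(path, index_col="participant_id")
    missing = [t for t in ALL_TESTS if t not in df.columns]
    if missing:
        raise ScoringError(f"CNPA table is missing test column(s): {missing}")
    return df


def write_cnpa_csv(cnpa: pd.DataFrame, path) -> None:
    cnpa.to_csv(path, index_label="participant_id")


def write_deficit_summaries(summaries: list[DeficitSummary], path) -> pd.DataFrame:
    """Write one row per participant: domain deficits, GDS, HAND and domain flags."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"participant_id": s.participant_id}
        for d in DOMAINS:
            row[f"deficit_{d}"] = s.domain_deficit[d]
        row["gds"] = s.gds
        row["hand"] = s.hand
        row["hand_category"] = s.hand_category
        for d in DOMAINS:
            row[f"impaired_{d}"] = s.domain_impaired[d]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("participant_id")
    if path is not None:
        df.to_csv(path, index_label="participant_id")
    return df


def prevalence_rows(summaries: list[DeficitSummary]) -> pd.DataFrame:
    """Per-domain impairment prevalence: all participants / HAND present / absent.

    Mirrors the layout of the study's within-domain prevalence table. Note the
    published table header reads "% Domain deficit score > 0" while the text
    applies a ≥ 1 cutoff; this package follows the ≥ 1 rule (see docs/methods.md).
    """
    hand = np.array([s.hand for s in summaries])
    rows = []
    for d in DOMAINS:
        imp = np.array([s.domain_impaired[d] for s in summaries])
        rows.append(
            {
                "domain": d,
                "pct_all": 100.0 * imp.mean(),
                "pct_hand_present": 100.0 * imp[hand].mean() if hand.any() else np.nan,
                "pct_hand_absent": 100.0 * imp[~hand].mean() if (~hand).any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("domain")
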