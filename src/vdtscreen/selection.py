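"""Split-consensus Kruskal-Wallis variable selection.

The screening procedure: build S stratified folds of the labeled cohort
(default S=5, seeded), use the complement of each fold as a training set,
rank every variable within each training set by its Kruskal-Wallis H against
HAND status (descending, ties broken by the variable that appears first in
the original column order), take the top-k prefix of each ranking (default
k=100, guided by an elbow scan of the mean-H-of-top-k curve), and define the
consensus as the intersection of all S top-k lists, ranked by the median H
across splits. Because any two training sets share S−2 of the S folds, the
per-split rankings are correlated; see docs/methods.md for the consequences
under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionConfig",
    "SelectionError",
    "RankedList",
    "Consensus",
    "stratified_training_sets",
    "kruskal_h",
    "kw_rank",
    "h_to_p",
    "mean_topk_curve",
    "find_elbow",
    "elbow_k",
    "form_consensus",
    "group_summaries",
    "abs_pct_median_difference",
    "format_abs_pct",
]


class SelectionError(ValueError):
    """Raised for invalid selection configuration or degenerate inputs."""


@dataclass
class SelectionConfig:
    n_splits: int = 5
    k: int = 100
    seed: int = 0

    def validate(self, n_variables: int | None = None) -> None:
        if self.n_splits < 2:
            raise SelectionError("selection.n_splits must be >= 2")
        if self.k < 1:
            raise SelectionError("selection.k must be >= 1")
        if n_variables is not None and self.k > n_variables:
            raise SelectionError(
                f"selection.k ({self.k}) exceeds the number of candidate "
                f"variables ({n_variables})"
            )


@dataclass
class RankedList:
    """One split's full ranking: every variable with its H, p and rank.

    ``table`` rows are ordered by rank (1 = largest H); columns: variable,
    column_index (position in the original matrix, used for tie-breaking),
    h, p, rank.
    """

    split_id: int
    table: pd.DataFrame

    @property
    def variable_ids(self) -> list[str]:
        return list(self.table["variable"])

    def top_k(self, k: int) -> list[str]:
        return self.variable_ids[:k]


@dataclass
class Consensus:
    """Intersection of all top-k lists, ranked by descending median H."""

    k: int
    table: pd.DataFrame  # columns: variable, median_h, median_p, rank

    @property
    def variable_ids(self) -> list[str]:
        return list(self.table["variable"])

    def __len__(self) -> int:
        return len(self.table)


def stratified_training_sets(labels: np.ndarray, config: SelectionConfig) -> list[np.ndarray]:
    """S training index sets: each the complement of one stratified fold.

    The folds partition the cohort with per-fold class counts within one of
    proportional, so each training set holds (S−1)/S of the samples and any
    two training sets share S−2 folds.
    """
    config.validate()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise SelectionError("labels contain a single class; stratified splitting is undefined")
    if counts.min() < config.n_splits:
        raise SelectionError(
            f"smallest class has {counts.min()} member(s); "
            f"need at least n_splits={config.n_splits} per class"
        )
    skf = StratifiedKFold(n_splits=config.n_splits, shuffle=True, random_state=config.seed)
    all_idx = np.arange(len(labels))
    return [np.setdiff1d(all_idx, test_idx) for _, test_idx in skf.split(all_idx, labels)]


def kruskal_h(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized Kruskal-Wallis H (mid-ranks, tie-corrected) per column.

    ``values`` is (n_samples, n_variables); ``labels`` assigns each sample to
    a group. A column that is constant within the sample (tie correction
    denominator zero) gets H = 0 rather than an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    groups = np.unique(labels)
    if len(groups) < 2:
        raise SelectionError("Kruskal-Wallis needs at least two groups")
    r = rankdata(values, axis=0)
    h0 = np.zeros(values.shape[1])
    for g in groups:
        mask = labels == g
        n_g = int(mask.sum())
        if n_g == 0:
            raise SelectionError(f"group {g!r} has no samples")
        h0 += r[mask].sum(axis=0) ** 2 / n_g
    h0 = 12.0 / (n * (n + 1)) * h0 - 3.0 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n) per column
    correction = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        _, cnt = np.unique(values[:, j], return_counts=True)
        correction[j] = 1.0 - (cnt**3 - cnt).sum() / (n**3 - n)
    h = np.where(correction > 0, h0 / np.where(correction > 0, correction, 1.0), 0.0)
    return np.maximum(h, 0.0)  # clip tiny negative rounding residue


def h_to_p(h, n_groups: int = 2):
    """Upper-tail chi-square probability of the KW statistic (df = groups − 1)."""
    h = np.asarray(h, dtype=float)
    if (h < 0).any():
        raise SelectionError("H must be non-negative")
    p = chi2.sf(h, df=n_groups - 1)
    return float(p) if p.ndim == 0 else p


def kw_rank(
    values: pd.DataFrame,
    labels: np.ndarray,
    train_idx: np.ndarray | None = None,
    split_id: int = 0,
) -> RankedList:
    """Rank all variables of one training set by descending KW H.

    Ties are broken in favour of the variable that appears first in the
    original column order (a stable descending sort on H).
    """
    labels = np.asarray(labels)
    if train_idx is not None:
        sub = values.iloc[train_idx]
        sub_labels = labels[train_idx]
    else:
        sub, sub_labels = values, labels
    h = kruskal_h(sub.to_numpy(), sub_labels)
    p = h_to_p(h)
    order = np.argsort(-h, kind="stable")  # stable: earlier column wins ties
    table = pd.DataFrame(
        {
            "variable": np.array(values.columns)[order],
            "column_index": order,
            "h": h[order],
            "p": p[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return RankedList(split_id=split_id, table=table)


def mean_topk_curve(ranked: RankedList, k_max: int | None = None) -> pd.Series:
    """Mean H of the top-k variables as a function of k (non-increasing)."""
    h = ranked.table["h"].to_numpy()
    if k_max is not None:
        h = h[:k_max]
    k = np.arange(1, len(h) + 1)
    return pd.Series(np.cumsum(h) / k, index=k, name="mean_top_k_h")


def find_elbow(y: np.ndarray, x: np.ndarray | None = None, tol: float = 1e-6) -> float | None:
    """Knee of a decreasing curve (kneedle, chord-distance formulation).

    The curve is normalized to the unit square and the knee is the point of
    maximum perpendicular offset from the chord joining its endpoints — the
    point of maximum curvature for a smooth diminishing-returns curve. Returns
    the x-value of the knee, or None for a (numerically) straight line.
    """
    y = np.asarray(y, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if x is None else np.asarray(x, dtype=float)
    if len(y) < 3:
        raise SelectionError("elbow estimation needs at least 3 points")
    if len(x) != len(y):
        raise SelectionError("x and y must have equal length")
    x_span = x[-1] - x[0]
    y_span = y.max() - y.min()
    if x_span == 0 or y_span == 0:
        return None
    xn = (x - x[0]) / x_span
    yn = (y - y.min()) / y_span
    chord = yn[0] + (yn[-1] - yn[0]) * xn
    d = np.abs(yn - chord)
    if d.max() <= tol:
        return None
    return float(x[int(np.argmax(d))])


def elbow_k(ranked_lists: list[RankedList], k_max: int = 1000) -> dict[int, float | None]:
    """Advisory per-split elbow estimate of k from the mean-top-k H curve."""
    out: dict[int, float | None] = {}
    for rl in ranked_lists:
        curve = mean_topk_curve(rl, k_max=k_max)
        out[rl.split_id] = find_elbow(curve.to_numpy(), curve.index.to_numpy(dtype=float))
    return out


def form_consensus(lists: list[RankedList], k: int) -> Consensus:
    """Intersect the S top-k lists; rank survivors by descending median H.

    An empty intersection is a valid (empty) consensus. Ties on the median H
    are broken by original column order, matching the per-split rule.
    """
    if not lists:
        raise SelectionError("no ranked lists supplied")
    universes = [frozenset(rl.variable_ids) for rl in lists]
    if len(set(universes)) > 1:
        raise SelectionError("ranked lists cover different variable universes")
    members = set(lists[0].top_k(k))
    for rl in lists[1:]:
        members &= set(rl.top_k(k))
    if not members:
        table = pd.DataFrame(columns=["variable", "median_h", "median_p", "rank"])
        return Consensus(k=k, table=table)
    rows = []
    for var in members:
        hs, ps, col = [], [], None
        for rl in lists:
            rec = rl.table.loc[rl.table["variable"] == var].iloc[0]
            hs.append(float(rec["h"]))
            ps.append(float(rec["p"]))
            col = int(rec["column_index"])
        rows.append(
            {
                "variable": var,
                "column_index": col,
                "median_h": float(np.median(hs)),
                "median_p": float(np.median(ps)),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        by=["median_h", "column_index"], ascending=[False, True], kind="stable"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return Consensus(k=k, table=table.reset_index(drop=True)[
        ["variable", "column_index", "median_h", "median_p", "rank"]
    ])


def abs_pct_median_difference(median_present: float, median_absent: float) -> float | None:
    """|median(HAND) − median(no HAND)| / |median(HAND)| × 100.

    Undefined (None) when the HAND-present group median is zero — reported as
    "UNDEF" in the published table layout.
    """
    if median_present == 0:
        return None
    return abs(median_present - median_absent) / abs(median_present) * 100.0


def format_abs_pct(value: float | None) -> str:
    return "UNDEF" if value is None else f"{round(value):.0f}%"


def group_summaries(
    values: pd.DataFrame,
    labels: np.ndarray,
    consensus: Consensus,
) -> pd.DataFrame:
    """Distribution table for the consensus variables, by HAND status.

    For each variable: median and IQR (Q3 − Q1, linear-interpolation
    quantiles) overall and within each group, the Abs% median difference, and
    the consensus median H / p.
    """
    labels = np.asarray(labels).astype(bool)
    if not labels.any() or labels.all():
        raise SelectionError("both HAND-present and HAND-absent groups must be non-empty")
    missing = [v for v in consensus.variable_ids if v not in values.columns]
    if missing:
        raise SelectionError(f"consensus variable(s) not in matrix: {missing}")
    rows = []
    for _, rec in consensus.table.iterrows():
        v = values[rec["variable"]].to_numpy(dtype=float)
        groups = {"all": v, "present": v[labels], "absent": v[~labels]}
        row: dict[str, object] = {"rank": int(rec["rank"]), "variable": rec["variable"]}
        for name, g in groups.items():
            q1, med, q3 = np.percentile(g, [25, 50, 75])
            row[f"median_{name}"] = med
            row[f"iqr_{name}"] = q3 - q1
        diff = abs_pct_median_difference(row["median_present"], row["median_absent"])
        row["abs_pct_median_diff"] = np.nan if diff is None else diff
        row["abs_pct_label"] = format_abs_pct(diff)
        row["median_h"] = rec["median_h"]
        row["median_p"] = rec["median_p"]
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "variable",
            "median_all", "iqr_all",
            "median_present", "iqr_present",
            "median_absent", "iqr_absent",
            "abs_pct_median_diff", "abs_pct_label",
            "median_h", "median_p",
        ],
    )
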