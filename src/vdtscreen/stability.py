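"""Stability diagnostics for the per-split top-k lists.

Pairwise Jaccard similarity of the top-k variable *sets*, the normalized
top-k Kendall distance between the top-k *rankings* (Fagin-style partial-list
comparison with penalty p for pairs whose relative order the two lists cannot
determine), and the analytic probability (k/M)^S of one variable landing in
all S lists were they drawn independently and uniformly.

Note on naming: the study literature sometimes calls the Kendall quantity a
"correlation", but the underlying partial-list framework defines a distance —
0 for identical lists. This module returns the distance, normalized so that
two disjoint lists score exactly 1 at any penalty p (the normalizer is the
disjoint-list value, which itself depends on p; the *raw* distance is
monotone in p, the normalized one need not be — see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

__all__ = [
    "StabilityConfig",
    "StabilityError",
    "StabilityReport",
    "jaccard",
    "topk_kendall",
    "null_selection_probability",
    "stability_report",
    "plot_jaccard_heatmap",
]


class StabilityError(ValueError):
    """Raised for invalid stability-metric inputs."""


@dataclass
class StabilityConfig:
    kendall_penalty: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.kendall_penalty <= 1.0:
            raise StabilityError("kendall_penalty must be in [0, 1]")


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for two id sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise StabilityError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def topk_kendall(a, b, p: float = 0.5, normalize: bool = True) -> float:
    """Top-k Kendall distance between two partial rankings with penalty ``p``.

    Every unordered pair from the union of the two lists contributes:

    * both elements in both lists — 1 if ranked in opposite orders, else 0;
    * both in one list, one of them also in the other — 0 if the shared
      element is ranked above the unshared one (consistent with the unshared
      element falling outside the other list's top k), else 1;
    * one element exclusive to each list — 1 (the lists are known to
      disagree);
    * both in one list only — ``p`` (the order in the other list is
      undetermined; p = 0.5 is the neutral convention).

    With ``normalize=True`` the raw sum is divided by its value for two
    disjoint lists of the same length, so identical lists score 0 and
    disjoint lists score exactly 1 for any p.
    """
    a, b = list(a), list(b)
    if len(set(a)) != len(a):
        raise StabilityError("list a contains duplicate ids")
    if len(set(b)) != len(b):
        raise StabilityError("list b contains duplicate ids")
    if len(a) != len(b):
        raise StabilityError("top-k lists must have equal length")
    if not 0.0 <= p <= 1.0:
        raise StabilityError("penalty p must be in [0, 1]")
    k = len(a)
    if k == 0:
        raise StabilityError("top-k lists must be non-empty")
    pos_a = {v: i for i, v in enumerate(a)}
    pos_b = {v: i for i, v in enumerate(b)}
    raw = 0.0
    for i, j in combinations(sorted(pos_a.keys() | pos_b.keys(), key=str), 2):
        ia, ja = pos_a.get(i), pos_a.get(j)
        ib, jb = pos_b.get(i), pos_b.get(j)
        in_a = (ia is not None, ja is not None)
        in_b = (ib is not None, jb is not None)
        if all(in_a) and all(in_b):
            if (ia < ja) != (ib < jb):
                raw += 1.0
        elif all(in_a) and any(in_b):
            # one of the pair missing from b: b implicitly ranks it below k
            present_b = i if ib is not None else j
            if (ia < ja) != (present_b == i):
                raw += 1.0
        elif all(in_b) and any(in_a):
            present_a = i if ia is not None else j
            if (ib < jb) != (present_a == i):
                raw += 1.0
        elif all(in_a) or all(in_b):
            raw += p  # both confined to a single list: order undetermined
        else:
            raw += 1.0  # one exclusive to each list
    if not normalize:
        return raw
    max_raw = k * k + p * k * (k - 1)
    return raw / max_raw


def null_selection_probability(k: int, m: int, s: int) -> float:
    """(k/M)^S: chance one variable lands in all S top-k lists independently."""
    if not 1 <= k <= m:
        raise StabilityError(f"need 1 <= k <= M, got k={k}, M={m}")
    if s < 1:
        raise StabilityError("S must be >= 1")
    return (k / m) ** s


@dataclass
class StabilityReport:
    jaccard_matrix: np.ndarray
    kendall_matrix: np.ndarray
    intersection_matrix: np.ndarray
    mean_jaccard: float
    mean_kendall: float
    mean_intersection: float
    null_probability: float
    k: int
    n_variables: int
    kendall_penalty: float

    def to_json(self, path=None) -> str:
        obj = {
            "k": self.k,
            "n_variables": self.n_variables,
            "kendall_penalty": self.kendall_penalty,
            "jaccard_matrix": self.jaccard_matrix.tolist(),
            "kendall_matrix": self.kendall_matrix.tolist(),
            "intersection_matrix": self.intersection_matrix.tolist(),
            "mean_jaccard": self.mean_jaccard,
            "mean_kendall": self.mean_kendall,
            "mean_intersection": self.mean_intersection,
            "null_probability": self.null_probability,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def stability_report(
    top_lists: list[list[str]],
    n_variables: int,
    config: StabilityConfig | None = None,
) -> StabilityReport:
    """All pairwise stability metrics for S top-k lists over one universe."""
    config = config or StabilityConfig()
    config.validate()
    s = len(top_lists)
    if s < 2:
        raise StabilityError("need at least two lists")
    k = len(top_lists[0])
    if any(len(lst) != k for lst in top_lists):
        raise StabilityError("all top-k lists must have the same length")
    jac = np.eye(s)
    ken = np.zeros((s, s))
    inter = np.full((s, s), float(k))
    for i, j in combinations(range(s), 2):
        jac[i, j] = jac[j, i] = jaccard(top_lists[i], top_lists[j])
        ken[i, j] = ken[j, i] = topk_kendall(top_lists[i], top_lists[j], config.kendall_penalty)
        inter[i, j] = inter[j, i] = len(set(top_lists[i]) & set(top_lists[j]))
    off = ~np.eye(s, dtype=bool)
    return StabilityReport(
        jaccard_matrix=jac,
        kendall_matrix=ken,
        intersection_matrix=inter,
        mean_jaccard=float(jac[off].mean()),
        mean_kendall=float(ken[off].mean()),
        mean_intersection=float(inter[off].mean()),
        null_probability=null_selection_probability(k, n_variables, s),
        k=k,
        n_variables=n_variables,
        kendall_penalty=config.kendall_penalty,
    )


def plot_jaccard_heatmap(report: StabilityReport, path) -> None:
    """Heat map of pairwise Jaccard values with intersection sizes annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = report.jaccard_matrix.shape[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(report.jaccard_matrix, vmin=0, vmax=1, cmap="viridis")
    for i in range(s):
        for j in range(s):
            ax.text(
                j, i, f"{int(report.intersection_matrix[i, j])}",
                ha="center", va="center", color="white", fontsize=8,
            )
    ax.set_xticks(range(s), [f"split {i}" for i in range(s)])
    ax.set_yticks(range(s), [f"split {i}" for i in range(s)])
    ax.set_title(f"Pairwise Jaccard of top-{report.k} lists")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
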