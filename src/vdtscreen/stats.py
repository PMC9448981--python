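"""Secondary and descriptive statistics around the consensus.

Spearman associations between consensus variables and the seven binary
domain-impairment flags (two significance tiers: per-cell α and Bonferroni
α/m over all tested cells), Fisher exact tests for the per-domain prevalence
contrasts, the uncorrected 2×2 Pearson chi-square, and the two-sample
rank-sum comparison (R-style W statistic with the tie-corrected normal
approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "DomainAssociationMatrix",
    "spearman_domain_matrix",
    "exact_test_2x2",
    "chi_square_2x2",
    "rank_sum_w",
    "prevalence_table",
    "drug_use_comparisons",
]


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass
class DomainAssociationMatrix:
    """Spearman rho / p per (variable, domain) with two significance tiers."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant_raw: pd.DataFrame
    significant_bonferroni: pd.DataFrame
    alpha: float
    n_comparisons: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_comparisons

    def tidy(self) -> pd.DataFrame:
        """Long-format table: one row per (variable, domain) cell."""
        rows = []
        for var in self.rho.index:
            for dom in self.rho.columns:
                rows.append(
                    {
                        "variable": var,
                        "domain": dom,
                        "rho": self.rho.loc[var, dom],
                        "p": self.p.loc[var, dom],
                        "significant_raw": bool(self.significant_raw.loc[var, dom]),
                        "significant_bonferroni": bool(
                            self.significant_bonferroni.loc[var, dom]
                        ),
                    }
                )
        return pd.DataFrame(rows)


def spearman_domain_matrix(
    values: pd.DataFrame,
    variable_ids: list[str],
    domain_flags: pd.DataFrame,
    alpha: float = 0.05,
) -> DomainAssociationMatrix:
    """Spearman rho of each selected variable against each domain flag.

    The Bonferroni family is every tested cell: m = |variables| × |domains|.
    A cell with a constant variable or a constant flag has no defined
    correlation and is reported as NaN (never significant), not raised.
    """
    missing = [v for v in variable_ids if v not in values.columns]
    if missing:
        raise StatsError(f"variable(s) not in matrix: {missing}")
    if len(domain_flags) != len(values):
        raise StatsError("domain flags are not aligned with the matrix rows")
    domains = list(domain_flags.columns)
    m = len(variable_ids) * len(domains)
    rho = pd.DataFrame(index=variable_ids, columns=domains, dtype=float)
    pval = pd.DataFrame(index=variable_ids, columns=domains, dtype=float)
    for var in variable_ids:
        x = values[var].to_numpy(dtype=float)
        for dom in domains:
            y = domain_flags[dom].to_numpy(dtype=float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                rho.loc[var, dom] = np.nan
                pval.loc[var, dom] = np.nan
                continue
            res = sps.spearmanr(x, y)
            rho.loc[var, dom] = res.statistic
            pval.loc[var, dom] = res.pvalue
    sig_raw = pval < alpha
    sig_bonf = pval < alpha / m
    return DomainAssociationMatrix(
        rho=rho,
        p=pval,
        significant_raw=sig_raw.fillna(False),
        significant_bonferroni=sig_bonf.fillna(False),
        alpha=alpha,
        n_comparisons=m,
    )


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise StatsError("table counts must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise StatsError("table counts must be integers")
        t = np.round(t).astype(int)
    return t


def exact_test_2x2(table) -> float:
    """Two-sided Fisher exact p-value (hypergeometric enumeration)."""
    t = _check_2x2(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("Fisher exact test undefined for a table with an empty margin")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = 1."""
    t = _check_2x2(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("chi-square undefined for a table with an empty margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def rank_sum_w(x, y) -> tuple[float, float]:
    """Two-sample rank-sum test: (W, two-sided p).

    W is the Mann-Whitney U of the first sample (the convention R's
    ``wilcox.test`` prints); p uses the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def prevalence_table(domain_flags: pd.DataFrame, hand: np.ndarray) -> pd.DataFrame:
    """Per-domain impairment prevalence by HAND status with Fisher exact p."""
    hand = np.asarray(hand).astype(bool)
    if len(hand) != len(domain_flags):
        raise StatsError("HAND labels not aligned with domain flags")
    rows = []
    for dom in domain_flags.columns:
        imp = domain_flags[dom].to_numpy().astype(bool)
        tab = [
            [int((imp & hand).sum()), int((~imp & hand).sum())],
            [int((imp & ~hand).sum()), int((~imp & ~hand).sum())],
        ]
        rows.append(
            {
                "domain": dom,
                "pct_all": 100.0 * imp.mean(),
                "pct_hand_present": 100.0 * imp[hand].mean(),
                "pct_hand_absent": 100.0 * imp[~hand].mean(),
                "p_exact": exact_test_2x2(tab),
            }
        )
    return pd.DataFrame(rows).set_index("domain")


def drug_use_comparisons(
    error_scores: np.ndarray,
    drug_positive: np.ndarray,
    hand: np.ndarray,
) -> dict[str, float]:
    """Drug-use sensitivity checks: rank-sum on the error score, chi-square on HAND.

    Mirrors the cohort-description analyses: does allowable drug use shift the
    VDT Error Score (rank-sum W) or the prevalence of HAND (2×2 chi-square)?
    """
    drug_positive = np.asarray(drug_positive).astype(bool)
    hand = np.asarray(hand).astype(bool)
    w, p_w = rank_sum_w(error_scores[drug_positive], error_scores[~drug_positive])
    tab = [
        [int((drug_positive & hand).sum()), int((drug_positive & ~hand).sum())],
        [int((~drug_positive & hand).sum()), int((~drug_positive & ~hand).sum())],
    ]
    chi2_stat, p_chi = chi_square_2x2(tab)
    return {"rank_sum_w": w, "rank_sum_p": p_w, "chi_square": chi2_stat, "chi_square_p": p_chi}
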