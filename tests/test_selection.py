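"""Stratified splits, KW ranking, elbow, consensus and group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

from vdtscreen import selection
from vdtscreen.selection import (
    Consensus,
    RankedList,
    SelectionConfig,
    SelectionError,
    abs_pct_median_difference,
    find_elbow,
    form_consensus,
    format_abs_pct,
    group_summaries,
    h_to_p,
    kruskal_h,
    kw_rank,
    mean_topk_curve,
    stratified_training_sets,
)


def kw_bruteforce(values: np.ndarray, labels: np.ndarray) -> float:
    """Independent oracle: explicit mid-ranks and explicit tie correction."""
    values = np.asarray(values, float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1  # average of 1-based positions i+1..j+1
        for idx in order[i : j + 1]:
            ranks[idx] = midrank
        i = j + 1
    h = 0.0
    for g in np.unique(labels):
        rg = ranks[labels == g]
        h += rg.sum() ** 2 / len(rg)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie_sum = 0.0
    for v in np.unique(values):
        t = (values == v).sum()
        tie_sum += t**3 - t
    denom = 1.0 - tie_sum / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def make_ranked(split_id, variables, h_values) -> RankedList:
    order = np.argsort(-np.asarray(h_values), kind="stable")
    table = pd.DataFrame(
        {
            "variable": np.asarray(variables)[order],
            "column_index": order,
            "h": np.asarray(h_values, float)[order],
            "p": h_to_p(np.asarray(h_values, float)[order]),
            "rank": np.arange(1, len(variables) + 1),
        }
    )
    return RankedList(split_id=split_id, table=table)


class TestStratifiedSplits:
    def test_study_scale_fold_arithmetic(self):
        labels = np.array([1] * 35 + [0] * 27)
        trains = stratified_training_sets(labels, SelectionConfig(seed=0))
        assert len(trains) == 5
        for tr in trains:
            fold = np.setdiff1d(np.arange(62), tr)
            assert (labels[fold] == 1).sum() == 7
            assert (labels[fold] == 0).sum() in (5, 6)
            assert len(tr) in (49, 50)
        # folds partition the cohort
        folds = [frozenset(np.setdiff1d(np.arange(62), tr)) for tr in trains]
        assert sum(len(f) for f in folds) == 62
        assert len(frozenset().union(*folds)) == 62

    def test_training_sets_share_three_folds(self):
        labels = np.array([1] * 35 + [0] * 27)
        trains = stratified_training_sets(labels, SelectionConfig(seed=0))
        share = len(np.intersect1d(trains[0], trains[1])) / 62
        assert 0.55 <= share <= 0.65  # 3 of 5 folds

    def test_single_class_rejected(self):
        with pytest.raises(SelectionError):
            stratified_training_sets(np.ones(20), SelectionConfig())

    def test_small_class_rejected(self):
        labels = np.array([1] * 3 + [0] * 17)
        with pytest.raises(SelectionError, match="n_splits"):
            stratified_training_sets(labels, SelectionConfig(n_splits=5))

    def test_seeded_determinism(self):
        labels = np.tile([0, 1], 15)
        a = stratified_training_sets(labels, SelectionConfig(seed=42))
        b = stratified_training_sets(labels, SelectionConfig(seed=42))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestKruskalWallis:
    def test_textbook_two_group_case(self):
        h = kruskal_h(np.array([1, 2, 3, 4, 5, 6], float), np.array([0, 0, 0, 1, 1, 1]))
        assert h[0] == pytest.approx(3.857142857, abs=1e-8)
        assert h_to_p(h[0]) == pytest.approx(0.0495, abs=1e-3)

    def test_matches_bruteforce_and_scipy_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(6, 31))
            x = rng.choice([0.0, 1.0, 2.5, 7.0, -1.0], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            mine = kruskal_h(x, labels)[0]
            assert mine == pytest.approx(kw_bruteforce(x, labels), abs=1e-10)
            if np.ptp(x) > 0:
                ref = kruskal(x[labels == 0], x[labels == 1]).statistic
                assert mine == pytest.approx(ref, abs=1e-10)

    def test_constant_variable_gets_h_zero(self):
        h = kruskal_h(np.ones(10), np.array([0] * 5 + [1] * 5))
        assert h[0] == 0.0

    def test_tie_break_prefers_earlier_column(self):
        x = np.column_stack([np.arange(8.0), np.arange(8.0)])  # identical columns
        values = pd.DataFrame(x, columns=["late_copy", "early_copy"][::-1])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ranked = kw_rank(values, labels)
        assert ranked.table["h"].nunique() == 1
        assert ranked.variable_ids[0] == values.columns[0]

    def test_negative_h_rejected_by_h_to_p(self):
        with pytest.raises(SelectionError):
            h_to_p(-0.1)

    def test_h_to_p_monotone_decreasing(self):
        p = h_to_p(np.array([0.0, 1.0, 5.0, 10.0]))
        assert p[0] == 1.0
        assert np.all(np.diff(p) < 0)


class TestElbow:
    def test_straight_line_has_no_knee(self):
        assert find_elbow(np.linspace(10, 0, 200)) is None

    def test_flat_then_linear_drop_knees_at_breakpoint(self):
        k = np.arange(1, 1001, dtype=float)
        y = np.where(k <= 150, 10.0, 10.0 - 0.01 * (k - 150))
        assert find_elbow(y, k) == pytest.approx(150, abs=5)

    def test_too_short_curve_rejected(self):
        with pytest.raises(SelectionError):
            find_elbow(np.array([1.0, 0.5]))

    def test_mean_topk_curve_nonincreasing(self, small_features, small_labels):
        ranked = kw_rank(small_features.values, small_labels)
        curve = mean_topk_curve(ranked).to_numpy()
        assert np.all(np.diff(curve) <= 1e-12)


class TestConsensus:
    def test_identical_lists_give_full_topk_in_order(self):
        lists = [make_ranked(s, ["a", "b", "c", "d"], [9.0, 7.0, 5.0, 1.0]) for s in range(5)]
        cons = form_consensus(lists, 3)
        assert cons.variable_ids == ["a", "b", "c"]

    def test_disjoint_topk_gives_empty_consensus(self):
        variables = [f"v{i}" for i in range(10)]
        lists = []
        for s in range(5):
            h = np.zeros(10)
            h[2 * s] = 10.0  # a different leader per split
            lists.append(make_ranked(s, variables, h))
        cons = form_consensus(lists, 1)
        assert len(cons) == 0

    def test_median_h_across_splits(self):
        hs = [7.0, 7.33, 7.5, 6.9, 8.0]
        lists = [make_ranked(s, ["v", "w"], [h, 0.1]) for s, h in enumerate(hs)]
        cons = form_consensus(lists, 1)
        assert cons.table.loc[0, "median_h"] == pytest.approx(7.33)

    def test_monotone_in_k(self, small_features, small_labels):
        cfg = SelectionConfig(seed=0)
        trains = stratified_training_sets(small_labels, cfg)
        lists = [kw_rank(small_features.values, small_labels, tr, s)
                 for s, tr in enumerate(trains)]
        prev: set = set()
        for k in (5, 20, 50, 120):
            cons = set(form_consensus(lists, k).variable_ids)
            assert prev <= cons
            prev = cons

    def test_membership_invariant_to_column_permutation(self, small_features, small_labels):
        cfg = SelectionConfig(seed=0)
        trains = stratified_training_sets(small_labels, cfg)
        values = small_features.values
        lists = [kw_rank(values, small_labels, tr, s) for s, tr in enumerate(trains)]
        base = set(form_consensus(lists, 40).variable_ids)
        rng = np.random.default_rng(1)
        shuffled = values[list(values.columns[rng.permutation(values.shape[1])])]
        lists_p = [kw_rank(shuffled, small_labels, tr, s) for s, tr in enumerate(trains)]
        permuted = set(form_consensus(lists_p, 40).variable_ids)
        # identical except possibly at tie boundaries; require near-total agreement
        assert len(base ^ permuted) <= 2

    def test_mismatched_universes_rejected(self):
        a = make_ranked(0, ["a", "b"], [2.0, 1.0])
        b = make_ranked(1, ["a", "c"], [2.0, 1.0])
        with pytest.raises(SelectionError, match="universe"):
            form_consensus([a, b], 1)


class TestGroupSummaries:
    @pytest.mark.parametrize(
        "mp, ma, label",
        [(46.00, 27.00, "41%"), (-4.52, 3.81, "184%"), (0.0, 5.0, "UNDEF"), (1.0, 1.0, "0%")],
    )
    def test_abs_pct_median_difference(self, mp, ma, label):
        assert format_abs_pct(abs_pct_median_difference(mp, ma)) == label

    def test_summary_table_numbers(self):
        values = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 10.0, 20.0, 30.0, 40.0]})
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cons = Consensus(
            k=1,
            table=pd.DataFrame(
                {"variable": ["v"], "column_index": [0], "median_h": [5.0],
                 "median_p": [0.02], "rank": [1]}
            ),
        )
        table = group_summaries(values, labels, cons)
        assert table.loc[0, "median_present"] == pytest.approx(25.0)
        assert table.loc[0, "median_absent"] == pytest.approx(2.5)
        assert table.loc[0, "iqr_present"] == pytest.approx(np.percentile([10, 20, 30, 40], 75)
                                                            - np.percentile([10, 20, 30, 40], 25))
        assert table.loc[0, "abs_pct_label"] == "90%"

    def test_single_group_rejected(self, small_features):
        cons = Consensus(k=1, table=pd.DataFrame(
            {"variable": [small_features.variable_ids[0]], "column_index": [0],
             "median_h": [1.0], "median_p": [0.3], "rank": [1]}))
        with pytest.raises(SelectionError):
            group_summaries(small_features.values, np.ones(len(small_features.values)), cons)
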