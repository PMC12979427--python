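"""Evaluation protocols: folds, negatives, metrics, thresholds, strata."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msat.protocols import (FoldPlan, attach_negatives, cold_start_split,
                            compute_metrics, degree_strata,
                            make_fold_plans, make_imbalance_testsets,
                            paired_fold_test, sample_negatives,
                            select_threshold)


def _pairs(n, n_adr=50):
    return [(f"C{i % 17}", f"A{i % n_adr}_{i}") for i in range(n)]


# -- folds --------------------------------------------------------------------

def test_fold_arithmetic_100_positives():
    plans = make_fold_plans(_pairs(100), k=10, seed=0)
    assert len(plans) == 10
    for p in plans:
        assert len(p.test_pos) == 10
        assert len(p.val_pos) == 9    # round(0.1 * 90)
        assert len(p.train_pos) == 81
        assert p.positive_union == set(_pairs(100))


def test_fold_arithmetic_101_positives():
    plans = make_fold_plans(_pairs(101), k=10, seed=0)
    sizes = sorted(len(p.test_pos) for p in plans)
    assert sizes == [10] * 9 + [11]
    assert sum(len(p.test_pos) for p in plans) == 101


def test_folds_are_deterministic_and_disjoint():
    a = make_fold_plans(_pairs(53), k=5, seed=7)
    b = make_fold_plans(_pairs(53), k=5, seed=7)
    assert [p.test_pos for p in a] == [p.test_pos for p in b]
    seen = set()
    for p in a:
        assert not (set(p.test_pos) & seen)
        seen |= set(p.test_pos)
        assert not (set(p.train_pos) & set(p.val_pos))
        assert not (set(p.train_pos) & set(p.test_pos))


def test_k_exceeding_positives_is_error():
    with pytest.raises(ValueError, match="exceeds"):
        make_fold_plans(_pairs(3), k=10)


def test_fold_plan_json_round_trip():
    plan = make_fold_plans(_pairs(30), k=3, seed=1)[0]
    attach_negatives(plan, {f"A{i}" for i in range(40)}, ratio=2)
    back = FoldPlan.from_json(plan.to_json())
    assert back.train_pos == plan.train_pos
    assert back.negatives == plan.negatives
    assert back.seeds == plan.seeds


# -- negative sampling ----------------------------------------------------------

def test_negatives_never_collide_with_positive_union():
    positives = [(f"C{i}", f"A{i}") for i in range(30)]
    union = set(positives)
    adr_set = {f"A{i}" for i in range(40)}
    negs = sample_negatives(positives, union, adr_set, ratio=3, seed=5)
    assert len(negs) == 90
    assert not (set(negs) & union)  # exhaustive scan
    # type constraint: CMM fixed per positive, ADR from the typed universe
    assert [n[0] for n in negs] == [p[0] for p in positives for _ in range(3)]
    assert all(n[1] in adr_set for n in negs)


def test_negatives_are_seed_reproducible_and_seed_sensitive():
    positives = [(f"C{i}", f"A{i}") for i in range(20)]
    union = set(positives)
    adr_set = {f"A{i}" for i in range(200)}
    a = sample_negatives(positives, union, adr_set, 2, seed=9)
    b = sample_negatives(positives, union, adr_set, 2, seed=9)
    c = sample_negatives(positives, union, adr_set, 2, seed=10)
    assert a == b
    assert a != c


def test_negatives_deduplicated_per_positive():
    negs = sample_negatives([("C0", "A0")], {("C0", "A0")},
                            {"A0", "A1", "A2"}, ratio=2, seed=0)
    assert sorted(negs) == [("C0", "A1"), ("C0", "A2")]


def test_negative_exhaustion_warns_and_underfills():
    # only one legal negative exists but two are requested
    with pytest.warns(UserWarning, match="exhausted"):
        negs = sample_negatives([("C0", "A0")], {("C0", "A0")},
                                {"A0", "A1"}, ratio=2, seed=0)
    assert negs == [("C0", "A1")]


def test_imbalance_testsets_are_nested_and_ratio_correct():
    plan = make_fold_plans(_pairs(60), k=3, seed=2)[0]
    attach_negatives(plan, {f"B{i}" for i in range(500)}, ratio=1)
    sets = make_imbalance_testsets(plan, {f"B{i}" for i in range(500)},
                                   ratios=(1, 2, 5, 10))
    n_test = len(plan.test_pos)
    for r in (1, 2, 5, 10):
        assert len(sets[r]) == r * n_test
        forbidden = plan.positive_union | set(plan.negatives["train"]) \
            | set(plan.negatives["val"])
        assert not (set(sets[r]) & forbidden)
    assert set(sets[1]) <= set(sets[2]) <= set(sets[5]) <= set(sets[10])


# -- metrics --------------------------------------------------------------------

def test_metrics_match_hand_arithmetic():
    # tp=45, fp=5, tn=40, fn=10
    scores = np.r_[np.ones(45), np.ones(5), np.zeros(40), np.zeros(10)]
    labels = np.r_[np.ones(45), np.zeros(5), np.zeros(40), np.ones(10)]
    rep = compute_metrics(scores, labels, threshold=0.5)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (45, 5, 40, 10)
    assert rep.precision == pytest.approx(0.9)
    assert rep.recall == pytest.approx(45 / 55)
    assert rep.f1 == pytest.approx(2 * 0.9 * (45 / 55) / (0.9 + 45 / 55))
    assert rep.mcc == pytest.approx(
        (45 * 40 - 5 * 10) / np.sqrt(50.0 * 55 * 45 * 50))


def test_auroc_matches_brute_force_concordance():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 2, size=60)
    labels[0], labels[1] = 0, 1  # both classes present
    scores = rng.random(60)
    rep = compute_metrics(scores, labels, threshold=0.5)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert rep.auroc == pytest.approx(conc / (len(pos) * len(neg)))


def test_metrics_zero_denominators_give_zero():
    rep = compute_metrics(np.zeros(4), np.array([1, 1, 0, 0]), threshold=0.5)
    assert rep.recall == 0.0 and rep.f1 == 0.0 and rep.mcc == 0.0


def test_metrics_single_class_has_no_ranking_metrics():
    rep = compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
    assert rep.auroc is None and rep.auprc is None


def test_metrics_rejects_empty_or_misaligned():
    with pytest.raises(ValueError):
        compute_metrics(np.zeros(0), np.zeros(0))
    with pytest.raises(ValueError):
        compute_metrics(np.zeros(3), np.zeros(2))


def test_threshold_selection_exhaustive_grid_oracle():
    rng = np.random.default_rng(1)
    scores = rng.random(40)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    tau = select_threshold(scores, labels)
    f1s = {float(t): compute_metrics(scores, labels, threshold=float(t)).f1
           for t in np.unique(scores)}
    best = max(f1s.values())
    assert f1s[tau] == pytest.approx(best)
    # smaller-tau tie-break
    ties = [t for t, f in f1s.items() if abs(f - best) <= 1e-15]
    assert tau == min(ties)


def test_threshold_selection_tie_break_prefers_smaller_tau():
    # both candidate thresholds classify identically on positives
    scores = np.array([0.2, 0.4, 0.9])
    labels = np.array([0, 1, 1])
    # tau=0.4 -> tp=2 fp=0; tau=0.9 -> tp=1 fp=0 (worse); tau=0.2 -> fp=1
    assert select_threshold(scores, labels) == pytest.approx(0.4)
    # exact tie: duplicate scores
    scores2 = np.array([0.5, 0.5, 0.5])
    labels2 = np.array([0, 1, 1])
    assert select_threshold(scores2, labels2) == pytest.approx(0.5)


def test_threshold_selection_single_class_is_error():
    with pytest.raises(ValueError, match="both classes"):
        select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


# -- stratification / cold start / paired tests --------------------------------

def test_degree_strata_20_60_20_arithmetic():
    degs = {f"N{i}": 100 - i for i in range(10)}
    strata = degree_strata(degs)
    assert [len(strata[s]) for s in ("Head", "Medium", "Tail")] == [2, 6, 2]
    assert strata["Head"] == ["N0", "N1"]
    assert strata["Tail"] == ["N8", "N9"]


def test_degree_strata_ceil_on_five_nodes():
    degs = {f"N{i}": i for i in range(5)}
    strata = degree_strata(degs)
    assert [len(strata[s]) for s in ("Head", "Medium", "Tail")] == [1, 3, 1]
    assert strata["Head"] == ["N4"]


def test_degree_strata_tie_break_on_id():
    degs = {"B": 5, "A": 5, "C": 5, "D": 1, "E": 0}
    strata = degree_strata(degs)
    assert strata["Head"] == ["A"]


def test_degree_strata_too_few_is_error():
    with pytest.raises(ValueError, match="at least 5"):
        degree_strata({"A": 1, "B": 2})


def test_cold_start_split_fractions():
    tagged = [("C1", "A1", "faers"), ("C2", "A2", "faers"),
              ("C2", "A3", "literature"), ("C3", "A4", "literature")]
    train, test, unseen = cold_start_split(tagged)
    assert train == [("C1", "A1"), ("C2", "A2")]
    assert test == [("C2", "A3"), ("C3", "A4")]
    assert unseen == pytest.approx(0.5)  # C3 unseen, C2 seen
    with pytest.raises(ValueError):
        cold_start_split([("C1", "A1", "faers")])


def test_paired_fold_test_matches_scipy_and_flags_degenerate():
    from scipy import stats
    a = np.array([0.9, 0.85, 0.88, 0.91])
    b = np.array([0.8, 0.82, 0.79, 0.86])
    t, p, degen = paired_fold_test(a, b)
    ref = stats.ttest_rel(a, b)
    assert not degen
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    t2, p2, degen2 = paired_fold_test(a, a + 0.01)
    assert degen2 and np.isnan(t2) and np.isnan(p2)
    with pytest.raises(ValueError):
        paired_fold_test([1.0], [2.0])


@settings(max_examples=25, deadline=None)
@given(n=st.integers(min_value=10, max_value=80),
       k=st.integers(min_value=2, max_value=8),
       seed=st.integers(min_value=0, max_value=999))
def test_fold_property_partition_and_sizes(n, k, seed):
    positives = [(f"C{i}", f"A{i}") for i in range(n)]
    plans = make_fold_plans(positives, k=k, seed=seed)
    all_test = [p for plan in plans for p in plan.test_pos]
    assert sorted(all_test) == sorted(positives)
    sizes = [len(p.test_pos) for p in plans]
    assert max(sizes) - min(sizes) <= 1
    for plan in plans:
        assert len(plan.train_pos) + len(plan.val_pos) + \
            len(plan.test_pos) == n
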