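"""Leakage-safe evaluation machinery for CMM-ADR link prediction.

Covers: stratified k-fold splitting with a nested train/validation split
(81:9:10 overall at k=10), type-constrained negative sampling with collision
filtering against the fold's full positive union, classification metrics
(precision, recall, F1, MCC, AUROC, AUPRC), validation-side F1-maximising
threshold selection, class-imbalance stress sets, degree-stratified CMM
grouping, cold-start source-transfer splits, and fold-wise paired t-tests.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

Pair = tuple[str, str]


@dataclass
class FoldPlan:
    """One cross-validation fold: positive splits, cached negatives, seeds."""

    fold_id: int
    train_pos: list[Pair]
    val_pos: list[Pair]
    test_pos: list[Pair]
    negatives: dict[str, list[Pair]] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    @property
    def positive_union(self) -> set[Pair]:
        return set(self.train_pos) | set(self.val_pos) | set(self.test_pos)

    def to_json(self) -> str:
        d = asdict(self)
        d["train_pos"] = [list(p) for p in self.train_pos]
        d["val_pos"] = [list(p) for p in self.val_pos]
        d["test_pos"] = [list(p) for p in self.test_pos]
        d["negatives"] = {k: [list(p) for p in v]
                          for k, v in self.negatives.items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(fold_id=d["fold_id"],
                   train_pos=[tuple(p) for p in d["train_pos"]],
                   val_pos=[tuple(p) for p in d["val_pos"]],
                   test_pos=[tuple(p) for p in d["test_pos"]],
                   negatives={k: [tuple(p) for p in v]
                              for k, v in d["negatives"].items()},
                   seeds=d["seeds"])


def _fold_seed(seed: int, fold: int, stream: int = 0) -> int:
    # distinct, reproducible 31-bit seeds per (fold, stream)
    return int((seed * 100003 + fold * 131 + stream) % (2 ** 31))


def make_fold_plans(positives: list[Pair], k: int = 10,
                    seed: int = 42) -> list[FoldPlan]:
    """Partition positives into k near-equal test folds; split each fold's
    development set 90/10 into train/validation with the fold's seed.

    Deterministic given the seed; fold test sizes differ by at most one.
    """
    n = len(positives)
    if k > n:
        raise ValueError(f"k={k} exceeds number of positives ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    chunks = np.array_split(order, k)
    plans = []
    for f, test_idx in enumerate(chunks):
        test = [positives[i] for i in test_idx]
        dev_idx = np.concatenate([c for j, c in enumerate(chunks) if j != f])
        split_seed = _fold_seed(seed, f, stream=0)
        dev_rng = np.random.default_rng(split_seed)
        dev_perm = dev_rng.permutation(len(dev_idx))
        n_val = int(round(0.1 * len(dev_idx)))
        val = [positives[dev_idx[i]] for i in dev_perm[:n_val]]
        train = [positives[dev_idx[i]] for i in dev_perm[n_val:]]
        plans.append(FoldPlan(
            fold_id=f, train_pos=train, val_pos=val, test_pos=test,
            seeds={"split": split_seed,
                   "neg_train": _fold_seed(seed, f, 1),
                   "neg_val": _fold_seed(seed, f, 2),
                   "neg_test": _fold_seed(seed, f, 3)}))
    return plans


# -- negative sampling --------------------------------------------------------

def _sample_negative_lists(positives: list[Pair], adr_list: list[str],
                           forbidden: set[Pair], ratio: int,
                           rng: np.random.Generator,
                           max_attempts_per_neg: int = 200
                           ) -> dict[Pair, list[str]]:
    """Per positive (h, a): up to ``ratio`` alternative ADRs a' drawn uniformly
    from the full ADR set, skipping forbidden pairs and per-positive duplicates."""
    out: dict[Pair, list[str]] = {}
    n_adr = len(adr_list)
    exhausted = 0
    for pos in positives:
        h = pos[0]
        chosen: list[str] = []
        chosen_set: set[str] = set()
        budget = max_attempts_per_neg * ratio
        while len(chosen) < ratio and budget > 0:
            a_prime = adr_list[int(rng.integers(n_adr))]
            budget -= 1
            if a_prime in chosen_set or (h, a_prime) in forbidden:
                continue
            chosen.append(a_prime)
            chosen_set.add(a_prime)
        if len(chosen) < ratio:
            exhausted += 1
        out[pos] = chosen
    if exhausted:
        warnings.warn(
            f"negative sampling exhausted for {exhausted} positive(s); "
            "fewer negatives returned", stacklevel=3)
    return out


def sample_negatives(positives: list[Pair], positive_union: set[Pair],
                     adr_set: set[str] | list[str], ratio: int,
                     seed: int) -> list[Pair]:
    """Type-constrained negatives: fix the CMM, resample the ADR uniformly.

    Candidates colliding with the fold's full positive union (train, val and
    test positives) are discarded, as are duplicate negatives for the same
    positive. Sampling is capped by an attempt budget, deterministic per seed,
    and intended to be generated once per fold/split and reused.
    """
    if not adr_set:
        raise ValueError("adr_set must be non-empty")
    adr_list = sorted(adr_set)
    rng = np.random.default_rng(seed)
    lists = _sample_negative_lists(positives, adr_list, positive_union,
                                   ratio, rng)
    return [(pos[0], a) for pos in positives for a in lists[pos]]


def attach_negatives(plan: FoldPlan, adr_set: set[str], ratio: int = 1
                     ) -> FoldPlan:
    """Cache per-split negative sets on a fold plan (done once, reused)."""
    union = plan.positive_union
    plan.negatives["train"] = sample_negatives(
        plan.train_pos, union, adr_set, ratio, plan.seeds["neg_train"])
    plan.negatives["val"] = sample_negatives(
        plan.val_pos, union, adr_set, ratio, plan.seeds["neg_val"])
    plan.negatives["test"] = sample_negatives(
        plan.test_pos, union, adr_set, ratio, plan.seeds["neg_test"])
    return plan


def make_imbalance_testsets(plan: FoldPlan, adr_set: set[str],
                            ratios: tuple[int, ...] = (1, 2, 5, 10),
                            seed: int | None = None
                            ) -> dict[int, list[Pair]]:
    """Per-ratio test negative sets, nested (ratio-1 set within ratio-2, ...).

    All test positives are retained at every ratio; negatives avoid the fold's
    positive union and any cached train/validation negative pair. Negatives
    are drawn once at the maximum ratio with a fixed seed; the ratio-r set
    takes the first r draws per positive, which nests the sets and reduces
    sampling variance across ratios.
    """
    if seed is None:
        seed = plan.seeds.get("neg_test", 0) + 7
    forbidden = set(plan.positive_union)
    for split in ("train", "val"):
        forbidden |= set(plan.negatives.get(split, []))
    adr_list = sorted(adr_set)
    rng = np.random.default_rng(seed)
    max_ratio = max(ratios)
    lists = _sample_negative_lists(plan.test_pos, adr_list, forbidden,
                                   max_ratio, rng)
    out: dict[int, list[Pair]] = {}
    for r in sorted(ratios):
        out[r] = [(pos[0], a) for pos in plan.test_pos
                  for a in lists[pos][:r]]
    return out


# -- metrics -----------------------------------------------------------------

@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: float | None
    auprc: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Classification metrics at ``score >= threshold`` plus ranking metrics.

    AUROC / AUPRC are None when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be non-empty and aligned")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    if len(np.unique(labels)) == 2:
        auroc = float(roc_auc_score(labels, scores))
        auprc = float(average_precision_score(labels, scores))
    else:
        auroc = None
        auprc = None
    return MetricReport(precision=precision, recall=recall, f1=f1, mcc=mcc,
                        auroc=auroc, auprc=auprc, tp=tp, fp=fp, tn=tn, fn=fn,
                        threshold=threshold)


def select_threshold(val_scores, val_labels) -> float:
    """F1-maximising threshold on the validation set.

    The candidate grid is the set of unique observed scores; classification is
    ``score >= tau``; ties in F1 resolve to the smaller threshold.
    """
    scores = np.asarray(val_scores, dtype=np.float64)
    labels = np.asarray(val_labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection needs both classes in validation")
    best_tau = None
    best_f1 = -1.0
    for tau in np.unique(scores):  # ascending, so first max wins = smallest tau
        rep = compute_metrics(scores, labels, threshold=float(tau))
        if rep.f1 > best_f1 + 1e-15:
            best_f1 = rep.f1
            best_tau = float(tau)
    return best_tau


# -- stratification, cold start, paired tests --------------------------------

def degree_strata(cmm_degrees: dict[str, int]) -> dict[str, list[str]]:
    """Head / Medium / Tail grouping of CMMs by degree rank (20/60/20).

    Rank is by degree descending with a stable tie-break on node id; Head and
    Tail take ceil(0.2 n) each, Medium the rest.
    """
    n = len(cmm_degrees)
    if n < 5:
        raise ValueError("degree stratification needs at least 5 CMMs")
    ranked = sorted(cmm_degrees, key=lambda nid: (-cmm_degrees[nid], nid))
    n_head = math.ceil(0.2 * n)
    n_tail = math.ceil(0.2 * n)
    return {"Head": ranked[:n_head],
            "Medium": ranked[n_head:n - n_tail],
            "Tail": ranked[n - n_tail:]}


def cold_start_split(positives_by_source: list[tuple[str, str, str]]
                     ) -> tuple[list[Pair], list[Pair], float]:
    """Source-transfer split: train on report-derived positives, test on
    literature-curated positives; report the fraction of test CMMs absent
    from the training positives."""
    train = [(c, a) for c, a, s in positives_by_source if s == "faers"]
    test = [(c, a) for c, a, s in positives_by_source if s == "literature"]
    if not train or not test:
        raise ValueError("cold-start split needs both source partitions")
    train_cmms = {c for c, _ in train}
    test_cmms = {c for c, _ in test}
    unseen = len(test_cmms - train_cmms) / len(test_cmms)
    return train, test, unseen


def paired_fold_test(metric_a, metric_b) -> tuple[float, float, bool]:
    """Two-sided paired t-test on fold-wise metric values.

    Returns (t, p, degenerate); a zero-variance difference vector is flagged
    degenerate with NaN statistics rather than raising.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return float("nan"), float("nan"), True
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), False


def leakage_audit(graph, test_pairs: list[Pair]) -> int:
    """Occurrences of test pairs anywhere in the graph, in either direction.

    Must be zero after fold-wise bidirectional test-edge removal.
    """
    return graph.pair_occurrences(test_pairs)
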