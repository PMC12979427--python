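"""End-to-end experiment orchestration: folds -> train -> evaluate -> rank.

The cross-validation driver enforces the leakage contract on every fold (test
edges absent from the training graph in both directions) before any training
step runs, evaluates at a fixed 0.5 threshold for the main protocol or at a
validation-selected F1-maximising threshold, and aggregates fold metrics as
arithmetic mean and sample standard deviation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import HeteroGraph
from .mapping import TcmRuleSet, map_predictions
from .network import ModelConfig
from .protocols import (FoldPlan, MetricReport, attach_negatives,
                        compute_metrics, leakage_audit, make_fold_plans,
                        make_imbalance_testsets, sample_negatives,
                        select_threshold)
from .training import Checkpoint, TrainConfig, predict_pairs, train_fold

logger = logging.getLogger(__name__)

SUMMARY_METRICS = ("precision", "recall", "f1", "mcc", "auroc", "auprc")


@dataclass
class FoldResult:
    plan: FoldPlan
    checkpoint: Checkpoint
    report: MetricReport
    log: list[dict]
    test_scores: np.ndarray
    test_labels: np.ndarray


@dataclass
class CvResult:
    folds: list[FoldResult]
    summary: dict[str, tuple[float, float]]  # metric -> (mean, sample sd)

    @property
    def reports(self) -> list[MetricReport]:
        return [f.report for f in self.folds]


def summarize_reports(reports: list[MetricReport]
                      ) -> dict[str, tuple[float, float]]:
    out = {}
    for m in SUMMARY_METRICS:
        vals = np.array([getattr(r, m) for r in reports], dtype=np.float64)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[m] = (float(vals.mean()), sd)
    return out


def _permute_split(pos, neg, rng):
    """Shuffle labels over the pooled pair list (label-permutation control)."""
    pairs = list(pos) + list(neg)
    labels = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    rng.shuffle(labels)
    new_pos = [p for p, y in zip(pairs, labels) if y == 1]
    new_neg = [p for p, y in zip(pairs, labels) if y == 0]
    return new_pos, new_neg


def run_cv(graph: HeteroGraph, model_config: ModelConfig,
           train_config: TrainConfig, k: int = 10, seed: int = 42,
           neg_ratio: int = 1, threshold: float | str = 0.5,
           permute_labels: bool = False) -> CvResult:
    """Stratified k-fold cross-validation over the graph's CMM-ADR positives.

    ``threshold`` is a fixed probability cut (main protocol, 0.5) or the
    string ``"select"`` for validation-side F1 maximisation. With
    ``permute_labels`` the supervision labels are shuffled within each split
    (a no-signal control); the folds, negatives and graph are untouched.
    """
    positives = graph.cmm_adr_pairs()
    plans = make_fold_plans(positives, k=k, seed=seed)
    adr_set = set(graph.node_ids["adr"])
    results: list[FoldResult] = []
    for plan in plans:
        attach_negatives(plan, adr_set, ratio=neg_ratio)
        train_graph = graph.remove_pair_edges(plan.test_pos)
        leaked = leakage_audit(train_graph, plan.test_pos)
        if leaked:
            raise RuntimeError(
                f"fold {plan.fold_id}: leakage audit found {leaked} residual "
                "test-pair edge(s); aborting")

        tr_pos, tr_neg = plan.train_pos, plan.negatives["train"]
        va_pos, va_neg = plan.val_pos, plan.negatives["val"]
        te_pos, te_neg = plan.test_pos, plan.negatives["test"]
        if permute_labels:
            prng = np.random.default_rng(plan.seeds["split"] + 13)
            tr_pos, tr_neg = _permute_split(tr_pos, tr_neg, prng)
            va_pos, va_neg = _permute_split(va_pos, va_neg, prng)
            te_pos, te_neg = _permute_split(te_pos, te_neg, prng)

        fold_tc = dataclasses.replace(
            train_config, seed=train_config.seed + plan.fold_id)
        ckpt, log = train_fold(train_graph, tr_pos, tr_neg, va_pos, va_neg,
                               model_config, fold_tc)

        test_pairs = list(te_pos) + list(te_neg)
        test_labels = np.r_[np.ones(len(te_pos)), np.zeros(len(te_neg))]
        scores = predict_pairs(ckpt, train_graph, test_pairs)
        if threshold == "select":
            val_pairs = list(va_pos) + list(va_neg)
            val_labels = np.r_[np.ones(len(va_pos)), np.zeros(len(va_neg))]
            val_scores = predict_pairs(ckpt, train_graph, val_pairs)
            tau = select_threshold(val_scores, val_labels)
        else:
            tau = float(threshold)
        report = compute_metrics(scores, test_labels, threshold=tau)
        logger.info("fold %d: AUROC=%.4f F1=%.4f (tau=%.3f, best epoch %d)",
                    plan.fold_id, report.auroc, report.f1, tau, ckpt.epoch)
        results.append(FoldResult(plan=plan, checkpoint=ckpt, report=report,
                                  log=log, test_scores=scores,
                                  test_labels=test_labels))
    return CvResult(folds=results, summary=summarize_reports(
        [r.report for r in results]))


def run_imbalance_stress(graph: HeteroGraph, cv: CvResult,
                         ratios: tuple[int, ...] = (1, 2, 5, 10)
                         ) -> dict[int, list[MetricReport]]:
    """Re-evaluate trained folds on progressively imbalanced test sets.

    Training stays balanced; per fold and ratio the test set keeps all fold
    positives plus nested, seed-fixed negatives avoiding every pair seen in
    training or validation. The decision threshold is selected per ratio on a
    ratio-matched validation set.
    """
    adr_set = set(graph.node_ids["adr"])
    out: dict[int, list[MetricReport]] = {r: [] for r in ratios}
    for fold in cv.folds:
        plan = fold.plan
        train_graph = graph.remove_pair_edges(plan.test_pos)
        testsets = make_imbalance_testsets(plan, adr_set, ratios=ratios)
        forbidden = plan.positive_union | set(plan.negatives["train"]) \
            | set(plan.negatives["val"])
        for r in ratios:
            # ratio-matched validation negatives for threshold selection
            val_neg_r = sample_negatives(
                plan.val_pos * 1, forbidden, adr_set, r,
                plan.seeds["neg_val"] + 1000 + r)
            val_pairs = list(plan.val_pos) + val_neg_r
            val_labels = np.r_[np.ones(len(plan.val_pos)),
                               np.zeros(len(val_neg_r))]
            val_scores = predict_pairs(fold.checkpoint, train_graph, val_pairs)
            tau = select_threshold(val_scores, val_labels)

            test_pairs = list(plan.test_pos) + testsets[r]
            test_labels = np.r_[np.ones(len(plan.test_pos)),
                                np.zeros(len(testsets[r]))]
            scores = predict_pairs(fold.checkpoint, train_graph, test_pairs)
            out[r].append(compute_metrics(scores, test_labels, threshold=tau))
    return out


def run_cold_start(graph: HeteroGraph, model_config: ModelConfig,
                   train_config: TrainConfig, seed: int = 42
                   ) -> tuple[MetricReport, float]:
    """Source-transfer evaluation: train on report-derived positives only,
    test on the held-out literature-curated positives."""
    from .protocols import cold_start_split

    attrs = graph.edge_attrs["cmm-adr"]
    pairs = graph.cmm_adr_pairs()
    tagged = [(c, a, str(s)) for (c, a), s in zip(pairs, attrs["provenance"])]
    train_all, test_pos, unseen = cold_start_split(tagged)
    train_graph = graph.remove_pair_edges(test_pos)
    if leakage_audit(train_graph, test_pos):
        raise RuntimeError("cold-start leakage audit failed")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_all))
    n_val = max(1, int(round(0.1 * len(train_all))))
    val_pos = [train_all[i] for i in order[:n_val]]
    tr_pos = [train_all[i] for i in order[n_val:]]
    adr_set = set(graph.node_ids["adr"])
    union = set(train_all) | set(test_pos)
    tr_neg = sample_negatives(tr_pos, union, adr_set, 1, seed + 1)
    va_neg = sample_negatives(val_pos, union, adr_set, 1, seed + 2)
    te_neg = sample_negatives(test_pos, union, adr_set, 1, seed + 3)

    ckpt, _ = train_fold(train_graph, tr_pos, tr_neg, val_pos, va_neg,
                         model_config, train_config)
    test_pairs = list(test_pos) + te_neg
    labels = np.r_[np.ones(len(test_pos)), np.zeros(len(te_neg))]
    scores = predict_pairs(ckpt, train_graph, test_pairs)
    return compute_metrics(scores, labels, threshold=0.5), unseen


def rank_predictions(checkpoint: Checkpoint, graph: HeteroGraph,
                     known_positives: set[tuple[str, str]],
                     rules: TcmRuleSet | None = None,
                     pt_to_soc: dict[str, str] | None = None,
                     candidate_cap: int | None = None,
                     seed: int = 42) -> pd.DataFrame:
    """Score and rank candidate pairs absent from the labeled positives.

    The candidate universe defaults to all non-positive (CMM, ADR) pairs,
    optionally capped by a seeded uniform subsample. Rows are annotated with
    TCM functional systems when a rule set is given.
    """
    cmms = graph.node_ids["cmm"]
    adrs = graph.node_ids["adr"]
    candidates = [(c, a) for c in cmms for a in adrs
                  if (c, a) not in known_positives]
    if candidate_cap is not None and len(candidates) > candidate_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=candidate_cap, replace=False)
        candidates = [candidates[i] for i in sorted(idx)]
    if not candidates:
        return pd.DataFrame(columns=["rank", "cmm_id", "adr_id", "score"])
    scores = predict_pairs(checkpoint, graph, candidates)
    df = pd.DataFrame({"cmm_id": [c for c, _ in candidates],
                       "adr_id": [a for _, a in candidates],
                       "score": scores})
    df = df.sort_values(["score", "cmm_id", "adr_id"],
                        ascending=[False, True, True], kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df = df.reset_index(drop=True)
    if rules is not None and pt_to_soc is not None:
        df = map_predictions(df, rules, pt_to_soc, pt_column="adr_id")
    return df


def sample_rank_stratum(ranked: pd.DataFrame, lo: int, hi: int, n: int,
                        seed: int) -> pd.DataFrame:
    """Seeded uniform sample of n rows from ranks [lo, hi] inclusive."""
    stratum = ranked[(ranked["rank"] >= lo) & (ranked["rank"] <= hi)]
    if len(stratum) <= n:
        return stratum.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(stratum), size=n, replace=False)
    return stratum.iloc[sorted(idx)].reset_index(drop=True)
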