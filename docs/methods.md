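# Methods

This note records what the package implements, the assumptions behind it, the
default parameters and why they are set as they are, what the synthetic
generator does and does not emulate, and the numerical choices that matter
for reproducing results.

## 1. Data model and curation

The unit of supervision is a (CMM, ADR) pair with a report count and a
provenance flag. `msat.curation` turns report-level exports into such pairs:

1. **Version deduplication** — one record per case, keeping the highest
   `case_version`. Duplicate (case_id, case_version) rows are treated as a
   validation error rather than silently resolved: with that invariant the
   per-case maximum is unique, so no tie-break policy is needed.
2. **Non-ADR filtering** — exact-PT blacklist for administrative and
   product-quality terms.
3. **Aggregation** — counts of distinct post-dedup reports per pair.
4. **Literature union** — literature-curated pairs carry zero counts; when a
   pair occurs in both sources the report-derived record wins so the count
   evidence survives into the edge features.

Assumption: each retained report contributes evidence for exactly one
(CMM, PT) pair per row; multi-drug reports can optionally be excluded with
the monotherapy filter but are kept by default.

## 2. Graph and leakage control

`msat.graph.HeteroGraph` stores edges in canonical direction only; reverse
relations are materialised at encode time. This makes held-out-edge removal
safe by construction: deleting a canonical CMM–ADR edge removes it from both
message-passing directions, and the aligned attribute rows are dropped
synchronously. `pair_occurrences` scans every relation in both orientations
and must return zero for every fold's test pairs before training starts; the
cross-validation driver aborts otherwise.

## 3. Evidence vectors

Each supervised edge carries, in order: feature cosine similarity, log1p
report count, provenance indicator, log1p CMM degree, log1p ADR degree, and
log1p mechanistic meta-path count (CMM→compound→target→ADR chains, computed
as a chained sparse biadjacency product). The four unbounded features are
min-max scaled by a scaler **fitted on the training fold's edges only** and
clamped into [0, 1] for held-out pairs, so no held-out statistic can leak
into the featurization. Degrees and meta-paths are always computed on the
training graph (test edges already removed).

## 4. Encoder and scorer

Per layer: (i) ESA-Gate maps evidence to per-head attention biases through a
learnable convex combination of an MLP branch and a linear shortcut, with a
scalar gate `g = σ(θ)` initialised at θ = 0 (g = 0.5, neither branch
favoured); (ii) multi-head attention with additive biases, softmax-normalised
jointly over **all** incoming edges of a destination node across relations
(canonical plus reverse), so attention weights sum to one per node per head
globally — mechanistic relations contribute learned per-relation biases;
(iii) the HSP expand-and-compress feed-forward block (`d_h → 2d_h → 3d_h →
d_h`, ReLU), then residual + LayerNorm.

The HCI scorer fuses a degree-aware MLP (inputs: both embeddings plus both
log1p degrees standardised by training-graph mean/sd — stable under
heavy-tailed degree distributions), an asymmetric bilinear form and a
symmetric DistMult term, with learnable fusion weights initialised to 1/3.

Full-scale architecture defaults (`ModelConfig`): 8 heads × width 72
(d_h = 576), 3 layers, dropout 0.18, evidence dim 6. Training defaults
(`TrainConfig`): AdamW, learning rate 4e-4, weight decay 1e-5, batch 512,
up to 1000 epochs, early-stop patience 100 on validation AUROC,
reduce-on-plateau (factor 0.6, patience 15), global gradient-norm clip 1.0.

### Target-edge exclusion

Every training positive is, by construction, also an edge of the training
graph, while evaluation pairs never are. At small scale the encoder can
therefore learn to read off *edge presence* instead of the evidence and
feature signal — training loss collapses while held-out ranking stays near
chance. The training loop therefore hides each mini-batch's own positive
edges from message passing for that step (`TrainConfig.exclude_target_edges`,
on by default), the standard link-prediction remedy that aligns training
conditions with evaluation conditions. All other supervised edges remain
visible, and evaluation always uses the full training graph.

## 5. Evaluation protocols

- **Folds**: seeded permutation, `np.array_split` into k near-equal test
  folds; each fold's development set is split 90/10 into train/validation
  (81:9:10 overall at k = 10). Per-fold substream seeds are derived
  arithmetically and kept below 2³¹.
- **Negatives**: type-constrained — keep the CMM, resample the ADR uniformly
  from the typed universe; candidates colliding with the fold's full positive
  union are discarded, duplicates per positive are rejected, and an attempt
  budget guards against exhaustion (under-filled positives produce a
  warning). Negative sets are generated once per fold and cached.
- **Imbalance stress**: negatives for the largest ratio are drawn once; the
  ratio-r set takes the first r draws per positive, nesting the sets and
  reducing cross-ratio sampling variance. Thresholds are re-selected on a
  ratio-matched validation set.
- **Metrics**: precision, recall, F1, MCC from explicit confusion counts
  (zero denominators yield 0.0); AUROC/AUPRC via scikit-learn (None when a
  split is single-class). Threshold selection maximises F1 over the grid of
  unique observed scores with ties resolved toward the smaller threshold.
- **Degree strata**: Head/Medium/Tail = 20/60/20 by degree rank (ceil on the
  20% ends, stable id tie-break).
- **Cold start**: train on report-derived positives only, test on
  literature-curated positives, reporting the fraction of test CMMs unseen
  in training.
- **Paired comparisons**: fold-wise two-sided paired t-test
  (`scipy.stats.ttest_rel`); zero-variance differences are flagged degenerate
  with NaN statistics instead of raising.

## 6. Synthetic generator

`msat.synthetic.generate` emulates the statistical structure the model
assumes, at desk scale and fully deterministic per seed:

- node features = shared latent-cluster centroids (unit norm) plus Gaussian
  noise, making the CMM–ADR feature cosine informative;
- mechanistic relations sampled independently at configured densities;
- positives planted by `P = σ(logit(rate) + b·metapath + c·cosine)`;
- report counts 1 + negative-binomial with mean growing with the meta-path
  count; a configured fraction of positives is literature-only (zero count).

Defaults (60/150/300/120 nodes, `noise_sd=0.05`, `signal_cosine=8.0`,
`signal_metapath=2.0`, `positive_rate=0.01`) were calibrated **against the
planted-probability oracle, not against any trained model**: scoring pairs by
the generative probability itself yields AUROC ≈ 0.96–0.98 across seeds, so
the planted signal is strong and a competent model has headroom. (With the
noisier `noise_sd=0.30` the oracle itself drops to ≈ 0.71 — per-dimension
noise 0.30 over 32 dimensions has norm ≈ 1.7 against unit centroids and
destroys the cosine channel, leaving no model able to rank well.)

The generator does **not** emulate reporting-bias mechanisms of real
spontaneous-report data: stimulated reporting, channeling bias,
co-medication confounding, or MedDRA coding drift. Conclusions about those
phenomena cannot be drawn from synthetic runs. `generate_report_records`
expands pairs back into report-level records with optional corruption dials
(version duplicates, blacklisted PTs, multi-drug reports) for exercising the
curation path; with all dials at zero, curation reproduces the pair table
exactly.

## 7. Desk-scale profile

Full-scale settings assume hours of training. For laptop-scale studies the
package fixes one profile (`msat.profiles`), chosen once up front: d_h = 64
(4 heads × 16), 2 layers, learning rate 3e-3, ≤ 120 epochs with early-stop
patience 30, 3-fold CV. The permuted-label control runs ≤ 40 epochs with
patience 15, since there is no signal to fit. On the default synthetic world
this yields CV AUROC ≈ 0.95 ± 0.01 with the permuted control at ≈ 0.49,
in roughly 80 seconds on one CPU.

## 8. Numerical choices

- All model arithmetic is float64 via a small reverse-mode autodiff engine
  over numpy (`msat.autodiff`); gradients of gather/scatter ops use
  `np.add.at` scatter-adds.
- The segment softmax subtracts a per-segment maximum (treated as a
  constant) for stability; binary cross-entropy is computed on raw logits
  with the `max(s,0) − s·y + log1p(exp(−|s|))` form and its analytic
  gradient.
- The sigmoid is evaluated piecewise to avoid overflow for large negative
  inputs.
- LayerNorm is composed from differentiable primitives (ε = 1e-5).
- Determinism: a single integer seed drives parameter init, batch order and
  dropout through one `np.random.Generator`; runs are bit-reproducible on
  one CPU thread. Checkpoints store best-validation parameters plus the
  fitted evidence scaler and degree statistics, so prediction is independent
  of training state.

## 9. Limitations

- No real FAERS/literature corpus ships with the package; all end-to-end
  numbers are on synthetic worlds and validate machinery, not clinical
  claims.
- The desk-scale profile is not a substitute for full-scale training; its
  purpose is fast, reproducible sanity studies.
- The TCM rule file covers the published worked examples plus common SOC
  defaults; it is data, intended to be extended, and unmatched terms are
  flagged `UNMAPPED` rather than resolved.
- Negative sampling assumes unobserved pairs are negative — the standard,
  but imperfect, pharmacovigilance assumption.
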