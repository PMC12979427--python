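# msat

Evidence-conditioned heterogeneous graph learning for Chinese Materia Medica
(CMM) pharmacovigilance.

## The problem

Spontaneous-report databases accumulate signals linking herbal medicines to
adverse drug reactions (ADRs), but the raw counts are sparse, noisy and biased
toward well-known pairs. `msat` predicts which (CMM, ADR) associations are
real by learning over a heterogeneous *pharmacological space*: a graph with
four node types — CMM, chemical compound, protein target and ADR (a MedDRA
Preferred Term) — and six relations, including mechanistic chains
CMM → compound → target → ADR. Each supervised CMM–ADR edge additionally
carries a 6-dimensional **evidence vector**: feature cosine similarity, log
report count, provenance (report-derived vs literature-curated), two degree
features and the mechanistic meta-path count.

Predicted MedDRA terms can finally be mapped onto 16 Traditional Chinese
Medicine (TCM) functional systems (Zang/Fu organs, Body Surface,
Qi-Blood-Fluid, …) via an editable rule file, so that outputs read in a
clinician-facing vocabulary.

## The model

A Multi-Scale Attention encoder stacks `L` layers of biased multi-head
attention over all incoming edges (canonical and reverse) of each node:

- **ESA-Gate** (evidence-semantic adaptive gate). Each CMM–ADR edge's evidence
  vector `e ∈ R^6` becomes one additive attention bias per head:
  `β = g · MLP(e) + (1 − g) · W_s e`, with a learnable scalar gate
  `g = σ(θ)`. Mechanistic relations, which carry no evidence vector, instead
  contribute a learned per-relation, per-head bias.
- **Biased attention**: `α_ij = softmax_j( q_i·k_j / √d_k + β_ij )`,
  normalised per head over the union of node *i*'s incoming edges.
- **HSP transform**: an expand-and-compress feed-forward block traversing
  widths `d_h → 2d_h → 3d_h → d_h` (576 → 1152 → 1728 → 576 at the full-scale
  defaults), followed by a residual connection and layer normalisation.

Pairs are scored by **hub-calibrated inference (HCI)**, a weighted fusion of
three views on the embeddings `z_c, z_a`:

```
s = w1 · MLP([z_c ‖ z_a ‖ deg_c ‖ deg_a])   degree-aware, hub-calibrating
  + w2 · z_cᵀ W_B z_a                        bilinear (asymmetric)
  + w3 · Σ_k z_c[k] · r[k] · z_a[k]          DistMult (symmetric)
P(association) = σ(s)
```

Training minimises binary cross-entropy with AdamW, gradient clipping, a
reduce-on-plateau schedule and early stopping on validation AUROC. Evaluation
uses 10-fold cross-validation with a nested 90/10 development split
(81:9:10), type-constrained negative sampling (fix the CMM, resample the
ADR, discard collisions with the fold's positive union), class-imbalance
stress tests up to 1:10, degree-stratified reporting (Head/Medium/Tail =
20/60/20) and a literature-held-out cold-start protocol. Before any training
step, a leakage audit asserts that no held-out pair survives anywhere in the
training graph in either direction.

There is no external deep-learning dependency: the package ships a small
reverse-mode automatic-differentiation engine over numpy (`msat.autodiff`)
providing exactly the primitives the encoder needs.

## Worked example

No real pharmacovigilance data ships with the package; a seeded generator
builds a synthetic world with planted signal (see `docs/methods.md`).

```bash
$ msat simulate --seed 7 --out world
wrote graph with 630 nodes, 2900 edges, 1343 positive pairs to world

$ msat folds --graph world/graph --k 3 --seed 7 --out folds
wrote 3 fold plans to folds

$ cat > config.yaml <<'YAML'
model: {heads: 4, head_dim: 16, layers: 2, dropout: 0.18}
train: {learning_rate: 0.003, max_epochs: 120, early_stop_patience: 30,
        scheduler_patience: 10, seed: 42}
YAML

$ msat train --graph world/graph --splits folds --fold 0 \
      --config config.yaml --out runs/fold0
best val AUROC 0.9860 at epoch 8

$ msat rank --graph world/graph --checkpoint runs/fold0/checkpoint \
      --top 5 --seed 7 --out top.tsv
wrote top 5 predictions to top.tsv

$ cut -f1-3 top.tsv
rank	cmm_id	adr_id
1	CMM_0007	ADR_0085
2	CMM_0007	ADR_0100
3	CMM_0009	ADR_0062
4	CMM_0025	ADR_0036
5	CMM_0042	ADR_0062
```

Mapping real MedDRA terms onto TCM functional systems:

```bash
$ msat map-tcm --predictions preds.tsv --out mapped.tsv
annotated 3 rows

$ cat mapped.tsv
rank	cmm_id	adr_id	score	tcm_systems	mapping_flag
1	Huzhang	Vomiting	0.99	Stomach	ok
2	Ciwujia	Tinnitus	0.95	Kidney	ok
3	Luole	Acute pulmonary oedema	0.93	Lung+Qi-Blood-Fluid	ok
```

Other subcommands: `msat curate` (report-level deduplication, non-ADR
filtering, literature union), `msat build-graph`, `msat featurize`,
`msat evaluate` (k-fold CV), `msat stress-test`, `msat cold-start`.

## Layout

| Module | Responsibility |
| --- | --- |
| `msat.curation` | report-level dedup, blacklist filter, literature union |
| `msat.graph` | typed heterogeneous graph, TSV IO, leakage-safe removal |
| `msat.evidence` | 6-dim evidence vectors, meta-path counts, fold-fitted scaling |
| `msat.autodiff` | numpy reverse-mode autodiff + AdamW |
| `msat.network` | ESA-Gate, biased attention, HSP encoder |
| `msat.scoring` | HCI fusion scorer, degree standardisation |
| `msat.training` | per-fold loop, checkpointing, prediction |
| `msat.protocols` | folds, negatives, metrics, thresholds, strata, t-tests |
| `msat.pipeline` | CV driver, stress/cold-start studies, ranking |
| `msat.mapping` | MedDRA PT/SOC → TCM functional systems |
| `msat.synthetic` | seeded generator with planted signal |
| `msat.cli` | `msat` console entry point |
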