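# Methods

## The problem

Whole-slide images (WSIs) of resected early-stage lung adenocarcinoma are
far too large to model directly, so they are tiled into non-overlapping
squares and the question becomes how to aggregate tile-level information
into a patient-level prognosis. `slidesurv` models each slide as a spatial
graph over its tiles and predicts a scalar risk score for progression-free
survival, trained against right-censored time-to-event outcomes.

## Graph construction

Tiles cover 512 µm × 512 µm of tissue regardless of scan magnification
(512 px at 10x / 1.0 µm per px, or 1024 px at 20x / 0.5 µm per px); partial
boundary tiles are dropped and tiles with less than 20% tissue are excluded
(the 20% boundary itself is kept). Each retained tile becomes a node with:

* **deep features** `X_deep` (consumed precomputed, e.g. foundation-model
  embeddings; the synthetic generator emits 32 channels),
* a **16-dim 2-D sinusoidal positional encoding** of the (row, col) grid
  position — the first 8 entries encode the row, the last 8 the column; per
  axis, entry 2m is `sin(p / 10000^(2m/8))` and entry 2m+1 the cosine. The
  axis-split adaptation keeps the encoding injective on realistic grids
  (verified on 50×50),
* a histologic **subtype** label out of six classes (lepidic, acinar,
  papillary, micropapillary, solid, non-tumor).

Edges connect each node to its k = 8 nearest neighbours by Euclidean
distance between tile centres. Edges are **directed** (neighbour → node;
message passing aggregates over in-edges), matching a literal k-NN
construction; an optional flag symmetrizes. Ties are broken by the smaller
node index and nodes are ordered row-major, so graphs are bit-reproducible.
Each edge carries a categorical feature — which of the 21 unordered
subtype pairs (6 classes, self-pairs allowed) it joins — and two continuous
features: cosine similarity of the endpoint deep features (defined as 0 for
zero-norm rows, with a logged warning) and the spatial distance between
endpoints, min-max scaled to [0, 1] per graph so that micrometre magnitudes
do not dominate the 2→16 edge projection.

## Model

The block operates on an 80-dim node state: `X = [L_node(X_deep) ‖ X_pe]`
with `L_node : D → 64`. Edge inputs are `E = EB_cat[c] + L_edge(E_cont)`,
a learned 21×16 embedding plus a 2→16 linear map.

**Local branch (graph attention).** Attention logits score the
concatenation of transformed target, source, and edge features,

    α_ij = softmax_j  LeakyReLU( aᵀ [ W X_i ‖ W X_j ‖ W_e E_ij ] ),

with negative slope 0.2, and the node update is the attention-weighted sum
of transformed sources, `X'_i = Σ_j α_ij W X_j`. Edge features enter the
logits only, not the value aggregation. One head by default; multiple heads
are averaged.

**Global branch (selective state space).** The graph's nodes in raster
order form a token sequence. The branch is a Mamba-style block: input
projection with expansion 2 (inner width 160), a causal depthwise
convolution of width 4, SiLU gating, a selective scan, and an output
projection back to width 80. The scan integrates the diagonal state
equation h' = A h + B x, y = C h under zero-order hold,

    Ā = exp(ΔA),   B̄ = (ΔA)⁻¹(exp(ΔA) − I) ΔB,

with the removable singularity at A = 0 evaluated exactly (B̄ → ΔB). B, C
and Δ are linear functions of each token (Δ through a softplus with bias
initialized to put steps in [10⁻³, 10⁻¹]); A = −exp(A_log) is per-channel
negative-real, initialized to −1…−16. Because B, C, Δ depend on the token,
the recurrence can suppress uninformative tiles while keeping linear
complexity in sequence length.

**Fusion.** Each branch applies Dropout → residual add of X → BatchNorm;
the two branch outputs are summed element-wise; a 2-layer MLP (expansion 2)
with residual and BatchNorm closes the block. The node states of all of a
patient's slides (processed independently, no inter-slide edges) are
mean-pooled into one embedding, and a 2-layer MLP head (hidden 32) emits
the risk score; higher means worse prognosis.

## Objective and evaluation

Training minimizes the negative log Cox partial likelihood, normalized by
the event count, within each mini-batch of 16 patients (batches without
events are skipped); tied event times use Breslow's convention (Efron
available behind a flag). The analytic gradient is exercised against
central finite differences in the tests.

Evaluation reports Harrell's concordance index (admissible pair: earlier
patient had the event; risk ties count ½), IPCW cumulative/dynamic AUC at
365 / 1095 / 1825 days (Uno's estimator via scikit-survival, censoring
distribution estimated on the training split), and a Kaplan–Meier /
log-rank comparison after splitting the test set at the training-set median
risk (strictly-greater ⇒ high risk).

## Training protocol

Five-fold cross-validation, stratified by event status, each fold an
independent 60/20/20 patient-level split (validation and test sizes are
`round(f·n)` with the remainder to train — 444 patients yield 266/89/89 —
and events are apportioned across splits by largest remainder). Adam with
learning rate 5×10⁻⁵, weight decay 10⁻⁴, dropout 0.3, early stopping after
5 epochs without validation-loss improvement, cap 200 epochs,
best-validation weights restored. All RNG streams derive from a single
seed; two runs with the same seed are bit-identical.

## Synthetic cohorts

The generator emulates a two-site early-stage LUAD cohort at desk scale:
300 patients by default, 1–3 slides each (75/20/5%), 8×8 tile grids, 32
feature channels. Each patient draws an archetype — indolent
(lepidic-rich) or aggressive (solid/micropapillary-rich) — lays subtypes
i.i.d. from the archetype mixture and then applies two neighbour-majority
smoothing passes so subtypes form contiguous patches (exercising the
subtype-pair edge categories non-trivially). Features are subtype-specific
Gaussian centroids plus unit noise; tissue fractions are Beta(8, 2).

Outcomes follow proportional hazards: the event time is exponential with
rate `baseline_hazard · exp(effect_size · aggressive_fraction)`, where the
aggressive fraction is the patient's share of micropapillary + solid tiles;
censoring is an independent exponential (4×10⁻⁴/day) capped at 1825 days.
The defaults (baseline 1.4×10⁻⁴/day, effect size 2.0) were calibrated by
simulating the generator so that cohorts land at ≈40% observed events and
the *oracle* concordance of the true aggressive fraction is ≈0.70–0.74 —
a planted signal strong enough that a correct model must recover it and
weak enough that censoring and within-archetype noise still matter.

What the generator does **not** emulate: real embedding geometry
(foundation-model features are anisotropic and high-dimensional), staining
and scanner variability, non-proportional hazards, and informative
censoring. Passing the recovery tests therefore shows the pipeline can
learn a spatially-organized, subtype-driven hazard from graph inputs — not
that it reproduces published cohort-level performance.

## Numerical choices

* The model trains in float32 (the convention for neural networks); all
  analytic and oracle tests run the same code paths in float64.
* The selective scan runs through fused numba JIT kernels; a pure-NumPy
  scan is kept as the reference implementation, and tests pin the kernels
  to it (1e-5) and to finite differences.
* The per-target attention softmax subtracts the segment maximum before
  exponentiation; the partial likelihood subtracts the batch maximum risk.
* BatchNorm keeps running statistics (momentum 0.1) for evaluation mode.
* Degenerate inputs: zero-norm feature rows give cosine 0 with a warning;
  an all-filtered slide raises a graph-too-small error; zero-event batches
  raise a typed signal that the training loop catches and skips.

## Problem sizes for the acceptance runs

The cross-validated signal-recovery check trains the full model on 300
patients (≈64 tiles/slide, 32 channels) for up to 40 epochs per fold with
early stopping — the point where the validation loss curve has flattened
to ≲10⁻³ per epoch — and repeats the CV on an effect-size-0 cohort as a
null calibration. Unit and oracle tests run in seconds.

## Known limitations

* Directed k-NN edges mean a node's influence radius is asymmetric where
  tile density varies; symmetrization is available but untrained defaults
  follow the literal construction.
* The raster token order for the state-space branch is one of many
  reasonable serializations; outputs are order-sensitive by design, and
  positional encodings carry the spatial information.
* Parameter totals are not comparable to published tables because the
  state-space internals of the reference implementations are not fully
  specified; component-level counts (48 for the edge linear, 336 for the
  pair embedding, 384 for the no-edge delta) are the tested surface.
* Mini-batch risk sets approximate the full-cohort partial likelihood;
  with batch 16 and ≈40% events the approximation is standard practice.
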