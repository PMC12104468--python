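# slidesurv

Spatial tile-graph survival modeling for whole-slide images (WSIs).

Gigapixel H&E slides are tiled into 512 µm squares; predicting a patient's
prognosis then hinges on how tile-level information is aggregated.
`slidesurv` represents each slide as a k-nearest-neighbour graph over its
tiles and learns a patient-level risk score with two parallel feature
learners over a shared 80-dim node state
(`X = [L_node(X_deep) ‖ X_pe]`, deep tile embeddings plus a 16-dim 2-D
sinusoidal positional encoding):

* a **graph-attention branch** for local context, with edge features —
  which of the 21 histologic subtype pairs an edge joins, the cosine
  similarity of its endpoint embeddings, and their spatial distance —
  entering the attention logits:

  `α_ij = softmax_j LeakyReLU(aᵀ [W X_i ‖ W X_j ‖ W_e E_ij])`

* a **selective state-space (Mamba-style) branch** for global context: the
  nodes in raster order form a token sequence scanned through
  `h_t = Ā_t h_{t−1} + B̄_t x_t`, `y_t = C_t h_t`, with zero-order-hold
  discretization `Ā = exp(ΔA)`, `B̄ = (ΔA)⁻¹(exp(ΔA) − I)ΔB` and
  input-dependent B, C, Δ so the recurrence can suppress uninformative
  tiles at linear cost.

Branch outputs are fused residually, mean-pooled over all of a patient's
slides, and a small MLP head emits the risk. Training minimizes the
negative log Cox partial likelihood (Breslow ties) under five-fold
event-stratified cross-validation; evaluation reports Harrell's C-index,
IPCW dynamic AUC at 1/3/5 years, and Kaplan–Meier / log-rank separation at
the training-median risk.

The model is implemented on a small reverse-mode autodiff engine over
NumPy (with numba-fused scan kernels), so the whole pipeline — including a
synthetic cohort generator that plants a recoverable subtype-driven hazard
— runs on a plain CPU with no deep-learning framework.

## Worked example

```python
import slidesurv as ss
from slidesurv.model import ModelConfig
from slidesurv.experiments import TrainConfig, cross_validate

cfg = ss.CohortConfig(n_patients=300, effect_size=2.0, seed=1)
patients = ss.generate_cohort(cfg)
records = [p.record for p in patients]
graphs = {p.record.patient_id: p.graphs for p in patients}
print(f"{len(records)} patients, "
      f"{100 * sum(r.event for r in records) / len(records):.1f}% events")

out = cross_validate(
    ModelConfig(d_features=32), TrainConfig(seed=1, max_epochs=40),
    graphs, records, n_folds=5, seed=1,
)
print(f"mean test C-index {out['c_index_mean']:.3f} ± {out['c_index_sd']:.3f}")
print("per fold:", [round(c, 3) for c in out["c_index_per_fold"]])
```

prints (about 13 minutes on one CPU):

```
300 patients, 42.0% events
mean test C-index 0.718 ± 0.048
per fold: [0.693, 0.763, 0.667, 0.774, 0.691]
```

The cohort plants its hazard through each patient's fraction of aggressive
(micropapillary + solid) tiles; the oracle C-index of that true fraction is
≈0.73, so a cross-validated 0.72 means the model recovers essentially all
of the planted signal from tile features and spatial structure alone. On
an `effect_size=0` cohort the same pipeline stays at chance (mean C 0.486
across folds).

The same flows are scriptable from a shell:

```bash
slidesurv simulate --out cohort/ --seed 1
slidesurv cv --cohort-dir cohort/ --out-dir results/ --seed 1 --max-epochs 40
slidesurv ablate --cohort-dir cohort/ --out-dir results/ --seed 1
```

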