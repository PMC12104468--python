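"""Cross-validated training, ablations and tile-sampling sweeps.

Experimental design: five-fold cross-validation stratified by event status,
each fold splitting patients 60/20/20 into train/validation/test.  Training
minimizes the batched negative log Cox partial likelihood with Adam
(batch 16 patients, learning rate 5e-5, weight decay 1e-4, dropout 0.3),
stopping early after 5 epochs without validation-loss improvement (cap 200
epochs) and restoring the best-validation weights.  Evaluation reports the
test-set concordance index, dynamic AUC at 1/3/5 years, and a Kaplan-Meier /
log-rank comparison of the groups split at the training-median risk.

Ablation variants: GAT-branch only, SSM-branch only, no edge features, no
positional encodings.  The sampling sweep retrains after rebuilding graphs
from random tile percentages or subtype-restricted tile sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .graph_construction import GraphConfig, SamplingMode, SamplingSpec
from .model import (
    GATMambaModel,
    ModelConfig,
    PatientBatch,
    load_state_dict,
    state_dict,
)
from .survival import (
    SurvivalRecord,
    ZeroEventBatchError,
    aggregate_reports,
    cox_loss,
    metric_report,
)

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = (
    "full",
    "gat_only",
    "mamba_only",
    "no_edge_features",
    "no_positional_encoding",
)

DEFAULT_SWEEP_FRACTIONS = (0.05, 0.10, 0.20, 0.30, 0.60, 1.00)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 5e-5
    weight_decay: float = 1e-4
    max_epochs: int = 200
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.max_epochs, self.early_stop_patience) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("hyperparameters must be non-negative")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def _apportion(strata_sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` slots across strata."""
    quotas = total * strata_sizes / strata_sizes.sum()
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


def make_folds(
    records: list[SurvivalRecord],
    n_folds: int = 5,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> list[FoldSplit]:
    """Patient-level, event-stratified train/val/test splits per fold.

    Split totals are round(fraction * n) for validation and test with the
    remainder going to train (444 patients at 60/20/20 -> 266/89/89); within
    each split, events and non-events are apportioned by largest remainder so
    every split mirrors the cohort's event fraction.
    """
    ids = np.array([r.patient_id for r in records])
    events = np.array([bool(r.event) for r in records])
    n = len(records)
    n_val = int(np.rint(fractions[1] * n))
    n_test = int(np.rint(fractions[2] * n))
    strata = [np.flatnonzero(events), np.flatnonzero(~events)]
    sizes = np.array([len(s) for s in strata])
    if np.any(sizes < n_folds):
        raise ValueError(
            f"each stratum needs >= {n_folds} patients (got sizes {sizes.tolist()})"
        )
    val_per = _apportion(sizes, n_val)
    test_per = _apportion(sizes, n_test)
    folds = []
    for f in range(n_folds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF0, f]))
        tr, va, te = [], [], []
        for s_idx, stratum in enumerate(strata):
            perm = stratum[rng.permutation(len(stratum))]
            nv, nt = val_per[s_idx], test_per[s_idx]
            te.extend(perm[:nt])
            va.extend(perm[nt : nt + nv])
            tr.extend(perm[nt + nv :])
        folds.append(
            FoldSplit(
                fold_id=f,
                train_ids=tuple(ids[sorted(tr)]),
                val_ids=tuple(ids[sorted(va)]),
                test_ids=tuple(ids[sorted(te)]),
            )
        )
    return folds


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to grads."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def model_config_for_variant(variant: str, base: ModelConfig) -> ModelConfig:
    """Map an ablation variant name onto a ModelConfig mutation."""
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}")
    mut = {
        "full": {},
        "gat_only": {"use_mamba": False},
        "mamba_only": {"use_gat": False},
        "no_edge_features": {"use_edge_features": False},
        "no_positional_encoding": {"use_positional_encoding": False},
    }[variant]
    return replace(base, **mut)


def _batch_for(ids, graphs_by_patient) -> PatientBatch:
    return PatientBatch.from_patients(
        list(ids), [graphs_by_patient[i] for i in ids]
    )


def _dataset_loss(model, ids, graphs_by_patient, records_by_id) -> float:
    """Full-set Cox loss in eval mode (validation monitor)."""
    batch = _batch_for(ids, graphs_by_patient)
    risks = model.predict_risk(batch, train=False)
    recs = [records_by_id[i] for i in ids]
    return float(cox_loss(risks, recs).data)


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    fold: FoldSplit,
    graphs_by_patient: dict,
    records: list[SurvivalRecord],
) -> tuple[GATMambaModel, dict]:
    """Train one fold; returns the best-validation model and the history."""
    records_by_id = {r.patient_id: r for r in records}
    val_events = sum(records_by_id[i].event for i in fold.val_ids)
    if val_events == 0:
        raise ValueError("validation set has zero events; loss is undefined")

    model = GATMambaModel(replace(model_config, seed=train_config.seed))
    opt = Adam(
        model.parameters(), train_config.learning_rate, train_config.weight_decay
    )
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 0x7A]))

    train_ids = list(fold.train_ids)
    best_val = np.inf
    best_state = state_dict(model)
    best_epoch = 0
    history = {"train_loss": [], "val_loss": []}
    bad_epochs = 0
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(len(train_ids))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            ids = [train_ids[i] for i in order[start : start + train_config.batch_size]]
            recs = [records_by_id[i] for i in ids]
            if not any(r.event for r in recs):
                logger.debug("skipping zero-event batch at epoch %d", epoch)
                continue
            batch = _batch_for(ids, graphs_by_patient)
            risks = model.predict_risk(batch, train=True, rng=rng)
            loss = cox_loss(risks, recs)
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _dataset_loss(model, fold.val_ids, graphs_by_patient, records_by_id)
        history["train_loss"].append(
            float(np.mean(epoch_losses)) if epoch_losses else float("nan")
        )
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = state_dict(model)
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_config.early_stop_patience:
                break
    load_state_dict(model, best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return model, history


def evaluate(
    model: GATMambaModel,
    fold: FoldSplit,
    graphs_by_patient: dict,
    records: list[SurvivalRecord],
) -> dict:
    """Per-fold metric report on the test split (train-median stratification)."""
    records_by_id = {r.patient_id: r for r in records}
    train_batch = _batch_for(fold.train_ids, graphs_by_patient)
    test_batch = _batch_for(fold.test_ids, graphs_by_patient)
    train_risks = model.predict_risk(train_batch, train=False).data
    test_risks = model.predict_risk(test_batch, train=False).data
    report = metric_report(
        train_risks,
        test_risks,
        [records_by_id[i] for i in fold.test_ids],
        train_records=[records_by_id[i] for i in fold.train_ids],
    )
    report["fold_id"] = fold.fold_id
    return report


def cross_validate(
    model_config: ModelConfig,
    train_config: TrainConfig,
    graphs_by_patient: dict,
    records: list[SurvivalRecord],
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Full stratified CV; per-fold reports plus mean ± SD aggregates."""
    folds = make_folds(records, n_folds=n_folds, seed=seed)
    reports = []
    for fold in folds:
        fold_seed = int((seed + 1000 * (fold.fold_id + 1)) % (2**31 - 1))
        model, history = train(
            model_config,
            replace(train_config, seed=fold_seed),
            fold,
            graphs_by_patient,
            records,
        )
        rep = evaluate(model, fold, graphs_by_patient, records)
        rep["epochs_trained"] = len(history["train_loss"])
        reports.append(rep)
        logger.info("fold %d: C-index %.3f", fold.fold_id, rep["c_index"])
    out = aggregate_reports(reports)
    out["folds"] = reports
    return out


def run_ablation(
    variants,
    base_model_config: ModelConfig,
    train_config: TrainConfig,
    graphs_by_patient: dict,
    records: list[SurvivalRecord],
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Train/evaluate each variant identically; include parameter counts."""
    out = {}
    for variant in variants:
        cfg = model_config_for_variant(variant, base_model_config)
        result = cross_validate(
            cfg, train_config, graphs_by_patient, records, n_folds=n_folds, seed=seed
        )
        result["n_parameters"] = GATMambaModel(cfg).count_parameters()["total"]
        out[variant] = result
    return out


def run_sampling_sweep(
    patients,
    base_graph_config: GraphConfig,
    model_config: ModelConfig,
    train_config: TrainConfig,
    fractions=DEFAULT_SWEEP_FRACTIONS,
    modes=(SamplingMode.RANDOM_FRACTION,),
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Rebuild graphs per sampling condition, retrain, and report C-indices.

    ``patients`` is a list of SyntheticPatient (tile tables + features are
    needed to rebuild graphs).  Conditions whose graphs collapse below two
    nodes are skipped with a logged reason.
    """
    from .graph_construction import GraphTooSmallError, build_graph

    records = [p.record for p in patients]
    conditions = []
    for mode in modes:
        if mode == SamplingMode.RANDOM_FRACTION:
            conditions.extend(
                (f"random_{int(round(f * 100))}pct", SamplingSpec(mode, f, seed))
                for f in fractions
            )
        else:
            conditions.append((mode.value, SamplingSpec(mode, 1.0, seed)))

    out = {"conditions": {}}
    for name, spec in conditions:
        gcfg = replace(base_graph_config, sampling=spec)
        graphs_by_patient = {}
        try:
            for p in patients:
                graphs_by_patient[p.record.patient_id] = [
                    build_graph(p.tiles[sid], p.features[sid], gcfg)
                    for sid in sorted(p.tiles)
                ]
        except GraphTooSmallError as e:
            logger.warning("skipping condition %s: %s", name, e)
            continue
        out["conditions"][name] = cross_validate(
            model_config, train_config, graphs_by_patient, records,
            n_folds=n_folds, seed=seed,
        )
    means = [c["c_index_mean"] for c in out["conditions"].values()]
    if means:
        out["macro_average_c_index"] = float(np.mean(means))
        out["c_index_range"] = float(np.max(means) - np.min(means))
    return out
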