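"""Training objective and evaluation for right-censored survival.

The training objective is the negative log Cox partial likelihood over a
batch of patients: for each observed event the patient's risk score is
compared against the log-sum-exp of the risks of everyone still at risk at
that time, with Breslow handling of tied event times (Efron available).  The
loss is normalized by the number of events in the batch.

Evaluation follows the conventions standard in survival modeling of
whole-slide-image cohorts:

* Harrell's concordance index over admissible pairs (earlier event vs. longer
  survivor; ties in risk score 0.5),
* cumulative/dynamic time-dependent AUC with inverse-probability-of-censoring
  weights (Uno), at 1 / 3 / 5-year horizons,
* Kaplan-Meier curves with a two-group log-rank test after splitting the test
  set at the training-set median risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor

DEFAULT_HORIZONS_DAYS = (365, 1095, 1825)  # 1, 3, 5 years


class ZeroEventBatchError(ValueError):
    """A batch with no observed events carries no partial-likelihood signal."""


class UndefinedMetricError(ValueError):
    """The metric's defining set (admissible pairs, cases/controls) is empty."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's right-censored outcome."""

    patient_id: str
    time_days: int
    event: bool
    cohort: str = ""

    def __post_init__(self):
        if self.time_days < 1:
            raise ValueError("time_days must be >= 1")


def records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time_days for r in records], dtype=np.float64)
    events = np.array([bool(r.event) for r in records])
    return times, events


# ---------------------------------------------------------------------------
# Cox partial likelihood


def cox_loss(
    risks,
    records,
    ties: str = "breslow",
) -> Tensor:
    """Negative log Cox partial likelihood, normalized by the event count.

    ``risks`` may be a plain array or an autodiff :class:`Tensor` (the loss is
    then differentiable w.r.t. the risks).  With Breslow ties, tied events
    share the full risk set; Efron's correction is available via
    ``ties="efron"``.  Raises :class:`ZeroEventBatchError` when the batch has
    no events (callers skip such batches).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    r = risks if isinstance(risks, Tensor) else Tensor(np.asarray(risks, dtype=float))
    times, events = records_to_arrays(records)
    if r.data.shape != times.shape:
        raise ValueError("risks and records length mismatch")
    n_events = int(events.sum())
    if n_events == 0:
        raise ZeroEventBatchError("no events in batch")

    # stabilize: partial likelihood is invariant to a constant risk shift
    shift = float(r.data.max())
    exp_r = (r - shift).exp()

    loss = Tensor(0.0)
    if ties == "breslow":
        for i in np.flatnonzero(events):
            at_risk = (times >= times[i]).astype(float)
            denom = (exp_r * Tensor(at_risk)).sum()
            loss = loss - ((r[i] - shift) - denom.log())
    else:  # efron
        for t in np.unique(times[events]):
            tied = events & (times == t)
            m = int(tied.sum())
            at_risk = (times >= t).astype(float)
            denom_full = (exp_r * Tensor(at_risk)).sum()
            denom_tied = (exp_r * Tensor(tied.astype(float))).sum()
            num = (r[np.flatnonzero(tied)] - shift).sum()
            for l in range(m):
                loss = loss - (
                    num * (1.0 / m) - (denom_full - denom_tied * (l / m)).log()
                )
    return loss * (1.0 / n_events)


def cox_loss_value(risks, records, ties: str = "breslow") -> float:
    return float(cox_loss(np.asarray(risks, dtype=float), records, ties).data)


# ---------------------------------------------------------------------------
# concordance


def concordance_index(risks, records) -> float:
    """Harrell's C over admissible pairs.

    A pair (i, j) is admissible when t_i < t_j and patient i had the event;
    it is concordant when r_i > r_j, and risk ties count 0.5.
    """
    risks = np.asarray(risks, dtype=float)
    times, events = records_to_arrays(records)
    lt = times[:, None] < times[None, :]
    admissible = lt & events[:, None]
    n_adm = int(admissible.sum())
    if n_adm == 0:
        raise UndefinedMetricError("no admissible pairs for the concordance index")
    gt = risks[:, None] > risks[None, :]
    eq = risks[:, None] == risks[None, :]
    score = (admissible & gt).sum() + 0.5 * (admissible & eq).sum()
    return float(score / n_adm)


def dynamic_auc(
    risks,
    records,
    horizons=DEFAULT_HORIZONS_DAYS,
    train_records=None,
) -> dict[int, float]:
    """Cumulative/dynamic AUC at fixed horizons, IPCW-weighted (Uno).

    The censoring distribution is estimated by Kaplan-Meier on
    ``train_records`` (falling back to ``records``).  A horizon with no cases
    or no controls — or beyond follow-up — is reported as NaN.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    risks = np.asarray(risks, dtype=float)
    times, events = records_to_arrays(records)
    ref = train_records if train_records is not None else records
    t_tr, e_tr = records_to_arrays(ref)
    y_train = Surv.from_arrays(event=e_tr, time=t_tr)
    y_test = Surv.from_arrays(event=events, time=times)

    out: dict[int, float] = {}
    for tau in horizons:
        n_cases = int((events & (times <= tau)).sum())
        n_controls = int((times > tau).sum())
        if n_cases == 0 or n_controls == 0:
            out[int(tau)] = float("nan")
            continue
        try:
            auc, _ = cumulative_dynamic_auc(y_train, y_test, risks, [tau])
            out[int(tau)] = float(auc[0])
        except ValueError:
            out[int(tau)] = float("nan")
    return out


# ---------------------------------------------------------------------------
# risk stratification and Kaplan-Meier


def stratify_by_median(train_risks, test_risks) -> np.ndarray:
    """Boolean high-risk mask for the test set, split at the training median.

    Strictly greater than the median counts as high risk; the median itself
    (and anything below) is low risk.  The median of an even-length set is the
    midpoint of the two central order statistics.
    """
    train_risks = np.asarray(train_risks, dtype=float)
    if train_risks.size == 0:
        raise ValueError("train risks must be non-empty")
    med = float(np.median(train_risks))
    return np.asarray(test_risks, dtype=float) > med


def km_logrank(groups, records):
    """Kaplan-Meier curves per group and the two-group log-rank p-value.

    ``groups`` is a boolean mask (True = high risk) aligned with ``records``.
    Returns ``(curves, p)`` where ``curves`` maps group name to a
    ``(times, survival)`` pair of arrays.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = np.asarray(groups, dtype=bool)
    times, events = records_to_arrays(records)
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be non-empty for the log-rank test")

    curves = {}
    for name, mask in (("low", ~groups), ("high", groups)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[name] = (sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy())

    res = logrank_test(times[groups], times[~groups], events[groups], events[~groups])
    p = float(res.p_value)
    return curves, min(max(p, np.nextafter(0.0, 1.0)), 1.0)


# ---------------------------------------------------------------------------
# reporting and I/O


def metric_report(
    train_risks,
    test_risks,
    test_records,
    train_records=None,
    horizons=DEFAULT_HORIZONS_DAYS,
) -> dict:
    """Per-fold evaluation bundle: C-index, dynamic AUCs, KM log-rank split."""
    high = stratify_by_median(train_risks, test_risks)
    report = {
        "c_index": concordance_index(test_risks, test_records),
        "dynamic_auc": dynamic_auc(
            test_risks, test_records, horizons, train_records=train_records
        ),
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }
    if 0 < high.sum() < high.size:
        _, p = km_logrank(high, test_records)
        report["logrank_p"] = p
    else:
        report["logrank_p"] = float("nan")
    return report


def aggregate_reports(reports: list[dict]) -> dict:
    """Mean ± SD of C-index and dynamic AUCs across folds."""
    c = np.array([r["c_index"] for r in reports], dtype=float)
    out = {
        "n_folds": len(reports),
        "c_index_mean": float(np.mean(c)),
        "c_index_sd": float(np.std(c, ddof=1)) if len(c) > 1 else 0.0,
        "c_index_per_fold": c.tolist(),
    }
    horizons = sorted(reports[0]["dynamic_auc"]) if reports else []
    for tau in horizons:
        vals = np.array([r["dynamic_auc"][tau] for r in reports], dtype=float)
        ok = vals[~np.isnan(vals)]
        out[f"auc_{tau}d_mean"] = float(np.mean(ok)) if ok.size else float("nan")
        out[f"auc_{tau}d_sd"] = (
            float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
        )
    return out


SURVIVAL_TABLE_COLUMNS = ["patient_id", "time_days", "event", "cohort"]


def write_survival_table(records, path) -> None:
    df = pd.DataFrame(
        [(r.patient_id, r.time_days, int(r.event), r.cohort) for r in records],
        columns=SURVIVAL_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_survival_table(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = {"patient_id", "time_days", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    out = []
    for rec in df.itertuples(index=False):
        cohort = getattr(rec, "cohort", "")
        out.append(
            SurvivalRecord(
                patient_id=str(rec.patient_id),
                time_days=int(rec.time_days),
                event=bool(int(rec.event)),
                cohort="" if pd.isna(cohort) else str(cohort),
            )
        )
    return out
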