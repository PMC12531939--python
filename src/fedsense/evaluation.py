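"""Per-batch and globally averaged error metrics.

For each batch and each predicted variable, predictions are compared with
ground measurements at the comparable days: sampling days after the first
input day (9 per full-grid batch), with titer compared from 3 dpi onward
(protein production only begins at induction). RMSE, MAE and R^2 are
computed per batch and then averaged, unweighted, across batches; nRMSE
and nMAE divide by the within-batch population SD of the ground truth, so
a mean predictor sits at exactly 1 and values below 1 beat the batch's
own variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import BatchRecord, OFFLINE_VARS
from .model import PredictionTrajectory

#: Titer errors are reported from this day (dpi) onward.
TITER_EVAL_START = 3

METRIC_KEYS = ("rmse", "mae", "r2", "nrmse", "nmae")


def batch_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, r2_mode: str = "ss"
) -> dict:
    """Error metrics for one variable of one batch.

    ``r2_mode="ss"`` gives the coefficient of determination
    1 - SSres/SStot (default); ``"corr"`` gives the squared Pearson
    correlation. Normalized metrics divide by the population SD of
    ``y_true``; a zero SD is an error since they are then undefined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    n = len(y_true)
    if n < 2:
        raise ValueError("need >= 2 comparable points")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sd = float(np.std(y_true))  # population convention
    if sd == 0.0:
        raise ValueError("zero batch SD: normalized metrics undefined")
    if r2_mode == "ss":
        r2 = 1.0 - float(np.sum(err**2) / np.sum((y_true - y_true.mean()) ** 2))
    elif r2_mode == "corr":
        r2 = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return {
        "rmse": rmse,
        "mae": mae,
        "r2": r2,
        "nrmse": rmse / sd,
        "nmae": mae / sd,
        "n_points": n,
        "batch_sd": sd,
    }


def comparable_points(
    traj: PredictionTrajectory, batch: BatchRecord, variable: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(days, y_true, y_pred) at the comparable days of one variable.

    Comparable days are sampling days strictly after the first input day;
    titer additionally starts at 3 dpi.
    """
    i = OFFLINE_VARS.index(variable)
    first_day = batch.day_grid[0]
    sel = batch.offline_mask[:, i] & (batch.day_grid > first_day)
    if variable == "titer":
        sel &= batch.day_grid >= TITER_EVAL_START
    days = batch.day_grid[sel]
    y_true = batch.offline[sel, i]
    idx = np.searchsorted(traj.days, days)
    y_pred = traj.x_hat[idx, i]
    return days, y_true, y_pred


def evaluate_batch(
    traj: PredictionTrajectory, batch: BatchRecord, r2_mode: str = "ss"
) -> dict:
    """Per-variable metric dict for one batch."""
    if not np.array_equal(traj.days, batch.day_grid):
        raise ValueError(
            f"batch {batch.batch_id}: trajectory day grid does not match"
        )
    out = {}
    for v in OFFLINE_VARS:
        _, y_true, y_pred = comparable_points(traj, batch, v)
        out[v] = batch_metrics(y_true, y_pred, r2_mode=r2_mode)
    return out


@dataclass
class MetricsReport:
    """Across-batch averages plus the per-batch table.

    ``global_mean[var][metric]`` is the unweighted mean over batches;
    ``global_sd[var]["rmse"/"mae"]`` the across-batch SDs (sigma-RMSE,
    sigma-MAE).
    """

    variables: tuple
    batch_ids: list
    per_batch: dict          # batch_id -> var -> metric dict
    global_mean: dict = field(default_factory=dict)
    global_sd: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per batch x variable x metric)."""
        rows = []
        for bid, per_var in self.per_batch.items():
            for v, metrics in per_var.items():
                for k in METRIC_KEYS:
                    rows.append({"batch_id": bid, "variable": v,
                                 "metric": k, "value": metrics[k]})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "variables": list(self.variables),
            "batch_ids": list(self.batch_ids),
            "per_batch": self.per_batch,
            "global_mean": self.global_mean,
            "global_sd": self.global_sd,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        return cls(
            variables=tuple(d["variables"]),
            batch_ids=list(d["batch_ids"]),
            per_batch=d["per_batch"],
            global_mean=d["global_mean"],
            global_sd=d["global_sd"],
        )


def global_metrics(per_batch: dict) -> MetricsReport:
    """Unweighted across-batch mean of each metric, plus sigma-RMSE/MAE."""
    if not per_batch:
        raise ValueError("no batch metrics to aggregate")
    batch_ids = list(per_batch)
    variables = tuple(next(iter(per_batch.values())))
    report = MetricsReport(variables=variables, batch_ids=batch_ids,
                           per_batch=per_batch)
    for v in variables:
        vals = {k: np.array([per_batch[b][v][k] for b in batch_ids])
                for k in METRIC_KEYS}
        report.global_mean[v] = {k: float(vals[k].mean()) for k in METRIC_KEYS}
        report.global_sd[v] = {
            "rmse": float(vals["rmse"].std()),
            "mae": float(vals["mae"].std()),
        }
    return report


def evaluate_batches(
    trajectories: list[PredictionTrajectory],
    batches: list[BatchRecord],
    r2_mode: str = "ss",
) -> MetricsReport:
    """Evaluate aligned trajectory/batch pairs and aggregate."""
    if len(trajectories) != len(batches):
        raise ValueError("trajectory/batch count mismatch")
    per_batch = {
        b.batch_id: evaluate_batch(t, b, r2_mode=r2_mode)
        for t, b in zip(trajectories, batches)
    }
    return global_metrics(per_batch)


def error_time_profile(
    y_true: np.ndarray, y_pred: np.ndarray, days: np.ndarray
) -> pd.DataFrame:
    """Per-day absolute percentage error, 100*|pred-true|/|true|.

    Days with zero ground truth are flagged (``valid=False``) and carry
    NaN instead of an error value.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    days = np.asarray(days)
    if not (len(y_true) == len(y_pred) == len(days)):
        raise ValueError("misaligned series")
    valid = y_true != 0
    pct = np.full(len(days), np.nan)
    pct[valid] = 100.0 * np.abs(y_pred[valid] - y_true[valid]) / np.abs(y_true[valid])
    return pd.DataFrame({"day_dpi": days, "pct_error": pct, "valid": valid})


def plot_error_boxes(report: MetricsReport, ax=None):
    """Box plot of per-batch RMSE/MAE distributions (unstyled)."""
    import matplotlib.pyplot as plt

    frame = report.to_frame()
    frame = frame[frame.metric.isin(["nrmse", "nmae"])]
    if ax is None:
        _, ax = plt.subplots()
    data, labels = [], []
    for v in report.variables:
        for k in ("nrmse", "nmae"):
            sel = frame[(frame.variable == v) & (frame.metric == k)]
            data.append(sel.value.to_numpy())
            labels.append(f"{v}\n{k}")
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(1.0, ls="--", lw=0.8)
    ax.set_ylabel("normalized error")
    return ax
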