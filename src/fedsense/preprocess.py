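"""Raw telemetry -> aligned daily feature grid.

The soft sensor consumes one 7-vector of online features per process day:
daily averages of (Savitzky-Golay smoothed) pH, DO and temperature, the
last base-volume reading of the day, and running trapezoidal integrals of
DO (DOint, %*day) and of the O2/CO2 sparge flows (total mL sparged).
This module implements those transformations and the cumulative-glucose
bookkeeping that turns pre/post-feed glucose assays into the cumulative
glucose consumed (cGC) series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid as _cumtrapz
from scipy.signal import savgol_filter

from .batch import BatchRecord, OFFLINE_VARS

logger = logging.getLogger(__name__)

#: Raw telemetry channel names (CSV column order after time_day).
RAW_CHANNELS = ("ph", "do_pct", "temp_c", "base_ml", "o2_flow", "co2_flow")

# Savitzky-Golay defaults for pH at 15-min telemetry cadence: a gentle
# ~7.75-hour window with a quadratic fit.
SG_WINDOW_DEFAULT = 31
SG_POLYORDER_DEFAULT = 2


@dataclass
class OnlineChannelSeries:
    """One raw telemetry channel: values sampled at fractional process days."""

    channel_name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.channel_name}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.channel_name}: values must be finite")


def smooth_ph(
    series: OnlineChannelSeries,
    window: int = SG_WINDOW_DEFAULT,
    polyorder: int = SG_POLYORDER_DEFAULT,
) -> OnlineChannelSeries:
    """Savitzky-Golay smoothing of a pH trace.

    Local least-squares polynomial smoothing; preserves polynomials up to
    ``polyorder`` exactly and keeps length and timestamps unchanged.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window >= len(series.values):
        raise ValueError(
            f"window {window} >= series length {len(series.values)}"
        )
    smoothed = savgol_filter(series.values, window, polyorder)
    return OnlineChannelSeries(series.channel_name, series.times.copy(), smoothed)


def daily_average(
    series: OnlineChannelSeries, day_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of all samples with time in [day, day+1) per day.

    Returns ``(values, present)`` where ``present`` flags days that had at
    least one sample; days with none get NaN.
    """
    if len(series.times) == 0:
        raise ValueError("empty series")
    days = np.asarray(day_grid)
    out = np.full(len(days), np.nan)
    present = np.zeros(len(days), dtype=bool)
    bucket = np.floor(series.times).astype(int)
    for k, d in enumerate(days):
        sel = bucket == d
        if sel.any():
            out[k] = series.values[sel].mean()
            present[k] = True
    return out, present


def last_in_day(
    series: OnlineChannelSeries, day_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Last reading within [day, day+1) per day (for running-total channels)."""
    if len(series.times) == 0:
        raise ValueError("empty series")
    days = np.asarray(day_grid)
    out = np.full(len(days), np.nan)
    present = np.zeros(len(days), dtype=bool)
    bucket = np.floor(series.times).astype(int)
    for k, d in enumerate(days):
        idx = np.flatnonzero(bucket == d)
        if idx.size:
            out[k] = series.values[idx[-1]]
            present[k] = True
    return out, present


def cumulative_trapezoid(
    series: OnlineChannelSeries, eval_days: np.ndarray
) -> np.ndarray:
    """Running trapezoidal integral of a channel, evaluated at given days.

    The integral starts at the first timestamp; the value reported for day
    ``d`` is the integral of the signal from the start of the series up to
    time ``d`` (sum over i of (t_{i+1}-t_i)*(v_{i+1}+v_i)/2).
    """
    if len(series.times) < 2:
        raise ValueError("need >= 2 samples to integrate")
    eval_days = np.asarray(eval_days, dtype=float)
    if eval_days.min() < series.times[0] - 1e-9 or eval_days.max() > series.times[-1] + 1e-9:
        raise ValueError("eval_days outside series time span")
    cum = np.concatenate([[0.0], _cumtrapz(series.values, series.times)])
    return np.interp(eval_days, series.times, cum)


def cumulative_glucose_consumed(
    post_feed_glc: np.ndarray,
    residual_glc: np.ndarray,
    negative_tol: float = 0.5,
    clamp_negative: bool = False,
) -> np.ndarray:
    """Cumulative glucose consumed (cGC) from pre/post-feed glucose assays.

    Consumption over sampling interval j -> j+1 is the difference between
    the post-feed glucose concentration at day j and the residual glucose
    measured at day j+1; cGC at sampling day k is the running sum of those
    interval consumptions, with cGC = 0 at the first sampling day.

    Parameters
    ----------
    post_feed_glc, residual_glc : array, shape (S,)
        Glucose concentration (mM) after feeding resp. before feeding at
        each of the S ordered sampling days.
    negative_tol : float
        Negative interval consumptions smaller than this (mM) are treated
        as measurement noise silently; beyond it a warning is emitted.
    clamp_negative : bool
        If True, negative interval consumptions are clamped to zero;
        default keeps the raw value.
    """
    post = np.asarray(post_feed_glc, dtype=float)
    resid = np.asarray(residual_glc, dtype=float)
    if post.shape != resid.shape or post.ndim != 1:
        raise ValueError("post-feed and residual arrays must match in shape")
    consumed = post[:-1] - resid[1:]
    neg = consumed < -negative_tol
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} sampling interval(s) show negative glucose "
            "consumption beyond tolerance (measurement noise?)",
            stacklevel=2,
        )
    if clamp_negative:
        consumed = np.maximum(consumed, 0.0)
    return np.concatenate([[0.0], np.cumsum(consumed)])


def assemble_batch(
    online_channels: dict,
    offline_log: pd.DataFrame,
    day_grid: np.ndarray,
    batch_id: str = "batch",
    pool_id: str = "unknown",
    passage: int = 0,
    msx: float = 50.0,
    sg_window: int = SG_WINDOW_DEFAULT,
    sg_polyorder: int = SG_POLYORDER_DEFAULT,
    truth: dict | None = None,
) -> BatchRecord:
    """Build a validated :class:`BatchRecord` from raw channels and samples.

    ``online_channels`` maps the six raw channel names (:data:`RAW_CHANNELS`)
    to :class:`OnlineChannelSeries`. ``offline_log`` must have columns
    ``day_dpi, vcd, lactate_mM, ammonia_mM, glucose_residual_mM,
    glucose_postfeed_mM, titer_mgL`` (extra columns tolerated); it may be
    empty, in which case the batch is pure-online with an all-false mask.
    """
    missing = [c for c in RAW_CHANNELS if c not in online_channels]
    if missing:
        raise ValueError(f"missing online channel(s): {', '.join(missing)}")
    day_grid = np.asarray(day_grid, dtype=int)

    ph = online_channels["ph"]
    if len(ph.values) > sg_window:
        ph = smooth_ph(ph, sg_window, sg_polyorder)
    ph_avg, ph_ok = daily_average(ph, day_grid)
    do_avg, do_ok = daily_average(online_channels["do_pct"], day_grid)
    temp_avg, temp_ok = daily_average(online_channels["temp_c"], day_grid)
    base_cum, base_ok = last_in_day(online_channels["base_ml"], day_grid)
    if not (ph_ok.all() and do_ok.all() and temp_ok.all() and base_ok.all()):
        bad = day_grid[~(ph_ok & do_ok & temp_ok & base_ok)]
        raise ValueError(f"no telemetry inside day(s) {bad.tolist()}")
    do_int = cumulative_trapezoid(online_channels["do_pct"], day_grid)
    o2_total = cumulative_trapezoid(online_channels["o2_flow"], day_grid)
    co2_total = cumulative_trapezoid(online_channels["co2_flow"], day_grid)
    online = np.column_stack(
        [ph_avg, do_avg, temp_avg, base_cum, do_int, o2_total, co2_total]
    )

    T = len(day_grid)
    offline = np.full((T, len(OFFLINE_VARS)), np.nan)
    mask = np.zeros((T, len(OFFLINE_VARS)), dtype=bool)
    if len(offline_log):
        log = offline_log.sort_values("day_dpi").reset_index(drop=True)
        samp_days = log["day_dpi"].to_numpy(dtype=int)
        outside = set(samp_days) - set(day_grid.tolist())
        if outside:
            raise ValueError(f"offline sample on day(s) {sorted(outside)} outside grid")
        resid = log["glucose_residual_mM"].to_numpy(dtype=float)
        post = log["glucose_postfeed_mM"].to_numpy(dtype=float)
        cgc = cumulative_glucose_consumed(post, resid)
        col_of = {
            "titer": "titer_mgL",
            "vcd": "vcd",
            "lactate": "lactate_mM",
            "ammonia": "ammonia_mM",
        }
        day_to_idx = {int(d): i for i, d in enumerate(day_grid)}
        for j, d in enumerate(samp_days):
            t = day_to_idx[int(d)]
            for i, var in enumerate(OFFLINE_VARS):
                val = cgc[j] if var == "cgc" else float(log.loc[j, col_of[var]])
                if np.isfinite(val):
                    offline[t, i] = val
                    mask[t, i] = True
    else:
        samp_days = np.array([], dtype=int)
        resid = np.array([])
        post = np.array([])

    record = BatchRecord(
        batch_id=batch_id,
        pool_id=pool_id,
        passage=passage,
        msx=msx,
        day_grid=day_grid,
        online=online,
        offline=offline,
        offline_mask=mask,
        sampling_days=samp_days,
        glucose_residual=resid,
        glucose_postfeed=post,
        truth=truth,
        raw_online=dict(online_channels),
    )
    record.validate()
    logger.info(
        "assembled batch %s: %d days, %d offline samples",
        batch_id, T, int(mask.sum()),
    )
    return record


def zscore_outlier_flags(values: np.ndarray, threshold: float = 4.0) -> np.ndarray:
    """Generic outlier-flag hook (off by default in all pipelines).

    Flags points whose robust z-score (median/MAD) exceeds ``threshold``.
    This is a screening aid for telemetry anomalies; flagged points are
    reported, never silently removed.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.zeros(v.shape, dtype=bool)
    return np.abs(v - med) / (1.4826 * mad) > threshold
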