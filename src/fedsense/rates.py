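"""Specific glucose consumption rate (qGluc) estimation.

The integral of viable cell concentration (IVCC, cell*day/mL) is the
trapezoidal time-integral of VCD. Dividing glucose consumed over an
interval by the interval's IVCC increment gives the cell-specific
consumption rate:

    qGluc_i = (cGC_{i+1} - cGC_i) / (IVCC_{i+1} - IVCC_i)

Applied to the model's daily predictions this yields a daily-resolution
rate estimate; applied to sampling-day ground data (with possibly
multi-day intervals) it yields the ground-truth stepwise rates. Interval
rates are attributed to the interval's end day.

Internally qGluc is carried in mM*mL/(cell*day); multiply by 1e6 for
pmol/(cell*day) (1 mM consumed per day at 1e6 cells/mL is exactly
1 pmol/(cell*day)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid as _cumtrapz

from .batch import OFFLINE_VARS
from .model import PredictionTrajectory

#: mM*mL/(cell*day) -> pmol/(cell*day)
QGLUC_TO_PMOL = 1.0e6


@dataclass
class RateSeries:
    """Interval-wise specific-rate estimates.

    ``days`` are interval end days; ``q_gluc`` is NaN where the IVCC
    increment was non-positive (rate undefined there).
    """

    days: np.ndarray
    ivcc: np.ndarray              # cell*day/mL at interval end days
    delta_ivcc: np.ndarray        # cell*day/mL per interval
    consumed_glucose: np.ndarray  # mM per interval
    q_gluc: np.ndarray            # mM*mL/(cell*day)
    source: str = "pred"

    @property
    def q_gluc_pmol(self) -> np.ndarray:
        return self.q_gluc * QGLUC_TO_PMOL

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day_dpi": self.days,
            "ivcc": self.ivcc,
            "delta_ivcc": self.delta_ivcc,
            "consumed_glucose_mM": self.consumed_glucose,
            "q_gluc": self.q_gluc,
            "q_gluc_pmol_per_cell_day": self.q_gluc_pmol,
            "source": self.source,
        })


def ivcc(times: np.ndarray, vcd: np.ndarray) -> np.ndarray:
    """Running trapezoidal integral of VCD over time (cell*day/mL)."""
    times = np.asarray(times, dtype=float)
    vcd = np.asarray(vcd, dtype=float)
    if len(times) < 2:
        raise ValueError("need >= 2 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(vcd < 0):
        raise ValueError("VCD must be >= 0")
    return np.concatenate([[0.0], _cumtrapz(vcd, times)])


def _rates(days, cgc, vcd, source) -> RateSeries:
    cum = ivcc(days, vcd)
    d_ivcc = np.diff(cum)
    consumed = np.diff(np.asarray(cgc, dtype=float))
    q = np.full(len(consumed), np.nan)
    ok = d_ivcc > 0
    q[ok] = consumed[ok] / d_ivcc[ok]
    return RateSeries(
        days=np.asarray(days)[1:], ivcc=cum[1:], delta_ivcc=d_ivcc,
        consumed_glucose=consumed, q_gluc=q, source=source,
    )


def qgluc_from_predictions(traj: PredictionTrajectory) -> RateSeries:
    """Daily specific glucose consumption rates from a model trajectory.

    Daily consumed glucose is the first difference of predicted cGC
    (unit day spacing); the IVCC increment comes from trapezoidal
    integration of the predicted VCD.
    """
    i_cgc = OFFLINE_VARS.index("cgc")
    i_vcd = OFFLINE_VARS.index("vcd")
    return _rates(traj.days, traj.x_hat[:, i_cgc], traj.x_hat[:, i_vcd], "pred")


def qgluc_from_arrays(days, cgc, vcd, source: str = "pred") -> RateSeries:
    """Rates from explicit daily cGC and VCD arrays (e.g. simulator truth)."""
    return _rates(days, cgc, vcd, source)


def qgluc_from_samples(
    sampling_days: np.ndarray,
    consumed_glucose: np.ndarray,
    vcd: np.ndarray,
) -> RateSeries:
    """Ground stepwise rates from sampling-day data.

    ``consumed_glucose[k]`` is the glucose consumed (mM) over the interval
    ending at ``sampling_days[k+1]``; ``vcd`` holds the measured VCD at
    each sampling day. Intervals may span several days; the IVCC increment
    covers the full interval.
    """
    days = np.asarray(sampling_days, dtype=float)
    consumed = np.asarray(consumed_glucose, dtype=float)
    if len(consumed) != len(days) - 1:
        raise ValueError("need one consumed-glucose value per interval")
    cgc = np.concatenate([[0.0], np.cumsum(consumed)])
    return _rates(days, cgc, vcd, "ground")
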