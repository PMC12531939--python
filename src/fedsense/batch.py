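"""Batch-level data containers for fed-batch production runs.

A :class:`BatchRecord` holds everything the soft sensor needs about one
production run: the aligned daily online feature grid (7 telemetry-derived
features), the sparse offline sampling measurements (5 assayed variables),
the per-day availability mask, and — for simulated runs — the noise-free
daily truth used by validation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Canonical order of the five offline (sampled) variables.
OFFLINE_VARS = ("titer", "vcd", "lactate", "ammonia", "cgc")

#: Canonical order of the seven daily online features.
ONLINE_FEATURES = (
    "ph_avg",
    "do_avg",
    "temp_avg",
    "base_cum",
    "do_int",
    "o2_total",
    "co2_total",
)

#: Online features that are running totals and must never decrease.
CUMULATIVE_ONLINE = ("base_cum", "do_int", "o2_total", "co2_total")

#: Units for reporting (offline variables).
OFFLINE_UNITS = {
    "titer": "mg/L",
    "vcd": "cells/mL",
    "lactate": "mM",
    "ammonia": "mM",
    "cgc": "mM",
}


class BatchValidationError(ValueError):
    """Raised when a BatchRecord violates a structural invariant."""


@dataclass
class BatchRecord:
    """One production run on an aligned integer process-day grid.

    Days are indexed in dpi (days post-induction); induction is day 0 and
    the standard grid runs -3..14 dpi (18 calendar days, 17 one-day
    transitions).

    Attributes
    ----------
    batch_id : str
        Unique identifier within a campaign.
    pool_id : str
        Cell-pool phenotype label (e.g. ``"Delta"``, ``"Beta"``, ``"WuTL"``).
    passage : int
        Cell passage number at seeding (process metadata).
    msx : float
        MSX supplementation at induction, uM (process metadata).
    day_grid : ndarray of int, shape (T,)
        Strictly increasing, unit-spaced process days (dpi).
    online : ndarray, shape (T, 7)
        Daily online features in :data:`ONLINE_FEATURES` order.
    offline : ndarray, shape (T, 5)
        Offline measurements in :data:`OFFLINE_VARS` order; NaN where the
        variable was not sampled that day.
    offline_mask : ndarray of bool, shape (T, 5)
        True exactly where ``offline`` holds a measurement.
    sampling_days : ndarray of int, shape (S,)
        Days on which offline samples were drawn.
    glucose_residual : ndarray, shape (S,)
        Residual (pre-feed) glucose at each sampling day, mM.
    glucose_postfeed : ndarray, shape (S,)
        Post-feed glucose at each sampling day, mM (equals the residual on
        sampling days without a feed).
    truth : dict or None
        Simulated batches only: noise-free daily values keyed by variable
        name (arrays of shape (T,)) plus ``"q_gluc"`` — the realized daily
        specific glucose consumption rate in mM*mL/(cell*day), shape (T-1,).
    """

    batch_id: str
    pool_id: str
    day_grid: np.ndarray
    online: np.ndarray
    offline: np.ndarray
    offline_mask: np.ndarray
    sampling_days: np.ndarray
    glucose_residual: np.ndarray
    glucose_postfeed: np.ndarray
    passage: int = 0
    msx: float = 50.0
    truth: Optional[dict] = None
    raw_online: Optional[dict] = field(default=None, repr=False)

    @property
    def n_days(self) -> int:
        return len(self.day_grid)

    def induction_index(self) -> int:
        """Index of day 0 dpi in the grid."""
        idx = np.flatnonzero(self.day_grid == 0)
        if idx.size != 1:
            raise BatchValidationError(
                f"batch {self.batch_id}: induction day 0 not on grid"
            )
        return int(idx[0])

    def validate(self) -> None:
        """Check all structural invariants; raise BatchValidationError."""
        d = np.asarray(self.day_grid)
        if d.ndim != 1 or len(d) < 2:
            raise BatchValidationError("day_grid must be 1-D with >= 2 days")
        if not np.all(np.diff(d) == 1):
            raise BatchValidationError(
                "day_grid must be strictly increasing with unit spacing"
            )
        T = len(d)
        if self.online.shape != (T, len(ONLINE_FEATURES)):
            raise BatchValidationError(
                f"online shape {self.online.shape} != ({T}, 7)"
            )
        if self.offline.shape != (T, len(OFFLINE_VARS)):
            raise BatchValidationError(
                f"offline shape {self.offline.shape} != ({T}, 5)"
            )
        if self.offline_mask.shape != self.offline.shape:
            raise BatchValidationError("offline_mask shape mismatch")
        if self.offline_mask.dtype != bool:
            raise BatchValidationError("offline_mask must be boolean")
        if not np.all(np.isfinite(self.online)):
            raise BatchValidationError("online features must be finite")
        if not np.all(np.isfinite(self.offline[self.offline_mask])):
            raise BatchValidationError("masked-in offline values must be finite")
        # cumulative online channels never decrease
        for name in CUMULATIVE_ONLINE:
            col = self.online[:, ONLINE_FEATURES.index(name)]
            if np.any(np.diff(col) < -1e-9):
                raise BatchValidationError(f"cumulative channel {name} decreases")
        # mask true only on sampling days
        samp = set(int(s) for s in self.sampling_days)
        for t, day in enumerate(d):
            if self.offline_mask[t].any() and int(day) not in samp:
                raise BatchValidationError(
                    f"offline_mask set on non-sampling day {day}"
                )
        # titer zero before induction; VCD positive where sampled
        i_titer = OFFLINE_VARS.index("titer")
        i_vcd = OFFLINE_VARS.index("vcd")
        pre = d < 0
        titer_pre = self.offline[pre, i_titer][self.offline_mask[pre, i_titer]]
        if titer_pre.size and np.any(np.abs(titer_pre) > 1e-9):
            raise BatchValidationError("titer must be 0 before induction")
        vcd_meas = self.offline[:, i_vcd][self.offline_mask[:, i_vcd]]
        if np.any(vcd_meas <= 0):
            raise BatchValidationError("VCD must be > 0 on sampled days")
        # observed cGC non-decreasing along the grid
        i_cgc = OFFLINE_VARS.index("cgc")
        cgc = self.offline[:, i_cgc][self.offline_mask[:, i_cgc]]
        if np.any(np.diff(cgc) < -1e-9):
            raise BatchValidationError("cumulative glucose consumed decreases")

    def offline_at(self, day: int) -> np.ndarray:
        """Offline 5-vector at a given day (NaN where unsampled)."""
        idx = np.flatnonzero(self.day_grid == day)
        if idx.size != 1:
            raise KeyError(f"day {day} not on grid")
        return self.offline[int(idx[0])]
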