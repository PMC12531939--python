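"""Synthetic fed-batch campaign generator.

Emulates a 17-day CHO fed-batch production process run in benchtop
bioreactors: Monod-type growth on glucose with a temperature-downshift
growth reduction, the lactate production/consumption metabolic switch
(with optional late re-production), an ammonia plateau followed by
accumulation, titer accumulation proportional to the viable-cell integral
from induction, bolus feeds with a glucose floor rule, deadband pH control
(base addition below the band, CO2 sparging above it) and a DO cascade
with O2 sparging proportional to oxygen demand.

Internal integration uses explicit Euler at 0.01-day steps; telemetry is
emitted on a 15-minute grid and then pushed through the :mod:`preprocess`
pipeline so that simulated batches flow through exactly the same code path
as real ones. Offline observations are corrupted with multiplicative
Gaussian noise (truncated at +/-3 SD) at the configured relative standard
deviations on sampling days only.

Three pool phenotypes are provided ("Delta", "Beta", "WuTL") whose kinetic
magnitudes are package defaults chosen to produce realistic-looking runs;
they are not literature measurements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import BatchRecord
from .preprocess import OnlineChannelSeries, assemble_batch

DT = 0.01            # integration step, days
TELEMETRY_DT = 1.0 / 96.0  # 15-minute emission cadence, days

#: Default measurement relative SDs of the offline assays.
DEFAULT_NOISE_RSD = {
    "vcd": 0.07,
    "lactate": 0.02,
    "ammonia": 0.03,
    "cgc": 0.03,
    "titer": 0.12,
}

DEFAULT_SAMPLING_DAYS = (-3, -2, -1, 0, 3, 5, 7, 10, 12, 14)
DEFAULT_FEED_DAYS = (0, 3, 5, 7, 10, 12)
DEFAULT_FEED_FRACTIONS = (5.0, 5.0, 5.0, 7.5, 5.0, 5.0)


class SimulationError(RuntimeError):
    """Raised when the process integration produces an invalid state."""


@dataclass
class SimConfig:
    """All kinetic, control-loop, feed-schedule and noise parameters.

    Specific rates (q_*) are in pmol/(cell*day) unless noted; with VCD
    expressed in 1e6 cells/mL a rate of 1 pmol/(cell*day) consumes or
    produces exactly 1 mM/day, which keeps the mass balance transparent.
    Days are dpi (days post-induction); seeding is at -3 dpi, so the
    temperature shift "3 days after seeding" lands on 0 dpi and the pH
    setpoint shift "2 days post-seeding" on -1 dpi.
    """

    pool_id: str = "Delta"
    seed_density: float = 0.4e6          # cells/mL at -3 dpi
    mu_max: float = 1.1                  # 1/day
    K_glc: float = 0.5                   # mM, Monod constant
    x_max: float = 14.0                  # 1e6 cells/mL, carrying capacity
    q_glc_growth: float = 2.5            # growth-coupled glucose uptake
    q_glc_prod: float = 0.8              # maintenance/production uptake
    q_lac_prod: float = 3.5              # lactate production (growth phase)
    q_lac_cons: float = 0.45             # lactate consumption after switch
    q_lac_late: float = 0.45             # late re-production (if enabled)
    lactate_switch_day: float = 1.5      # dpi of the metabolic switch
    late_lactate_reproduction: bool = False
    q_amm_growth: float = 0.10           # ammonia production during growth
    q_amm: float = 0.05                  # ammonia production after plateau
    amm_plateau: tuple = (0.0, 7.0)      # dpi window of near-zero production
    q_titer: float = 3.2                 # pg/(cell*day) from induction
    secondary_growth: bool = True        # keep growing after the temp shift
    temp_shift_day: float = 3.0          # days post-seeding (37 -> 32 C)
    ph_shift_day: float = 2.0            # days post-seeding
    ph_deadband_pre: tuple = (7.00, 7.10)
    ph_deadband_post: tuple = (6.90, 7.00)
    do_setpoint: float = 40.0            # % air saturation
    sparger: str = "micro"               # "micro" or "macro" sparger
    feed_days: tuple = DEFAULT_FEED_DAYS
    feed_fractions: tuple = DEFAULT_FEED_FRACTIONS  # % of initial volume
    glucose_floor: float = 17.0          # mM
    initial_glucose: float = 35.0        # mM in the basal medium
    feed_glucose: float = 40.0           # mM contributed by the feed medium
    v0: float = 0.5                      # L initial working volume
    noise_rsd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_RSD))
    online_noise: dict = field(
        default_factory=lambda: {"ph": 0.005, "do": 0.3, "temp": 0.02}
    )
    sampling_days: tuple = DEFAULT_SAMPLING_DAYS
    first_day: int = -3
    last_day: int = 14                   # inclusive; horizon = last-first+1
    truncate_day: int | None = None      # early harvest (e.g. 12 dpi)
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "mu_max", "K_glc", "q_glc_growth", "q_glc_prod", "q_lac_prod",
            "q_lac_cons", "q_lac_late", "q_amm_growth", "q_amm", "q_titer",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for band in (self.ph_deadband_pre, self.ph_deadband_post):
            if not band[0] < band[1]:
                raise ValueError(f"pH deadband low must be < high, got {band}")
        for v in self.noise_rsd.values():
            if not 0 <= v < 1:
                raise ValueError("noise RSDs must lie in [0, 1)")
        if self.sparger not in _SPARGER:
            raise ValueError(f"unknown sparger type {self.sparger!r}")
        last = self.effective_last_day()
        days = set(range(self.first_day, last + 1))
        if not set(self.sampling_days_effective()) <= days:
            raise ValueError("sampling_days must lie on the simulated grid")
        if len(self.feed_days) != len(self.feed_fractions):
            raise ValueError("feed_days and feed_fractions length mismatch")

    def effective_last_day(self) -> int:
        if self.truncate_day is not None:
            return min(self.last_day, int(self.truncate_day))
        return self.last_day

    def sampling_days_effective(self) -> tuple:
        last = self.effective_last_day()
        return tuple(d for d in self.sampling_days if d <= last)


#: Pool phenotype presets. Magnitudes are package defaults, not measured
#: values: Delta grows to the highest density with variable lactate, Beta
#: shows a secondary growth spurt and an ammonia lag until ~7 dpi, WuTL
#: plateaus after the temperature shift, accumulates ammonia right after
#: induction, has the highest specific productivity and can re-produce
#: lactate late in the run.
POOL_PRESETS: dict[str, dict] = {
    "Delta": dict(
        pool_id="Delta", mu_max=1.10, x_max=14.0, q_titer=3.2,
        q_lac_prod=3.5, secondary_growth=True, amm_plateau=(0.0, 7.0),
        sparger="micro",
    ),
    "Beta": dict(
        pool_id="Beta", mu_max=1.00, x_max=11.0, q_titer=3.0,
        q_lac_prod=2.8, secondary_growth=True, amm_plateau=(0.0, 7.0),
        sparger="macro",
    ),
    "WuTL": dict(
        pool_id="WuTL", mu_max=0.95, x_max=8.5, q_titer=4.5,
        q_lac_prod=3.0, secondary_growth=False, amm_plateau=(0.0, 1.0),
        late_lactate_reproduction=True, sparger="macro",
    ),
}

# pH / gassing loop constants (package defaults).
_ACID_PER_LACTATE = 0.018     # pH drop per mM lactate produced
_PH_DRIFT = 0.025             # pH/day upward drift (CO2 stripping)
_BASE_GAIN = 120.0            # mL/day per pH unit below the band
_BASE_EFFECT = 0.02           # pH per mL base
_CO2_GAIN = 1.0e5             # mL/day per pH unit above the band
_CO2_EFFECT = 2.0e-4          # pH per mL CO2
_Q_O2 = 0.35                  # pmol O2/(cell*day) scale
# micro-spargers transfer oxygen far more efficiently than macro-spargers:
# the same oxygen demand needs less sparged volume, and the air cap covers
# more of it, so each sparger type leaves a distinct gas-flow signature
_SPARGER = {
    "micro": {"air_cap_mmol": 0.55, "ml_per_mmol": 400.0},
    "macro": {"air_cap_mmol": 0.35, "ml_per_mmol": 900.0},
}
_DO_DIP_SCALE = 4.0           # mmol/L/day OUR that depresses DO by 1%


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_batch(config: SimConfig, seed: int, batch_id: str | None = None,
                   passage: int = 5, msx: float = 50.0) -> BatchRecord:
    """Integrate one fed-batch run and return an assembled BatchRecord.

    Deterministic given ``(config, seed)``. Telemetry is generated on a
    15-minute grid and processed by :func:`fedsense.preprocess.assemble_batch`,
    so the returned record is exactly what the preprocessing pipeline would
    produce from the emitted raw files.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    last_day = config.effective_last_day()
    day_grid = np.arange(config.first_day, last_day + 1)
    t0, t_end = float(config.first_day), float(last_day + 1)
    n_steps = int(round((t_end - t0) / DT))
    times = t0 + DT * np.arange(n_steps + 1)

    # state (units: Xv 1e6 cells/mL; concentrations mM; titer mg/L; V L)
    xv = config.seed_density / 1e6
    glc = config.initial_glucose
    lac = 0.6
    amm = 0.3
    titer = 0.0
    cgc = 0.0
    vol = config.v0
    ph = 7.05
    base_ml = 0.0
    o2_ml = 0.0
    co2_ml = 0.0
    ivcc_fine = 0.0  # 1e6 cells*day/mL, exact running integral of Xv

    feed_at = {float(d): f for d, f in zip(config.feed_days, config.feed_fractions)
               if d <= last_day}
    sampling = list(config.sampling_days_effective())
    next_sampling_after = {}
    for j, d in enumerate(sampling[:-1]):
        next_sampling_after[d] = sampling[j + 1]

    # recorders
    rec = {k: np.empty(n_steps + 1) for k in
           ("xv", "glc", "lac", "amm", "titer", "cgc", "ph", "do",
            "base", "o2f", "co2f", "temp", "ivcc")}
    resid_truth: dict[int, float] = {}
    post_truth: dict[int, float] = {}

    def growth_rate(t: float, xv: float, glc: float, amm: float) -> float:
        d_ps = t - config.first_day  # days post-seeding
        if d_ps < config.temp_shift_day:
            tf = 1.0
        else:
            tf = 0.38 if config.secondary_growth else 0.12
        monod = glc / (config.K_glc + glc) if glc > 0 else 0.0
        cap = max(0.0, 1.0 - xv / config.x_max)
        inh = 1.0 / (1.0 + (amm / 12.0) ** 2)
        return config.mu_max * tf * monod * cap * inh

    for k in range(n_steps + 1):
        t = times[k]
        d_ps = t - config.first_day
        day = int(np.floor(t + 1e-9))
        on_day_start = abs(t - round(t)) < DT / 2 and round(t) <= last_day

        # --- sampling at day start (residual glucose before any feed)
        if on_day_start and int(round(t)) in sampling:
            resid_truth[int(round(t))] = glc

        # --- bolus feed just after sampling
        fd = round(t - 0.02, 6)
        if abs(t - 0.02 - round(t - 0.02)) < DT / 2 and fd in feed_at:
            frac = feed_at[fd] / 100.0
            v_new = vol + frac * config.v0
            dil = vol / v_new
            xv *= dil
            lac *= dil
            amm *= dil
            titer *= dil
            glc = glc * dil + (1 - dil) * config.feed_glucose
            vol = v_new
            # glucose top-up: extrapolate consumption to the next sampling day
            mu = growth_rate(t, xv, glc, amm)
            q_glc = config.q_glc_growth * (mu / config.mu_max) + config.q_glc_prod
            nxt = next_sampling_after.get(int(fd), last_day)
            horizon = max(1.0, nxt - fd)
            needed = config.glucose_floor + 1.15 * q_glc * xv * horizon
            if glc < needed:
                glc = needed  # concentrated stock, volume change negligible
            post_truth[int(fd)] = glc
        if on_day_start and int(round(t)) in sampling and int(round(t)) not in feed_at:
            post_truth[int(round(t))] = glc

        # --- kinetics
        mu = growth_rate(t, xv, glc, amm)
        kd = 0.015 + 0.10 * _sigmoid((t - 12.5) / 0.8)
        rel_mu = mu / config.mu_max
        q_glc = config.q_glc_growth * rel_mu + config.q_glc_prod
        w_prod = _sigmoid((config.lactate_switch_day - t) / 0.4)
        q_lac = config.q_lac_prod * max(rel_mu, 0.25) * w_prod
        q_lac -= config.q_lac_cons * (1 - w_prod) * lac / (lac + 5.0)
        if config.late_lactate_reproduction and t >= 10.0:
            q_lac += config.q_lac_late
        in_plateau = config.amm_plateau[0] <= t < config.amm_plateau[1]
        if t < config.amm_plateau[0]:
            q_amm = config.q_amm_growth * rel_mu
        elif in_plateau:
            q_amm = 0.004
        else:
            q_amm = config.q_amm
        q_tit = config.q_titer if t >= 0 else 0.0

        dxv = (mu - kd) * xv
        dglc = -q_glc * xv
        dlac = q_lac * xv
        damm = q_amm * xv
        dtit = q_tit * xv

        # --- pH loop: lactate flux acidifies, stripping drifts pH up,
        #     base is added only below the band, CO2 sparged only above it
        lo, hi = (config.ph_deadband_pre if d_ps < config.ph_shift_day
                  else config.ph_deadband_post)
        base_rate = _BASE_GAIN * max(0.0, lo - ph)
        co2_rate = _CO2_GAIN * max(0.0, ph - hi)
        dph = (-_ACID_PER_LACTATE * dlac + _PH_DRIFT
               + _BASE_EFFECT * base_rate - _CO2_EFFECT * co2_rate)

        # --- oxygen demand and DO cascade
        prod_active = 1.0 if t >= 0 else 0.0
        our = _Q_O2 * (0.4 + 0.6 * rel_mu + 0.3 * prod_active) * xv  # mmol/L/day
        sp = _SPARGER[config.sparger]
        o2_rate = sp["ml_per_mmol"] * max(0.0, our * vol - sp["air_cap_mmol"])
        do = config.do_setpoint - our / _DO_DIP_SCALE

        temp = 37.0 if d_ps < config.temp_shift_day else 32.0

        for name, val in (("xv", xv), ("glc", glc), ("lac", lac), ("amm", amm),
                          ("titer", titer), ("ph", ph)):
            if not np.isfinite(val):
                raise SimulationError(
                    f"non-finite state '{name}' at day {t:.2f}"
                )

        rec["xv"][k] = xv
        rec["glc"][k] = glc
        rec["lac"][k] = lac
        rec["amm"][k] = amm
        rec["titer"][k] = titer
        rec["cgc"][k] = cgc
        rec["ph"][k] = ph
        rec["do"][k] = do
        rec["base"][k] = base_ml
        rec["o2f"][k] = o2_rate
        rec["co2f"][k] = co2_rate
        rec["temp"][k] = temp
        rec["ivcc"][k] = ivcc_fine

        if k == n_steps:
            break

        # --- Euler update
        xv = max(xv + DT * dxv, 1e-4)
        glc = glc + DT * dglc
        if glc < -1e-6:
            raise SimulationError(
                f"glucose driven negative at day {t:.2f} (feed logic)"
            )
        glc = max(glc, 0.0)
        lac = max(lac + DT * dlac, 0.0)
        amm = max(amm + DT * damm, 0.0)
        titer = titer + DT * dtit
        cgc = cgc + DT * q_glc * rec["xv"][k]
        ph = ph + DT * dph
        base_ml += DT * base_rate
        o2_ml += DT * o2_rate
        co2_ml += DT * co2_rate
        ivcc_fine += DT * rec["xv"][k]

    # --- daily truth at day starts
    day_idx = np.array([int(round((d - t0) / DT)) for d in day_grid])
    truth = {
        "days": day_grid.copy(),
        "vcd": rec["xv"][day_idx] * 1e6,
        "lactate": rec["lac"][day_idx],
        "ammonia": rec["amm"][day_idx],
        "cgc": rec["cgc"][day_idx],
        "titer": rec["titer"][day_idx],
    }
    # offset cGC so it is zero at the first sampling day
    c0 = rec["cgc"][int(round((sampling[0] - t0) / DT))]
    truth["cgc"] = truth["cgc"] - c0
    divcc = np.diff(rec["ivcc"][day_idx]) * 1e6  # cells*day/mL per day
    truth["q_gluc"] = np.diff(truth["cgc"]) / divcc  # mM*mL/(cell*day)

    # --- telemetry on a 15-minute grid, with small additive sensor noise
    tele_t = np.arange(t0, t_end - 1e-9, TELEMETRY_DT)
    nz = config.online_noise

    def emit(key: str, sd: float) -> np.ndarray:
        vals = np.interp(tele_t, times, rec[key])
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=len(vals))
        return vals

    channels = {
        "ph": OnlineChannelSeries("ph", tele_t, emit("ph", nz.get("ph", 0.0))),
        "do_pct": OnlineChannelSeries("do_pct", tele_t, emit("do", nz.get("do", 0.0))),
        "temp_c": OnlineChannelSeries("temp_c", tele_t, emit("temp", nz.get("temp", 0.0))),
        "base_ml": OnlineChannelSeries("base_ml", tele_t, emit("base", 0.0)),
        "o2_flow": OnlineChannelSeries("o2_flow", tele_t, emit("o2f", 0.0)),
        "co2_flow": OnlineChannelSeries("co2_flow", tele_t, emit("co2f", 0.0)),
    }

    # --- offline observations with truncated multiplicative noise
    def noisy(value: float, rsd: float) -> float:
        if rsd == 0.0:
            return value
        eps = float(np.clip(rng.normal(), -3.0, 3.0))
        return value * (1.0 + rsd * eps)

    rsd = config.noise_rsd
    samp = np.array(sampling)
    g2i = {int(d): int(np.flatnonzero(day_grid == d)[0]) for d in samp}
    obs = {v: np.empty(len(samp)) for v in ("vcd", "lactate", "ammonia", "titer")}
    for j, d in enumerate(samp):
        i = g2i[int(d)]
        obs["vcd"][j] = max(noisy(truth["vcd"][i], rsd.get("vcd", 0.0)), 1.0)
        obs["lactate"][j] = max(noisy(truth["lactate"][i], rsd.get("lactate", 0.0)), 0.0)
        obs["ammonia"][j] = max(noisy(truth["ammonia"][i], rsd.get("ammonia", 0.0)), 0.0)
        obs["titer"][j] = (0.0 if d < 0
                           else max(noisy(truth["titer"][i], rsd.get("titer", 0.0)), 0.0))
    # observed cGC: noisy truth, clipped non-decreasing, zero at first sample
    cgc_truth_samp = np.array([truth["cgc"][g2i[int(d)]] for d in samp])
    cgc_obs = np.array([
        0.0 if j == 0 else noisy(cgc_truth_samp[j], rsd.get("cgc", 0.0))
        for j in range(len(samp))
    ])
    cgc_obs = np.maximum.accumulate(cgc_obs)
    # back out residual/post-feed glucose consistent with the observed cGC
    post = np.array([post_truth[int(d)] for d in samp])
    resid = np.empty(len(samp))
    resid[0] = resid_truth[int(samp[0])]
    resid[1:] = post[:-1] - np.diff(cgc_obs)

    offline_log = pd.DataFrame({
        "day_dpi": samp,
        "vcd": obs["vcd"],
        "lactate_mM": obs["lactate"],
        "ammonia_mM": obs["ammonia"],
        "glucose_residual_mM": resid,
        "glucose_postfeed_mM": post,
        "titer_mgL": obs["titer"],
    })

    if batch_id is None:
        batch_id = f"{config.pool_id}_{seed}"
    return assemble_batch(
        channels, offline_log, day_grid,
        batch_id=batch_id, pool_id=config.pool_id,
        passage=passage, msx=msx, truth=truth,
    )


def _draw_pool_config(pool: str, rng: np.random.Generator) -> SimConfig:
    """Draw one batch's kinetic parameters from pool-specific distributions."""
    cfg = SimConfig(**POOL_PRESETS[pool])

    def jit(x: float, sd: float = 0.08) -> float:
        return x * float(1.0 + sd * np.clip(rng.normal(), -2.5, 2.5))

    cfg.mu_max = jit(cfg.mu_max)
    cfg.x_max = jit(cfg.x_max, 0.10)
    cfg.q_glc_growth = jit(cfg.q_glc_growth)
    cfg.q_glc_prod = jit(cfg.q_glc_prod)
    cfg.q_lac_prod = jit(cfg.q_lac_prod, 0.15)
    cfg.q_lac_cons = jit(cfg.q_lac_cons, 0.10)
    cfg.q_amm = jit(cfg.q_amm, 0.10)
    cfg.q_titer = jit(cfg.q_titer, 0.12)
    if pool == "Delta":
        cfg.secondary_growth = bool(rng.random() < 0.5)
    if pool == "WuTL":
        cfg.late_lactate_reproduction = bool(rng.random() < 0.5)
    return cfg


def generate_dataset(
    n_per_pool: dict[str, int] | None = None,
    base_seed: int = 0,
    test_fraction: float = 0.2,
    truncate_one: bool = True,
) -> tuple[list[BatchRecord], dict[str, list[str]]]:
    """Simulate a campaign and assign a grouped train/test split.

    Defaults emulate a 21-run campaign (10 Delta, 6 Beta, 5 WuTL) with an
    approximate 80/20 split within each pool (8/2, 5/1, 4/1). One WuTL
    test batch is harvested early (12 dpi) when ``truncate_one`` is set,
    exercising variable-length sequences.

    Returns ``(batches, split)`` with ``split = {"train": [...ids],
    "test": [...ids]}``. Deterministic given ``base_seed``.
    """
    from .training import grouped_split_ids

    if n_per_pool is None:
        n_per_pool = {"Delta": 10, "Beta": 6, "WuTL": 5}
    for pool, n in n_per_pool.items():
        if n < 1:
            raise ValueError(f"pool {pool}: count must be >= 1")

    master = np.random.SeedSequence(base_seed)
    pool_order = sorted(n_per_pool)
    ids_by_pool = {
        pool: [f"{pool}_{j:02d}" for j in range(n_per_pool[pool])]
        for pool in pool_order
    }
    split = grouped_split_ids(ids_by_pool, test_fraction,
                              seed=int(master.generate_state(1)[0] % 2**31))

    truncate_id = None
    if truncate_one:
        wutl_test = [b for b in split["test"] if b.startswith("WuTL")]
        if wutl_test:
            truncate_id = wutl_test[0]

    batches: list[BatchRecord] = []
    child_seeds = master.spawn(sum(n_per_pool.values()))
    k = 0
    for pool in pool_order:
        for bid in ids_by_pool[pool]:
            ss = child_seeds[k]
            k += 1
            rng = np.random.default_rng(ss)
            cfg = _draw_pool_config(pool, rng)
            if bid == truncate_id:
                cfg.truncate_day = 12
            passage = int(rng.choice([5, 8, 11]))
            msx = float(rng.choice([50.0, 125.0]))
            sim_seed = int(ss.generate_state(1)[0] % 2**31)
            batches.append(
                simulate_batch(cfg, sim_seed, batch_id=bid,
                               passage=passage, msx=msx)
            )
    return batches, split
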