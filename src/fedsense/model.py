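"""Recurrent soft-sensor core.

A shared hidden-state network combined with five per-variable decoder
heads. At each process day t the network consumes the previous hidden
state h_{t-1}, the day's 7 online features O_t and the day's 5 offline
values X_t (measured where available, otherwise the model's own previous
predictions), and emits the new hidden state plus next-day predictions of
all five sampled variables:

    h_t        = W_hidden @ relu(W_in @ [h_{t-1}; O_t; X_t] + b) + b'
    x_hat[i]   = W_out_i @ relu(W_hin_i @ h_t + b_i) + b_i'

Every MLP is a single affine -> ReLU -> affine block of width H (default
256); no activation is applied after W_hidden. The initial hidden state is
the zero vector (no information carried in from before seeding). Biases
are included by default and can be disabled for a strict reading of the
update equations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .batch import BatchRecord, OFFLINE_VARS, ONLINE_FEATURES

if TYPE_CHECKING:  # pragma: no cover
    from .training import Scaler

N_ONLINE = len(ONLINE_FEATURES)
N_OFFLINE = len(OFFLINE_VARS)

ROLLOUT_MODES = ("full_feedback", "cellcount_only")

CHECKPOINT_FORMAT = "fedsense-checkpoint-1"


@dataclass
class ModelParams:
    """All weights of the shared hidden MLP and the five decoder heads.

    Decoder weights are stacked along a leading variable axis in
    :data:`fedsense.batch.OFFLINE_VARS` order.
    """

    H: int
    W_in: np.ndarray        # (H, H + 7 + 5)
    b_in: np.ndarray        # (H,)
    W_hidden: np.ndarray    # (H, H)
    b_hidden: np.ndarray    # (H,)
    W_dec_in: np.ndarray    # (5, H, H)
    b_dec_in: np.ndarray    # (5, H)
    W_dec_out: np.ndarray   # (5, H)
    b_dec_out: np.ndarray   # (5,)
    use_bias: bool = True

    def validate(self) -> None:
        H = self.H
        if H < 1:
            raise ValueError("hidden width H must be >= 1")
        expect = {
            "W_in": (H, H + N_ONLINE + N_OFFLINE),
            "b_in": (H,),
            "W_hidden": (H, H),
            "b_hidden": (H,),
            "W_dec_in": (N_OFFLINE, H, H),
            "b_dec_in": (N_OFFLINE, H),
            "W_dec_out": (N_OFFLINE, H),
            "b_dec_out": (N_OFFLINE,),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in (
            "W_in", "b_in", "W_hidden", "b_hidden",
            "W_dec_in", "b_dec_in", "W_dec_out", "b_dec_out")}


def init_hidden(H: int) -> np.ndarray:
    """Zero initial hidden state: no information carried over from the past."""
    if H < 1:
        raise ValueError("hidden width H must be >= 1")
    return np.zeros(H)


def init_params(H: int = 256, seed: int = 0, use_bias: bool = True) -> ModelParams:
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    rng = np.random.default_rng(seed)

    def lin(out_dim: int, in_dim: int, shape=None) -> np.ndarray:
        bound = 1.0 / np.sqrt(in_dim)
        return rng.uniform(-bound, bound, size=shape or (out_dim, in_dim))

    n_in = H + N_ONLINE + N_OFFLINE
    params = ModelParams(
        H=H,
        W_in=lin(H, n_in),
        b_in=lin(H, n_in, (H,)) if use_bias else np.zeros(H),
        W_hidden=lin(H, H),
        b_hidden=lin(H, H, (H,)) if use_bias else np.zeros(H),
        W_dec_in=lin(H, H, (N_OFFLINE, H, H)),
        b_dec_in=lin(H, H, (N_OFFLINE, H)) if use_bias else np.zeros((N_OFFLINE, H)),
        W_dec_out=lin(1, H, (N_OFFLINE, H)),
        b_dec_out=lin(1, H, (N_OFFLINE,)) if use_bias else np.zeros(N_OFFLINE),
        use_bias=use_bias,
    )
    params.validate()
    return params


def rnn_step(
    params: ModelParams, h_prev: np.ndarray, o_t: np.ndarray, x_t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One recurrence step in standardized space.

    Returns ``(h_t, x_hat_next)`` where ``x_hat_next`` holds next-day
    predictions of the five sampled variables (standardized).
    """
    if h_prev.shape != (params.H,):
        raise ValueError(f"hidden state has shape {h_prev.shape}, expected ({params.H},)")
    if o_t.shape != (N_ONLINE,) or x_t.shape != (N_OFFLINE,):
        raise ValueError("online/offline input vector shape mismatch")
    inp = np.concatenate([h_prev, o_t, x_t])
    a = np.maximum(params.W_in @ inp + params.b_in, 0.0)
    h_t = params.W_hidden @ a + params.b_hidden
    u = np.maximum(
        np.einsum("vij,j->vi", params.W_dec_in, h_t) + params.b_dec_in, 0.0
    )
    x_hat = np.einsum("vi,vi->v", params.W_dec_out, u) + params.b_dec_out
    return h_t, x_hat


@dataclass
class PredictionTrajectory:
    """Daily predictions of the five offline variables, physical units.

    ``x_hat[0]`` carries the initial (day-one) measured values; rows 1..T-1
    are genuine next-day predictions. ``input_source[t, i]`` records what
    the model consumed as variable i's input at step t: ``"initial"``,
    ``"measured"`` or ``"predicted"``.
    """

    batch_id: str
    mode: str
    days: np.ndarray                 # (T,)
    x_hat: np.ndarray                # (T, 5) physical units
    input_source: np.ndarray         # (T, 5) of str
    variables: tuple = OFFLINE_VARS

    def to_frame(self):
        import pandas as pd

        cols = {"day_dpi": self.days}
        for i, v in enumerate(self.variables):
            cols[f"pred_{v}"] = self.x_hat[:, i]
        for i, v in enumerate(self.variables):
            cols[f"source_{v}"] = self.input_source[:, i]
        return pd.DataFrame(cols)


def rollout(
    params: ModelParams,
    scaler: "Scaler",
    batch: BatchRecord,
    mode: str = "full_feedback",
) -> PredictionTrajectory:
    """Iterate the recurrence over a batch's day grid.

    ``full_feedback``: on sampling days, measured offline values replace
    the model's predictions as the next step's input (teacher forcing);
    elsewhere the model consumes its own previous predictions.

    ``cellcount_only``: only VCD is ever replaced by its measurement; the
    other four variables run on the model's predictions after day one (the
    soft-sensing mode: metabolite/titer assays never fed back).
    """
    if mode not in ROLLOUT_MODES:
        raise ValueError(f"unknown rollout mode {mode!r}; use one of {ROLLOUT_MODES}")
    if not np.all(batch.offline_mask[0]):
        raise ValueError(
            f"batch {batch.batch_id}: first-day offline values required as "
            "initial guesses"
        )
    T = batch.n_days
    i_vcd = OFFLINE_VARS.index("vcd")

    o_std = scaler.transform_online(batch.online)        # (T, 7)
    x_meas_std = scaler.transform_offline(batch.offline)  # (T, 5), NaN off-mask

    x_hat_std = np.empty((T, N_OFFLINE))
    source = np.empty((T, N_OFFLINE), dtype=object)
    x_hat_std[0] = x_meas_std[0]
    source[0] = "initial"

    h = init_hidden(params.H)
    x_in = x_meas_std[0].copy()
    for t in range(T - 1):
        h, pred = rnn_step(params, h, o_std[t], x_in)
        x_hat_std[t + 1] = pred
        x_in = pred.copy()
        src = np.full(N_OFFLINE, "predicted", dtype=object)
        if mode == "full_feedback":
            feed = batch.offline_mask[t + 1]
        else:
            feed = np.zeros(N_OFFLINE, dtype=bool)
            feed[i_vcd] = batch.offline_mask[t + 1, i_vcd]
        x_in[feed] = x_meas_std[t + 1][feed]
        src[feed] = "measured"
        source[t + 1] = src

    x_hat = scaler.inverse_offline(x_hat_std)
    return PredictionTrajectory(
        batch_id=batch.batch_id, mode=mode, days=batch.day_grid.copy(),
        x_hat=x_hat, input_source=source,
    )


def save_checkpoint(path, params: ModelParams, scaler: "Scaler",
                    meta: dict | None = None) -> None:
    """Persist weights + scaler statistics as a single npz archive."""
    payload = {f"param_{k}": v for k, v in params.arrays().items()}
    payload.update(
        scaler_online_mean=scaler.online_mean,
        scaler_online_sd=scaler.online_sd,
        scaler_offline_mean=scaler.offline_mean,
        scaler_offline_sd=scaler.offline_sd,
    )
    header = {
        "format": CHECKPOINT_FORMAT,
        "H": params.H,
        "use_bias": params.use_bias,
        "meta": meta or {},
    }
    payload["header_json"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[ModelParams, "Scaler"]:
    from .training import Scaler

    with np.load(path, allow_pickle=False) as z:
        header = json.loads(bytes(z["header_json"].tobytes()).decode())
        if header.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format: {header.get('format')}")
        params = ModelParams(
            H=int(header["H"]),
            use_bias=bool(header["use_bias"]),
            **{k: z[f"param_{k}"] for k in (
                "W_in", "b_in", "W_hidden", "b_hidden",
                "W_dec_in", "b_dec_in", "W_dec_out", "b_dec_out")},
        )
        params.validate()
        scaler = Scaler(
            online_mean=z["scaler_online_mean"],
            online_sd=z["scaler_online_sd"],
            offline_mean=z["scaler_offline_mean"],
            offline_sd=z["scaler_offline_sd"],
        )
    return params, scaler
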