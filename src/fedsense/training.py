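"""Standardization, grouped splitting and the optimization protocol.

Training minimizes the mean squared error between standardized one-day-
ahead predictions and standardized measured offline values, summed over
the five sampled variables and accumulated (by default) only at sampling
days. Teacher forcing is mask-driven and identical to the
``full_feedback`` rollout: measured values are fed where available, the
model's own previous predictions elsewhere — and the gradient flows
through that prediction-feedback path (full backpropagation through time).

The optimizer is plain SGD with momentum and coupled L2 weight decay; one
epoch is one full pass over all training sequences, updating after each
sequence (batch size = one sequence) in an order reshuffled every epoch
with the seeded generator.

Standardization uses the population SD convention (divide by n) so that a
mean predictor attains nRMSE exactly 1 in the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .batch import BatchRecord, OFFLINE_VARS, ONLINE_FEATURES
from .model import (
    ModelParams,
    N_OFFLINE,
    N_ONLINE,
    init_params,
)


@dataclass
class Scaler:
    """Per-feature mean/SD of the 7 online and 5 offline features."""

    online_mean: np.ndarray
    online_sd: np.ndarray
    offline_mean: np.ndarray
    offline_sd: np.ndarray

    def transform_online(self, x: np.ndarray) -> np.ndarray:
        return (x - self.online_mean) / self.online_sd

    def transform_offline(self, x: np.ndarray) -> np.ndarray:
        return (x - self.offline_mean) / self.offline_sd

    def inverse_offline(self, z: np.ndarray) -> np.ndarray:
        return z * self.offline_sd + self.offline_mean


def fit_scaler(train_batches: list[BatchRecord]) -> Scaler:
    """Pooled mean/population-SD statistics over the training batches.

    Online features use every day of every batch; offline features use
    masked-in (measured) values only. A constant feature is an error,
    named explicitly, since it cannot be standardized.
    """
    if not train_batches:
        raise ValueError("need at least one training batch")
    online = np.vstack([b.online for b in train_batches])
    on_mean = online.mean(axis=0)
    on_sd = online.std(axis=0)  # population convention
    off_mean = np.empty(N_OFFLINE)
    off_sd = np.empty(N_OFFLINE)
    for i in range(N_OFFLINE):
        vals = np.concatenate([
            b.offline[b.offline_mask[:, i], i] for b in train_batches
        ])
        if vals.size == 0:
            raise ValueError(f"no measurements for feature '{OFFLINE_VARS[i]}'")
        off_mean[i] = vals.mean()
        off_sd[i] = vals.std()
    for name, sd in list(zip(ONLINE_FEATURES, on_sd)) + list(
        zip(OFFLINE_VARS, off_sd)
    ):
        if sd <= 0:
            raise ValueError(f"feature '{name}' is constant; cannot standardize")
    return Scaler(on_mean, on_sd, off_mean, off_sd)


def grouped_split_ids(
    ids_by_pool: dict[str, list[str]], test_fraction: float, seed: int
) -> dict[str, list[str]]:
    """Within-pool whole-batch split of identifiers, deterministic by seed."""
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for pool in sorted(ids_by_pool):
        ids = list(ids_by_pool[pool])
        n = len(ids)
        n_test = int(round(test_fraction * n)) if test_fraction > 0 else 0
        if test_fraction > 0:
            n_test = max(1, n_test)
        if n_test >= n:
            raise ValueError(
                f"pool {pool}: cannot hold out {n_test} of {n} batches"
            )
        if test_fraction > 0 and n < 2:
            raise ValueError(f"pool {pool}: need >= 2 batches to split")
        order = rng.permutation(n)
        test += [ids[k] for k in order[:n_test]]
        train += [ids[k] for k in order[n_test:]]
    return {"train": sorted(train), "test": sorted(test)}


def grouped_split(
    batches: list[BatchRecord],
    fractions: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
) -> tuple[list[BatchRecord], list[BatchRecord]]:
    """Split whole batches into train/test within each pool.

    Never splits a batch's time series; approximates the requested
    fractions per pool with at least one test batch per pool (so a
    10/6/5-batch campaign at 80/20 yields 8/2, 5/1, 4/1).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids_by_pool: dict[str, list[str]] = {}
    for b in batches:
        ids_by_pool.setdefault(b.pool_id, []).append(b.batch_id)
    split = grouped_split_ids(ids_by_pool, fractions[1], seed)
    by_id = {b.batch_id: b for b in batches}
    return ([by_id[i] for i in split["train"]], [by_id[i] for i in split["test"]])


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol (defaults as published)."""

    learning_rate: float = 1.6e-4
    momentum: float = 0.97
    weight_decay: float = 0.125
    epochs: int = 5000
    hidden: int = 256
    rng_seed: int = 0
    loss_days: str = "sampling_only"   # or "all_days" (simulated truth)
    loss_scale: float = 5.0            # constant factor on the summed loss
    use_bias: bool = True
    decoupled_weight_decay: bool = False
    dtype: str = "float32"             # numeric precision of the training loop

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss_days not in ("sampling_only", "all_days"):
            raise ValueError(f"unknown loss_days {self.loss_days!r}")


def _prepare_sequence(
    batch: BatchRecord, scaler: Scaler, loss_days: str
) -> dict:
    """Standardized arrays for one training sequence."""
    o = scaler.transform_online(batch.online)
    x = scaler.transform_offline(np.where(batch.offline_mask, batch.offline, 0.0))
    feed_mask = batch.offline_mask.copy()
    if loss_days == "sampling_only":
        target = x
        sup_mask = feed_mask.copy()
    else:
        if batch.truth is None:
            raise ValueError(
                f"batch {batch.batch_id}: all_days loss requires simulated truth"
            )
        truth = np.column_stack([batch.truth[v] for v in OFFLINE_VARS])
        target = scaler.transform_offline(truth)
        sup_mask = np.ones_like(feed_mask)
    if not feed_mask[0].all():
        raise ValueError(
            f"batch {batch.batch_id}: first-day offline values required"
        )
    n_sup = sup_mask[1:].sum(axis=0)  # supervised days per variable
    if n_sup.sum() == 0:
        raise ValueError(f"batch {batch.batch_id}: no supervised points")
    # loss is the per-variable MSE over supervised days, summed over the
    # five variables; variables never measured in a batch contribute 0
    inv_n = np.where(n_sup > 0, 1.0 / np.maximum(n_sup, 1), 0.0)
    return dict(o=o, x=x, target=target, feed=feed_mask, sup=sup_mask,
                inv_n=inv_n)


def _forward_backward(params: ModelParams, seq: dict) -> tuple[float, dict]:
    """Loss and full-BPTT gradients for one sequence.

    The forward pass mirrors the ``full_feedback`` rollout in standardized
    space; the backward pass propagates through both the hidden-state
    recursion and the prediction-feedback path on non-sampling days.
    """
    H = params.H
    o, x, target = seq["o"], seq["x"], seq["target"]
    feed, sup, inv_n = seq["feed"], seq["sup"], seq["inv_n"]
    T = o.shape[0]
    n_in = H + N_ONLINE + N_OFFLINE

    W_dec_flat = params.W_dec_in.reshape(N_OFFLINE * H, H)
    b_dec_flat = params.b_dec_in.reshape(N_OFFLINE * H)

    dt = params.W_in.dtype
    inp = np.empty((T - 1, n_in), dtype=dt)
    act = np.empty((T - 1, H), dtype=dt)
    hid = np.empty((T - 1, H), dtype=dt)
    dec = np.empty((T - 1, N_OFFLINE * H), dtype=dt)
    yhat = np.empty((T - 1, N_OFFLINE), dtype=dt)

    inp[0, :H] = 0.0
    inp[0, H:H + N_ONLINE] = o[0]
    inp[0, H + N_ONLINE:] = x[0]
    for t in range(T - 1):
        v = inp[t]
        a = act[t]
        np.dot(params.W_in, v, out=a)
        a += params.b_in
        np.maximum(a, 0.0, out=a)
        h = hid[t]
        np.dot(params.W_hidden, a, out=h)
        h += params.b_hidden
        u = dec[t]
        np.dot(W_dec_flat, h, out=u)
        u += b_dec_flat
        np.maximum(u, 0.0, out=u)
        y = (params.W_dec_out * u.reshape(N_OFFLINE, H)).sum(axis=1)
        y += params.b_dec_out
        yhat[t] = y
        if t + 1 < T - 1:
            nxt = inp[t + 1]
            nxt[:H] = h
            nxt[H:H + N_ONLINE] = o[t + 1]
            nxt[H + N_ONLINE:] = np.where(feed[t + 1], x[t + 1], y)

    err = yhat - target[1:]
    m = sup[1:]
    loss = float(np.sum(np.where(m, err, 0.0) ** 2 @ inv_n))

    # backward
    da_all = np.empty((T - 1, H), dtype=dt)
    gh_all = np.empty((T - 1, H), dtype=dt)
    du_all = np.empty((T - 1, N_OFFLINE * H), dtype=dt)
    gy_all = np.empty((T - 1, N_OFFLINE), dtype=dt)
    g_h_carry = np.zeros(H, dtype=dt)
    g_x = np.zeros(N_OFFLINE, dtype=dt)
    W_hidden_T = params.W_hidden.T
    W_in_T = params.W_in.T
    W_dec_flat_T = W_dec_flat.T
    for t in range(T - 2, -1, -1):
        g_y = np.where(m[t], 2.0 * err[t] * inv_n, 0.0) + g_x
        du = du_all[t]
        np.multiply(params.W_dec_out, g_y[:, None],
                    out=du.reshape(N_OFFLINE, H))
        du *= dec[t] > 0
        g_h = gh_all[t]
        np.dot(W_dec_flat_T, du, out=g_h)
        g_h += g_h_carry  # total gradient w.r.t. h_t
        da = da_all[t]
        np.dot(W_hidden_T, g_h, out=da)
        da *= act[t] > 0
        g_inp = W_in_T @ da
        gy_all[t] = g_y
        g_h_carry = g_inp[:H]
        if t >= 1:
            g_x = np.where(feed[t], 0.0, g_inp[H + N_ONLINE:])

    grads = {
        "W_in": da_all.T @ inp,
        "b_in": da_all.sum(axis=0),
        "W_hidden": gh_all.T @ act,
        "b_hidden": gh_all.sum(axis=0),
        "W_dec_in": (du_all.T @ hid).reshape(N_OFFLINE, H, H),
        "b_dec_in": du_all.sum(axis=0).reshape(N_OFFLINE, H),
        "W_dec_out": (gy_all[:, :, None] * dec.reshape(T - 1, N_OFFLINE, H)).sum(axis=0),
        "b_dec_out": gy_all.sum(axis=0),
    }
    if not params.use_bias:
        for k in ("b_in", "b_hidden", "b_dec_in", "b_dec_out"):
            grads[k] = np.zeros_like(grads[k])
    return loss, grads


def train_model(
    train_batches: list[BatchRecord],
    config: TrainConfig | None = None,
    scaler: Scaler | None = None,
) -> tuple[ModelParams, np.ndarray]:
    """Train the recurrent soft sensor with SGD + momentum + weight decay.

    Returns ``(params, loss_history)`` where ``loss_history[e]`` is the
    mean per-sequence loss seen during epoch ``e``. Deterministic given
    ``config.rng_seed``. If no scaler is supplied one is fitted on
    ``train_batches`` (the scaler must always come from the training set).
    """
    if config is None:
        config = TrainConfig()
    if not train_batches:
        raise ValueError("no training batches")
    if scaler is None:
        scaler = fit_scaler(train_batches)

    dtype = np.dtype(config.dtype)
    seqs = []
    for b in train_batches:
        seq = _prepare_sequence(b, scaler, config.loss_days)
        # the coupled weight decay makes the loss scale meaningful: it sets
        # the equilibrium between data gradient and decay pull
        seq["inv_n"] = seq["inv_n"] * config.loss_scale
        for key in ("o", "x", "target", "inv_n"):
            seq[key] = seq[key].astype(dtype)
        seqs.append(seq)
    params = init_params(config.hidden, seed=config.rng_seed,
                         use_bias=config.use_bias)
    for k, arr in params.arrays().items():
        setattr(params, k, arr.astype(dtype))
    names = list(params.arrays())
    velocity = {k: np.zeros_like(getattr(params, k)) for k in names}
    scratch = {k: np.empty_like(getattr(params, k)) for k in names}
    rng = np.random.default_rng(config.rng_seed + 1)
    lr, mu, wd = config.learning_rate, config.momentum, config.weight_decay

    loss_history = np.empty(config.epochs)
    n_seq = len(seqs)
    for epoch in range(config.epochs):
        order = rng.permutation(n_seq)
        total = 0.0
        for s in order:
            loss, grads = _forward_backward(params, seqs[s])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            total += loss
            for k in names:
                p = getattr(params, k)
                g = grads[k]
                tmp = scratch[k]
                if wd:
                    if config.decoupled_weight_decay:
                        p *= 1.0 - lr * wd
                    else:
                        np.multiply(p, wd, out=tmp)
                        g += tmp
                v = velocity[k]
                v *= mu
                v += g
                np.multiply(v, lr, out=tmp)
                p -= tmp
        loss_history[epoch] = total / n_seq
    return params, loss_history
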