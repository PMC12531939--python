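import numpy as np
import pytest

import fedsense as fs
from fedsense.batch import OFFLINE_VARS
from fedsense.model import (
    N_OFFLINE,
    N_ONLINE,
    ModelParams,
    init_hidden,
    init_params,
    load_checkpoint,
    rnn_step,
    rollout,
    save_checkpoint,
)
from fedsense.training import Scaler, fit_scaler


def zero_params(H: int) -> ModelParams:
    p = init_params(H, seed=0)
    for k, arr in p.arrays().items():
        setattr(p, k, np.zeros_like(arr))
    return p


def identity_scaler() -> Scaler:
    return Scaler(
        online_mean=np.zeros(N_ONLINE), online_sd=np.ones(N_ONLINE),
        offline_mean=np.zeros(N_OFFLINE), offline_sd=np.ones(N_OFFLINE),
    )


def brute_force_unroll(params, o_seq, x_seq, feed_mask):
    """Independent loop-and-index evaluation of the two update equations."""
    H = params.H
    h = [0.0] * H
    preds = []
    x_in = list(x_seq[0])
    for t in range(len(o_seq) - 1):
        full = list(h) + list(o_seq[t]) + list(x_in)
        z = [sum(params.W_in[i][j] * full[j] for j in range(len(full)))
             + params.b_in[i] for i in range(H)]
        a = [max(v, 0.0) for v in z]
        h = [sum(params.W_hidden[i][j] * a[j] for j in range(H))
             + params.b_hidden[i] for i in range(H)]
        y = []
        for v in range(N_OFFLINE):
            u = [max(sum(params.W_dec_in[v][i][j] * h[j] for j in range(H))
                     + params.b_dec_in[v][i], 0.0) for i in range(H)]
            y.append(sum(params.W_dec_out[v][i] * u[i] for i in range(H))
                     + params.b_dec_out[v])
        preds.append(y)
        x_in = [x_seq[t + 1][v] if feed_mask[t + 1][v] else y[v]
                for v in range(N_OFFLINE)]
    return np.array(preds)


class TestInitHidden:
    def test_zero_vector(self):
        h = init_hidden(256)
        assert h.shape == (256,) and np.linalg.norm(h) == 0.0
        assert init_hidden(1).tolist() == [0.0]

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            init_hidden(0)


class TestRnnStep:
    def test_zero_weights_give_zero_outputs(self):
        p = zero_params(4)
        h, y = rnn_step(p, np.zeros(4), np.ones(N_ONLINE), np.ones(N_OFFLINE))
        assert not h.any() and not y.any()

    def test_hand_computed_two_unit_oracle(self):
        # H=2, tiny fixed weights; expected values worked out by hand from
        # h = W_hidden @ relu(W_in @ [h; o; x] + b_in) + b_hidden and the
        # per-variable decoder equations.
        p = zero_params(2)
        p.W_in[0, 2] = 1.0    # reads h... index 2 = first online feature
        p.W_in[1, 2] = -2.0
        p.b_in[:] = [0.5, 0.25]
        p.W_hidden[:] = [[1.0, 1.0], [0.0, 3.0]]
        p.b_hidden[:] = [0.0, -1.0]
        p.W_dec_in[0, 0, 0] = 2.0   # titer head reads h[0]
        p.W_dec_out[0, 0] = 1.5
        p.b_dec_out[0] = 0.1
        o = np.zeros(N_ONLINE)
        o[0] = 2.0
        h, y = rnn_step(p, np.zeros(2), o, np.zeros(N_OFFLINE))
        # z = [1*2+0.5, -2*2+0.25] = [2.5, -3.75] -> a = [2.5, 0]
        # h = [2.5+0, 0*2.5+3*0] + [0,-1] = [2.5, -1]
        np.testing.assert_allclose(h, [2.5, -1.0], atol=1e-12)
        # titer: u0 = relu(2*2.5) = 5 -> y = 1.5*5 + 0.1 = 7.6
        assert y[0] == pytest.approx(7.6, abs=1e-12)
        assert y[1:] == pytest.approx(0.0)

    def test_zero_input_with_zero_bias_maps_to_zero(self):
        p = init_params(8, seed=3, use_bias=False)
        h, y = rnn_step(p, np.zeros(8), np.zeros(N_ONLINE), np.zeros(N_OFFLINE))
        np.testing.assert_allclose(h, 0.0, atol=1e-15)
        np.testing.assert_allclose(y, 0.0, atol=1e-15)

    def test_shape_mismatch_rejected(self):
        p = init_params(4, seed=0)
        with pytest.raises(ValueError):
            rnn_step(p, np.zeros(5), np.zeros(N_ONLINE), np.zeros(N_OFFLINE))


class TestRollout:
    def test_matches_brute_force_unroll_small(self, delta_batch):
        # equivalence of the vectorized rollout with a scalar-arithmetic
        # unroll of the update equations, H <= 3 over a short grid
        rng = np.random.default_rng(0)
        for H in (1, 3):
            p = init_params(H, seed=int(rng.integers(100)))
            sc = identity_scaler()
            b = _clip_batch(delta_batch, 4)
            traj = rollout(p, sc, b, mode="full_feedback")
            x = np.where(b.offline_mask, b.offline, 0.0)
            oracle = brute_force_unroll(p, b.online, x, b.offline_mask)
            np.testing.assert_allclose(traj.x_hat[1:], oracle, atol=1e-10)

    def test_saturated_mask_never_consumes_own_output(self, delta_batch):
        b = _daily_mask_batch(delta_batch)
        p = init_params(4, seed=1)
        traj = rollout(p, identity_scaler(), b, mode="full_feedback")
        assert (traj.input_source[1:] == "measured").all()

    def test_paper_grid_has_nine_comparable_days(self, delta_batch):
        from fedsense.evaluation import comparable_points

        p = init_params(4, seed=1)
        traj = rollout(p, identity_scaler(), delta_batch)
        days, y_true, y_pred = comparable_points(traj, delta_batch, "vcd")
        assert len(days) == 9
        # titer comparisons start at 3 dpi
        days_t, _, _ = comparable_points(traj, delta_batch, "titer")
        assert days_t.min() >= 3 and len(days_t) == 6

    def test_cellcount_only_carries_initial_titer_with_identity_weights(
        self, delta_batch
    ):
        p = _identity_carry_params()
        sc = identity_scaler()
        traj = rollout(p, sc, delta_batch, mode="cellcount_only")
        i_t = OFFLINE_VARS.index("titer")
        init_titer = delta_batch.offline[0, i_t]
        np.testing.assert_allclose(traj.x_hat[:, i_t], init_titer, atol=1e-9)
        # VCD input is refreshed from measurements on sampling days
        i_v = OFFLINE_VARS.index("vcd")
        src = traj.input_source[:, i_v]
        meas_days = delta_batch.offline_mask[:, i_v]
        assert (src[1:][meas_days[1:]] == "measured").all()
        assert (traj.input_source[1:, i_t] == "predicted").all()

    def test_deterministic(self, delta_batch):
        p = init_params(8, seed=2)
        sc = identity_scaler()
        a = rollout(p, sc, delta_batch)
        b = rollout(p, sc, delta_batch)
        np.testing.assert_array_equal(a.x_hat, b.x_hat)

    def test_vcd_input_stream_identical_across_modes(self, delta_batch):
        p = init_params(6, seed=4)
        sc = identity_scaler()
        full = rollout(p, sc, delta_batch, mode="full_feedback")
        cc = rollout(p, sc, delta_batch, mode="cellcount_only")
        i_v = OFFLINE_VARS.index("vcd")
        np.testing.assert_array_equal(
            full.input_source[:, i_v], cc.input_source[:, i_v]
        )

    def test_unknown_mode_rejected(self, delta_batch):
        p = init_params(4, seed=0)
        with pytest.raises(ValueError, match="mode"):
            rollout(p, identity_scaler(), delta_batch, mode="oracle")


class TestCheckpoint:
    def test_round_trip(self, tmp_path, delta_batch):
        p = init_params(8, seed=5)
        sc = fit_scaler([delta_batch])
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, p, sc, meta={"note": "test"})
        p2, sc2 = load_checkpoint(path)
        for k, arr in p.arrays().items():
            np.testing.assert_array_equal(arr, getattr(p2, k))
        np.testing.assert_array_equal(sc.offline_sd, sc2.offline_sd)
        traj1 = rollout(p, sc, delta_batch)
        traj2 = rollout(p2, sc2, delta_batch)
        np.testing.assert_array_equal(traj1.x_hat, traj2.x_hat)


def _clip_batch(batch, n_days):
    import dataclasses

    return dataclasses.replace(
        batch,
        day_grid=batch.day_grid[:n_days],
        online=batch.online[:n_days],
        offline=batch.offline[:n_days],
        offline_mask=batch.offline_mask[:n_days],
        truth=None,
    )


def _daily_mask_batch(batch):
    import dataclasses

    offline = np.where(batch.offline_mask, batch.offline, 1.0)
    offline[batch.day_grid < 0, OFFLINE_VARS.index("titer")] = 0.0
    return dataclasses.replace(
        batch,
        offline=offline,
        offline_mask=np.ones_like(batch.offline_mask),
        sampling_days=batch.day_grid.copy(),
        truth=None,
    )


def _identity_carry_params():
    """Weights that make every head output its own input unchanged.

    Pairs of ReLU units encode x and -x so that h reconstructs the input
    exactly; each decoder reads back its variable the same way.
    """
    H = 2 * N_OFFLINE
    p = zero_params(H)
    off = H + N_ONLINE
    for v in range(N_OFFLINE):
        p.W_in[v, off + v] = 1.0
        p.W_in[N_OFFLINE + v, off + v] = -1.0
        p.W_hidden[v, v] = 1.0
        p.W_hidden[v, N_OFFLINE + v] = -1.0
        p.W_dec_in[v, 0, v] = 1.0
        p.W_dec_in[v, 1, v] = -1.0
        p.W_dec_out[v, 0] = 1.0
        p.W_dec_out[v, 1] = -1.0
    return p
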