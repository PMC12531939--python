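"""scikit-learn style estimator facade over the recurrent soft sensor."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .batch import BatchRecord
from .model import PredictionTrajectory, rollout
from .training import Scaler, TrainConfig, fit_scaler, train_model


class RecurrentSoftSensor(BaseEstimator):
    """One-day-ahead soft sensor for fed-batch offline variables.

    A shared-hidden-state recurrent network with five per-variable decoder
    heads, trained by SGD with momentum and L2 weight decay on
    standardized data with mask-driven teacher forcing. Composes with
    sklearn tooling through ``get_params``/``set_params``; ``fit`` takes a
    list of :class:`~fedsense.batch.BatchRecord` (each one whole batch —
    grouping is by batch, never within a time series).

    Parameters mirror the published training protocol: ``hidden=256``
    units per MLP, ReLU activations, learning rate 1.6e-4, momentum 0.97,
    weight decay 0.125 and 5000 epochs.

    Attributes
    ----------
    params_ : ModelParams
        Trained weights.
    scaler_ : Scaler
        Feature standardization statistics (training batches only).
    loss_history_ : ndarray, shape (epochs,)
        Mean per-sequence training loss per epoch.
    """

    def __init__(
        self,
        hidden: int = 256,
        learning_rate: float = 1.6e-4,
        momentum: float = 0.97,
        weight_decay: float = 0.125,
        epochs: int = 5000,
        rng_seed: int = 0,
        loss_days: str = "sampling_only",
        loss_scale: float = 5.0,
        use_bias: bool = True,
        decoupled_weight_decay: bool = False,
    ):
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.rng_seed = rng_seed
        self.loss_days = loss_days
        self.loss_scale = loss_scale
        self.use_bias = use_bias
        self.decoupled_weight_decay = decoupled_weight_decay

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            hidden=self.hidden,
            rng_seed=self.rng_seed,
            loss_days=self.loss_days,
            loss_scale=self.loss_scale,
            use_bias=self.use_bias,
            decoupled_weight_decay=self.decoupled_weight_decay,
        )

    def fit(self, batches: list[BatchRecord], y=None) -> "RecurrentSoftSensor":
        if not batches:
            raise ValueError("fit requires at least one batch")
        self.scaler_: Scaler = fit_scaler(batches)
        self.params_, self.loss_history_ = train_model(
            batches, self._train_config(), scaler=self.scaler_
        )
        self.n_features_in_ = batches[0].online.shape[1]
        return self

    def predict(
        self, batch: BatchRecord, mode: str = "full_feedback"
    ) -> PredictionTrajectory:
        """Roll the trained recurrence over one batch's day grid."""
        check_is_fitted(self, "params_")
        return rollout(self.params_, self.scaler_, batch, mode=mode)

    def predict_many(
        self, batches: list[BatchRecord], mode: str = "full_feedback"
    ) -> list[PredictionTrajectory]:
        return [self.predict(b, mode=mode) for b in batches]

    def score(self, batches: list[BatchRecord], y=None,
              mode: str = "full_feedback") -> float:
        """Mean across-batch, across-variable R^2 at comparable days."""
        from .evaluation import evaluate_batches

        report = evaluate_batches(self.predict_many(batches, mode), batches)
        return float(np.mean([report.global_mean[v]["r2"]
                              for v in report.variables]))
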