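"""The three crown-profile architectures, the training loop and PSO tuning.

* ``vanilla_lstm``        — one LSTM layer on the raw feature sequence,
                            per-step linear head.
* ``cnn_lstm``            — residual 1-D convolution block (second conv with
                            twice the filters, linear input projection added
                            elementwise) feeding the LSTM.
* ``cnn_lstm_attention``  — additionally reweights the 10 LSTM outputs with a
                            learned softmax distribution over time steps
                            before the per-step head.

Training minimises MSE on normalised targets with Adam, early stopping on
validation loss and best-weight restoration.  Everything is seeded and runs
on plain NumPy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import Dataset, Normalizer
from .nn import (
    LSTM, Adam, Dense, Network, ResidualConvBlock, TimeAttention, mse_loss,
)
from . import pso

ARCHITECTURES = ("vanilla_lstm", "cnn_lstm", "cnn_lstm_attention")

#: PSO search ranges for (filters, lstm_units, learning_rate, batch_size)
TUNABLE_RANGES = {
    "filters": (32, 256),
    "lstm_units": (32, 128),
    "learning_rate": (1e-5, 1e-2),
    "batch_size": (16, 64),
}


@dataclass
class ModelConfig:
    kind: str = "cnn_lstm_attention"
    filters: int = 32
    lstm_units: int = 48
    learning_rate: float = 3e-3
    batch_size: int = 32
    kernel_size: int = 3
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def validate(self, strict: bool = False) -> None:
        if self.kind not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.kind!r}")
        if strict:
            checks = {
                "filters": self.filters, "lstm_units": self.lstm_units,
                "learning_rate": self.learning_rate, "batch_size": self.batch_size,
            }
            for name, value in checks.items():
                if self.kind == "vanilla_lstm" and name == "filters":
                    continue
                lo, hi = TUNABLE_RANGES[name]
                if not lo <= value <= hi:
                    raise ValueError(
                        f"{name}={value} outside tuned range [{lo}, {hi}]"
                    )


def build_model(config: ModelConfig, n_features: int, n_steps: int = 10) -> Network:
    """Untrained network for the requested architecture."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    layers = []
    lstm_in = n_features
    if config.kind in ("cnn_lstm", "cnn_lstm_attention"):
        layers.append(
            ResidualConvBlock(n_features, config.filters, config.kernel_size, rng)
        )
        lstm_in = 2 * config.filters
    layers.append(LSTM(lstm_in, config.lstm_units, rng))
    if config.kind == "cnn_lstm_attention":
        layers.append(TimeAttention(n_steps, rng))
    layers.append(Dense(config.lstm_units, 1, rng))
    return Network(layers)


@dataclass
class TrainedModel:
    network: Network
    config: ModelConfig
    normalizer: Normalizer | None
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Normalised per-step predictions, shape (n, 10)."""
        return self.network.forward(x)

    def predict_radii(self, dataset: Dataset, lag_mode: str = "teacher") -> np.ndarray:
        """Predicted radii in metres.

        ``teacher`` feeds the observed lagged radius (as stored in the
        dataset); ``autoregressive`` replaces the lag feature at each step
        with the model's own previous prediction.
        """
        if self.normalizer is None:
            raise ValueError("model has no attached normalizer")
        if lag_mode == "teacher":
            return self.normalizer.inverse_y(self.predict(dataset.x))
        if lag_mode != "autoregressive":
            raise ValueError("lag_mode must be 'teacher' or 'autoregressive'")
        norm = self.normalizer
        names = dataset.feature_names
        lag = names.index("CR_lag")
        lo, hi = norm.x_min[lag], norm.x_max[lag]
        span = (hi - lo) if hi > lo else 1.0
        x = dataset.x.copy()
        pred_m = np.zeros_like(dataset.y_m)
        for k in range(x.shape[1]):
            prev = np.zeros(len(x)) if k == 0 else pred_m[:, k - 1]
            x[:, k, lag] = (prev - lo) / span
            pred_m[:, k] = norm.inverse_y(self.network.forward(x)[:, k])
        return pred_m


def train(
    network: Network,
    train_data: Dataset,
    val_data: Dataset,
    config: ModelConfig,
    normalizer: Normalizer | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Minibatch Adam with early stopping on validation MSE; the weights of
    the best-validation epoch are restored before returning."""
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.params(), lr=config.learning_rate)
    n = len(train_data.x)
    bs = min(config.batch_size, n)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = network.get_weights()
    wait = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            pred = network.forward(train_data.x[idx])
            loss, grad = mse_loss(pred, train_data.y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={config.learning_rate}); aborting"
                )
            network.backward(grad)
            opt.step(network.grads())
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)

        val_pred = network.forward(val_data.x)
        val_loss = float(np.mean((val_pred - val_data.y) ** 2))
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch:3d}  train {history['train_loss'][-1]:.5f}  "
                  f"val {val_loss:.5f}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = network.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    network.set_weights(best_weights)
    return TrainedModel(network, config, normalizer, history)


def fit(
    train_data: Dataset,
    val_data: Dataset,
    config: ModelConfig,
    normalizer: Normalizer | None = None,
) -> TrainedModel:
    """Convenience: build + train in one call."""
    net = build_model(config, train_data.x.shape[2])
    return train(net, train_data, val_data, config, normalizer)


def pso_tune(
    kind: str,
    train_data: Dataset,
    val_data: Dataset,
    normalizer: Normalizer | None = None,
    swarm_size: int = 10,
    iterations: int = 20,
    seed: int = 0,
    tune_epochs: int = 50,
) -> tuple[ModelConfig, np.ndarray]:
    """Particle-swarm search over (filters, LSTM units, learning rate,
    batch size) minimising validation MSE of a shortened training run.

    Returns the best configuration and the best-so-far objective trace
    (monotone nonincreasing).  ``filters`` is ignored, and not searched,
    for the vanilla LSTM.
    """
    dims = ["lstm_units", "learning_rate", "batch_size"]
    if kind != "vanilla_lstm":
        dims = ["filters"] + dims
    lb = np.array([TUNABLE_RANGES[d][0] for d in dims], dtype=float)
    ub = np.array([TUNABLE_RANGES[d][1] for d in dims], dtype=float)
    integer_dims = [i for i, d in enumerate(dims) if d != "learning_rate"]

    def objective(x: np.ndarray) -> float:
        values = dict(zip(dims, x))
        cfg = ModelConfig(
            kind=kind,
            filters=int(values.get("filters", 32)),
            lstm_units=int(values["lstm_units"]),
            learning_rate=float(values["learning_rate"]),
            batch_size=int(values["batch_size"]),
            max_epochs=tune_epochs,
            patience=max(5, tune_epochs // 5),
            seed=seed,
        )
        try:
            model = fit(train_data, val_data, cfg)
        except RuntimeError:  # diverged (e.g. extreme learning rate)
            return np.inf
        return min(model.history["val_loss"])

    best_x, _, trace = pso.minimize(
        objective, lb, ub, swarm_size=swarm_size, iterations=iterations,
        seed=seed, integer_dims=integer_dims,
    )
    values = dict(zip(dims, best_x))
    best = ModelConfig(
        kind=kind,
        filters=int(values.get("filters", 32)),
        lstm_units=int(values["lstm_units"]),
        learning_rate=float(values["learning_rate"]),
        batch_size=int(values["batch_size"]),
        seed=seed,
    )
    return best, trace


def config_to_dict(config: ModelConfig) -> dict:
    return asdict(config)


def clone_network(model: TrainedModel) -> Network:  # pragma: no cover - helper
    return copy.deepcopy(model.network)
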