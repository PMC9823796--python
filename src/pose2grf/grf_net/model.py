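"""Model/Results interface around the bidirectional LSTM.

`GRFRegression` holds the training data and configuration; `fit()` trains
with Adam on a mean-squared-error objective, tracks the validation loss each
epoch, restores the weights of the best epoch, and returns a
`GRFRegressionResults` carrying the fitted weights, the standardisation
constants (computed on training data only and travelling with the model),
the loss history and a `summary()` table.

Architecture: two stacked bidirectional LSTM layers of 400 units per
direction with dropout 0.5 between layers and a per-timestep affine head to
the three force components; sequences are 101 normalised-time frames of 16
keypoint channels. Learning rate 0.003, 40 epochs by default.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from pose2grf.grf_net.layers import Adam, BiLSTMRegressor, mse_loss


@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters of the GRF estimator."""

    seq_len: int = 101
    in_channels: int = 16
    hidden_units: int = 400
    n_hidden_layers: int = 2
    dropout: float = 0.5
    out_channels: int = 3
    learning_rate: float = 0.003
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.seq_len, self.in_channels, self.hidden_units,
               self.n_hidden_layers, self.out_channels, self.epochs, self.batch_size) < 1:
            raise ValueError("all structural sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class _Standardizer:
    """Per-channel z-score constants; fitted on training data only."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, Y: np.ndarray) -> "_Standardizer":
        x_mean = X.mean(axis=(0, 1))
        x_std = X.std(axis=(0, 1))
        y_mean = Y.mean(axis=(0, 1))
        y_std = Y.std(axis=(0, 1))
        x_std = np.where(x_std < 1e-12, 1.0, x_std)
        y_std = np.where(y_std < 1e-12, 1.0, y_std)
        return cls(x_mean, x_std, y_mean, y_std)

    def fx(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std

    def fy(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.y_mean) / self.y_std

    def inv_y(self, Yz: np.ndarray) -> np.ndarray:
        return Yz * self.y_std + self.y_mean


class GRFRegression:
    """Sequence regression model from keypoint features to GRF curves.

    Parameters
    ----------
    inputs : ndarray, shape (n, seq_len, in_channels)
        Hip-centred keypoint features per stance phase.
    targets : ndarray, shape (n, seq_len, out_channels)
        Mass-normalised GRF curves in N/kg.
    config : NetConfig
    subject_ids : sequence of str, optional
        When given, used to assert subject-level disjointness with the
        validation set at fit time.
    """

    def __init__(self, inputs, targets, config: NetConfig = NetConfig(), subject_ids=None):
        self.X = np.asarray(inputs, dtype=float)
        self.Y = np.asarray(targets, dtype=float)
        self.config = config
        c = config
        if self.X.ndim != 3 or self.X.shape[1:] != (c.seq_len, c.in_channels):
            raise ValueError(
                f"inputs must be (n, {c.seq_len}, {c.in_channels}), got {self.X.shape}"
            )
        if self.Y.shape != (self.X.shape[0], c.seq_len, c.out_channels):
            raise ValueError("targets shape does not match inputs/config")
        self.subject_ids = list(subject_ids) if subject_ids is not None else None

    def build(self) -> BiLSTMRegressor:
        # single precision: the standard working precision for this kind of
        # network, and twice the arithmetic throughput of float64 on one core
        c = self.config
        return BiLSTMRegressor(
            n_in=c.in_channels,
            n_hidden=c.hidden_units,
            n_out=c.out_channels,
            n_layers=c.n_hidden_layers,
            dropout=c.dropout,
            seed=c.seed,
            dtype=np.float32,
        )

    def fit(self, val_inputs, val_targets, val_subject_ids=None, verbose: bool = False) -> "GRFRegressionResults":
        """Train for ``config.epochs`` epochs and keep the weights of the
        epoch with the smallest validation loss."""
        Xv = np.asarray(val_inputs, dtype=float)
        Yv = np.asarray(val_targets, dtype=float)
        if Xv.shape[0] == 0:
            raise ValueError("validation set must not be empty")
        if self.subject_ids is not None and val_subject_ids is not None:
            overlap = set(self.subject_ids) & set(val_subject_ids)
            if overlap:
                raise ValueError(f"subject leakage between train and validation: {sorted(overlap)}")
        c = self.config
        std = _Standardizer.fit(self.X, self.Y)
        Xtr = std.fx(self.X).astype(np.float32)
        Ytr = std.fy(self.Y).astype(np.float32)
        Xvz = std.fx(Xv).astype(np.float32)
        Yvz = std.fy(Yv).astype(np.float32)

        net = self.build()
        opt = Adam(net.params, lr=c.learning_rate)
        rng = np.random.default_rng(c.seed + 1)
        n = Xtr.shape[0]
        history = {"train_loss": [], "val_loss": []}
        best = {"epoch": 0, "val_loss": np.inf, "state": net.get_state()}
        for epoch in range(1, c.epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                Y_hat, cache = net.forward(Xtr[idx], training=True, rng=rng)
                loss, dY = mse_loss(Y_hat, Ytr[idx])
                grads = net.backward(dY, cache)
                opt.step(net.params, grads)
                epoch_loss += loss * len(idx)
            train_loss = epoch_loss / n
            val_pred = net.predict(Xvz)
            val_loss = float(np.mean((val_pred - Yvz) ** 2))
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if val_loss < best["val_loss"]:
                best = {"epoch": epoch, "val_loss": val_loss, "state": net.get_state()}
            if verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.5f}  val {val_loss:.5f}")
        net.set_state(best["state"])
        return GRFRegressionResults(
            config=c,
            net=net,
            standardizer=std,
            best_epoch=int(best["epoch"]),
            history=history,
        )


class GRFRegressionResults:
    """Fitted GRF estimator: weights, standardisation constants, history."""

    def __init__(self, config: NetConfig, net: BiLSTMRegressor,
                 standardizer: _Standardizer, best_epoch: int, history: dict):
        self.config = config
        self.net = net
        self.standardizer = standardizer
        self.best_epoch = best_epoch
        self.history = history

    def predict(self, inputs) -> np.ndarray:
        """Predict GRF curves in N/kg for ``(m, seq_len, in_channels)`` inputs.

        Inputs are standardised with the model's own training constants; a
        channel-count mismatch is refused (the cross-estimator misuse guard).
        """
        X = np.asarray(inputs, dtype=float)
        c = self.config
        if X.shape[0] == 0:
            return np.zeros((0, c.seq_len, c.out_channels))
        if X.ndim != 3 or X.shape[1:] != (c.seq_len, c.in_channels):
            raise ValueError(
                f"inputs must be (m, {c.seq_len}, {c.in_channels}), got {X.shape}"
            )
        Yz = self.net.predict(self.standardizer.fx(X))
        return self.standardizer.inv_y(Yz)

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.net.params.values()))

    def summary(self) -> str:
        c = self.config
        lines = [
            "GRF bidirectional LSTM regression results",
            "=" * 45,
            f"layers: {c.n_hidden_layers} bi-LSTM x {c.hidden_units} units/direction",
            f"dropout between layers: {c.dropout}",
            f"sequence: {c.seq_len} frames x {c.in_channels} channels -> {c.out_channels}",
            f"parameters: {self.n_parameters}",
            f"optimiser: Adam, lr={c.learning_rate}, batch={c.batch_size}",
            f"epochs trained: {len(self.history['train_loss'])}",
            f"best epoch (min val loss): {self.best_epoch}",
            f"val loss at best epoch: {min(self.history['val_loss']):.6f}",
            f"final train loss: {self.history['train_loss'][-1]:.6f}",
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Single-archive save: weights, config, standardisation constants,
        best epoch and loss history."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "pose2grf-model/1",
            "config": asdict(self.config),
            "best_epoch": self.best_epoch,
            "history": self.history,
        }
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        arrays.update(
            std_x_mean=self.standardizer.x_mean,
            std_x_std=self.standardizer.x_std,
            std_y_mean=self.standardizer.y_mean,
            std_y_std=self.standardizer.y_std,
        )
        np.savez(path, meta=json.dumps(meta), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GRFRegressionResults":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format") != "pose2grf-model/1":
                raise ValueError(f"unknown model archive format in {path}")
            config = NetConfig(**meta["config"])
            net = BiLSTMRegressor(
                n_in=config.in_channels,
                n_hidden=config.hidden_units,
                n_out=config.out_channels,
                n_layers=config.n_hidden_layers,
                dropout=config.dropout,
                seed=config.seed,
            )
            net.set_state({k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")})
            std = _Standardizer(
                x_mean=data["std_x_mean"],
                x_std=data["std_x_std"],
                y_mean=data["std_y_mean"],
                y_std=data["std_y_std"],
            )
        return cls(config=config, net=net, standardizer=std,
                   best_epoch=meta["best_epoch"], history=meta["history"])
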