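"""CNN heart-rate regressor: one normalized 400-sample window in, one HR out.

An 11-layer strided convolutional network (18.8 k parameters at width 1)
replaces pooling with stride-2 convolutions and has no dense layers; the
final single-filter kernel-1 layer reads the scalar out.  Targets are
z-scored against training-set heart rates, the loss is the MSE on that
normalized scale with an L2 kernel penalty, and optimization is Adam with
default parameters for a fixed number of epochs with no early stopping —
the final state is the model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import Adam, Network, NetworkSpec, build, reference_spec
from .preprocessing import WindowSet
from .series import HRSeries

__all__ = [
    "CNNHeartRateRegressor",
    "split_subjects",
    "predict_hr",
    "reference_spec",
]


def split_subjects(
    subject_ids: list[str], train_fraction: float = 2 / 3, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random subject-level train/test split, fixed before any optimization.

    Splitting by subject (never by window) keeps every subject's windows on
    one side of the boundary.
    """
    ids = sorted(set(subject_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


class CNNHeartRateRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style regressor wrapping the strided 1-D CNN.

    Parameters
    ----------
    epochs : number of full passes over the training windows (no early
        stopping; the final state is kept).
    batch_size : minibatch size for Adam.
    lr : Adam learning rate (framework default).
    l2_kernel : L2 penalty coefficient applied to convolution kernels only.
    width_factor : multiplies every hidden channel count of the reference
        architecture.
    leaky_slope : negative slope of the leaky ReLU activations.
    seed : seeds weight initialization and minibatch shuffling.

    Fitted attributes
    -----------------
    model_ : the trained :class:`~bcgpulse.nn.Network`.
    target_mean_, target_sd_ : training-set HR normalizer, applied inversely
        at prediction time.
    history_ : per-epoch DataFrame (epoch, loss, mae_bpm, mape_pct) on the
        denormalized scale, computed over the training set.
    """

    def __init__(
        self,
        epochs: int = 30,
        batch_size: int = 64,
        lr: float = 1e-3,
        l2_kernel: float = 1e-4,
        width_factor: float = 1.0,
        leaky_slope: float = 0.3,
        seed: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.l2_kernel = l2_kernel
        self.width_factor = width_factor
        self.leaky_slope = leaky_slope
        self.seed = seed

    def _spec(self) -> NetworkSpec:
        return reference_spec(self.width_factor)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D window matrix")
        defined = ~np.isnan(y)
        X, y = X[defined], y[defined]
        if len(y) == 0:
            raise ValueError("no training windows with a defined target HR")
        self.n_features_in_ = X.shape[1]
        self.target_mean_ = float(np.mean(y))
        self.target_sd_ = float(np.std(y))
        if self.target_sd_ == 0:
            raise ValueError("training HR targets have zero variance")
        y_norm = (y - self.target_mean_) / self.target_sd_

        self.model_ = build(self._spec(), seed=self.seed, leaky_slope=self.leaky_slope)
        opt = Adam(lr=self.lr)
        rng = np.random.default_rng(self.seed + 1)
        n = len(y_norm)
        history = []
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            losses, abs_err, ape = [], [], []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y_norm[idx]
                out = self.model_.forward(xb, training=True)
                err = out - yb
                loss = float(np.mean(err**2))
                if self.l2_kernel > 0:
                    loss += self.l2_kernel * sum(
                        float(np.sum(w**2)) for w in self.model_.kernel_params
                    )
                grads = self.model_.backward(2.0 * err / len(idx))
                if self.l2_kernel > 0:
                    kernels = {id(w) for w in self.model_.kernel_params}
                    for p, g in zip(self.model_.params, grads):
                        if id(p) in kernels:
                            g += 2.0 * self.l2_kernel * p
                opt.step(self.model_.params, grads)
                losses.append(loss)
                err_bpm = err * self.target_sd_
                y_bpm = yb * self.target_sd_ + self.target_mean_
                abs_err.extend(np.abs(err_bpm))
                ape.extend(np.abs(err_bpm) / y_bpm)
            history.append(
                {
                    "epoch": epoch,
                    "loss": float(np.mean(losses)),
                    "mae_bpm": float(np.mean(abs_err)),
                    "mape_pct": float(100 * np.mean(ape)),
                }
            )
        self.history_ = pd.DataFrame(history)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for start in range(0, len(X), 256):
            out[start : start + 256] = self.model_.forward(X[start : start + 256], training=False)
        return out * self.target_sd_ + self.target_mean_

    # --- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights (.npz) plus a JSON sidecar with normalizer and config."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.model_.params)}
        bn_state = {}
        for i, layer in enumerate(self.model_.layers):
            if hasattr(layer, "running_mean"):
                bn_state[f"rm{i}"] = layer.running_mean
                bn_state[f"rv{i}"] = layer.running_var
        np.savez(path.with_suffix(".npz"), **arrays, **bn_state)
        sidecar = {
            "target_mean_bpm": self.target_mean_,
            "target_sd_bpm": self.target_sd_,
            "params": self.get_params(),
            "n_trainable": int(self.model_.count_params()),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CNNHeartRateRegressor":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        est = cls(**sidecar["params"])
        est.model_ = build(est._spec(), seed=est.seed, leaky_slope=est.leaky_slope)
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(est.model_.params):
            p[...] = data[f"p{i}"]
        for i, layer in enumerate(est.model_.layers):
            if hasattr(layer, "running_mean"):
                layer.running_mean = data[f"rm{i}"]
                layer.running_var = data[f"rv{i}"]
        est.target_mean_ = sidecar["target_mean_bpm"]
        est.target_sd_ = sidecar["target_sd_bpm"]
        est.n_features_in_ = est._spec().input_len
        return est


def predict_hr(est: CNNHeartRateRegressor, ws: WindowSet) -> HRSeries:
    """Per-window HR series from a fitted regressor; excluded windows are NaN."""
    hr = np.full(len(ws), np.nan)
    active = ~ws.excluded
    if active.any():
        hr[active] = est.predict(ws.windows[active])
    return HRSeries(
        subject_id=ws.subject_id,
        window_index=np.arange(len(ws)),
        hr_bpm=hr,
        n_peaks=np.zeros(len(ws), dtype=int),
        source="cnn",
        window_start_ms=ws.start_times_ms,
    )
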