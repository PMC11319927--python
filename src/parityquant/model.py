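"""The multi-quantification regressor: one CNN trunk, nine regression heads.

:class:`MultiQuantRegressor` is a scikit-learn style estimator (``fit`` /
``predict`` / ``get_params``) over the numpy backbone in
:mod:`parityquant.nn`.  Labels are z-score normalized per index from the
training split (the nine indices span roughly 1.7–22 mm, so unnormalized MSE
would be dominated by the long lengths); the loss is the unweighted mean of
the nine per-index MSEs on the normalized scale, optimized with Adam, and
predictions are de-normalized back to mm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, MultiHeadNet, normalize_backbone_name


class MultiQuantRegressor(BaseEstimator, RegressorMixin):
    """Multi-output CNN regressor for the nine basal-bone indices.

    Parameters
    ----------
    backbone : str
        One of the residual backbone names (``small-resnet`` is the CPU-scale
        default; the six standard recipes are available for fidelity runs).
    n_heads : int
        Number of parallel scalar regression heads (one per index).
    learning_rate, batch_size, epochs : float, int, int
        Adam step size and schedule.  The defaults (5e-4 / 4 / 200) are the
        settings selected on the clinical validation split; CPU-scale runs
        override them.
    augment_flip : bool
        Horizontal (bucco-palatal) flip augmentation.  All nine labels are
        invariant under this mirroring (widths are unsigned, lengths axis-wise),
        so only the image is flipped.
    pretrained_weights : str | None
        Optional ``.npz`` checkpoint to initialize the network from.
    """

    def __init__(
        self,
        backbone: str = "small-resnet",
        n_heads: int = 9,
        head_hidden: int = 16,
        learning_rate: float = 5e-4,
        batch_size: int = 4,
        epochs: int = 200,
        augment_flip: bool = True,
        weight_decay: float = 0.0,
        pretrained_weights: str | None = None,
        val_every: int = 1,
        calibrate_bias: bool = True,
        avg_tail_frac: float = 0.25,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.n_heads = n_heads
        self.head_hidden = head_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.augment_flip = augment_flip
        self.weight_decay = weight_decay
        self.pretrained_weights = pretrained_weights
        self.val_every = val_every
        self.calibrate_bias = calibrate_bias
        self.avg_tail_frac = avg_tail_frac
        self.random_state = random_state

    # -- internals ----------------------------------------------------------
    def _validate_config(self):
        normalize_backbone_name(self.backbone)
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_images, H, W), got shape {X.shape}")
        if hasattr(self, "input_shape_") and X.shape[1:] != self.input_shape_:
            raise ValueError(f"expected images of shape {self.input_shape_}, got {X.shape[1:]}")
        return X

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images ``X`` (n, H, W) and labels ``y`` (n, n_heads) in mm.

        If a validation set is given, per-epoch validation MSE (mm^2, averaged
        over heads) is recorded in ``history_`` alongside the training loss.
        """
        self._validate_config()
        X = self._check_X(X)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim != 2 or y.shape != (X.shape[0], self.n_heads):
            raise ValueError(f"y must be ({X.shape[0]}, {self.n_heads}), got {y.shape}")
        if X.shape[0] == 0:
            raise ValueError("training split is empty")
        self.input_shape_ = X.shape[1:]

        rng = np.random.default_rng(self.random_state)
        self.net_ = MultiHeadNet(self.backbone, self.n_heads, self.head_hidden, rng=rng)
        if self.pretrained_weights is not None:
            loaded, _ = MultiHeadNet.load(self.pretrained_weights)
            for p, q in zip(self.net_.state_arrays(), loaded.state_arrays()):
                p[...] = q

        self.label_mean_ = y.mean(axis=0)
        sd = y.std(axis=0)
        self.label_std_ = np.where(sd > 1e-9, sd, 1.0)
        yn = (y - self.label_mean_) / self.label_std_

        opt = Adam(self.net_.params_grads(), lr=self.learning_rate, weight_decay=self.weight_decay)
        n = X.shape[0]
        rows = []
        # tail averaging (Polyak): mean of the end-of-epoch weights over the
        # last avg_tail_frac of training, damping optimization noise
        avg_start = self.epochs - max(1, int(round(self.avg_tail_frac * self.epochs)))
        avg_params = None
        n_avg = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            sq_mm = 0.0
            loss_sum = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx]
                if self.augment_flip:
                    flip = rng.random(len(idx)) < 0.5
                    xb = np.where(flip[:, None, None], xb[:, :, ::-1], xb)
                pred = self.net_.forward(xb)
                err = pred - yn[idx]
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                loss_sum += loss * len(idx)
                sq_mm += float(np.sum((err * self.label_std_) ** 2)) / self.n_heads
                self.net_.backward(2.0 * err / err.size)
                opt.step()
            if self.avg_tail_frac > 0 and epoch >= avg_start:
                cur = [p for p, _ in self.net_.params_grads()]
                if avg_params is None:
                    avg_params = [p.copy() for p in cur]
                else:
                    for a, p_ in zip(avg_params, cur):
                        a += p_
                n_avg += 1
            row = {"epoch": epoch, "train_loss": loss_sum / n, "train_mse_mm": sq_mm / n}
            if X_val is not None and (epoch % self.val_every == 0 or epoch == self.epochs - 1):
                row["val_mse_mm"] = self.mse(X_val, y_val)
            rows.append(row)
        if avg_params is not None:
            for (p_, _), a in zip(self.net_.params_grads(), avg_params):
                p_[...] = a / n_avg
        self.history_ = pd.DataFrame(rows)
        # mean-bias correction on the training split: removes the per-index
        # global offset left by stochastic optimization (no test-set leakage)
        self.bias_offset_ = np.zeros(self.n_heads)
        if self.calibrate_bias:
            self.bias_offset_ = self.predict(X).mean(axis=0) - y.mean(axis=0)
        return self

    def predict(self, X, batch_size: int = 64) -> np.ndarray:
        """Predict the nine indices in mm for each image; deterministic."""
        check_is_fitted(self, "net_")
        X = self._check_X(X)
        out = []
        for start in range(0, X.shape[0], batch_size):
            out.append(self.net_.forward(X[start : start + batch_size]))
        pred = np.concatenate(out, axis=0) if out else np.empty((0, self.n_heads))
        offset = getattr(self, "bias_offset_", 0.0)
        return pred * self.label_std_ + self.label_mean_ - offset

    def mse(self, X, y) -> float:
        """Mean squared error in mm^2, averaged over heads."""
        y = np.asarray(y, dtype=np.float64)
        return float(np.mean((self.predict(X) - y) ** 2))

    def grad_cam(self, image, head_index: int) -> np.ndarray:
        """Grad-CAM heatmap of one head for one image (values in [0, 1])."""
        check_is_fitted(self, "net_")
        image = np.asarray(image, dtype=np.float64)
        if image.shape != self.input_shape_:
            raise ValueError(f"expected image shape {self.input_shape_}, got {image.shape}")
        return self.net_.grad_cam(image, head_index)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "net_")
        self.net_.save(
            path,
            extra_meta={
                "params": self.get_params(),
                "label_mean": self.label_mean_.tolist(),
                "label_std": self.label_std_.tolist(),
                "bias_offset": self.bias_offset_.tolist(),
                "input_shape": list(self.input_shape_),
            },
        )

    @classmethod
    def load(cls, path) -> "MultiQuantRegressor":
        net, extra = MultiHeadNet.load(path)
        est = cls(**extra["params"])
        est.net_ = net
        est.label_mean_ = np.asarray(extra["label_mean"])
        est.label_std_ = np.asarray(extra["label_std"])
        est.bias_offset_ = np.asarray(extra.get("bias_offset", np.zeros(len(extra["label_mean"]))))
        est.input_shape_ = tuple(extra["input_shape"])
        est.history_ = pd.DataFrame()
        return est


def select_model(candidates, X, y, X_val, y_val):
    """Train every candidate and return the one with minimum validation MSE.

    ``candidates`` is a sequence of parameter dicts for
    :class:`MultiQuantRegressor` (or unfitted estimator instances).  Ties are
    broken by candidate order (strict improvement required to replace the
    leader).  Returns ``(best_estimator, selection_table)``.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    best = None
    best_mse = np.inf
    rows = []
    for i, cand in enumerate(candidates):
        est = MultiQuantRegressor(**cand) if isinstance(cand, dict) else cand
        est.fit(X, y, X_val=X_val, y_val=y_val)
        mse = est.mse(X_val, y_val)
        rows.append({"candidate": i, **est.get_params(), "val_mse_mm": mse})
        if mse < best_mse:
            best, best_mse = est, mse
    return best, pd.DataFrame(rows)
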