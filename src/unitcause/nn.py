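"""Feedforward myopia classifier with analytic derivatives.

A small fully connected network — by default 16 inputs, hidden layers of 12
and 8 ReLU units, and a 2-unit softmax output — trained with mini-batch SGD
on the cross-entropy loss.  Inputs are standardized with training-set
statistics inside the model, so the public surface works on raw features.

Because the hidden layers are piecewise linear, the logits are locally
affine in the input: z(x) = A·x_std + c with A the product of the weight
matrices through the active ReLU masks.  The class-probability surface
therefore has the exact local Hessian ∇²p_c = Aᵀ·H_softmax(z)·A, which is
what the Taylor-expansion attribution machinery consumes.  A central
finite-difference Hessian is provided as an independent cross-check.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np

from .cohort import CohortTable

__all__ = [
    "Hyperparams",
    "FeedforwardClassifier",
    "Metrics",
    "train_fnn",
    "predict_proba",
    "output_hessian",
    "evaluate",
    "split_metrics",
]

_KINK_TOL = 1e-8
_KINK_NUDGE = 1e-6


@dataclasses.dataclass(frozen=True)
class Hyperparams:
    """SGD training configuration (defaults documented in the methods note)."""

    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 200
    hidden: tuple[int, ...] = (12, 8)


@dataclasses.dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float  # NaN when undefined (single-class test set)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class FeedforwardClassifier:
    """ReLU feedforward softmax classifier over named raw features."""

    def __init__(self, weights: Sequence[np.ndarray],
                 biases: Sequence[np.ndarray],
                 feature_order: Sequence[str],
                 shift: np.ndarray, scale: np.ndarray) -> None:
        self.weights = [np.asarray(w, float) for w in weights]
        self.biases = [np.asarray(b, float) for b in biases]
        self.feature_order = tuple(feature_order)
        self.shift = np.asarray(shift, float)
        self.scale = np.asarray(scale, float)
        if len(self.feature_order) != self.weights[0].shape[0]:
            raise ValueError("feature_order does not match input width")
        self.loss_log: list[float] = []

    # -- construction ------------------------------------------------------
    @classmethod
    def random(cls, layer_sizes: Sequence[int], seed: int = 0,
               weight_scale: float | None = None,
               feature_order: Sequence[str] | None = None
               ) -> "FeedforwardClassifier":
        """Randomly initialized (untrained) network; identity standardization."""
        rng = np.random.default_rng(seed)
        ws, bs = [], []
        for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
            s = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
            ws.append(rng.normal(0.0, s, size=(fan_in, fan_out)))
            bs.append(np.zeros(fan_out))
        names = (tuple(feature_order) if feature_order is not None
                 else tuple(f"x{i}" for i in range(layer_sizes[0])))
        return cls(ws, bs, names, np.zeros(layer_sizes[0]),
                   np.ones(layer_sizes[0]))

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    # -- forward pass ------------------------------------------------------
    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.shift) / self.scale

    def de_standardize(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.scale + self.shift

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Hidden activations (post-ReLU) and logits for standardized input."""
        h = X
        acts = []
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        return acts, logits

    def predict_logits(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != len(self.feature_order):
            raise ValueError(
                f"expected {len(self.feature_order)} features, got {X.shape[1]}"
            )
        _, logits = self._forward(self.standardize(X))
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.predict_logits(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def value(self, point, class_index: int, mode: str = "proba") -> float:
        logits = self.predict_logits(np.asarray(point, float).reshape(1, -1))
        if mode == "logit":
            return float(logits[0, class_index])
        return float(_softmax(logits)[0, class_index])

    # -- derivatives -------------------------------------------------------
    def _local_affine(self, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Local logit map z = A·x_std + c at a point (raw coordinates).

        Points lying on a ReLU kink are nudged by a tiny perturbation with a
        warning, since the derivative is undefined there.
        """
        x = self.standardize(np.asarray(point, float).reshape(-1))
        for _ in range(3):
            h = x
            on_kink = False
            for w, b in zip(self.weights[:-1], self.biases[:-1]):
                pre = h @ w + b
                if np.any(np.abs(pre) < _KINK_TOL):
                    on_kink = True
                    break
                h = np.maximum(pre, 0.0)
            if not on_kink:
                break
            warnings.warn("evaluation point lies on a ReLU kink; nudging")
            x = x + _KINK_NUDGE
        A = np.eye(len(x))
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            pre = h @ w + b
            mask = (pre > 0).astype(float)
            A = (w.T * mask[:, None]) @ A  # diag(mask) · wᵀ · A
            h = np.maximum(pre, 0.0)
        A = self.weights[-1].T @ A
        logits = h @ self.weights[-1] + self.biases[-1]
        return A, logits - A @ x

    def gradient(self, point, class_index: int, mode: str = "proba") -> np.ndarray:
        """∇f wrt raw features of the class probability (or logit)."""
        point = np.asarray(point, float).reshape(-1)
        A, _ = self._local_affine(point)
        if mode == "logit":
            g_z = np.zeros(A.shape[0])
            g_z[class_index] = 1.0
        else:
            p = self.predict_proba(point.reshape(1, -1))[0]
            g_z = p[class_index] * ((np.arange(len(p)) == class_index) - p)
        return (g_z @ A) / self.scale

    def hessian(self, point, class_index: int, mode: str = "proba",
                method: str = "analytic", fd_step: float = 1e-3) -> np.ndarray:
        """Symmetric Hessian ∇²f wrt raw features.

        ``method="analytic"`` exploits the locally affine logits;
        ``method="fd"`` is a central finite difference with step ``fd_step``
        on the standardized scale (independent cross-check).
        """
        point = np.asarray(point, float).reshape(-1)
        if not np.all(np.isfinite(point)):
            raise ValueError("evaluation point must be finite")
        if method == "fd":
            return self._fd_hessian(point, class_index, mode, fd_step)
        if mode == "logit":
            return np.zeros((len(point), len(point)))
        A, _ = self._local_affine(point)
        p = self.predict_proba(point.reshape(1, -1))[0]
        k = len(p)
        e = (np.arange(k) == class_index).astype(float)
        d = e - p
        # ∂²p_c/∂z_i∂z_j = p_c[(δ_ci−p_i)(δ_cj−p_j) − p_i δ_ij + p_i p_j]
        Hz = p[class_index] * (np.outer(d, d) - np.diag(p) + np.outer(p, p))
        H = A.T @ Hz @ A
        H = (H + H.T) / 2.0
        return H / np.outer(self.scale, self.scale)

    def _fd_hessian(self, point: np.ndarray, class_index: int,
                    mode: str, step: float) -> np.ndarray:
        d = len(point)
        H = np.zeros((d, d))
        hs = step * self.scale  # step on the standardized scale
        f = lambda x: self.value(x, class_index, mode)
        f0 = f(point)
        for i in range(d):
            ei = np.zeros(d); ei[i] = hs[i]
            H[i, i] = (f(point + ei) - 2 * f0 + f(point - ei)) / hs[i] ** 2
            for j in range(i + 1, d):
                ej = np.zeros(d); ej[j] = hs[j]
                H[i, j] = H[j, i] = (
                    f(point + ei + ej) - f(point + ei - ej)
                    - f(point - ei + ej) + f(point - ei - ej)
                ) / (4 * hs[i] * hs[j])
        return (H + H.T) / 2.0

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "layer_sizes": self.layer_sizes,
            "feature_order": list(self.feature_order),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "shift": self.shift.tolist(),
            "scale": self.scale.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FeedforwardClassifier":
        with open(path) as fh:
            d = json.load(fh)
        return cls([np.array(w) for w in d["weights"]],
                   [np.array(b) for b in d["biases"]],
                   d["feature_order"], np.array(d["shift"]),
                   np.array(d["scale"]))


def activation_margin(model: FeedforwardClassifier, point,
                      cov: np.ndarray) -> float:
    """Distance from a point to the nearest ReLU kink, in perturbation SDs.

    For Gaussian perturbations with covariance ``cov`` (raw scale), each
    hidden unit's pre-activation moves with a linearized SD; the margin is
    the minimum over units of |pre-activation| / SD.  The second-order
    Taylor expansion is trustworthy only where this margin is large (the
    activation pattern is then stable over the perturbation support).
    """
    x = model.standardize(np.asarray(point, float).reshape(-1))
    C = np.asarray(cov, float) / np.outer(model.scale, model.scale)
    margin = np.inf
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        pre = x @ w + b
        sd = np.sqrt(np.maximum(np.einsum("ij,ik,kj->j", w, C, w), 1e-300))
        margin = min(margin, float(np.min(np.abs(pre) / sd)))
        mask = (pre > 0).astype(float)
        C = (w.T @ C @ w) * np.outer(mask, mask)
        x = np.maximum(pre, 0.0)
    return margin


def train_fnn(cohort: CohortTable | tuple,
              hyperparams: Hyperparams | None = None,
              seed: int = 0) -> FeedforwardClassifier:
    """Train the feedforward classifier with mini-batch SGD.

    Accepts a :class:`CohortTable` or an ``(X, y, feature_names)`` tuple.
    Fixed seed ⇒ identical weights.  Raises on a single-class cohort or on a
    diverging (NaN) loss.
    """
    hp = hyperparams or Hyperparams()
    if isinstance(cohort, CohortTable):
        X = cohort.features.to_numpy(dtype=float)
        y = cohort.outcome
        names = cohort.feature_names
    else:
        X, y, names = cohort
        X = np.asarray(X, float)
        y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort contains a single outcome class")
    rng = np.random.default_rng(seed)
    shift = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - shift) / scale
    sizes = [X.shape[1], *hp.hidden, 2]
    model = FeedforwardClassifier.random(sizes, seed=seed)
    model = FeedforwardClassifier(model.weights, model.biases, names,
                                  shift, scale)
    n = len(y)
    Y = np.eye(2)[y]
    for epoch in range(hp.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = perm[start:start + hp.batch_size]
            zb, yb = Z[idx], Y[idx]
            # forward
            acts = [zb]
            h = zb
            for w, b in zip(model.weights[:-1], model.biases[:-1]):
                h = np.maximum(h @ w + b, 0.0)
                acts.append(h)
            logits = h @ model.weights[-1] + model.biases[-1]
            p = _softmax(logits)
            eps = 1e-12
            epoch_loss += -np.sum(yb * np.log(p + eps))
            # backward
            delta = (p - yb) / len(idx)
            for layer in range(len(model.weights) - 1, -1, -1):
                gw = acts[layer].T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ model.weights[layer].T) * (acts[layer] > 0)
                model.weights[layer] -= hp.learning_rate * gw
                model.biases[layer] -= hp.learning_rate * gb
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={epoch_loss}"
            )
        model.loss_log.append(float(epoch_loss))
    return model


def predict_proba(model: FeedforwardClassifier, record) -> np.ndarray:
    """Class-probability pair for one record (16 raw features in order)."""
    record = np.asarray(record, float).reshape(-1)
    return model.predict_proba(record.reshape(1, -1))[0]


def output_hessian(model: FeedforwardClassifier, point, class_index: int,
                   **kw) -> np.ndarray:
    """Module-level alias for :meth:`FeedforwardClassifier.hessian`."""
    return model.hessian(point, class_index, **kw)


def evaluate(model: FeedforwardClassifier, cohort: CohortTable) -> Metrics:
    """Confusion-matrix metrics at the 0.5 threshold plus rank-based AUC."""
    if len(cohort) == 0:
        raise ValueError("empty test cohort")
    X = cohort.features.to_numpy(dtype=float)
    y = cohort.outcome
    p1 = model.predict_proba(X)[:, 1]
    yhat = (p1 >= 0.5).astype(int)
    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * sens / (prec + sens)) if (prec + sens) else 0.0
    if len(np.unique(y)) < 2:
        warnings.warn("single-class test set: AUC undefined")
        auc = float("nan")
    else:
        from sklearn.metrics import roc_auc_score
        auc = float(roc_auc_score(y, p1))
    return Metrics(accuracy=float(acc), sensitivity=float(sens),
                   specificity=float(spec), f1=float(f1), auc=auc)


def split_metrics(cohort: CohortTable, hyperparams: Hyperparams | None = None,
                  n_splits: int = 5, test_frac: float = 0.2,
                  seed: int = 0) -> dict[str, tuple[float, float]]:
    """Mean ± SD of each metric over random 80/20 train/test splits."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_splits):
        idx = rng.permutation(len(cohort))
        n_test = max(1, int(round(test_frac * len(cohort))))
        test_idx, train_idx = idx[:n_test], idx[n_test:]
        train = CohortTable(cohort.frame.iloc[train_idx].reset_index(drop=True),
                            cohort.specs)
        test = CohortTable(cohort.frame.iloc[test_idx].reset_index(drop=True),
                           cohort.specs)
        model = train_fnn(train, hyperparams, seed=int(rng.integers(2**31)))
        rows.append(dataclasses.asdict(evaluate(model, test)))
    out = {}
    for key in rows[0]:
        vals = np.array([r[key] for r in rows], float)
        out[key] = (float(vals.mean()), float(vals.std()))
    return out
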