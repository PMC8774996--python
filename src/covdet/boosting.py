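"""AdaBoost ensemble of back-propagation neural networks (AB_BP_NN).

Each weak learner is a small fully-connected network — two hidden layers of
nine cells (tangent-sigmoid then rectified-linear activations) and a single
pure-linear output node — trained by gradient back-propagation on a
sample-weighted squared-error loss, with early stopping on a held-out 15 %
validation slice of the training data.

The boosting loop maintains a distribution D over the M training examples.
After training learner i and binarising its output at 0.5:

* weighted error        ``E_i = Σ_j D_j · I(|y_j − ŷ_j|)``,
* learner weight        ``w_i = 1 / E_i``  (E floored at ε = 1e−6),
* distribution update   ``D_j ← D_j · (1 + δ · I(|y_j − ŷ_j|))`` then
  renormalised to sum 1,

where ``I(x) = 1 iff x > 0.2`` (strict).  The indicator argument is the
*absolute* label/prediction difference so both error directions upweight.
A learner with E ≥ 0.5 is discarded and the loop halts.  The ensemble
score is the normalised weighted mean of the learners' clamped outputs,
``Q = Σ (w_i/Σw) p_i ∈ [0, 1]``, thresholded at 0.5 by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import (DegenerateLabelError, InvalidArgumentError,
                         InvalidStateError)

logger = logging.getLogger("covdet")

DEFAULT_ERROR_THRESHOLD = 0.2
DEFAULT_DELTA = 1.0
DEFAULT_L = 10
ERROR_EPS = 1e-6


@dataclass
class BPNetworkConfig:
    """Geometry and training hyper-parameters of one weak network."""

    hidden: tuple[int, int] = (9, 9)
    learning_rate: float = 0.02
    max_epochs: int = 300
    patience: int = 30
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden):
            raise InvalidArgumentError("hidden sizes must be >= 1")
        if not (0 <= self.val_fraction < 1):
            raise InvalidArgumentError("val_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# Boosting arithmetic
# ---------------------------------------------------------------------------

def indicator(x: float, threshold: float = DEFAULT_ERROR_THRESHOLD) -> int:
    """Binary error indicator: 1 iff ``x > threshold`` (strict)."""
    if not np.isfinite(x):
        raise InvalidArgumentError("indicator argument must be finite")
    return 1 if x > threshold else 0


def _error_flags(y, y_pred, threshold: float = DEFAULT_ERROR_THRESHOLD) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise InvalidArgumentError("labels and predictions differ in length")
    return (np.abs(y - y_pred) > threshold).astype(float)


def update_distribution(D, y, y_pred, delta: float = DEFAULT_DELTA,
                        threshold: float = DEFAULT_ERROR_THRESHOLD) -> np.ndarray:
    """Upweight misclassified examples by ``(1 + δ)`` and renormalise."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise InvalidArgumentError("distribution entries must be >= 0")
    total = D.sum()
    if total <= 0:
        raise InvalidStateError("distribution sums to zero")
    out = D * (1.0 + delta * _error_flags(y, y_pred, threshold))
    return out / out.sum()


def ensemble_error(D, y, y_pred,
                   threshold: float = DEFAULT_ERROR_THRESHOLD) -> float:
    """D-weighted misclassification mass, in [0, 1] for normalised D."""
    D = np.asarray(D, dtype=float)
    flags = _error_flags(y, y_pred, threshold)
    if D.shape != flags.shape:
        raise InvalidArgumentError("distribution length mismatch")
    return float(np.abs(D * flags).sum())


def learner_weight(E: float, eps: float = ERROR_EPS) -> float:
    """Inverse-error weight ``w = 1/E``; E floored at ε so w stays finite."""
    if E < 0:
        raise InvalidArgumentError("error must be >= 0")
    if E < eps:
        logger.debug("learner error %g floored at eps=%g", E, eps)
        E = eps
    return 1.0 / E


def ensemble_score(predictions, weights) -> np.ndarray | float:
    """Normalised weighted score ``Q = Σ (w_i/Σw) p_i``.

    ``predictions`` is length-L (one scalar per learner) or ``L × n``.
    Q lies in [0, 1] whenever every p does (convex combination).
    """
    p = np.asarray(predictions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape[0] != w.shape[0] or w.size == 0:
        raise InvalidArgumentError("need one weight per learner")
    total = w.sum()
    if total <= 0:
        raise InvalidStateError("all-zero learner weights")
    q = np.tensordot(w / total, p, axes=1)
    return float(q) if np.ndim(q) == 0 else q


# ---------------------------------------------------------------------------
# The weak learner
# ---------------------------------------------------------------------------

def _relu(z):
    return np.maximum(z, 0.0)


class BPNetwork:
    """Two-hidden-layer back-propagation network with weighted MSE loss.

    Forward pass: ``tanh`` (tangent sigmoid) → ReLU → linear scalar output.
    Trained full-batch with Adam; early stopping restores the parameters of
    the best validation epoch.  Predictions are clamped to [0, 1].
    """

    def __init__(self, cfg: BPNetworkConfig | None = None):
        self.cfg = cfg or BPNetworkConfig()
        self.params_: dict[str, np.ndarray] | None = None

    # -- forward ------------------------------------------------------------
    def _forward(self, X, params):
        a1 = np.tanh(X @ params["W1"] + params["b1"])
        a2 = _relu(a1 @ params["W2"] + params["b2"])
        out = a2 @ params["W3"] + params["b3"]
        return a1, a2, out[:, 0]

    def predict_raw(self, X) -> np.ndarray:
        if self.params_ is None:
            raise InvalidStateError("network is not fitted")
        X = np.asarray(X, dtype=float)
        return self._forward(X, self.params_)[2]

    def predict_proba(self, X) -> np.ndarray:
        """Network output clamped to [0, 1]."""
        return np.clip(self.predict_raw(X), 0.0, 1.0)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # -- training -----------------------------------------------------------
    @staticmethod
    def _loss(out, y, w):
        return float(np.sum(w * (out - y) ** 2) / np.sum(w))

    def fit(self, X, y, sample_weight=None) -> "BPNetwork":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise InvalidArgumentError("X must be 2-D with one row per label")
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateLabelError("training set contains a single class")
        if not np.isin(classes, [0.0, 1.0]).all():
            raise InvalidArgumentError("labels must be binary 0/1")
        n, d = X.shape
        w = (np.full(n, 1.0 / n) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise InvalidArgumentError("invalid sample weights")
        w = w / w.sum()

        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)

        # stratified validation slice so both classes stay in training
        val_idx = []
        if cfg.val_fraction > 0:
            for cls in (0.0, 1.0):
                idx = np.flatnonzero(y == cls)
                n_val = int(round(cfg.val_fraction * idx.size))
                n_val = min(n_val, idx.size - 1)  # keep >=1 of each class to train
                if n_val > 0:
                    val_idx.extend(rng.permutation(idx)[:n_val])
        val_idx = np.array(sorted(val_idx), dtype=int)
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        Xt, yt, wt = X[train_mask], y[train_mask], w[train_mask]
        wt = wt / wt.sum()
        has_val = val_idx.size > 0
        if has_val:
            Xv, yv = X[val_idx], y[val_idx]
            wv = w[val_idx]
            wv = wv / wv.sum() if wv.sum() > 0 else np.full(val_idx.size, 1 / val_idx.size)

        h1, h2 = cfg.hidden
        params = {
            "W1": rng.normal(0, np.sqrt(1.0 / d), (d, h1)),
            "b1": np.zeros(h1),
            "W2": rng.normal(0, np.sqrt(2.0 / h1), (h1, h2)),
            "b2": np.zeros(h2),
            "W3": rng.normal(0, np.sqrt(1.0 / h2), (h2, 1)),
            "b3": np.zeros(1),
        }
        m_adam = {k: np.zeros_like(v) for k, v in params.items()}
        v_adam = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        best = {k: v.copy() for k, v in params.items()}
        best_loss = np.inf
        stall = 0
        for epoch in range(1, cfg.max_epochs + 1):
            a1, a2, out = self._forward(Xt, params)
            # gradient of sum_j w_j (out_j - y_j)^2  (weights pre-normalised)
            g_out = (2.0 * wt * (out - yt))[:, None]
            grads = {}
            grads["W3"] = a2.T @ g_out
            grads["b3"] = g_out.sum(axis=0)
            g_a2 = g_out @ params["W3"].T
            g_z2 = g_a2 * (a2 > 0)
            grads["W2"] = a1.T @ g_z2
            grads["b2"] = g_z2.sum(axis=0)
            g_a1 = g_z2 @ params["W2"].T
            g_z1 = g_a1 * (1.0 - a1 ** 2)
            grads["W1"] = Xt.T @ g_z1
            grads["b1"] = g_z1.sum(axis=0)

            for k in params:
                m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * grads[k]
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                mhat = m_adam[k] / (1 - beta1 ** epoch)
                vhat = v_adam[k] / (1 - beta2 ** epoch)
                params[k] = params[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

            if has_val:
                monitor = self._loss(self._forward(Xv, params)[2], yv, wv)
            else:
                monitor = self._loss(self._forward(Xt, params)[2], yt, wt)
            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best = {k: v.copy() for k, v in params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        self.params_ = best
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        if self.params_ is None:
            raise InvalidStateError("network is not fitted")
        return {"config": asdict(self.cfg),
                "params": {k: v.tolist() for k, v in self.params_.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "BPNetwork":
        cfg = d["config"].copy()
        cfg["hidden"] = tuple(cfg["hidden"])
        net = cls(BPNetworkConfig(**cfg))
        net.params_ = {k: np.asarray(v, dtype=float) for k, v in d["params"].items()}
        return net


def train_bp(X, y, cfg: BPNetworkConfig | None = None,
             sample_weights=None) -> BPNetwork:
    """Train one weak back-propagation network (functional wrapper)."""
    return BPNetwork(cfg).fit(X, y, sample_weight=sample_weights)


# ---------------------------------------------------------------------------
# The ensemble
# ---------------------------------------------------------------------------

@dataclass
class BoostedEnsemble:
    """Ordered weak networks with their errors and inverse-error weights."""

    learners: list[BPNetwork]
    weights: np.ndarray
    errors: np.ndarray
    decision_threshold: float = 0.5
    halted_early: bool = False

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    def predict_score(self, X) -> np.ndarray:
        """Q per example — normalised weighted mean of clamped outputs."""
        preds = np.stack([net.predict_proba(X) for net in self.learners])
        return ensemble_score(preds, self.weights)

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= self.decision_threshold).astype(int)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"format_version": 1,
                "learners": [net.to_dict() for net in self.learners],
                "weights": np.asarray(self.weights).tolist(),
                "errors": np.asarray(self.errors).tolist(),
                "decision_threshold": self.decision_threshold,
                "halted_early": self.halted_early}

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedEnsemble":
        return cls(learners=[BPNetwork.from_dict(x) for x in d["learners"]],
                   weights=np.asarray(d["weights"], dtype=float),
                   errors=np.asarray(d["errors"], dtype=float),
                   decision_threshold=d.get("decision_threshold", 0.5),
                   halted_early=d.get("halted_early", False))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BoostedEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_adaboost(X, y, L: int = DEFAULT_L, cfg: BPNetworkConfig | None = None,
                 delta: float = DEFAULT_DELTA, seed: int = 0,
                 error_threshold: float = DEFAULT_ERROR_THRESHOLD) -> BoostedEnsemble:
    """Train the boosted ensemble.

    Iterates: train a weak network on the D-weighted data → binarise its
    training predictions at 0.5 → weighted error E → weight w = 1/E →
    distribution update.  A learner with E ≥ 0.5 is discarded and the loop
    halts; if that happens to the very first learner it is retained with
    weight 1 so the ensemble stays usable (no-signal data).
    """
    if L < 1:
        raise InvalidArgumentError("L must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    M = y.size
    base_cfg = cfg or BPNetworkConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=L)

    D = np.full(M, 1.0 / M)
    learners: list[BPNetwork] = []
    weights: list[float] = []
    errors: list[float] = []
    halted = False
    for i in range(L):
        cfg_i = BPNetworkConfig(hidden=base_cfg.hidden,
                                learning_rate=base_cfg.learning_rate,
                                max_epochs=base_cfg.max_epochs,
                                patience=base_cfg.patience,
                                val_fraction=base_cfg.val_fraction,
                                seed=int(child_seeds[i]))
        net = BPNetwork(cfg_i).fit(X, y, sample_weight=D)
        y_pred = net.predict(X)
        E = ensemble_error(D, y, y_pred, error_threshold)
        if E >= 0.5:
            if not learners:
                logger.warning("first learner error %.3f >= 0.5; retained with weight 1", E)
                learners.append(net)
                weights.append(1.0)
                errors.append(E)
            else:
                logger.info("learner %d discarded (error %.3f >= 0.5); boosting halted", i, E)
            halted = True
            break
        learners.append(net)
        weights.append(learner_weight(E))
        errors.append(E)
        D = update_distribution(D, y, y_pred, delta, error_threshold)
    return BoostedEnsemble(learners=learners, weights=np.asarray(weights),
                           errors=np.asarray(errors), halted_early=halted)
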