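"""Data-driven half of the hybrid model.

A single-hidden-layer network (4 tanh neurons, linear output) maps
z-scored process inputs to the two specific rates (growth rate mu and
specific production rate v_px), and is trained by a damped
Levenberg-Marquardt loop with an L2 weight-decay penalty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np


@dataclass
class ScalerStats:
    """Per-input mean and standard deviation of the training set."""

    mean: np.ndarray
    std: np.ndarray
    names: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "mean": list(map(float, self.mean)),
            "std": list(map(float, self.std)),
            "names": self.names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerStats":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            names=d.get("names"),
        )


def fit_scaler(X: np.ndarray, names: Sequence[str] | None = None) -> ScalerStats:
    """Training-set z-score statistics.

    Raises ``ValueError`` naming the offending input if a column is
    (numerically) constant.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    for j, s in enumerate(std):
        if s <= 1e-12 * max(1.0, abs(mean[j])):
            label = names[j] if names is not None else f"column {j}"
            raise ValueError(f"constant input {label!r} cannot be z-scored")
    return ScalerStats(mean=mean, std=std, names=list(names) if names else None)


def apply_scaler(stats: ScalerStats, x: np.ndarray) -> np.ndarray:
    """z-score ``x`` (row vector or matrix) with training statistics."""
    return (np.asarray(x, dtype=float) - stats.mean) / stats.std


@dataclass
class Network:
    """1-hidden-layer tanh network with linear outputs.

    ``W_h`` has shape (n_hidden, n_inputs); ``W_o`` shape
    (n_outputs, n_hidden).  Outputs are (mu, v_px) in scaled rate units.
    """

    W_h: np.ndarray
    b_h: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray
    input_names: list[str] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.W_h.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_h.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W_o.shape[0]

    # -- weight vector helpers -------------------------------------------
    def get_weights(self) -> np.ndarray:
        return np.concatenate(
            [self.W_h.ravel(), self.b_h.ravel(), self.W_o.ravel(), self.b_o.ravel()]
        )

    def set_weights(self, w: np.ndarray) -> None:
        nh, ni, no = self.n_hidden, self.n_inputs, self.n_outputs
        k = 0
        self.W_h = w[k : k + nh * ni].reshape(nh, ni).copy(); k += nh * ni
        self.b_h = w[k : k + nh].copy(); k += nh
        self.W_o = w[k : k + no * nh].reshape(no, nh).copy(); k += no * nh
        self.b_o = w[k : k + no].copy(); k += no
        if k != len(w):
            raise ValueError(f"weight vector length {len(w)}, expected {k}")

    def copy(self) -> "Network":
        return Network(
            W_h=self.W_h.copy(), b_h=self.b_h.copy(),
            W_o=self.W_o.copy(), b_o=self.b_o.copy(),
            input_names=list(self.input_names),
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "W_h": self.W_h.tolist(),
            "b_h": self.b_h.tolist(),
            "W_o": self.W_o.tolist(),
            "b_o": self.b_o.tolist(),
            "input_names": self.input_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Network":
        return cls(
            W_h=np.asarray(d["W_h"], dtype=float),
            b_h=np.asarray(d["b_h"], dtype=float),
            W_o=np.asarray(d["W_o"], dtype=float),
            b_o=np.asarray(d["b_o"], dtype=float),
            input_names=list(d.get("input_names", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        return cls.from_dict(json.loads(Path(path).read_text()))


def init_network(
    seed: int,
    n_inputs: int = 6,
    n_hidden: int = 4,
    n_outputs: int = 2,
    input_names: Sequence[str] | None = None,
) -> Network:
    """Reproducible small random initialization (|w| <= 0.5).

    Small weights keep the tanh units in their near-linear regime at the
    start of training.
    """
    rng = np.random.default_rng(seed)
    return Network(
        W_h=rng.uniform(-0.5, 0.5, size=(n_hidden, n_inputs)),
        b_h=rng.uniform(-0.1, 0.1, size=n_hidden),
        W_o=rng.uniform(-0.5, 0.5, size=(n_outputs, n_hidden)),
        b_o=np.zeros(n_outputs),
        input_names=list(input_names) if input_names else [],
    )


def ann_forward(net: Network, x_scaled: np.ndarray) -> np.ndarray:
    """Forward pass; ``x_scaled`` is a vector or a (n, n_inputs) matrix.

    Returns the output vector (mu, v_px) in scaled rate units (or an
    (n, n_outputs) matrix for batched input).
    """
    x = np.asarray(x_scaled, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != net.n_inputs:
        raise ValueError(f"expected {net.n_inputs} inputs, got {x.shape[1]}")
    h = np.tanh(x @ net.W_h.T + net.b_h)
    out = h @ net.W_o.T + net.b_o
    return out[0] if single else out


@dataclass
class TrainConfig:
    """Levenberg-Marquardt settings.

    ``weight_decay`` is the L2 penalty coefficient added to the residual
    sum of squares; training stops after ``patience`` accepted steps
    without relative improvement better than ``min_improvement``, or at
    ``max_iter`` iterations.
    """

    damping_init: float = 1e-2
    damping_up: float = 10.0
    damping_down: float = 0.3
    weight_decay: float = 1e-4
    max_iter: int = 100
    patience: int = 5
    min_improvement: float = 1e-6
    max_escalations: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.damping_init <= 0:
            raise ValueError("damping_init must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def residual_jacobian(
    objective: Callable[[np.ndarray], np.ndarray],
    weights: np.ndarray,
    eps: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian d r / d w (shape n_res x n_w)."""
    w = np.asarray(weights, dtype=float)
    r0 = np.asarray(objective(w), dtype=float)
    if not np.all(np.isfinite(r0)):
        raise ValueError("objective returned non-finite residuals")
    J = np.empty((len(r0), len(w)))
    for j in range(len(w)):
        h = eps * max(1.0, abs(w[j]))
        wp = w.copy(); wp[j] += h
        wm = w.copy(); wm[j] -= h
        rp = np.asarray(objective(wp), dtype=float)
        rm = np.asarray(objective(wm), dtype=float)
        if not (np.all(np.isfinite(rp)) and np.all(np.isfinite(rm))):
            raise ValueError(f"objective returned non-finite residuals at weight {j}")
        J[:, j] = (rp - rm) / (2 * h)
    return J


def lm_minimize(
    objective: Callable[[np.ndarray], np.ndarray],
    w0: np.ndarray,
    cfg: TrainConfig,
    jac: Callable[[np.ndarray], np.ndarray] | None = None,
    callback: Callable[[int, np.ndarray, float], None] | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Damped Levenberg-Marquardt on ``objective`` with L2 weight decay.

    Minimizes ``||r(w)||^2 + weight_decay * ||w||^2``.  A step is accepted
    only if this penalized SSE decreases, otherwise the damping factor is
    raised.  Returns the best weights and the history of penalized SSE
    values over accepted steps (history[0] is the initial loss).

    ``callback(n_accepted, w, loss)`` is invoked after every accepted step
    (used by cross-validation to snapshot validation performance).
    """
    w = np.asarray(w0, dtype=float).copy()
    lam = cfg.weight_decay

    def penalized(r, wv):
        return float(r @ r + lam * (wv @ wv))

    r = np.asarray(objective(w), dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("objective returned non-finite residuals at initial weights")
    loss = penalized(r, w)
    history = [loss]
    if float(r @ r) <= 1e-30:
        return w, history  # already a perfect fit; nothing to do

    damping = cfg.damping_init
    stall = 0
    n_accepted = 0
    for _ in range(cfg.max_iter):
        J = jac(w) if jac is not None else residual_jacobian(objective, w)
        A = J.T @ J + lam * np.eye(len(w))
        g = J.T @ r + lam * w
        accepted = False
        for _esc in range(cfg.max_escalations):
            try:
                step = np.linalg.solve(A + damping * np.eye(len(w)), -g)
            except np.linalg.LinAlgError:
                damping *= cfg.damping_up
                continue
            w_new = w + step
            r_new = np.asarray(objective(w_new), dtype=float)
            if np.all(np.isfinite(r_new)):
                loss_new = penalized(r_new, w_new)
                if loss_new < loss:
                    rel = (loss - loss_new) / max(loss, 1e-300)
                    w, r, loss = w_new, r_new, loss_new
                    history.append(loss)
                    damping = max(damping * cfg.damping_down, 1e-12)
                    n_accepted += 1
                    accepted = True
                    if callback is not None:
                        callback(n_accepted, w, loss)
                    stall = stall + 1 if rel < cfg.min_improvement else 0
                    break
            damping *= cfg.damping_up
        if not accepted:
            if damping > 1e12:
                break  # converged: no descent direction at any damping
            stall += 1
        if stall >= cfg.patience:
            break
    return w, history


def train_lm(
    objective: Callable[[np.ndarray], np.ndarray],
    net: Network,
    cfg: TrainConfig,
    jac: Callable[[np.ndarray], np.ndarray] | None = None,
    callback: Callable[[int, np.ndarray, float], None] | None = None,
) -> tuple[Network, list[float]]:
    """Train ``net`` by Levenberg-Marquardt on ``objective`` (see lm_minimize).

    ``objective`` maps the flattened weight vector to a residual vector.
    Returns a trained copy of the network and the penalized-loss history.
    """
    w, history = lm_minimize(objective, net.get_weights(), cfg, jac=jac, callback=callback)
    trained = net.copy()
    trained.set_weights(w)
    return trained, history
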