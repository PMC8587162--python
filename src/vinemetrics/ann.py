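"""Shallow feedforward regression networks trained by damped Gauss–Newton.

The regression engine behind all four berry/wine models: one hidden layer of
tan-sigmoid units, a linear output layer, min-max scaling of inputs and
targets to [-1, 1], and two training algorithms implemented from scratch on
an analytic error Jacobian:

* Levenberg–Marquardt (LM) — damped Gauss–Newton on the sum of squared
  scaled errors, with validation-based early stopping;
* Bayesian regularization (BR) — LM on the regularized objective
  ``F = beta * E_D + alpha * E_W`` with MacKay evidence updates of
  ``alpha`` and ``beta`` after every accepted step (no validation set
  needed; the effective number of parameters ``gamma`` tracks how much of
  the network the data actually supports).

Internally ``E_D = 1/2 * sum(e^2)`` over scaled errors and
``E_W = 1/2 * sum(w^2)`` over all weights and biases, the convention under
which the evidence updates take their textbook form. With ``alpha`` pinned
at 0 (and ``beta`` at 1) BR reduces exactly to plain LM.

Model selection over hidden-layer sizes ("neuron trimming") trains one
network per candidate on a shared split and keeps the candidate with the
best overall correlation among those showing no under- or overfitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AffineScaler",
    "NetworkConfig",
    "Network",
    "SplitSpec",
    "TrainingResult",
    "TrimmingReport",
    "split_dataset",
    "forward",
    "error_jacobian",
    "train_levenberg_marquardt",
    "train_bayesian_regularization",
    "train",
    "neuron_trimming",
    "save_network",
    "load_network",
]

DEFAULT_NEURON_CANDIDATES = (3, 5, 7, 10)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class AffineScaler:
    """Per-feature min-max map onto [-1, 1]; constant features map to 0."""

    minimum: np.ndarray
    maximum: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "AffineScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return cls(minimum=X.min(axis=0), maximum=X.max(axis=0))

    @property
    def _span(self) -> np.ndarray:
        span = self.maximum - self.minimum
        return np.where(span == 0, 1.0, span)

    def scale(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(X, dtype=float) - self.minimum) / self._span - 1.0

    def unscale(self, Xs: np.ndarray) -> np.ndarray:
        return (np.asarray(Xs, dtype=float) + 1.0) / 2.0 * self._span + self.minimum


# ---------------------------------------------------------------------------
# configuration and network container
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    n_inputs: int
    n_hidden: int
    n_outputs: int
    algorithm: str = "levenberg_marquardt"  # or "bayesian_regularization"
    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_factor: float = 10.0
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    val_patience: int = 6  # LM only
    seed: int = 0
    alpha_fixed: Optional[float] = None  # pin BR's alpha (testing/ablation)

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.algorithm not in ("levenberg_marquardt", "bayesian_regularization"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class Network:
    """One-hidden-layer tanh network with affine input/target scaling."""

    W1: np.ndarray  # hidden x inputs
    b1: np.ndarray  # hidden
    W2: np.ndarray  # outputs x hidden
    b2: np.ndarray  # outputs
    input_scaler: AffineScaler
    target_scaler: AffineScaler

    @property
    def n_weights(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def flat(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    def set_flat(self, w: np.ndarray) -> None:
        h, i = self.W1.shape
        o = self.W2.shape[0]
        parts = np.split(w, np.cumsum([h * i, h, o * h])[:3])
        self.W1 = parts[0].reshape(h, i)
        self.b1 = parts[1].copy()
        self.W2 = parts[2].reshape(o, h)
        self.b2 = parts[3].copy()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return forward(self, X)


def _nguyen_widrow_init(config: NetworkConfig, input_scaler: AffineScaler,
                        target_scaler: AffineScaler) -> Network:
    """Seeded Nguyen–Widrow-style initialization for inputs in [-1, 1]."""
    rng = np.random.default_rng(config.seed)
    h, i, o = config.n_hidden, config.n_inputs, config.n_outputs
    magnitude = 0.7 * h ** (1.0 / i)
    W1 = rng.uniform(-0.5, 0.5, size=(h, i))
    norms = np.linalg.norm(W1, axis=1, keepdims=True)
    W1 = magnitude * W1 / np.where(norms == 0, 1.0, norms)
    b1 = magnitude * np.linspace(-1.0, 1.0, h) * np.sign(rng.uniform(-1, 1, h))
    W2 = rng.uniform(-0.5, 0.5, size=(o, h))
    b2 = rng.uniform(-0.5, 0.5, size=o)
    return Network(W1=W1, b1=b1, W2=W2, b2=b2,
                   input_scaler=input_scaler, target_scaler=target_scaler)


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Random train/validation/test partition of sample indices.

    Stage counts follow the convention that reproduces the published stage
    tables: validation and test counts are ``round(fraction * n)`` and
    training receives the remainder.
    """

    fractions: tuple[float, float, float]  # train, val, test
    seed: int = 0
    train_idx: Optional[np.ndarray] = None
    val_idx: Optional[np.ndarray] = None
    test_idx: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be non-negative")

    @property
    def counts(self) -> tuple[int, int, int]:
        return tuple(len(ix) for ix in (self.train_idx, self.val_idx, self.test_idx))

    @property
    def assignment(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for stage, idx in zip(("training", "validation", "testing"),
                              (self.train_idx, self.val_idx, self.test_idx)):
            for i in idx:
                out[int(i)] = stage
        return out


def split_dataset(n_samples: int, spec: SplitSpec) -> SplitSpec:
    """Seeded random partition of ``range(n_samples)`` by the split fractions."""
    if n_samples < 5:
        raise ValueError("need at least 5 samples to split")
    f_train, f_val, f_test = spec.fractions
    n_val = int(round(f_val * n_samples))
    n_test = int(round(f_test * n_samples))
    n_train = n_samples - n_val - n_test
    for frac, n in ((f_train, n_train), (f_val, n_val), (f_test, n_test)):
        if frac > 0 and n == 0:
            raise ValueError("a stage with positive fraction received no samples")
    perm = np.random.default_rng(spec.seed).permutation(n_samples)
    return SplitSpec(
        fractions=spec.fractions,
        seed=spec.seed,
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train:n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val:]),
    )


# ---------------------------------------------------------------------------
# forward pass and Jacobian
# ---------------------------------------------------------------------------

def forward(net: Network, X: np.ndarray) -> np.ndarray:
    """Predict in raw target units: unscale(W2 tanh(W1 scale(x) + b1) + b2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.W1.shape[1]:
        raise ValueError(f"expected {net.W1.shape[1]} input features, got {X.shape[1]}")
    Xs = net.input_scaler.scale(X)
    H = np.tanh(Xs @ net.W1.T + net.b1)
    Ys = H @ net.W2.T + net.b2
    return net.target_scaler.unscale(Ys)


def _forward_scaled(net: Network, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = np.tanh(Xs @ net.W1.T + net.b1)
    return H, H @ net.W2.T + net.b2


def error_jacobian(net: Network, Xs: np.ndarray, Ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled errors and their Jacobian w.r.t. the flattened weights.

    Errors are ``e = yhat_scaled - y_scaled`` flattened row-major over
    (sample, output); the Jacobian is exact (per-sample backpropagation),
    shape (n_samples * n_outputs, n_weights), ordered to match
    ``Network.flat()``.
    """
    n, _ = Xs.shape
    h = net.W1.shape[0]
    o = net.W2.shape[0]
    H, Yhat = _forward_scaled(net, Xs)
    e = (Yhat - Ys).ravel()

    dtanh = 1.0 - H ** 2                                  # n x h
    A = net.W2[None, :, :] * dtanh[:, None, :]            # n x o x h
    J_W1 = (A[:, :, :, None] * Xs[:, None, None, :]).reshape(n * o, h * Xs.shape[1])
    J_b1 = A.reshape(n * o, h)
    eye_o = np.eye(o)
    J_W2 = (eye_o[None, :, :, None] * H[:, None, None, :]).reshape(n * o, o * h)
    J_b2 = np.tile(eye_o, (n, 1))
    return e, np.hstack([J_W1, J_b1, J_W2, J_b2])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingResult:
    algorithm: str
    epochs: int
    stop_reason: str
    objective_trace: list[float]
    mse_train: float
    mse_val: Optional[float]
    mse_test: Optional[float]
    mu_final: float
    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    n_weights: int = 0
    warnings: list[str] = field(default_factory=list)


def _stage_mse(net: Network, X: np.ndarray, Y: np.ndarray,
               idx: Optional[np.ndarray]) -> Optional[float]:
    if idx is None or len(idx) == 0:
        return None
    pred = forward(net, X[idx])
    return float(np.mean((pred - Y[idx]) ** 2))


def _prepare(data, spec: SplitSpec, config: NetworkConfig):
    X, Y = data
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have equal sample counts")
    if spec.train_idx is None:
        spec = split_dataset(X.shape[0], spec)
    in_scaler = AffineScaler.fit(X[spec.train_idx])
    out_scaler = AffineScaler.fit(Y[spec.train_idx])
    net = _nguyen_widrow_init(config, in_scaler, out_scaler)
    return X, Y, spec, net


def _lm_core(net: Network, Xs_tr, Ys_tr, config: NetworkConfig,
             alpha: float, beta: float, adapt_hyper: bool,
             val_pack=None):
    """Damped Gauss–Newton on F = beta*E_D + alpha*E_W.

    E_D = 1/2 sum(e^2) over scaled training errors, E_W = 1/2 sum(w^2).
    With adapt_hyper, MacKay evidence updates of (alpha, beta, gamma) run
    after every accepted step. With a validation pack (LM), training stops
    after ``val_patience`` consecutive validation-MSE increases and the
    best-validation weights are restored.
    """
    N = Xs_tr.shape[0] * Ys_tr.shape[1]
    Nw = net.n_weights
    mu = config.mu_init
    gamma = float(Nw)
    warns: list[str] = []
    trace: list[float] = []

    def objective(w_flat):
        net.set_flat(w_flat)
        e, J = error_jacobian(net, Xs_tr, Ys_tr)
        E_D = 0.5 * float(e @ e)
        E_W = 0.5 * float(w_flat @ w_flat)
        return e, J, E_D, E_W

    w = net.flat()
    e, J, E_D, E_W = objective(w)
    F = beta * E_D + alpha * E_W
    stop = "max_epochs"
    epoch = 0

    best_val = np.inf
    best_w = w.copy()
    val_increases = 0
    prev_val = np.inf

    for epoch in range(1, config.max_epochs + 1):
        grad = beta * (J.T @ e) + alpha * w
        if np.max(np.abs(grad)) < config.grad_tol:
            stop = "gradient"
            break
        H_gn = beta * (J.T @ J) + alpha * np.eye(Nw)
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(H_gn + mu * np.eye(Nw), -grad)
            except np.linalg.LinAlgError:
                mu *= config.mu_factor
                continue
            w_try = w + delta
            e_t, J_t, E_D_t, E_W_t = objective(w_try)
            F_try = beta * E_D_t + alpha * E_W_t
            if F_try < F:
                w, e, J, E_D, E_W, F = w_try, e_t, J_t, E_D_t, E_W_t, F_try
                mu = max(mu / config.mu_factor, 1e-20)
                accepted = True
                break
            mu *= config.mu_factor
        if not accepted:
            net.set_flat(w)
            stop = "mu_max"
            break
        trace.append(F)

        if adapt_hyper:
            H_map = beta * (J.T @ J) + max(alpha, 1e-300) * np.eye(Nw)
            try:
                tr_Hinv = float(np.trace(np.linalg.inv(H_map)))
            except np.linalg.LinAlgError:
                tr_Hinv = float(np.trace(np.linalg.pinv(H_map)))
            # gamma = sum of beta*lam/(beta*lam + alpha) over Hessian
            # eigenvalues: the effective number of well-determined weights;
            # bounded by rank(J) <= number of error terms
            gamma = float(np.clip(Nw - alpha * tr_Hinv, 0.0, min(Nw, N)))
            if E_W <= 0 and gamma > 0:
                alpha = 1e10
                warns.append("zero weight norm with positive gamma; alpha capped")
            else:
                alpha = gamma / (2.0 * E_W) if E_W > 0 else 0.0
            beta = max((N - gamma) / (2.0 * E_D), 1e-12) if E_D > 0 else 1.0
            F = beta * E_D + alpha * E_W

        if val_pack is not None:
            Xval, Yval = val_pack
            net.set_flat(w)
            e_val = _forward_scaled(net, Xval)[1] - Yval
            val_mse = float(np.mean(e_val ** 2))
            if val_mse < best_val:
                best_val = val_mse
                best_w = w.copy()
            if val_mse > prev_val:
                val_increases += 1
                if val_increases >= config.val_patience:
                    stop = "validation"
                    break
            else:
                val_increases = 0
            prev_val = val_mse
    else:
        stop = "max_epochs"

    if val_pack is not None and np.isfinite(best_val):
        w = best_w
    net.set_flat(w)
    return epoch, stop, trace, mu, alpha, beta, gamma, warns


def train_levenberg_marquardt(data, spec: SplitSpec, config: NetworkConfig):
    """LM training with validation-based early stopping. Returns (net, result)."""
    if config.algorithm != "levenberg_marquardt":
        raise ValueError("config.algorithm must be 'levenberg_marquardt'")
    X, Y, spec, net = _prepare(data, spec, config)
    Xs = net.input_scaler.scale(X)
    Ys = net.target_scaler.scale(Y)
    val_pack = None
    if spec.val_idx is not None and len(spec.val_idx):
        val_pack = (Xs[spec.val_idx], Ys[spec.val_idx])
    epochs, stop, trace, mu, *_, warns = _lm_core(
        net, Xs[spec.train_idx], Ys[spec.train_idx], config,
        alpha=0.0, beta=1.0, adapt_hyper=False, val_pack=val_pack)
    result = TrainingResult(
        algorithm="levenberg_marquardt", epochs=epochs, stop_reason=stop,
        objective_trace=trace, mu_final=mu,
        mse_train=_stage_mse(net, X, Y, spec.train_idx),
        mse_val=_stage_mse(net, X, Y, spec.val_idx),
        mse_test=_stage_mse(net, X, Y, spec.test_idx),
        n_weights=net.n_weights, warnings=warns)
    return net, result


def train_bayesian_regularization(data, spec: SplitSpec, config: NetworkConfig):
    """BR training (no validation set). Returns (net, result)."""
    if config.algorithm != "bayesian_regularization":
        raise ValueError("config.algorithm must be 'bayesian_regularization'")
    X, Y, spec, net = _prepare(data, spec, config)
    Xs = net.input_scaler.scale(X)
    Ys = net.target_scaler.scale(Y)
    fixed = config.alpha_fixed is not None
    alpha0 = config.alpha_fixed if fixed else 0.0
    epochs, stop, trace, mu, alpha, beta, gamma, warns = _lm_core(
        net, Xs[spec.train_idx], Ys[spec.train_idx], config,
        alpha=alpha0, beta=1.0, adapt_hyper=not fixed, val_pack=None)
    result = TrainingResult(
        algorithm="bayesian_regularization", epochs=epochs, stop_reason=stop,
        objective_trace=trace, mu_final=mu,
        mse_train=_stage_mse(net, X, Y, spec.train_idx),
        mse_val=_stage_mse(net, X, Y, spec.val_idx),
        mse_test=_stage_mse(net, X, Y, spec.test_idx),
        alpha=alpha, beta=beta, gamma=gamma,
        n_weights=net.n_weights, warnings=warns)
    return net, result


def train(data, spec: SplitSpec, config: NetworkConfig):
    if config.algorithm == "levenberg_marquardt":
        return train_levenberg_marquardt(data, spec, config)
    return train_bayesian_regularization(data, spec, config)


# ---------------------------------------------------------------------------
# neuron trimming (hidden-layer size selection)
# ---------------------------------------------------------------------------

@dataclass
class TrimmingCandidate:
    n_hidden: int
    overall_r: float
    mse_train: float
    mse_val: Optional[float]
    mse_test: Optional[float]
    admissible: bool
    network: Network
    result: TrainingResult


@dataclass
class TrimmingReport:
    candidates: list[TrimmingCandidate]
    selected: int
    criterion_trace: list[str]

    @property
    def best(self) -> TrimmingCandidate:
        return next(c for c in self.candidates if c.n_hidden == self.selected)


def neuron_trimming(data, spec: SplitSpec, config: NetworkConfig,
                    candidates: Sequence[int] = DEFAULT_NEURON_CANDIDATES) -> TrimmingReport:
    """Train one network per hidden-layer size and pick the best honest one.

    A candidate is admissible when its training MSE does not exceed its test
    MSE (no overfitting) and, when a validation stage exists, validation and
    test MSE agree within 25%. Among admissible candidates the one with the
    highest overall Pearson correlation wins, compared at the two-decimal
    precision such models are reported at, so candidates whose R differs
    only in the third decimal count as tied; ties break toward fewer
    neurons. If nothing is admissible the best-R candidate is returned,
    flagged.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    X, Y = data
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if spec.train_idx is None:
        spec = split_dataset(X.shape[0], spec)

    out: list[TrimmingCandidate] = []
    trace: list[str] = []
    for h in sorted(candidates):
        cfg = NetworkConfig(**{**config.__dict__, "n_hidden": h})
        net, res = train((X, Y), spec, cfg)
        pred = forward(net, X)
        r = _pearson(pred.ravel(), Y.ravel())
        admissible = res.mse_train <= res.mse_test if res.mse_test is not None else True
        if admissible and res.mse_val is not None and res.mse_test:
            admissible = abs(res.mse_val - res.mse_test) <= 0.25 * res.mse_test
        trace.append(f"n_hidden={h}: R={r:.4f} mse_train={res.mse_train:.4g} "
                     f"mse_val={res.mse_val} mse_test={res.mse_test} "
                     f"admissible={admissible}")
        out.append(TrimmingCandidate(h, r, res.mse_train, res.mse_val,
                                     res.mse_test, admissible, net, res))
    pool = [c for c in out if c.admissible] or out
    if not any(c.admissible for c in out):
        trace.append("no admissible candidate; returning best-R, flagged")
    # R compared at printed precision; ties toward fewer neurons
    best = max(pool, key=lambda c: (round(c.overall_r, 2), -c.n_hidden))
    return TrimmingReport(candidates=out, selected=best.n_hidden, criterion_trace=trace)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_network(net: Network, path: str | Path,
                 config: Optional[NetworkConfig] = None,
                 result: Optional[TrainingResult] = None) -> None:
    blob = {
        "W1": net.W1.tolist(), "b1": net.b1.tolist(),
        "W2": net.W2.tolist(), "b2": net.b2.tolist(),
        "input_scaler": {"min": net.input_scaler.minimum.tolist(),
                         "max": net.input_scaler.maximum.tolist()},
        "target_scaler": {"min": net.target_scaler.minimum.tolist(),
                          "max": net.target_scaler.maximum.tolist()},
    }
    if config is not None:
        blob["config"] = dict(config.__dict__)
    if result is not None:
        blob["diagnostics"] = {k: v for k, v in result.__dict__.items()
                               if k != "objective_trace"}
    Path(path).write_text(json.dumps(blob, indent=1))


def load_network(path: str | Path) -> Network:
    blob = json.loads(Path(path).read_text())
    return Network(
        W1=np.array(blob["W1"]), b1=np.array(blob["b1"]),
        W2=np.array(blob["W2"]), b2=np.array(blob["b2"]),
        input_scaler=AffineScaler(np.array(blob["input_scaler"]["min"]),
                                  np.array(blob["input_scaler"]["max"])),
        target_scaler=AffineScaler(np.array(blob["target_scaler"]["min"]),
                                   np.array(blob["target_scaler"]["max"])),
    )
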