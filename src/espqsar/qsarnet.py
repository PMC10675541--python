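"""Sigmoid feed-forward network mapping ESP descriptor scores to pIC50.

The model is an N x M x 1 fully connected network with logistic
activations and no bias terms:

    H_i = sgm( sum_k w_ki I_k ),    O = sgm( sum_i w_i H_i )

Experimental pIC50 values are min-max normalized to [0, 1] using the
training set's bounds; the training objective is the plain sum of squared
errors F = sum_j (D_j - O_j)^2 over the training molecules, minimized by
full-batch gradient descent with analytic backpropagation gradients.
Training stops when F drops to the convergence tolerance (default 1e-4)
or the iteration cap is reached.

Because the output unit is a sigmoid rescaled by the training bounds,
predictions always fall strictly inside (act_min, act_max) — an explicit
range limitation of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ANNModel",
    "TrainingRecord",
    "sigmoid",
    "normalize_activity",
    "denormalize_activity",
    "forward",
    "loss",
    "gradients",
    "train",
    "predict_pic50",
    "save_model",
    "load_model",
]


def sigmoid(x):
    """Logistic function 1/(1+exp(-x)), overflow-safe for any finite x."""
    return expit(x)


@dataclass
class ANNModel:
    """Weights and normalization bounds of a trained N x M x 1 network."""

    w_in: np.ndarray    # (N, M)
    w_out: np.ndarray   # (M,)
    act_min: float
    act_max: float
    seed: int = 0
    final_F: float = np.nan
    iterations: int = 0

    def __post_init__(self):
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_in.ndim != 2 or self.w_out.ndim != 1:
            raise ValueError("w_in must be (N, M) and w_out (M,)")
        if self.w_in.shape[1] != self.w_out.shape[0]:
            raise ValueError("hidden widths of w_in and w_out disagree")
        if not (np.all(np.isfinite(self.w_in)) and np.all(np.isfinite(self.w_out))):
            raise ValueError("weights must be finite")
        if not self.act_max > self.act_min:
            raise ValueError("act_max must exceed act_min")

    @property
    def n_in(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]


@dataclass
class TrainingRecord:
    """Loss trace and stopping information of one training run."""

    F_history: np.ndarray
    converged: bool
    stop_reason: str  # "tolerance" | "max_iter"

    @property
    def final_F(self) -> float:
        return float(self.F_history[-1])


def normalize_activity(values, act_min: float, act_max: float) -> np.ndarray:
    """Min-max map to [0,1] with training-set bounds; values outside the
    bounds (test-set extrapolation) map outside [0,1] and are not clipped."""
    if not act_max > act_min:
        raise ValueError("degenerate activity bounds (act_max == act_min)")
    return (np.asarray(values, dtype=float) - act_min) / (act_max - act_min)


def denormalize_activity(values, act_min: float, act_max: float) -> np.ndarray:
    return np.asarray(values, dtype=float) * (act_max - act_min) + act_min


def _forward_batch(w_in, w_out, X):
    H = expit(X @ w_in)          # (n, M)
    O = expit(H @ w_out)         # (n,)
    return H, O


def forward(model: ANNModel, input: np.ndarray) -> float | np.ndarray:
    """Normalized network output in (0,1) for one N-vector or an (n,N) batch."""
    X = np.asarray(input, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_in:
        raise ValueError(f"input width {X.shape[1]} != network N={model.n_in}")
    _, O = _forward_batch(model.w_in, model.w_out, X)
    return float(O[0]) if single else O


def loss(model: ANNModel, inputs: np.ndarray, targets_norm: np.ndarray) -> float:
    """Sum of squared errors F over the given samples (normalized scale)."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    D = np.asarray(targets_norm, dtype=float)
    if X.shape[0] != D.shape[0]:
        raise ValueError("inputs and targets disagree in sample count")
    _, O = _forward_batch(model.w_in, model.w_out, X)
    return float(np.sum((D - O) ** 2))


def gradients(w_in, w_out, X, D):
    """Analytic dF/dw for F = sum (D - O)^2 with logistic layers, no biases."""
    H, O = _forward_batch(w_in, w_out, X)
    dO = -2.0 * (D - O) * O * (1.0 - O)       # (n,)
    g_out = H.T @ dO                           # (M,)
    dH = np.outer(dO, w_out) * H * (1.0 - H)   # (n, M)
    g_in = X.T @ dH                            # (N, M)
    F = float(np.sum((D - O) ** 2))
    return g_in, g_out, F


def train(
    inputs: np.ndarray,
    pic50: np.ndarray,
    n_hidden: int = 35,
    seed: int = 0,
    lr: float = 0.1,
    max_iter: int = 200_000,
    tol: float = 1e-4,
    momentum: float = 0.0,
    adaptive_lr: bool = False,
    record_history: bool = True,
) -> tuple[ANNModel, TrainingRecord]:
    """Train the network on raw pIC50 targets.

    Activities are normalized with the training set's min/max; weights are
    initialized uniformly in [-0.5, 0.5] from ``seed``. Optimization is
    full-batch gradient descent, optionally with momentum, or — with
    ``adaptive_lr`` — an accept/reject step-size schedule (grow the rate on
    improvement, halve it and revert on worsening) that keeps the loss
    non-increasing over accepted steps.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(pic50, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("inputs and pic50 disagree in sample count")
    act_min, act_max = float(y.min()), float(y.max())
    D = normalize_activity(y, act_min, act_max)
    n, N = X.shape
    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5, 0.5, size=(N, n_hidden))
    w_out = rng.uniform(-0.5, 0.5, size=n_hidden)

    v_in = np.zeros_like(w_in)
    v_out = np.zeros_like(w_out)
    history = [] if record_history else None
    g_in, g_out, F = gradients(w_in, w_out, X, D)
    if not np.isfinite(F):
        raise FloatingPointError("non-finite loss at initialization")
    step = lr
    it = 0
    stop_reason = "max_iter"
    while it < max_iter:
        it += 1
        if adaptive_lr:
            new_in = w_in - step * g_in
            new_out = w_out - step * g_out
            ng_in, ng_out, newF = gradients(new_in, new_out, X, D)
            if np.isfinite(newF) and newF <= F:
                w_in, w_out = new_in, new_out
                g_in, g_out, F = ng_in, ng_out, newF
                step *= 1.1
            else:
                step *= 0.5
                if step < 1e-300:
                    stop_reason = "max_iter"
                    break
        else:
            v_in = momentum * v_in - step * g_in
            v_out = momentum * v_out - step * g_out
            w_in = w_in + v_in
            w_out = w_out + v_out
            g_in, g_out, F = gradients(w_in, w_out, X, D)
            if not np.isfinite(F):
                raise FloatingPointError(
                    f"non-finite loss at iteration {it}; reduce the learning rate"
                )
        if history is not None:
            history.append(F)
        if F <= tol:
            stop_reason = "tolerance"
            break
    if history is None or not history:
        history = [F]
    converged = stop_reason == "tolerance"
    model = ANNModel(
        w_in=w_in,
        w_out=w_out,
        act_min=act_min,
        act_max=act_max,
        seed=seed,
        final_F=F,
        iterations=it,
    )
    record = TrainingRecord(
        F_history=np.asarray(history), converged=converged, stop_reason=stop_reason
    )
    return model, record


def predict_pic50(model: ANNModel, pca, descriptor: np.ndarray):
    """Denormalized pIC50 prediction for a raw ESP K-vector (or a stack).

    The descriptor is projected with the PCA model fitted on the same
    training subset; components orthogonal to the PCA subspace cannot
    influence the prediction.
    """
    from .descriptors import pca_project

    scores = pca_project(pca, descriptor)
    if scores.shape[-1] != model.n_in:
        raise ValueError(
            f"PCA width {scores.shape[-1]} != network input width {model.n_in}"
        )
    out = forward(model, scores)
    return denormalize_activity(out, model.act_min, model.act_max)


def save_model(model: ANNModel, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("w_in", data=model.w_in)
        fh.create_dataset("w_out", data=model.w_out)
        fh.attrs["act_min"] = model.act_min
        fh.attrs["act_max"] = model.act_max
        fh.attrs["seed"] = model.seed
        fh.attrs["final_F"] = model.final_F
        fh.attrs["iterations"] = model.iterations


def load_model(path) -> ANNModel:
    import h5py

    with h5py.File(path, "r") as fh:
        return ANNModel(
            w_in=fh["w_in"][...],
            w_out=fh["w_out"][...],
            act_min=float(fh.attrs["act_min"]),
            act_max=float(fh.attrs["act_max"]),
            seed=int(fh.attrs["seed"]),
            final_F=float(fh.attrs["final_F"]),
            iterations=int(fh.attrs["iterations"]),
        )
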