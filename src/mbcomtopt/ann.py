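"""A small feed-forward network trained by Levenberg-Marquardt.

The response-surface model of the induction study is a fully connected
3-input / 2-hidden / 1-output network (11 free parameters): hyperbolic-
tangent sigmoid hidden units and a linear output unit.  Inputs and the
response are min-max scaled to [-1, +1] from the calibration data before
training; predictions are mapped back to natural units (nmol/h/mg protein).

Training minimizes the sum of squared errors on the scaled response with a
damped Gauss-Newton (Levenberg-Marquardt) iteration,

    (J^T J + lambda I) delta = J^T r,

where a step is accepted only if the SSE decreases.  On acceptance the
damping ``lambda`` is divided by ``damping_decrease_ratio``; on rejection it
is multiplied by ``rate_increase_ratio`` and the step retried.  The fit is
nonconvex, so the public entry point is a seeded multi-restart that keeps
the restart with the lowest SSE.

The hot loop is compiled with numba; parameters are stored flat in the order
[hidden weights row-major, hidden biases, output weights, output bias].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "NetworkParams",
    "ScalingSpec",
    "TrainingConfig",
    "FitResult",
    "n_parameters",
    "forward",
    "jacobian",
    "train_lm",
    "multistart_fit",
    "ANNSurfaceRegressor",
    "save_fit",
    "load_fit",
]

LAMBDA_MAX = 1e10


def n_parameters(n_inputs: int, n_hidden: int, n_outputs: int = 1) -> int:
    """Free-parameter count of a (i/h/o) one-hidden-layer network:
    (i+1)*h weights+biases into the hidden layer plus (h+1)*o out of it."""
    return (n_inputs + 1) * n_hidden + (n_hidden + 1) * n_outputs


@dataclass(frozen=True)
class NetworkParams:
    """Weights of the one-hidden-layer tanh/linear network."""

    hidden_weights: np.ndarray  # (h, k)
    hidden_biases: np.ndarray  # (h,)
    output_weights: np.ndarray  # (h,)
    output_bias: float

    def __post_init__(self) -> None:
        W = np.asarray(self.hidden_weights, dtype=float)
        b = np.asarray(self.hidden_biases, dtype=float)
        v = np.asarray(self.output_weights, dtype=float)
        if W.ndim != 2:
            raise ValueError("hidden_weights must be a 2-D matrix")
        h = W.shape[0]
        if b.shape != (h,) or v.shape != (h,):
            raise ValueError("bias/output-weight shapes inconsistent with hidden_weights")
        object.__setattr__(self, "hidden_weights", W)
        object.__setattr__(self, "hidden_biases", b)
        object.__setattr__(self, "output_weights", v)
        object.__setattr__(self, "output_bias", float(self.output_bias))
        if not (
            np.all(np.isfinite(W))
            and np.all(np.isfinite(b))
            and np.all(np.isfinite(v))
            and np.isfinite(self.output_bias)
        ):
            raise ValueError("network parameters must be finite")

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_free(self) -> int:
        return n_parameters(self.n_inputs, self.n_hidden)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.hidden_weights.ravel(),
                self.hidden_biases,
                self.output_weights,
                [self.output_bias],
            ]
        )

    @classmethod
    def from_vector(
        cls, p: np.ndarray, n_inputs: int, n_hidden: int
    ) -> "NetworkParams":
        p = np.asarray(p, dtype=float)
        if p.shape != (n_parameters(n_inputs, n_hidden),):
            raise ValueError(
                f"expected {n_parameters(n_inputs, n_hidden)} parameters, "
                f"got {p.shape}"
            )
        hk = n_hidden * n_inputs
        return cls(
            hidden_weights=p[:hk].reshape(n_hidden, n_inputs).copy(),
            hidden_biases=p[hk : hk + n_hidden].copy(),
            output_weights=p[hk + n_hidden : hk + 2 * n_hidden].copy(),
            output_bias=float(p[-1]),
        )


@dataclass(frozen=True)
class ScalingSpec:
    """Min-max bounds mapping inputs and response into [-1, +1]."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        x_min = np.asarray(self.x_min, dtype=float)
        x_max = np.asarray(self.x_max, dtype=float)
        object.__setattr__(self, "x_min", x_min)
        object.__setattr__(self, "x_max", x_max)
        object.__setattr__(self, "y_min", float(self.y_min))
        object.__setattr__(self, "y_max", float(self.y_max))
        if np.any(x_max <= x_min) or self.y_max <= self.y_min:
            raise ValueError("scaling requires max > min for every variable")

    @classmethod
    def from_data(cls, X: np.ndarray, y: np.ndarray) -> "ScalingSpec":
        """Bounds from calibration data; a zero-range variable is padded by
        0.5 on each side so it maps to the midpoint 0."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        x_min, x_max = X.min(axis=0).copy(), X.max(axis=0).copy()
        flat = x_max - x_min <= 0
        x_min[flat] -= 0.5
        x_max[flat] += 0.5
        y_min, y_max = float(y.min()), float(y.max())
        if y_max - y_min <= 0:
            y_min -= 0.5
            y_max += 0.5
        return cls(x_min, x_max, y_min, y_max)

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(X, float) - self.x_min) / (self.x_max - self.x_min) - 1.0

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(y, float) - self.y_min) / (self.y_max - self.y_min) - 1.0

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return (np.asarray(ys, float) + 1.0) / 2.0 * (self.y_max - self.y_min) + self.y_min


@dataclass(frozen=True)
class TrainingConfig:
    """Levenberg-Marquardt settings.

    ``learning_rate`` is the initial damping lambda and
    ``rate_increase_ratio`` the multiplier applied on every rejected step
    (the values used in the induction study, 0.01 and 1.05);
    ``damping_decrease_ratio`` divides lambda on accepted steps.
    ``sse_tolerance`` stops the iteration once an accepted step improves the
    scaled SSE by less than this amount; ``gradient_tolerance`` stops it on
    a small gradient norm.
    """

    max_epochs: int = 1000
    learning_rate: float = 0.01
    rate_increase_ratio: float = 1.05
    damping_decrease_ratio: float = 10.0
    sse_tolerance: float = 1e-12
    gradient_tolerance: float = 1e-8
    n_restarts: int = 200
    seed: int = 0
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.rate_increase_ratio <= 1 or self.damping_decrease_ratio <= 1:
            raise ValueError("damping ratios must be > 1")
        if self.sse_tolerance <= 0 or self.gradient_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.learning_rate <= 0 or self.init_scale <= 0:
            raise ValueError("learning_rate and init_scale must be > 0")


@dataclass(frozen=True)
class FitResult:
    """A trained network together with everything needed to reproduce any
    prediction bit-exactly."""

    params: NetworkParams
    scaling: ScalingSpec
    sse: float
    epochs_run: int
    converged: bool
    restart_index: int = 0
    config: TrainingConfig | None = None

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return forward(self.params, self.scaling, X)


# ---------------------------------------------------------------------------
# numba kernels (flat parameter vector, scaled space)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_scaled(p, Xs, h):
    n, k = Xs.shape
    out = np.empty(n)
    for i in range(n):
        s = p[h * k + 2 * h]
        for j in range(h):
            a = p[h * k + j]
            for m in range(k):
                a += p[j * k + m] * Xs[i, m]
            s += p[h * k + h + j] * np.tanh(a)
        out[i] = s
    return out


@njit(cache=True)
def _jacobian_scaled(p, Xs, h):
    n, k = Xs.shape
    P = h * k + 2 * h + 1
    J = np.empty((n, P))
    for i in range(n):
        for j in range(h):
            a = p[h * k + j]
            for m in range(k):
                a += p[j * k + m] * Xs[i, m]
            t = np.tanh(a)
            dt = 1.0 - t * t
            v = p[h * k + h + j]
            for m in range(k):
                J[i, j * k + m] = v * dt * Xs[i, m]
            J[i, h * k + j] = v * dt
            J[i, h * k + h + j] = t
        J[i, P - 1] = 1.0
    return J


@njit(cache=True)
def _solve(A, b):
    """Gaussian elimination with partial pivoting; returns (x, ok)."""
    n = A.shape[0]
    M = np.empty((n, n + 1))
    M[:, :n] = A
    M[:, n] = b
    for col in range(n):
        piv = col
        big = abs(M[col, col])
        for r in range(col + 1, n):
            if abs(M[r, col]) > big:
                big = abs(M[r, col])
                piv = r
        if big < 1e-300 or not np.isfinite(big):
            return np.zeros(n), False
        if piv != col:
            for c in range(col, n + 1):
                tmp = M[col, c]
                M[col, c] = M[piv, c]
                M[piv, c] = tmp
        for r in range(col + 1, n):
            f = M[r, col] / M[col, col]
            for c in range(col, n + 1):
                M[r, c] -= f * M[col, c]
    x = np.empty(n)
    for r in range(n - 1, -1, -1):
        s = M[r, n]
        for c in range(r + 1, n):
            s -= M[r, c] * x[c]
        x[r] = s / M[r, r]
    return x, True


@njit(cache=True)
def _grad_norm(p, Xs, ys, h):
    r = ys - _forward_scaled(p, Xs, h)
    g = _jacobian_scaled(p, Xs, h).T @ r
    gn = 0.0
    for q in range(g.shape[0]):
        gn += g[q] * g[q]
    return np.sqrt(gn)


@njit(cache=True)
def _train_lm_kernel(
    p0, Xs, ys, h, max_epochs, lam0, up, down, gtol, stol, lam_max, trace
):
    """LM loop; ``trace`` (length >= max_epochs + 1) receives the accepted
    SSE sequence, trace[0] being the initial SSE.  Returns
    (params, sse, epochs, converged, n_trace)."""
    P = p0.shape[0]
    p = p0.copy()
    lam = lam0
    r = ys - _forward_scaled(p, Xs, h)
    sse = r @ r
    trace[0] = sse
    n_trace = 1
    eye = np.eye(P)
    epochs = 0
    overflow = False
    for _ in range(max_epochs):
        epochs += 1
        J = _jacobian_scaled(p, Xs, h)
        g = J.T @ r
        gn = 0.0
        for q in range(P):
            gn += g[q] * g[q]
        if np.sqrt(gn) < gtol:
            break
        JTJ = J.T @ J
        accepted = False
        drop = 0.0
        while True:
            d, ok = _solve(JTJ + lam * eye, g)
            if ok:
                for q in range(P):
                    if not np.isfinite(d[q]):
                        ok = False
                        break
            if ok:
                pn = p + d
                rn = ys - _forward_scaled(pn, Xs, h)
                ssen = rn @ rn
                if np.isfinite(ssen) and ssen < sse:
                    drop = sse - ssen
                    p = pn
                    r = rn
                    sse = ssen
                    lam /= down
                    accepted = True
                    break
            lam *= up
            if lam > lam_max:
                overflow = True
                break
        if not accepted:
            # damping overflowed: no descent direction found from here
            break
        trace[n_trace] = sse
        n_trace += 1
        if drop < stol:
            break
    # "converged" means the final iterate is (numerically) stationary: the
    # damping overflowing rules that out regardless of the gradient
    converged = (not overflow) and _grad_norm(p, Xs, ys, h) < gtol
    return p, sse, epochs, converged, n_trace


# ---------------------------------------------------------------------------
# public functional API
# ---------------------------------------------------------------------------


def forward(
    params: NetworkParams, scaling: ScalingSpec, x: Sequence[float] | np.ndarray
) -> float | np.ndarray:
    """Predict activity in natural units at natural-unit input(s).

    Accepts a single length-k vector or an (n, k) matrix; returns a scalar
    or a length-n vector accordingly.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.n_inputs:
        raise ValueError(
            f"expected {params.n_inputs} inputs, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    Xs = scaling.scale_x(X)
    H = np.tanh(Xs @ params.hidden_weights.T + params.hidden_biases)
    ys = H @ params.output_weights + params.output_bias
    y = scaling.unscale_y(ys)
    return float(y[0]) if single else y


def jacobian(
    params: NetworkParams, scaling: ScalingSpec, X: np.ndarray
) -> np.ndarray:
    """n x P matrix of scaled-space prediction derivatives.

    Entry (i, j) is d f(x_i) / d p_j with f in scaled response units and the
    flat parameter order [hidden weights row-major, hidden biases, output
    weights, output bias].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = scaling.scale_x(X)
    return _jacobian_scaled(params.to_vector(), Xs, params.n_hidden)


def train_lm(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
    init: NetworkParams | None = None,
    scaling: ScalingSpec | None = None,
    n_hidden: int = 2,
) -> FitResult:
    """Train from a single initialization (natural-unit data).

    When ``init`` is omitted a seeded uniform initialization on
    [-init_scale, +init_scale] is drawn from ``config.seed``; when
    ``scaling`` is omitted it is computed from the data.
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and y must hold the same positive number of rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    if scaling is None:
        scaling = ScalingSpec.from_data(X, y)
    k = X.shape[1]
    if init is None:
        rng = np.random.default_rng(config.seed)
        p0 = rng.uniform(
            -config.init_scale, config.init_scale, n_parameters(k, n_hidden)
        )
    else:
        if init.n_inputs != k:
            raise ValueError("init network has wrong input width")
        n_hidden = init.n_hidden
        p0 = init.to_vector()
    Xs = scaling.scale_x(X)
    ys = scaling.scale_y(y)
    trace = np.empty(config.max_epochs + 1)
    p, sse, epochs, converged, n_trace = _train_lm_kernel(
        p0,
        Xs,
        ys,
        n_hidden,
        config.max_epochs,
        config.learning_rate,
        config.rate_increase_ratio,
        config.damping_decrease_ratio,
        config.gradient_tolerance,
        config.sse_tolerance,
        LAMBDA_MAX,
        trace,
    )
    return FitResult(
        params=NetworkParams.from_vector(p, k, n_hidden),
        scaling=scaling,
        sse=float(sse),
        epochs_run=int(epochs),
        converged=bool(converged),
        restart_index=0,
        config=config,
    )


def lm_sse_trace(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
    init: NetworkParams | None = None,
    n_hidden: int = 2,
) -> np.ndarray:
    """Accepted-step SSE sequence of a single LM run (trace[0] = initial
    SSE); strictly decreasing by construction of the accept rule."""
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    scaling = ScalingSpec.from_data(X, y)
    k = X.shape[1]
    if init is None:
        rng = np.random.default_rng(config.seed)
        p0 = rng.uniform(
            -config.init_scale, config.init_scale, n_parameters(k, n_hidden)
        )
    else:
        n_hidden = init.n_hidden
        p0 = init.to_vector()
    trace = np.empty(config.max_epochs + 1)
    *_rest, n_trace = _train_lm_kernel(
        p0,
        scaling.scale_x(X),
        scaling.scale_y(y),
        n_hidden,
        config.max_epochs,
        config.learning_rate,
        config.rate_increase_ratio,
        config.damping_decrease_ratio,
        config.gradient_tolerance,
        config.sse_tolerance,
        LAMBDA_MAX,
        trace,
    )
    return trace[:n_trace].copy()


def multistart_fit(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
    n_hidden: int = 2,
) -> FitResult:
    """Best-of-``n_restarts`` Levenberg-Marquardt fit.

    Restart initializations are drawn sequentially from a generator seeded
    with ``config.seed``, so for a fixed seed the restart sequence is nested:
    increasing ``n_restarts`` can only improve (never worsen) the best SSE.
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and y must hold the same positive number of rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    scaling = ScalingSpec.from_data(X, y)
    Xs = scaling.scale_x(X)
    ys = scaling.scale_y(y)
    k = X.shape[1]
    P = n_parameters(k, n_hidden)
    rng = np.random.default_rng(config.seed)
    best: tuple[float, np.ndarray, int, bool, int] | None = None
    trace = np.empty(config.max_epochs + 1)
    for idx in range(config.n_restarts):
        p0 = rng.uniform(-config.init_scale, config.init_scale, P)
        p, sse, epochs, converged, _nt = _train_lm_kernel(
            p0,
            Xs,
            ys,
            n_hidden,
            config.max_epochs,
            config.learning_rate,
            config.rate_increase_ratio,
            config.damping_decrease_ratio,
            config.gradient_tolerance,
            config.sse_tolerance,
            LAMBDA_MAX,
            trace,
        )
        if best is None or sse < best[0]:
            best = (float(sse), p, int(epochs), bool(converged), idx)
    assert best is not None
    sse, p, epochs, converged, idx = best
    return FitResult(
        params=NetworkParams.from_vector(p, k, n_hidden),
        scaling=scaling,
        sse=sse,
        epochs_run=epochs,
        converged=converged,
        restart_index=idx,
        config=config,
    )


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------


class ANNSurfaceRegressor(BaseEstimator, RegressorMixin):
    """Response-surface regressor: a (k/n_hidden/1) tanh network fitted by
    multi-restart Levenberg-Marquardt.

    Parameters
    ----------
    n_hidden : int, default=2
        Hidden-layer width; 2 gives the 11-parameter model used for the
        three induction factors.
    n_restarts : int, default=200
        Seeded random initializations; the minimum-SSE fit is kept.
    max_epochs, learning_rate, rate_increase_ratio, damping_decrease_ratio,
    sse_tolerance, gradient_tolerance, init_scale
        Levenberg-Marquardt settings; see :class:`TrainingConfig`.
    random_state : int, default=0
        Seed for the restart initializations.

    Attributes
    ----------
    network_ : NetworkParams
        Fitted weights.
    scaling_ : ScalingSpec
        Min-max bounds used to map data into [-1, +1].
    sse_ : float
        Sum of squared errors on the scaled response.
    n_iter_ : int
        Epochs run by the winning restart.
    converged_ : bool
    restart_index_ : int

    Examples
    --------
    >>> from mbcomtopt.dataset import (load_reference_experiments,
    ...     calibration_subset, inputs_matrix, observed_vector)
    >>> rec = calibration_subset(load_reference_experiments())
    >>> model = ANNSurfaceRegressor(n_restarts=200, random_state=0)
    >>> model.fit(inputs_matrix(rec), observed_vector(rec))  # doctest: +SKIP
    """

    def __init__(
        self,
        n_hidden: int = 2,
        n_restarts: int = 200,
        max_epochs: int = 1000,
        learning_rate: float = 0.01,
        rate_increase_ratio: float = 1.05,
        damping_decrease_ratio: float = 10.0,
        sse_tolerance: float = 1e-12,
        gradient_tolerance: float = 1e-8,
        init_scale: float = 0.5,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.n_restarts = n_restarts
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.rate_increase_ratio = rate_increase_ratio
        self.damping_decrease_ratio = damping_decrease_ratio
        self.sse_tolerance = sse_tolerance
        self.gradient_tolerance = gradient_tolerance
        self.init_scale = init_scale
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            max_epochs=self.max_epochs,
            learning_rate=self.learning_rate,
            rate_increase_ratio=self.rate_increase_ratio,
            damping_decrease_ratio=self.damping_decrease_ratio,
            sse_tolerance=self.sse_tolerance,
            gradient_tolerance=self.gradient_tolerance,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            init_scale=self.init_scale,
        )

    def fit(self, X, y) -> "ANNSurfaceRegressor":
        X, y = check_X_y(X, y, y_numeric=True)
        result = multistart_fit(X, y, self._config(), n_hidden=self.n_hidden)
        self.n_features_in_ = X.shape[1]
        self.network_ = result.params
        self.scaling_ = result.scaling
        self.sse_ = result.sse
        self.n_iter_ = result.epochs_run
        self.converged_ = result.converged
        self.restart_index_ = result.restart_index
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = check_array(X)
        return np.asarray(forward(self.network_, self.scaling_, X))

    def to_fit_result(self) -> FitResult:
        check_is_fitted(self, "network_")
        return FitResult(
            params=self.network_,
            scaling=self.scaling_,
            sse=self.sse_,
            epochs_run=self.n_iter_,
            converged=self.converged_,
            restart_index=self.restart_index_,
            config=self._config(),
        )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_fit(fit: FitResult, path: str | Path) -> None:
    """Write a fitted model as YAML (weights, scaling, config, seed)."""
    doc = {
        "network": {
            "hidden_weights": fit.params.hidden_weights.tolist(),
            "hidden_biases": fit.params.hidden_biases.tolist(),
            "output_weights": fit.params.output_weights.tolist(),
            "output_bias": fit.params.output_bias,
        },
        "scaling": {
            "x_min": fit.scaling.x_min.tolist(),
            "x_max": fit.scaling.x_max.tolist(),
            "y_min": fit.scaling.y_min,
            "y_max": fit.scaling.y_max,
        },
        "sse": fit.sse,
        "epochs_run": fit.epochs_run,
        "converged": fit.converged,
        "restart_index": fit.restart_index,
        "config": None if fit.config is None else asdict(fit.config),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_fit(path: str | Path) -> FitResult:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    net = doc["network"]
    sc = doc["scaling"]
    return FitResult(
        params=NetworkParams(
            hidden_weights=np.array(net["hidden_weights"], dtype=float),
            hidden_biases=np.array(net["hidden_biases"], dtype=float),
            output_weights=np.array(net["output_weights"], dtype=float),
            output_bias=float(net["output_bias"]),
        ),
        scaling=ScalingSpec(
            x_min=np.array(sc["x_min"], dtype=float),
            x_max=np.array(sc["x_max"], dtype=float),
            y_min=float(sc["y_min"]),
            y_max=float(sc["y_max"]),
        ),
        sse=float(doc["sse"]),
        epochs_run=int(doc["epochs_run"]),
        converged=bool(doc["converged"]),
        restart_index=int(doc.get("restart_index", 0)),
        config=None
        if doc.get("config") is None
        else TrainingConfig(**doc["config"]),
    )
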