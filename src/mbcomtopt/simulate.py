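"""Synthetic experiment tables with the structure of the calibration study.

A *teacher surface* is a known ground-truth response over the three
induction factors (methanol rate, temperature, DMSO).  Simulated campaigns
evaluate the teacher on a design, add homoscedastic Gaussian replicate
noise, and emit standard experiment records, so the whole
fit-optimize-iterate pipeline can be exercised against a known argmax.

The default noise level (sd 11 nmol/h/mg) matches the replicate scatter of
the three recorded center-point fermentations (252.5, 243.8, 230.3, sample
sd 11.1); negative noisy draws are truncated at zero because activities are
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ann import FitResult, NetworkParams, ScalingSpec, TrainingConfig, forward
from .dataset import ExperimentRecord
from .doe import DEFAULT_FACTORS, DesignPoint, FactorSpec, build_ccd, code
from .optimize import DEFAULT_BOUNDS, run_optimization_loop

__all__ = [
    "TeacherSurface",
    "RecoveryReport",
    "DEFAULT_NOISE_SD",
    "default_teacher",
    "evaluate_teacher",
    "simulate_experiments",
    "end_to_end_recovery",
]

#: Replicate noise, nmol/h/mg: sample sd of the three recorded center points.
DEFAULT_NOISE_SD = 11.0


@dataclass(frozen=True)
class TeacherSurface:
    """Ground-truth response surface, quadratic or network-backed.

    For ``kind="quadratic"`` the response over x = (methanol, temperature,
    dmso) is

        intercept + linear . x + pure_quadratic . x**2
        + interactions . (x1*x2, x1*x3, x2*x3)

    For ``kind="ann"`` evaluation delegates to a stored network and scaling.
    """

    kind: str
    intercept: float = 0.0
    linear: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pure_quadratic: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interactions: tuple[float, float, float] = (0.0, 0.0, 0.0)
    network: NetworkParams | None = None
    scaling: ScalingSpec | None = None
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.kind not in ("quadratic", "ann"):
            raise ValueError(f"unknown teacher kind {self.kind!r}")
        if self.kind == "ann" and (self.network is None or self.scaling is None):
            raise ValueError("ann teacher needs network and scaling")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def quadratic(
        cls,
        intercept: float,
        linear: Sequence[float] = (0.0, 0.0, 0.0),
        pure_quadratic: Sequence[float] = (0.0, 0.0, 0.0),
        interactions: Sequence[float] = (0.0, 0.0, 0.0),
        noise_sd: float = DEFAULT_NOISE_SD,
    ) -> "TeacherSurface":
        return cls(
            kind="quadratic",
            intercept=float(intercept),
            linear=tuple(float(v) for v in linear),
            pure_quadratic=tuple(float(v) for v in pure_quadratic),
            interactions=tuple(float(v) for v in interactions),
            noise_sd=noise_sd,
        )

    @classmethod
    def from_fit(
        cls, fit: FitResult, noise_sd: float = DEFAULT_NOISE_SD
    ) -> "TeacherSurface":
        return cls(
            kind="ann",
            network=fit.params,
            scaling=fit.scaling,
            noise_sd=noise_sd,
        )

    def argmax(
        self, bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS
    ) -> tuple[np.ndarray, float]:
        """Analytic argmax over a box for interaction-free quadratics.

        Each axis is an independent 1-D quadratic: the vertex if concave and
        interior, otherwise the better endpoint.
        """
        if self.kind != "quadratic" or any(v != 0 for v in self.interactions):
            raise ValueError(
                "closed-form argmax is only available for interaction-free "
                "quadratic teachers"
            )
        x_star = []
        for li, qi, (lo, hi) in zip(self.linear, self.pure_quadratic, bounds):
            if qi < 0:
                vertex = -li / (2 * qi)
                x_star.append(min(max(vertex, lo), hi))
            else:
                f = lambda t: li * t + qi * t * t
                x_star.append(lo if f(lo) >= f(hi) else hi)
        x = np.array(x_star)
        return x, float(evaluate_teacher(self, x))


def default_teacher(noise_sd: float = DEFAULT_NOISE_SD) -> TeacherSurface:
    """A smooth concave teacher with interior argmax 250 at (2.4, 27, 5.5),
    on the activity scale of the calibration data."""
    # y = 250 - 30(m-2.4)^2 - 1.5(T-27)^2 - 20(d-5.5)^2, expanded
    m0, t0, d0 = 2.4, 27.0, 5.5
    am, at, ad = 30.0, 1.5, 20.0
    return TeacherSurface.quadratic(
        intercept=250.0 - am * m0**2 - at * t0**2 - ad * d0**2,
        linear=(2 * am * m0, 2 * at * t0, 2 * ad * d0),
        pure_quadratic=(-am, -at, -ad),
        noise_sd=noise_sd,
    )


def evaluate_teacher(
    surface: TeacherSurface, x: Sequence[float] | np.ndarray
) -> float | np.ndarray:
    """Deterministic noiseless teacher response at natural-unit input(s)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if surface.kind == "ann":
        assert surface.network is not None and surface.scaling is not None
        y = np.asarray(forward(surface.network, surface.scaling, X))
    else:
        lin = np.array(surface.linear)
        quad = np.array(surface.pure_quadratic)
        inter = np.array(surface.interactions)
        cross = np.stack(
            [X[:, 0] * X[:, 1], X[:, 0] * X[:, 2], X[:, 1] * X[:, 2]], axis=-1
        )
        y = surface.intercept + X @ lin + (X**2) @ quad + cross @ inter
    return float(y[0]) if single else y


def simulate_experiments(
    design: Sequence[DesignPoint] | np.ndarray,
    surface: TeacherSurface,
    seed: int = 0,
    phase: str = "doe",
    start_run_id: int = 1,
) -> list[ExperimentRecord]:
    """Observe the teacher on a design with seeded replicate noise.

    ``design`` may be a list of design points or an (n, 3) array of natural
    inputs.  Observed activities are teacher + N(0, noise_sd), truncated at
    zero; two calls with the same seed are identical.
    """
    if isinstance(design, np.ndarray):
        X = np.atleast_2d(np.asarray(design, dtype=float))
    else:
        X = np.array([pt.natural for pt in design], dtype=float)
    rng = np.random.default_rng(seed)
    truth = np.atleast_1d(np.asarray(evaluate_teacher(surface, X)))
    noisy = truth + rng.normal(0.0, surface.noise_sd, size=truth.shape)
    noisy = np.maximum(noisy, 0.0)
    return [
        ExperimentRecord(
            run_id=start_run_id + i,
            phase=phase,
            methanol_rate=float(X[i, 0]),
            temperature=float(X[i, 1]),
            dmso=float(X[i, 2]),
            observed_activity=float(noisy[i]),
        )
        for i in range(X.shape[0])
    ]


@dataclass(frozen=True)
class RecoveryReport:
    """How well the full pipeline recovered a known teacher optimum."""

    recovered_x: tuple[float, float, float]
    recovered_y: float
    true_x: tuple[float, float, float]
    true_y: float
    coded_argmax_error: float
    predicted_max_relative_error: float
    n_iterations: int


def end_to_end_recovery(
    surface: TeacherSurface,
    factors: Sequence[FactorSpec] = DEFAULT_FACTORS,
    config: TrainingConfig | None = None,
    seed: int = 0,
    *,
    n_center: int = 3,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    n_replicates: int = 3,
    max_iterations: int = 4,
    grid_n: int = 101,
    tol_coded: float = 0.05,
) -> RecoveryReport:
    """Design -> simulate -> multistart fit -> optimization loop, then score
    argmax recovery against the teacher's known optimum.

    The coded-space argmax error uses the affine factor coding, so one unit
    equals half a factor range.
    """
    config = config or TrainingConfig()
    design = build_ccd(factors, n_center=n_center)
    records = simulate_experiments(design, surface, seed=seed)

    def observe(x: np.ndarray, rng: np.random.Generator) -> float:
        return float(evaluate_teacher(surface, x)) + float(
            rng.normal(0.0, surface.noise_sd)
        )

    history = run_optimization_loop(
        records,
        config,
        bounds,
        mode="simulate",
        observe=observe,
        n_replicates=n_replicates,
        max_iterations=max_iterations,
        tol_coded=tol_coded,
        grid_n=grid_n,
        seed=seed + 1,
    )
    final = history[-1].optimum
    true_x, true_y = surface.argmax(bounds)
    coded_err = float(
        np.linalg.norm(
            code(np.array(final.x_star), factors) - code(true_x, factors)
        )
    )
    rel_err = abs(final.y_star - true_y) / abs(true_y) if true_y != 0 else abs(
        final.y_star
    )
    return RecoveryReport(
        recovered_x=tuple(final.x_star),
        recovered_y=final.y_star,
        true_x=tuple(float(v) for v in true_x),
        true_y=true_y,
        coded_argmax_error=coded_err,
        predicted_max_relative_error=float(rel_err),
        n_iterations=len(history) - 1,
    )
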