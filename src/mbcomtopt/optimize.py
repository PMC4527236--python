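"""Surface maximization, the iterative fit-propose-augment loop, and fit
diagnostics.

The induction-phase optimization is sequential: fit the network to the
current calibration set, locate the maximum of the fitted surface over the
factor box, run replicate fermentations at that point, append the new
observations, and refit — until the proposed optimum stops moving or an
iteration budget is exhausted.  The loop can replay recorded iteration
groups from an experiment table or simulate new observations from a known
teacher surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ann import FitResult, TrainingConfig, forward, multistart_fit
from .dataset import (
    ITERATION_PHASES,
    ExperimentRecord,
    calibration_subset,
    inputs_matrix,
    observed_vector,
)
from .doe import FactorSpec, code

__all__ = [
    "FACTOR_NAMES",
    "DEFAULT_BOUNDS",
    "OptimumEstimate",
    "FitDiagnostics",
    "LoopIteration",
    "ContourGrid",
    "surface_max",
    "run_optimization_loop",
    "diagnostics",
    "predict_records",
    "contour_grid",
    "fold_improvement",
]

FACTOR_NAMES = ("methanol_rate", "temperature", "dmso")

#: The natural ranges of the calibration design: methanol 1-3 mL/L/H,
#: temperature 20-30 C, DMSO 4-6 % v/v.  Extrapolating a two-hidden-unit
#: network beyond its calibrated ranges is unsupported, so this box is also
#: the default search region.
DEFAULT_BOUNDS = ((1.0, 3.0), (20.0, 30.0), (4.0, 6.0))


@dataclass(frozen=True)
class OptimumEstimate:
    """Argmax of a fitted surface over a factor box."""

    x_star: tuple[float, ...]
    y_star: float
    on_boundary: tuple[bool, ...]

    @property
    def as_dict(self) -> dict[str, float]:
        return dict(zip(FACTOR_NAMES, self.x_star))


@dataclass(frozen=True)
class FitDiagnostics:
    """Least-squares line of predicted (y) on observed (x) activities."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    outlier_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise ValueError("diagnostics need at least 2 points")


@dataclass(frozen=True)
class LoopIteration:
    """One pass of the fit-propose-augment loop."""

    fit: FitResult
    optimum: OptimumEstimate
    proposed: tuple[ExperimentRecord, ...]


@dataclass(frozen=True)
class ContourGrid:
    """A grid_n x grid_n prediction slice through the fitted surface;
    ``values[i, j]`` is the prediction at (axis1[i], axis2[j])."""

    var_pair: tuple[str, str]
    fixed_name: str
    fixed_value: float
    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.axis1, name=self.var_pair[0]),
            columns=pd.Index(self.axis2, name=self.var_pair[1]),
        )
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def surface_max(
    fit: FitResult,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    grid_n: int = 101,
    polish: bool = True,
) -> OptimumEstimate:
    """Maximize the fitted surface over a box.

    A full ``grid_n``-per-axis lattice is evaluated (degenerate axes with
    low == high collapse to a single node) and the best node is taken, ties
    broken by lowest lattice index.  With ``polish`` the node is refined by
    bounded local ascent (L-BFGS-B on the negated prediction); the polished
    point is kept only if it improves on the lattice value.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for lo, hi in bounds:
        if hi < lo:
            raise ValueError(f"invalid bounds ({lo}, {hi})")
    axes = [
        np.array([lo]) if hi == lo else np.linspace(lo, hi, grid_n)
        for lo, hi in bounds
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    lattice = np.stack([m.ravel() for m in mesh], axis=-1)
    values = np.asarray(forward(fit.params, fit.scaling, lattice))
    best = int(np.argmax(values))
    x_star = lattice[best].astype(float)
    y_star = float(values[best])

    if polish:
        res = minimize(
            lambda x: -float(forward(fit.params, fit.scaling, x)),
            x_star,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if res.success and -res.fun > y_star:
            x_star = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
            y_star = float(forward(fit.params, fit.scaling, x_star))

    on_boundary = tuple(
        bool(
            abs(x - lo) <= 1e-9 + 1e-6 * (hi - lo)
            or abs(x - hi) <= 1e-9 + 1e-6 * (hi - lo)
        )
        for x, (lo, hi) in zip(x_star, bounds)
    )
    return OptimumEstimate(tuple(float(v) for v in x_star), y_star, on_boundary)


def _factors_from_bounds(
    bounds: Sequence[tuple[float, float]],
) -> list[FactorSpec]:
    return [
        FactorSpec(name, lo, 0.5 * (lo + hi), hi)
        for name, (lo, hi) in zip(FACTOR_NAMES, bounds)
    ]


def run_optimization_loop(
    records: Sequence[ExperimentRecord],
    config: TrainingConfig | None = None,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    *,
    mode: str = "replay",
    observe: Callable[[np.ndarray, np.random.Generator], float] | None = None,
    n_replicates: int = 2,
    max_iterations: int = 4,
    tol_coded: float = 0.05,
    grid_n: int = 101,
    seed: int = 0,
    n_hidden: int = 2,
) -> list[LoopIteration]:
    """Run the sequential model-based optimization loop.

    Parameters
    ----------
    records
        Starting experiments; must contain at least one observed design run.
    mode
        ``"replay"``: each iteration appends the recorded runs of the next
        iteration phase found in ``records`` (the proposed optimum is
        reported but the historical runs are what is appended, so a recorded
        campaign is reproduced exactly, including its stopping point).
        ``"simulate"``: each iteration appends ``n_replicates`` noisy
        observations of ``observe`` at the proposed optimum, and the loop
        additionally stops once the optimum moves less than ``tol_coded`` in
        coded units between iterations.
    observe
        Callback ``(x, rng) -> activity`` used in simulate mode.
    max_iterations
        Proposal iterations after the initial fit; 0 returns only the
        initial fit and optimum.

    Returns
    -------
    list of LoopIteration
        One entry per fit; every entry but the last carries the runs that
        were appended after it.
    """
    if mode not in ("replay", "simulate"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "simulate" and observe is None:
        raise ValueError("simulate mode needs an observe callback")
    config = config or TrainingConfig()
    factors = _factors_from_bounds(bounds)
    rng = np.random.default_rng(seed)

    calib = calibration_subset(records)
    if not any(r.phase == "doe" for r in calib):
        raise ValueError("need at least one observed design run to start")
    # keep only pre-iteration data in the calibration set; iteration groups
    # are appended as the replay proceeds
    replay_groups = [
        [r for r in records if r.phase == phase] for phase in ITERATION_PHASES
    ]
    calib = [r for r in calib if r.phase == "doe"]
    next_run_id = max(r.run_id for r in records) + 1

    history: list[LoopIteration] = []
    prev_coded: np.ndarray | None = None
    for it in range(max_iterations + 1):
        fit = multistart_fit(
            inputs_matrix(calib), observed_vector(calib), config, n_hidden=n_hidden
        )
        optimum = surface_max(fit, bounds, grid_n=grid_n)
        coded = code(np.array(optimum.x_star), factors)
        moved = (
            None
            if prev_coded is None
            else float(np.linalg.norm(coded - prev_coded))
        )
        prev_coded = coded

        if it == max_iterations:
            history.append(LoopIteration(fit, optimum, ()))
            break
        if mode == "simulate" and moved is not None and moved < tol_coded:
            history.append(LoopIteration(fit, optimum, ()))
            break

        if mode == "replay":
            proposed = tuple(replay_groups[it]) if it < len(replay_groups) else ()
            if not proposed:
                history.append(LoopIteration(fit, optimum, ()))
                break
        else:
            phase = ITERATION_PHASES[min(it, len(ITERATION_PHASES) - 1)]
            x = np.array(optimum.x_star)
            new = []
            for _ in range(n_replicates):
                y_obs = max(0.0, float(observe(x, rng)))
                new.append(
                    ExperimentRecord(
                        run_id=next_run_id,
                        phase=phase,
                        methanol_rate=float(x[0]),
                        temperature=float(x[1]),
                        dmso=float(x[2]),
                        observed_activity=y_obs,
                        predicted_activity=optimum.y_star,
                    )
                )
                next_run_id += 1
            proposed = tuple(new)

        history.append(LoopIteration(fit, optimum, proposed))
        calib.extend(calibration_subset(proposed))
    return history


def predict_records(
    fit: FitResult, records: Sequence[ExperimentRecord]
) -> list[ExperimentRecord]:
    """Fill ``predicted_activity`` of every record from a fitted surface."""
    preds = np.asarray(forward(fit.params, fit.scaling, inputs_matrix(records)))
    return [r.with_prediction(p) for r, p in zip(records, preds)]


def diagnostics(records: Sequence[ExperimentRecord]) -> FitDiagnostics:
    """Observed-versus-predicted calibration line.

    Ordinary least squares of predicted (y-axis) on observed (x-axis) over
    all records that carry both values; outlier-flagged records are reported
    in ``outlier_ids`` but excluded from the line.  ``r_squared`` is the
    squared Pearson correlation of the retained pairs.
    """
    paired = [
        r
        for r in records
        if r.observed_activity is not None and r.predicted_activity is not None
    ]
    outlier_ids = tuple(r.run_id for r in paired if r.is_outlier)
    kept = [r for r in paired if not r.is_outlier]
    if len(kept) < 2:
        raise ValueError("diagnostics need at least 2 non-outlier pairs")
    obs = np.array([r.observed_activity for r in kept], dtype=float)
    pred = np.array([r.predicted_activity for r in kept], dtype=float)
    if np.ptp(obs) == 0:
        raise ValueError("observed activities have zero variance: slope undefined")
    slope, intercept = np.polyfit(obs, pred, 1)
    if np.ptp(pred) == 0:
        r_squared = 0.0
    else:
        r_squared = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return FitDiagnostics(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(r_squared, 1.0),
        n_points=len(kept),
        outlier_ids=outlier_ids,
    )


def contour_grid(
    fit: FitResult,
    var_pair: tuple[str, str],
    fixed: float,
    grid_n: int = 101,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
) -> ContourGrid:
    """Prediction grid over two factors with the third held fixed."""
    a, b = var_pair
    if a == b:
        raise ValueError("var_pair must name two distinct factors")
    for name in var_pair:
        if name not in FACTOR_NAMES:
            raise KeyError(f"unknown factor {name!r}")
    fixed_name = next(n for n in FACTOR_NAMES if n not in var_pair)
    idx = {n: i for i, n in enumerate(FACTOR_NAMES)}
    lo_f, hi_f = bounds[idx[fixed_name]]
    if not lo_f <= fixed <= hi_f:
        raise ValueError(
            f"fixed value {fixed} outside bounds of {fixed_name!r}"
        )
    axis1 = np.linspace(*bounds[idx[a]], grid_n)
    axis2 = np.linspace(*bounds[idx[b]], grid_n)
    A1, A2 = np.meshgrid(axis1, axis2, indexing="ij")
    X = np.empty((grid_n * grid_n, 3))
    X[:, idx[a]] = A1.ravel()
    X[:, idx[b]] = A2.ravel()
    X[:, idx[fixed_name]] = fixed
    values = np.asarray(forward(fit.params, fit.scaling, X)).reshape(
        grid_n, grid_n
    )
    return ContourGrid(
        var_pair=(a, b),
        fixed_name=fixed_name,
        fixed_value=float(fixed),
        axis1=axis1,
        axis2=axis2,
        values=values,
    )


def fold_improvement(y_star: float, baseline: float) -> float:
    """Ratio of a predicted optimum to a baseline activity."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return y_star / baseline
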