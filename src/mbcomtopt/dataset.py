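"""Experiment tables: records, CSV I/O, and the bundled calibration table.

The package ships the full calibration table of the MBCOMT induction-phase
study as a CSV resource: 17 central-composite-design runs, four groups of
model-guided iteration runs, and a final validation run at the predicted
optimum (which has a model prediction but no measured activity).  Run 8 is
flagged as a model outlier and is excluded from every calibration subset by
default, but kept for diagnostics.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentRecord",
    "PHASES",
    "ITERATION_PHASES",
    "SHAKE_FLASK_ACTIVITY",
    "SchemaError",
    "load_experiments",
    "save_experiments",
    "load_reference_experiments",
    "calibration_subset",
    "records_to_frame",
    "inputs_matrix",
    "observed_vector",
]

PHASES = (
    "doe",
    "iteration_1",
    "iteration_2",
    "iteration_3",
    "iteration_4",
    "final_validation",
)

ITERATION_PHASES = ("iteration_1", "iteration_2", "iteration_3", "iteration_4")

#: Best MBCOMT specific activity from small-scale shake-flask biosynthesis
#: (X33 strain, 0.5 % v/v methanol), nmol/h/mg protein — the baseline for
#: the overall fold-improvement of the optimized bioreactor process.
SHAKE_FLASK_ACTIVITY = 60.25

_COLUMNS = (
    "run_id",
    "phase",
    "methanol_rate_ml_per_l_h",
    "temperature_c",
    "dmso_pct",
    "observed_activity",
    "predicted_activity",
    "is_outlier",
)


class SchemaError(ValueError):
    """Raised when an experiment CSV does not match the expected schema."""


@dataclass(frozen=True)
class ExperimentRecord:
    """One fermentation run: induction conditions plus observed/predicted
    MBCOMT specific activity (nmol/h/mg protein)."""

    run_id: int
    phase: str
    methanol_rate: float  # mL/L/H
    temperature: float  # degrees C
    dmso: float  # % v/v
    observed_activity: float | None = None
    predicted_activity: float | None = None
    is_outlier: bool = False

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"run {self.run_id}: unknown phase {self.phase!r}")
        if not self.methanol_rate > 0:
            raise ValueError(
                f"run {self.run_id}: methanol_rate must be > 0, "
                f"got {self.methanol_rate}"
            )
        if not self.temperature > 0:
            raise ValueError(
                f"run {self.run_id}: temperature must be > 0, "
                f"got {self.temperature}"
            )
        if not 0 <= self.dmso <= 100:
            raise ValueError(
                f"run {self.run_id}: dmso must be in [0, 100] % v/v, "
                f"got {self.dmso}"
            )
        if self.observed_activity is not None and self.observed_activity < 0:
            raise ValueError(
                f"run {self.run_id}: observed_activity must be >= 0"
            )
        if self.observed_activity is None and self.predicted_activity is None:
            raise ValueError(
                f"run {self.run_id}: needs an observed or a predicted activity"
            )

    @property
    def inputs(self) -> tuple[float, float, float]:
        """(methanol_rate, temperature, dmso) in natural units."""
        return (self.methanol_rate, self.temperature, self.dmso)

    def with_prediction(self, value: float) -> "ExperimentRecord":
        return replace(self, predicted_activity=float(value))


def _parse_float(
    cell: str, row_num: int, column: str, allow_empty: bool = False
) -> float | None:
    cell = cell.strip()
    if cell == "":
        if allow_empty:
            return None
        raise SchemaError(f"row {row_num}: empty value in column {column!r}")
    try:
        value = float(cell)
    except ValueError as exc:
        raise SchemaError(
            f"row {row_num}: non-numeric value {cell!r} in column {column!r}"
        ) from exc
    if not math.isfinite(value):
        raise SchemaError(
            f"row {row_num}: non-finite value in column {column!r}"
        )
    return value


def _parse_bool(cell: str, row_num: int, column: str) -> bool:
    norm = cell.strip().lower()
    if norm in ("true", "1", "yes"):
        return True
    if norm in ("false", "0", "no", ""):
        return False
    raise SchemaError(
        f"row {row_num}: cannot interpret {cell!r} in column {column!r} "
        "as a boolean"
    )


def load_experiments(path: str | Path) -> list[ExperimentRecord]:
    """Load and validate an experiment CSV.

    The schema is the eight comma-separated columns written by
    :func:`save_experiments`; the header row is mandatory.  Rows that violate
    record invariants are rejected with a row-numbered message.
    """
    records: list[ExperimentRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("empty file: missing header row")
        missing = set(_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"missing column(s): {sorted(missing)}")
        for row_num, row in enumerate(reader, start=2):
            run_id_raw = _parse_float(row["run_id"], row_num, "run_id")
            assert run_id_raw is not None
            try:
                record = ExperimentRecord(
                    run_id=int(run_id_raw),
                    phase=row["phase"].strip(),
                    methanol_rate=_parse_float(
                        row["methanol_rate_ml_per_l_h"],
                        row_num,
                        "methanol_rate_ml_per_l_h",
                    ),
                    temperature=_parse_float(
                        row["temperature_c"], row_num, "temperature_c"
                    ),
                    dmso=_parse_float(row["dmso_pct"], row_num, "dmso_pct"),
                    observed_activity=_parse_float(
                        row["observed_activity"],
                        row_num,
                        "observed_activity",
                        allow_empty=True,
                    ),
                    predicted_activity=_parse_float(
                        row["predicted_activity"],
                        row_num,
                        "predicted_activity",
                        allow_empty=True,
                    ),
                    is_outlier=_parse_bool(
                        row["is_outlier"], row_num, "is_outlier"
                    ),
                )
            except ValueError as exc:
                raise SchemaError(f"row {row_num}: {exc}") from exc
            records.append(record)
    return records


def save_experiments(
    records: Iterable[ExperimentRecord], path: str | Path
) -> None:
    """Write records in the standard CSV schema (empty cell = missing)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.run_id,
                    r.phase,
                    _fmt(r.methanol_rate),
                    _fmt(r.temperature),
                    _fmt(r.dmso),
                    "" if r.observed_activity is None else _fmt(r.observed_activity),
                    "" if r.predicted_activity is None else _fmt(r.predicted_activity),
                    "true" if r.is_outlier else "false",
                ]
            )


def _fmt(x: float) -> str:
    return repr(float(x)) if x != int(x) else str(int(x))


def load_reference_experiments() -> list[ExperimentRecord]:
    """Load the bundled 27-run calibration table of the induction study."""
    ref = resources.files("mbcomtopt").joinpath("data/calibration_campaign.csv")
    with resources.as_file(ref) as path:
        return load_experiments(path)


def calibration_subset(
    records: Iterable[ExperimentRecord],
    exclude_outliers: bool = True,
    phases: Sequence[str] | None = None,
    require_observed: bool = True,
) -> list[ExperimentRecord]:
    """Filter records for model calibration, preserving order.

    Parameters
    ----------
    exclude_outliers
        Drop rows flagged as model outliers.
    phases
        Keep only these phases (default: all).
    require_observed
        Drop rows without a measured activity (the final-validation run has
        only a prediction and can never be calibrated on).
    """
    phase_set = set(PHASES if phases is None else phases)
    out = []
    for r in records:
        if r.phase not in phase_set:
            continue
        if exclude_outliers and r.is_outlier:
            continue
        if require_observed and r.observed_activity is None:
            continue
        out.append(r)
    return out


def records_to_frame(records: Iterable[ExperimentRecord]) -> pd.DataFrame:
    rows = [
        {
            "run_id": r.run_id,
            "phase": r.phase,
            "methanol_rate_ml_per_l_h": r.methanol_rate,
            "temperature_c": r.temperature,
            "dmso_pct": r.dmso,
            "observed_activity": r.observed_activity,
            "predicted_activity": r.predicted_activity,
            "is_outlier": r.is_outlier,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(_COLUMNS))


def inputs_matrix(records: Sequence[ExperimentRecord]) -> np.ndarray:
    """n x 3 array of (methanol_rate, temperature, dmso)."""
    return np.array([r.inputs for r in records], dtype=float)


def observed_vector(records: Sequence[ExperimentRecord]) -> np.ndarray:
    return np.array(
        [math.nan if r.observed_activity is None else r.observed_activity for r in records],
        dtype=float,
    )
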