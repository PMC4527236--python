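"""Face-centered central composite designs over fermentation factors.

A face-centered CCD for k factors consists of the 2**k factorial corners at
coded levels +/-1, 2k axial points on the face centers (axial distance
alpha = 1, so every factor takes only the three levels -1/0/+1), and a block
of replicated center points.  Factor values move between coded and natural
units through the affine map

    coded = (natural - mid) / ((high - low) / 2)

so that low/mid/high correspond to -1/0/+1.  Off-design values (for example
an induction temperature of 22.5 C) pass through both maps unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "InvalidDesignError",
    "DEFAULT_FACTORS",
    "build_ccd",
    "code",
    "decode",
    "design_to_frame",
    "write_design_csv",
]

_REL_TOL = 1e-9


class InvalidDesignError(ValueError):
    """Raised for design requests that cannot form a CCD."""


@dataclass(frozen=True)
class FactorSpec:
    """One fermentation factor with equispaced coded levels -1/0/+1.

    ``mid`` must sit halfway between ``low`` and ``high``: the three-level
    structure of the design requires equispaced levels.
    """

    name: str
    low: float
    mid: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ValueError(
                f"factor {self.name!r}: require low < mid < high, "
                f"got {self.low}, {self.mid}, {self.high}"
            )
        expected_mid = 0.5 * (self.low + self.high)
        scale = max(abs(self.low), abs(self.high), 1.0)
        if abs(self.mid - expected_mid) > _REL_TOL * scale:
            raise ValueError(
                f"factor {self.name!r}: mid {self.mid} is not the midpoint of "
                f"[{self.low}, {self.high}] (levels must be equispaced)"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


@dataclass(frozen=True)
class DesignPoint:
    """A single design run in both coded and natural units."""

    coded: tuple[float, ...]
    natural: tuple[float, ...]
    role: str  # "factorial" | "axial" | "center"

    def __post_init__(self) -> None:
        if len(self.coded) != len(self.natural):
            raise ValueError("coded and natural vectors differ in length")
        if self.role not in ("factorial", "axial", "center"):
            raise ValueError(f"unknown design role {self.role!r}")


#: The three induction-phase factors at their design levels: methanol constant
#: feed rate 1/2/3 mL/L/H, induction temperature 20/25/30 C, DMSO 4/5/6 % v/v.
DEFAULT_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("methanol_rate", 1.0, 2.0, 3.0, units="mL/L/H"),
    FactorSpec("temperature", 20.0, 25.0, 30.0, units="C"),
    FactorSpec("dmso", 4.0, 5.0, 6.0, units="% v/v"),
)


def code(natural: Sequence[float], factors: Sequence[FactorSpec]) -> np.ndarray:
    """Map natural factor values onto coded units (low/mid/high -> -1/0/+1)."""
    natural = np.asarray(natural, dtype=float)
    if natural.shape[-1] != len(factors):
        raise ValueError(
            f"expected {len(factors)} factor values, got {natural.shape[-1]}"
        )
    mids = np.array([f.mid for f in factors])
    halves = np.array([f.half_range for f in factors])
    return (natural - mids) / halves


def decode(coded: Sequence[float], factors: Sequence[FactorSpec]) -> np.ndarray:
    """Inverse of :func:`code`; out-of-range coded values pass through."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise ValueError(
            f"expected {len(factors)} coded values, got {coded.shape[-1]}"
        )
    mids = np.array([f.mid for f in factors])
    halves = np.array([f.half_range for f in factors])
    return mids + halves * coded


def build_ccd(
    factors: Sequence[FactorSpec], n_center: int = 3
) -> list[DesignPoint]:
    """Construct a face-centered CCD: factorial, then axial, then center runs.

    Parameters
    ----------
    factors
        Factor specifications (k >= 2 of them).
    n_center
        Number of replicated center points (>= 1); defaults to 3, the
        replication used in the calibration design.

    Returns
    -------
    list of DesignPoint
        ``2**k`` factorial corners, ``2k`` face-centered axial points, and
        ``n_center`` identical center points, in that order.  The ordering is
        bookkeeping only; no downstream computation depends on it.
    """
    k = len(factors)
    if k < 2:
        raise InvalidDesignError(f"a CCD needs at least 2 factors, got {k}")
    if n_center < 1:
        raise InvalidDesignError(f"n_center must be >= 1, got {n_center}")

    points: list[DesignPoint] = []

    # factorial corners: all +/-1 combinations, first factor slowest
    for i in range(2**k):
        coded = tuple(
            -1.0 if (i >> (k - 1 - j)) & 1 == 0 else 1.0 for j in range(k)
        )
        points.append(
            DesignPoint(coded, tuple(decode(coded, factors)), "factorial")
        )

    # face-centered axial points (alpha = 1): one factor at +/-1, rest at 0
    for j in range(k):
        for level in (-1.0, 1.0):
            coded = tuple(level if m == j else 0.0 for m in range(k))
            points.append(
                DesignPoint(coded, tuple(decode(coded, factors)), "axial")
            )

    center = (0.0,) * k
    center_nat = tuple(decode(center, factors))
    points.extend(
        DesignPoint(center, center_nat, "center") for _ in range(n_center)
    )
    return points


def design_to_frame(
    points: Iterable[DesignPoint], factors: Sequence[FactorSpec]
) -> pd.DataFrame:
    """Tabulate a design with one coded and one natural column per factor."""
    rows = []
    for run_id, pt in enumerate(points, start=1):
        row: dict[str, object] = {"run_id": run_id, "role": pt.role}
        for f, c in zip(factors, pt.coded):
            row[f"coded_{f.name}"] = c
        for f, v in zip(factors, pt.natural):
            suffix = f"_{f.units}" if f.units else ""
            header = f"{f.name}{suffix}".replace(" ", "_").replace("/", "_per_")
            row[header] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_design_csv(
    points: Iterable[DesignPoint],
    factors: Sequence[FactorSpec],
    path: str,
) -> None:
    design_to_frame(points, factors).to_csv(path, index=False)
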