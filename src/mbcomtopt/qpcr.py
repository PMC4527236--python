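"""qPCR relative gene-dosage: primer efficiency and average copy number.

Copy number of the integrated expression cassette is estimated by relative
quantification against a single-copy genomic reference.  A target primer
pair amplifies a transcription-terminator sequence carried by the plasmid
(one endogenous copy plus one per integrated cassette) and a reference pair
amplifies a promoter stretch present exactly once in the genome.  With mean
primer efficiency E (amplification factor per cycle) the average copy
number is

    Ravg = E^-(Ct_target,sample - Ct_ref,sample)
         / E^-(Ct_target,control - Ct_ref,control)

and the cassette count is round(Ravg) - 1, subtracting the endogenous
target-sequence copy.  Primer efficiency comes from a serial-dilution
standard curve: the least-squares slope m of Ct against log10 template
amount gives E = 10^(-1/m) (m = -3.32 for perfect doubling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "QpcrMeasurement",
    "primer_efficiency",
    "average_copy_number",
    "mbcomt_copies",
    "ravg_interval",
    "simulate_measurement",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values (target and reference pairs, transformant and untransformed
    control) plus the mean primer efficiency."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_control: float
    ct_ref_control: float
    efficiency: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_sample",
            "ct_ref_sample",
            "ct_target_control",
            "ct_ref_control",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError(
                "efficiency must lie in (1, 2] (an amplification factor "
                f"per cycle); got {self.efficiency}"
            )


def primer_efficiency(
    dilution_log10: Sequence[float], ct: Sequence[float]
) -> float:
    """Efficiency from a serial-dilution standard curve.

    Parameters
    ----------
    dilution_log10
        log10 template amounts, strictly decreasing (serial dilution).
    ct
        Measured Ct at each dilution.

    Returns
    -------
    float
        ``10 ** (-1/m)`` with m the least-squares slope of Ct on
        log10(template).
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dilution_log10 and ct must be equal-length vectors")
    if x.size < 3:
        raise ValueError("a standard curve needs at least 3 points")
    if not np.all(np.diff(x) < 0):
        raise ValueError("template amounts must be strictly decreasing")
    m = float(np.polyfit(x, y, 1)[0])
    if abs(m) < 1.0:
        raise ValueError(
            f"slope {m:.3f} is implausibly shallow (implies efficiency > 10); "
            "check the standard curve"
        )
    return 10.0 ** (-1.0 / m)


def average_copy_number(m: QpcrMeasurement) -> float:
    """Average copy number Ravg from efficiency-corrected ddCt."""
    E = m.efficiency
    num = E ** -(m.ct_target_sample - m.ct_ref_sample)
    den = E ** -(m.ct_target_control - m.ct_ref_control)
    return num / den


def mbcomt_copies(ravg: float) -> int:
    """Integer cassette count: round(Ravg) minus the endogenous copy.

    Rounding is half-away-from-zero.  ``ravg < 1`` is impossible for a true
    transformant (the endogenous sequence alone gives 1) and raises.
    """
    if ravg < 1.0:
        raise ValueError(
            f"Ravg = {ravg:.3f} < 1: below the endogenous single copy"
        )
    return int(math.floor(ravg + 0.5)) - 1


def ravg_interval(
    m: QpcrMeasurement, ct_sd: float, n_replicates: int = 3
) -> tuple[float, float]:
    """First-order (Ravg - s, Ravg + s) interval from replicate Ct scatter.

    With ddCt variance 4 * ct_sd^2 / n (four averaged Ct terms), the
    propagated standard deviation of Ravg is |ln E| * Ravg * sd(ddCt).
    """
    if ct_sd < 0 or n_replicates < 1:
        raise ValueError("ct_sd must be >= 0 and n_replicates >= 1")
    ravg = average_copy_number(m)
    sd_ddct = 2.0 * ct_sd / math.sqrt(n_replicates)
    s = abs(math.log(m.efficiency)) * ravg * sd_ddct
    return (ravg - s, ravg + s)


def simulate_measurement(
    n_copies: int,
    efficiency: float,
    rng: np.random.Generator,
    ct_ref: float = 23.0,
    noise_sd: float = 0.1,
) -> QpcrMeasurement:
    """Simulate Ct values for a transformant carrying ``n_copies`` cassettes.

    The target template is (n_copies + 1)-fold more abundant than in the
    untransformed control, so its Ct comes down by log_E(n_copies + 1);
    Gaussian noise of ``noise_sd`` cycles perturbs the target-sample Ct,
    with the other three Ct values held at their nominal level.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    shift = math.log(n_copies + 1) / math.log(efficiency)
    return QpcrMeasurement(
        ct_target_sample=float(
            ct_ref - shift + rng.normal(0.0, noise_sd)
        ),
        ct_ref_sample=ct_ref,
        ct_target_control=ct_ref,
        ct_ref_control=ct_ref,
        efficiency=efficiency,
    )
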