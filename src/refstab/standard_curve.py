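"""Standard-curve fitting and amplification efficiency.

A qPCR standard curve regresses Ct on log10 of the relative template
input over a serial dilution (5-fold here, steps 5^0 .. 5^-4).  The
slope ``k`` of the fitted line gives the per-cycle amplification
efficiency

    E% = (10^(-1/k) - 1) * 100

so a perfectly doubling assay (k = -1/log10(2) = -3.3219) has E = 100%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats

logger = logging.getLogger(__name__)

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # ~ -3.321928


@dataclass
class DilutionSeries:
    """Ct measurements over a serial dilution for one assay.

    ``points`` holds (log10 relative input, Ct) pairs; for the canonical
    series step ``s`` of a ``dilution_factor``-fold dilution has
    log10 input ``-s * log10(dilution_factor)``.
    """

    gene: str
    points: list[tuple[float, float]]
    dilution_factor: float = 5.0

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("a dilution series needs at least 3 points")

    @staticmethod
    def from_steps(gene: str, step_ct: list[tuple[int, float]],
                   dilution_factor: float = 5.0) -> "DilutionSeries":
        """Build a series from (dilution step, Ct) pairs: step 0 is undiluted."""
        lf = math.log10(dilution_factor)
        return DilutionSeries(
            gene=gene,
            points=[(-step * lf, ct) for step, ct in step_ct],
            dilution_factor=dilution_factor,
        )


@dataclass
class StandardCurveFit:
    """Least-squares fit of Ct on log10 input: slope, intercept, R², E%."""

    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    n_points: int = field(default=0)

    def format_row(self) -> dict:
        return dict(
            gene=self.gene,
            slope=round(self.slope, 2),
            E_pct=round(self.efficiency_pct, 1),
            R2=round(self.r_squared, 3),
        )


def efficiency_from_slope(k: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope.

    E% = (10^(-1/k) - 1) * 100; k = 0 is rejected.
    """
    if k == 0:
        raise ValueError("slope must be nonzero")
    return (10.0 ** (-1.0 / k) - 1.0) * 100.0


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Fit one standard curve by ordinary least squares.

    Returns slope (cycles per log10 input, expected negative), intercept,
    R² of the fit, and efficiency in percent.  A positive slope is an
    assay anomaly (Ct should fall with more template); it is logged and
    the efficiency still computed.
    """
    x = [p[0] for p in series.points]
    y = [p[1] for p in series.points]
    if max(x) == min(x):
        raise ValueError("input levels have zero variance; cannot fit a curve")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        logger.warning("gene %s: positive standard-curve slope %.4f (assay anomaly)",
                       series.gene, res.slope)
    if res.slope == 0:
        raise ValueError(f"gene {series.gene}: zero slope, efficiency undefined")
    return StandardCurveFit(
        gene=series.gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency_pct=efficiency_from_slope(float(res.slope)),
        n_points=len(series.points),
    )
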