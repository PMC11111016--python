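"""Isotopologue ratios and isotope-dilution concentrations.

Two ratio estimators are provided.  The *area* ratio divides integrated
peak areas of two channels.  The *regression* ratio fits trace intensity
against monoisotopomer intensity scan-by-scan by ordinary least squares;
its slope equals the isotopologue ratio, and the intercept absorbs any
constant background — which is why slope estimation outperforms areas on
noisy, low-abundance signals.

Concentrations follow from isotope dilution: the analyte/internal-standard
signal ratio times the spiked amount, per gram fresh weight.  *Reverse*
isotope dilution spikes an unlabeled standard so that the endogenous
(baseline-label) and tracer-derived pools of a labeled plant are quantified
concurrently against the same denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .eic import Chromatogram, PeakIntegration

__all__ = [
    "RatioEstimate",
    "QuantResult",
    "regression_ratio",
    "area_ratio",
    "isotope_dilution_quant",
    "reverse_dilution_quant",
    "label_fraction",
]


@dataclass(frozen=True)
class RatioEstimate:
    """OLS slope of trace vs monoisotopomer intensities."""

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise ValueError(f"need n >= 3 points, got {self.n}")
        if self.slope_se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class QuantResult:
    """Concentration of one channel of one compound, in ng/g fresh weight."""

    compound: str
    channel: str
    ratio: float
    q_is_ng: float
    fresh_weight_mg: float
    concentration: float  # ng / g FW
    ratio_se: float | None = None

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


def regression_ratio(
    trace: Chromatogram,
    mono: Chromatogram,
    rt_bounds: tuple[float, float] | None = None,
    zero_intercept: bool = False,
    weights: np.ndarray | None = None,
) -> RatioEstimate:
    """Scan-wise OLS of trace intensity on monoisotopomer intensity.

    The two chromatograms must share an identical RT grid.  By default the
    model includes an intercept (robust to constant background); a
    zero-intercept variant and user weights are available.
    """
    if trace.rt.shape != mono.rt.shape or not np.array_equal(trace.rt, mono.rt):
        raise ValueError("trace and monoisotopomer chromatograms must share one RT grid")
    x = mono.intensity
    y = trace.intensity
    if rt_bounds is not None:
        mask = (trace.rt >= rt_bounds[0]) & (trace.rt <= rt_bounds[1])
        x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 points in bounds, found {n}")
    if not np.any(x != 0):
        raise ValueError("monoisotopomer channel is identically zero: ratio undefined")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match the number of regression points")
    if zero_intercept:
        sw = np.sum(w * x * x)
        slope = float(np.sum(w * x * y) / sw)
        resid = y - slope * x
        dof = n - 1
        s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
        se = float(np.sqrt(s2 / sw))
        intercept = 0.0
    else:
        W = np.sum(w)
        xbar = np.sum(w * x) / W
        ybar = np.sum(w * y) / W
        sxx = np.sum(w * (x - xbar) ** 2)
        if sxx == 0:
            raise ValueError("monoisotopomer channel is constant: slope undefined")
        sxy = np.sum(w * (x - xbar) * (y - ybar))
        slope = float(sxy / sxx)
        intercept = float(ybar - slope * xbar)
        resid = y - (intercept + slope * x)
        dof = n - 2
        s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
        se = float(np.sqrt(s2 / sxx))
    syy = float(np.sum(w * (y - np.sum(w * y) / np.sum(w)) ** 2))
    ss_res = float(np.sum(w * resid**2))
    r2 = 1.0 if syy == 0 else max(0.0, 1.0 - ss_res / syy)
    return RatioEstimate(slope=slope, intercept=intercept, slope_se=se, r_squared=r2, n=n)


def area_ratio(peak_a: PeakIntegration, peak_b: PeakIntegration) -> float:
    """Ratio of two integrated peak areas, a / b."""
    if peak_b.area <= 0:
        raise ValueError("denominator peak area must be > 0")
    return peak_a.area / peak_b.area


def isotope_dilution_quant(
    ratio: float,
    q_is_ng: float,
    fresh_weight_mg: float,
    compound: str = "",
    channel: str = "endogenous",
    ratio_se: float | None = None,
) -> QuantResult:
    """Concentration from an analyte/internal-standard ratio.

    concentration [ng/g FW] = ratio x q_is [ng] / fresh weight [g].
    """
    if q_is_ng <= 0:
        raise ValueError("internal-standard amount must be > 0")
    if fresh_weight_mg <= 0:
        raise ValueError("fresh weight must be > 0")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    conc = ratio * q_is_ng / (fresh_weight_mg / 1000.0)
    return QuantResult(
        compound=compound,
        channel=channel,
        ratio=ratio,
        q_is_ng=q_is_ng,
        fresh_weight_mg=fresh_weight_mg,
        concentration=conc,
        ratio_se=ratio_se,
    )


def reverse_dilution_quant(
    channel_ratios: dict[str, float],
    q_std_ng: float,
    fresh_weight_mg: float,
    compound: str = "",
) -> dict[str, QuantResult]:
    """Quantify several labeled channels against one unlabeled standard.

    ``channel_ratios`` maps channel role (e.g. ``"endogenous"``,
    ``"tracer"``) to its signal ratio versus the unlabeled spiked standard;
    each channel gets the same isotope-dilution arithmetic, so endogenous
    and newly synthesized pools are reported side by side.
    """
    return {
        role: isotope_dilution_quant(
            r, q_std_ng, fresh_weight_mg, compound=compound, channel=role
        )
        for role, r in channel_ratios.items()
    }


def label_fraction(tracer_amount: float, endogenous_amount: float) -> float:
    """Fraction of the pool carrying the tracer label: tracer/(tracer+endogenous)."""
    if tracer_amount < 0 or endogenous_amount < 0:
        raise ValueError("amounts must be >= 0")
    total = tracer_amount + endogenous_amount
    if total == 0:
        raise ValueError("label fraction undefined: both amounts are zero")
    return tracer_amount / total


def ratio_confidence_interval(est: RatioEstimate, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for a regression slope."""
    dof = est.n - 2
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    return (est.slope - tcrit * est.slope_se, est.slope + tcrit * est.slope_se)
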