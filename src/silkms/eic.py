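"""Narrow-window extracted ion chromatograms and peak integration.

An EIC sums, per scan, the intensities of all centroids falling inside a
closed m/z window — the convention that makes channel signals proportional
to isotopologue amounts even when a satellite peak shares the window.
Integration is trapezoidal, optionally after subtracting a linear baseline
chord between the integration bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem import MzWindow
from .msdata import Run

__all__ = ["Chromatogram", "PeakIntegration", "extract_eic", "integrate_peak", "auto_bounds"]


@dataclass
class Chromatogram:
    """Per-scan summed intensity within one m/z window."""

    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray
    window: MzWindow | None = None
    compound: str | None = None
    channel: str | None = None

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("RT and intensity arrays differ in length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("RT array must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.rt.size

    def slice(self, rt_bounds: tuple[float, float]) -> "Chromatogram":
        lo, hi = rt_bounds
        mask = (self.rt >= lo) & (self.rt <= hi)
        return Chromatogram(
            self.rt[mask], self.intensity[mask], self.window, self.compound, self.channel
        )


@dataclass(frozen=True)
class PeakIntegration:
    """Result of integrating one chromatographic peak."""

    area: float  # intensity * min
    rt_bounds: tuple[float, float]
    baseline: str  # "none" | "linear"
    apex_rt: float
    apex_intensity: float


def extract_eic(
    run: Run,
    window: MzWindow,
    rt_range: tuple[float, float] | None = None,
    compound: str | None = None,
    channel: str | None = None,
) -> Chromatogram:
    """Extract one chromatogram point per scan within ``rt_range``.

    Window bounds are a closed interval; scans without a matching centroid
    contribute zero.  If the window lies outside every scan's acquisition
    range, the all-zero result is returned with a warning.
    """
    rts, values = [], []
    for s in run.spectra:
        if rt_range is not None and not (rt_range[0] <= s.rt <= rt_range[1]):
            continue
        lo = np.searchsorted(s.mz, window.low, side="left")
        hi = np.searchsorted(s.mz, window.high, side="right")
        rts.append(s.rt)
        values.append(float(s.intensity[lo:hi].sum()))
    chrom = Chromatogram(np.array(rts), np.array(values), window, compound, channel)
    if len(chrom) and not chrom.intensity.any() and not _window_covered(run, window):
        warnings.warn(
            f"window [{window.low:.4f}, {window.high:.4f}] lies outside all "
            "scan acquisition ranges; chromatogram is all zero",
            stacklevel=2,
        )
    return chrom


def _window_covered(run: Run, window: MzWindow) -> bool:
    for s in run.spectra:
        if s.scan_window is None:
            return True  # unknown acquisition range: assume covered
        if s.scan_window[0] <= window.high and window.low <= s.scan_window[1]:
            return True
    return False


def integrate_peak(
    chrom: Chromatogram,
    rt_bounds: tuple[float, float],
    baseline: str = "none",
) -> PeakIntegration:
    """Trapezoidal area between ``rt_bounds``.

    ``baseline="linear"`` subtracts the chord joining the boundary
    intensities; post-baseline values are clipped at zero before summation,
    so the area is always non-negative.
    """
    if baseline not in ("none", "linear"):
        raise ValueError(f"unknown baseline model {baseline!r}")
    sub = chrom.slice(rt_bounds)
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 points inside bounds {rt_bounds}, found {len(sub)}"
        )
    y = sub.intensity.copy()
    if baseline == "linear":
        chord = np.interp(sub.rt, [sub.rt[0], sub.rt[-1]], [y[0], y[-1]])
        y = np.clip(y - chord, 0.0, None)
    apex = int(np.argmax(sub.intensity))
    return PeakIntegration(
        area=float(np.trapezoid(y, sub.rt)),
        rt_bounds=tuple(rt_bounds),
        baseline=baseline,
        apex_rt=float(sub.rt[apex]),
        apex_intensity=float(sub.intensity[apex]),
    )


def auto_bounds(chrom: Chromatogram, k: float = 2.0) -> tuple[float, float]:
    """Apex-centred integration bounds: apex RT +/- k * FWHM.

    Estimates the full width at half maximum by linear interpolation of the
    half-height crossings around the apex.  Intended for simulated peaks;
    real targets carry configured RT windows instead.
    """
    if len(chrom) < 3:
        raise ValueError("need >= 3 points for automatic bounds")
    apex = int(np.argmax(chrom.intensity))
    half = chrom.intensity[apex] / 2.0
    if half <= 0:
        raise ValueError("flat chromatogram: no peak to bound")
    left = chrom.rt[0]
    for i in range(apex, 0, -1):
        if chrom.intensity[i - 1] < half:
            left = float(
                np.interp(
                    half,
                    [chrom.intensity[i - 1], chrom.intensity[i]],
                    [chrom.rt[i - 1], chrom.rt[i]],
                )
            )
            break
    right = chrom.rt[-1]
    for i in range(apex, len(chrom) - 1):
        if chrom.intensity[i + 1] < half:
            right = float(
                np.interp(
                    half,
                    [chrom.intensity[i + 1], chrom.intensity[i]],
                    [chrom.rt[i + 1], chrom.rt[i]],
                )
            )
            break
    fwhm = right - left
    apex_rt = float(chrom.rt[apex])
    return (apex_rt - k * fwhm, apex_rt + k * fwhm)
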