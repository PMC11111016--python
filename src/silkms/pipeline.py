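"""Orchestration: target design -> extraction -> quantification -> kinetics.

``run_quantify`` turns a sample manifest plus a target table into a tidy
per-channel quantification table; ``run_kinetics`` fits incorporation
curves per compound x channel x treatment group and compares treatment
arms against the reference group timepoint by timepoint.  All randomness
lives upstream in the simulator seed, so identical inputs give identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import IonTarget
from .eic import extract_eic, integrate_peak
from .kinetics import TimeSeries, compare_timepoints, fit_best, _FITTERS
from .msdata import Run, load_run
from .quant import isotope_dilution_quant, regression_ratio, area_ratio

__all__ = ["ExperimentConfig", "run_quantify", "run_kinetics"]

log = logging.getLogger(__name__)

QUANT_COLUMNS = [
    "sample", "treatment", "timepoint", "replicate", "compound", "channel",
    "ratio", "ratio_se", "concentration", "flag",
]


@dataclass
class ExperimentConfig:
    """Manifest-driven quantification settings.

    ``samples`` requires columns: file, timepoint, replicate, treatment,
    fresh_weight_mg, is_spike_ng.  ``mode`` is ``"regression"`` (slope of
    trace vs internal standard, default) or ``"area"``.
    """

    targets: list[IonTarget]
    samples: pd.DataFrame
    mode: str = "regression"
    kinetic_model: str | None = None  # None = lowest AICc among all models
    baseline: str = "none"
    outdir: Path | None = None
    runs: dict[str, Run] = field(default_factory=dict)  # optional in-memory runs

    def __post_init__(self):
        if self.mode not in ("regression", "area"):
            raise ValueError(f"unknown quantification mode {self.mode!r}")
        required = {"file", "timepoint", "replicate", "treatment",
                    "fresh_weight_mg", "is_spike_ng"}
        missing = required - set(self.samples.columns)
        if len(self.samples) and missing:
            raise ValueError(f"sample manifest lacks columns: {sorted(missing)}")


def _channel_ratio(run, target: IonTarget, is_target: IonTarget, mode: str, baseline: str):
    """(ratio, se) of one channel against the internal-standard channel."""
    bounds = target.rt_window
    trace = extract_eic(run, target.window, bounds, target.compound, target.channel)
    denom = extract_eic(run, is_target.window, bounds, target.compound, "internal-standard")
    if mode == "regression":
        est = regression_ratio(trace, denom, bounds)
        return est.slope, est.slope_se
    peak_t = integrate_peak(trace, bounds, baseline)
    peak_d = integrate_peak(denom, bounds, baseline)
    return area_ratio(peak_t, peak_d), None


def run_quantify(config: ExperimentConfig) -> pd.DataFrame:
    """Quantify every sample x compound x channel in the manifest.

    Unreadable files flag their rows and processing continues; channels not
    covered by a run's acquisition come back as missing values.  Exit state
    for the CLI: any flagged row -> exit code 2.
    """
    if not len(config.samples):
        log.warning("empty sample manifest: returning empty quantification table")
        return pd.DataFrame(columns=QUANT_COLUMNS)

    by_compound: dict[str, dict[str, IonTarget]] = {}
    for t in config.targets:
        by_compound.setdefault(t.compound, {})[t.channel] = t

    rows = []
    for _, sample in config.samples.iterrows():
        name = str(sample["file"])
        try:
            run = config.runs.get(name) or load_run(name)
        except (OSError, ValueError) as exc:
            log.error("sample %s unreadable: %s", name, exc)
            for compound, channels in by_compound.items():
                for channel in channels:
                    if channel == "internal-standard":
                        continue
                    rows.append(_row(sample, compound, channel, flag=f"unreadable: {exc}"))
            continue
        for compound, channels in by_compound.items():
            is_target = channels.get("internal-standard")
            if is_target is None:
                for channel in channels:
                    rows.append(_row(sample, compound, channel,
                                     flag="no internal-standard channel configured"))
                continue
            for channel, target in channels.items():
                if channel == "internal-standard":
                    continue
                try:
                    ratio, se = _channel_ratio(run, target, is_target, config.mode, config.baseline)
                    ratio = max(ratio, 0.0)  # noise can push a blank channel below zero
                    q = isotope_dilution_quant(
                        ratio,
                        float(sample["is_spike_ng"]),
                        float(sample["fresh_weight_mg"]),
                        compound=compound,
                        channel=channel,
                        ratio_se=se,
                    )
                    rows.append(_row(sample, compound, channel, ratio=ratio,
                                     ratio_se=se, concentration=q.concentration))
                except ValueError as exc:
                    rows.append(_row(sample, compound, channel, flag=str(exc)))
        log.info("quantified %s: %d scans", name, len(run))
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def _row(sample, compound, channel, ratio=np.nan, ratio_se=None,
         concentration=np.nan, flag=""):
    return {
        "sample": str(sample["file"]),
        "treatment": sample["treatment"],
        "timepoint": float(sample["timepoint"]),
        "replicate": sample["replicate"],
        "compound": compound,
        "channel": channel,
        "ratio": ratio,
        "ratio_se": np.nan if ratio_se is None else ratio_se,
        "concentration": concentration,
        "flag": flag,
    }


def run_kinetics(
    quant_table: pd.DataFrame,
    model: str | None = None,
    reference: str = "mock",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit incorporation curves and compare treatment arms per timepoint.

    Returns (fit table, comparison table).  One fit per compound x channel
    x treatment; comparisons test every non-reference arm against
    ``reference`` with a per-timepoint Student's t test on concentrations.
    """
    good = quant_table[quant_table["flag"] == ""].copy()
    fit_rows, cmp_rows = [], []
    for (compound, channel, arm), grp in good.groupby(["compound", "channel", "treatment"]):
        ts = TimeSeries(
            grp["timepoint"].to_numpy(float),
            grp["concentration"].to_numpy(float),
            group=str(arm),
        )
        try:
            if model is None:
                fit = fit_best(ts)
            else:
                fit = _FITTERS[model](ts)
        except (ValueError, KeyError) as exc:
            fit_rows.append({"compound": compound, "channel": channel, "treatment": arm,
                             "model": model or "auto", "converged": False,
                             "message": str(exc)})
            continue
        row = {"compound": compound, "channel": channel, "treatment": arm,
               "model": fit.model, "converged": fit.converged,
               "rss": fit.rss, "aicc": fit.aicc, "half_time": fit.half_time,
               "message": fit.message}
        for p, v in fit.params.items():
            row[p] = v
            row[f"{p}_se"] = fit.stderr.get(p, np.nan)
        fit_rows.append(row)

    arms = [a for a in good["treatment"].unique() if a != reference]
    for (compound, channel), grp in good.groupby(["compound", "channel"]):
        ref = grp[grp["treatment"] == reference]
        if not len(ref):
            continue
        ref_ts = TimeSeries(ref["timepoint"].to_numpy(float),
                            ref["concentration"].to_numpy(float))
        for arm in arms:
            other = grp[grp["treatment"] == arm]
            if not len(other):
                continue
            other_ts = TimeSeries(other["timepoint"].to_numpy(float),
                                  other["concentration"].to_numpy(float))
            table = compare_timepoints(ref_ts, other_ts)
            table.insert(0, "compound", compound)
            table.insert(1, "channel", channel)
            table.insert(2, "treatment", arm)
            cmp_rows.append(table)
    comparisons = (
        pd.concat(cmp_rows, ignore_index=True)
        if cmp_rows
        else pd.DataFrame(columns=["compound", "channel", "treatment", "time",
                                   "n_a", "n_b", "t", "p", "note"])
    )
    return pd.DataFrame(fit_rows), comparisons
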