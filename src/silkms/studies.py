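"""Self-contained validation studies run by the test suite and the
reproduction script.

Each function sets up its own inputs (formulas, label schemes, simulated
experiments) and returns plain numbers, so results are reproducible from a
single seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .chem import Formula, LabelScheme, ion_mz, isotopologue_envelope, labeled_mz, window_for, ISOTOPES
from .eic import Chromatogram, extract_eic, integrate_peak
from .kinetics import TimeSeries, compare_timepoints, fit_first_order
from .pipeline import ExperimentConfig, run_quantify
from .quant import area_ratio, isotope_dilution_quant, regression_ratio
from .simulate import (
    LabelState,
    SimConfig,
    default_network,
    effective_rate,
    iter_samples,
    synthesize_run,
)
from .chem import build_target_table

QUINOLINIUM = Formula.parse("C9H8N")
IAA = Formula.parse("C10H9NO2")

#: The five monitored quinolinium channels (label scheme string per channel).
QUINOLINIUM_SCHEMES = ("", "15N1", "13C6", "2H4", "13C8,15N1")


def isotope_increments() -> dict[str, float]:
    """Exact-mass increments of one heavy substitution, 5 d.p."""
    return {
        "13C": round(ISOTOPES.heavy_shift("C", 13), 5),
        "2H": round(ISOTOPES.heavy_shift("H", 2), 5),
        "15N": round(ISOTOPES.heavy_shift("N", 15), 5),
    }


def quinolinium_windows() -> dict[str, tuple[float, float]]:
    """Extraction windows (4 d.p.) for every monitored quinolinium channel."""
    base = ion_mz(QUINOLINIUM)
    out = {}
    for scheme in QUINOLINIUM_SCHEMES:
        mz = labeled_mz(base, LabelScheme.parse(scheme))
        w = window_for(mz)
        out[scheme] = (w.low, w.high)
    return out


def iaa_m1_percent() -> float:
    """M+1/M+0 of IAA under natural abundances, in percent."""
    return float(isotopologue_envelope(IAA, 1)[1])


def regression_vs_area(background: float = 0.0, ratio: float = 0.25) -> dict[str, float]:
    """Compare slope- and area-based ratio estimates on a synthetic peak pair.

    With ``background`` added to the trace channel, the regression intercept
    absorbs it while the plain area ratio is biased upward — the motivation
    for slope-based quantification under background noise.
    """
    rt = np.linspace(0.0, 1.0, 101)
    mono = Chromatogram(rt, 5000.0 * np.exp(-0.5 * ((rt - 0.5) / 0.08) ** 2))
    trace = Chromatogram(rt, ratio * mono.intensity + background)
    slope = regression_ratio(trace, mono).slope
    areas = area_ratio(
        integrate_peak(trace, (0.0, 1.0)), integrate_peak(mono, (0.0, 1.0))
    )
    return {"truth": ratio, "slope": slope, "area": areas}


def _iaa_targets(design):
    return build_target_table(
        [("IAA", IAA, (4.2, 4.8), None)], design, protonated=True
    )


def _quantify_experiment(cfg: SimConfig, network=None) -> pd.DataFrame:
    network = network or default_network()
    runs, rows = {}, []
    for arm, ai, net, state, tp, rep in iter_samples(cfg, network):
        run, _ = synthesize_run(net, state, cfg, tp, rep, arm, ai)
        name = f"{arm}_{tp:g}_{rep}"
        runs[name] = run
        rows.append(
            {"file": name, "timepoint": tp, "replicate": rep, "treatment": arm,
             "fresh_weight_mg": cfg.fresh_weight_mg, "is_spike_ng": cfg.is_spike_ng}
        )
    return run_quantify(
        ExperimentConfig(
            targets=_iaa_targets(cfg.design), samples=pd.DataFrame(rows), runs=runs
        )
    )


def dilution_roundtrip(seed: int, noise_mult_sd: float = 0.0) -> dict[str, float]:
    """Simulate, quantify and compare against truth for the IAA channels.

    Concentrations are recovered as replicate means (3 biological
    replicates, as sampled per timepoint); returns the worst relative error
    across timepoints and channels, plus the ratio-1 sanity value (0.2 ng
    spike into 10 mg tissue at ratio 1).
    """
    cfg = SimConfig(
        seed=seed,
        timepoints=(1.0, 8.0, 64.0),
        replicates=3,
        noise_mult_sd=noise_mult_sd,
        baseline_counts=20.0 if noise_mult_sd else 0.0,
        mass_error_ppm_sd=2.0 if noise_mult_sd else 0.0,
        rt_range=(4.0, 5.0),
    )
    network = default_network()
    table = _quantify_experiment(cfg, network)
    frac = LabelState(network, cfg.entry_pool).at(np.array(cfg.timepoints))
    pool = network.pools["IAA"].pool_size
    errors = []
    for tp in cfg.timepoints:
        L = float(frac.loc[tp, "IAA"])
        truth = {"tracer": L * pool, "endogenous": (1 - L) * pool}
        for channel, true_conc in truth.items():
            got = table[(table.timepoint == tp) & (table.channel == channel)][
                "concentration"
            ].to_numpy()
            if true_conc > 0.01 * pool:  # skip near-zero channels: rel err undefined
                errors.append(abs(float(np.mean(got)) - true_conc) / true_conc)
    return {
        "max_rel_error": float(np.max(errors)),
        "unit_ratio_conc": isotope_dilution_quant(1.0, 0.2, 10.0).concentration,
    }


def k_recovery_study(
    base_seed: int, n_seeds: int = 200, tolerance: float = 0.15
) -> dict[str, float]:
    """Recover the effective IAA incorporation rate over many noisy replicates.

    Each replicate simulates a full mock-arm experiment (9 timepoints from
    0.5 to 256 min, 3 biological replicates, 5% multiplicative noise),
    quantifies the tracer channel and fits first-order incorporation.
    Returns the fraction of replicates whose fitted k lies within
    ``tolerance`` of the deterministic effective rate.
    """
    network = default_network()
    timepoints = SimConfig(seed=0).timepoints
    k_eff = effective_rate(network, "anthranilate", "IAA", np.array(timepoints))
    hits, ks = 0, []
    for i in range(n_seeds):
        cfg = SimConfig(seed=base_seed + i, rt_range=(4.0, 5.0))
        table = _quantify_experiment(cfg, network)
        tracer = table[table.channel == "tracer"]
        fit = fit_first_order(
            TimeSeries(tracer.timepoint.to_numpy(float), tracer.concentration.to_numpy(float))
        )
        if fit.converged:
            ks.append(fit.params["k"])
            if abs(fit.params["k"] - k_eff) / k_eff <= tolerance:
                hits += 1
    return {
        "k_eff": k_eff,
        "fraction_within_tolerance": hits / n_seeds,
        "median_k": float(np.median(ks)),
        "n_seeds": n_seeds,
    }


def inhibitor_significance(seed: int) -> pd.DataFrame:
    """Per-timepoint mock-vs-inhibitor t tests on the tracer IAA channel.

    The inhibitor arm multiplies the Trp -> IPyA step by 0.1.
    """
    cfg = SimConfig(
        seed=seed, rt_range=(4.0, 5.0),
        treatments={"mock": {}, "inhibitor": {("Trp", "IPyA"): 0.1}},
    )
    table = _quantify_experiment(cfg)
    tracer = table[table.channel == "tracer"]
    mock = tracer[tracer.treatment == "mock"]
    inh = tracer[tracer.treatment == "inhibitor"]
    return compare_timepoints(
        TimeSeries(mock.timepoint.to_numpy(float), mock.concentration.to_numpy(float)),
        TimeSeries(inh.timepoint.to_numpy(float), inh.concentration.to_numpy(float)),
    )


def ttest_type_i_rate(
    seed: int, n_reps: int = 10_000, n_per_group: int = 3, alpha: float = 0.05
) -> float:
    """Empirical type-I error of the per-timepoint Student's t test."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group))
    _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    return float(np.mean(p < alpha))
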