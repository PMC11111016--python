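"""Synthetic SILK experiments: tracer kinetics through a metabolic pool
network, rendered as LC-MS runs with ground truth.

The model is a steady-state pool network: pool sizes are constant and only
*label fractions* evolve.  Under step labeling of the entry pool, the label
fraction of pool i with inflow flux k_i (sum of inbound edge constants
times their inhibitor multipliers, in ng/g/min) and size P_i (ng/g) obeys

    dL_i/dt = (k_i / P_i) * (L_upstream - L_i),

a linear ODE solved exactly by matrix exponential.  Each sampled seedling
becomes one simulated LC-MS run: Gaussian elution peaks per pool with one
centroid per isotopologue channel (endogenous baseline-label channel scaled
by 1-L, tracer channel by L, unlabeled internal-standard channel by the
spike), natural-abundance M+1 satellites, per-channel log-normal amplitude
noise, optional Poisson counting noise, additive baseline centroids and
ppm-scale mass error.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .chem import Formula, LabelScheme, LabelingDesign, ion_mz, isotopologue_envelope
from .msdata import Run, Spectrum, write_run

__all__ = [
    "Pool",
    "PoolNetwork",
    "LabelState",
    "SimConfig",
    "default_network",
    "default_design",
    "solve_label_kinetics",
    "synthesize_run",
    "generate_experiment",
    "iter_samples",
    "effective_rate",
]

#: Nominal exact-mass offset used to place M+1 satellites (dominant 13C shift).
M1_OFFSET = 1.0033548378


@dataclass(frozen=True)
class Pool:
    """One metabolite pool rendered as one chromatographic peak."""

    name: str
    ion_formula: Formula
    pool_size: float  # steady-state size, ng/g FW
    rt: float  # apex retention time, min
    peak_sd: float  # chromatographic sigma, min


@dataclass
class PoolNetwork:
    """Acyclic directed network of metabolite pools.

    ``edges`` maps (upstream, downstream) to a first-order flux constant in
    ng/g/min; ``inhibitor_factors`` multiplies individual edges by a factor
    in [0, 1] (an inhibitor treatment).
    """

    pools: dict[str, Pool]
    edges: dict[tuple[str, str], float]
    inhibitor_factors: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        g = nx.DiGraph(list(self.edges))
        for (a, b), k in self.edges.items():
            if k < 0:
                raise ValueError(f"rate constant for {a}->{b} must be >= 0")
            if a not in self.pools or b not in self.pools:
                raise ValueError(f"edge {a}->{b} references unknown pool")
        for edge, m in self.inhibitor_factors.items():
            if edge not in self.edges:
                raise ValueError(f"inhibitor factor on unknown edge {edge}")
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"inhibitor multiplier must be in [0,1], got {m}")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("pool network must be acyclic")

    def with_inhibitors(self, factors: dict[tuple[str, str], float]) -> "PoolNetwork":
        merged = dict(self.inhibitor_factors)
        merged.update(factors)
        return PoolNetwork(self.pools, self.edges, merged)

    def effective_edge(self, edge: tuple[str, str]) -> float:
        return self.edges[edge] * self.inhibitor_factors.get(edge, 1.0)

    def pool_order(self) -> list[str]:
        g = nx.DiGraph(list(self.edges))
        g.add_nodes_from(self.pools)
        return list(nx.topological_sort(g))


@dataclass
class LabelState:
    """Exact solution of the label-fraction ODE for one network and tracer."""

    network: PoolNetwork
    entry_pool: str
    tracer_start: float = 0.0
    uptake_rate: float | None = None  # 1/min; None = instantaneous step to 1

    def __post_init__(self):
        order = [p for p in self.network.pool_order()]
        if self.entry_pool not in self.network.pools:
            raise ValueError(f"unknown entry pool {self.entry_pool!r}")
        # state pools: entry included only under finite uptake
        instant = self.uptake_rate is None
        self._state_pools = [p for p in order if not (instant and p == self.entry_pool)]
        idx = {p: i for i, p in enumerate(self._state_pools)}
        n = len(self._state_pools)
        A = np.zeros((n, n))
        c = np.zeros(n)
        for p in self._state_pools:
            i = idx[p]
            if p == self.entry_pool:  # finite-uptake entry: fed by fully labeled source
                A[i, i] -= self.uptake_rate
                c[i] += self.uptake_rate
                continue
            inflows = [
                (src, self.network.effective_edge((src, dst)))
                for (src, dst) in self.network.edges
                if dst == p
            ]
            total = sum(k for _, k in inflows)
            if total == 0:
                continue
            r = total / self.network.pools[p].pool_size
            A[i, i] -= r
            for src, k in inflows:
                w = r * (k / total)
                if instant and src == self.entry_pool:
                    c[i] += w  # entry fixed at L = 1
                else:
                    A[i, idx[src]] += w
        self._A, self._c = A, c

    def at(self, times: np.ndarray) -> pd.DataFrame:
        """Label fractions per pool at the requested times (rows = times)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        n = len(self._state_pools)
        # augmented system d/dt [L, 1] = [[A, c], [0, 0]] [L, 1]
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = self._A
        M[:n, n] = self._c
        out = np.zeros((times.size, len(self.network.pools)))
        cols = list(self.network.pools)
        col_idx = {p: j for j, p in enumerate(cols)}
        x0 = np.zeros(n + 1)
        x0[n] = 1.0
        for ti, t in enumerate(times):
            dt = t - self.tracer_start
            if dt <= 0:
                frac = np.zeros(n)
            else:
                frac = (expm(M * dt) @ x0)[:n]
            frac = np.clip(frac, 0.0, 1.0)
            for p, i in zip(self._state_pools, range(n)):
                out[ti, col_idx[p]] = frac[i]
            if self.uptake_rate is None:
                out[ti, col_idx[self.entry_pool]] = 1.0 if dt > 0 else 0.0
        return pd.DataFrame(out, index=times, columns=cols)


def solve_label_kinetics(
    network: PoolNetwork,
    times: np.ndarray,
    entry_pool: str,
    tracer_start: float = 0.0,
    uptake_rate: float | None = None,
) -> pd.DataFrame:
    """Label fraction of every pool at ``times`` under step tracer labeling."""
    state = LabelState(network, entry_pool, tracer_start, uptake_rate)
    return state.at(times)


@dataclass
class SimConfig:
    """Experiment-level simulation parameters.

    Noise model: per-channel log-normal amplitude factor (sigma =
    ``noise_mult_sd``), additive exponential baseline centroids with mean
    ``baseline_counts`` in every channel window, optional Poisson counting
    noise, and Gaussian m/z error with ``mass_error_ppm_sd`` ppm.
    """

    seed: int
    timepoints: tuple[float, ...] = (0.5, 1.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0)
    replicates: int = 3
    noise_mult_sd: float = 0.05
    baseline_counts: float = 20.0
    poisson: bool = False
    mass_error_ppm_sd: float = 2.0
    scan_interval_s: float = 1.0
    rt_range: tuple[float, float] = (0.0, 8.5)
    design: LabelingDesign | None = None
    is_spike_ng: float = 0.2
    fresh_weight_mg: float = 10.0
    response_factor: float = 1000.0  # counts per ng/g at the peak apex
    half_width: float = 0.0010
    entry_pool: str = "anthranilate"
    uptake_rate: float | None = None
    treatments: dict = field(default_factory=lambda: {"mock": {}})

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        tp = tuple(float(t) for t in self.timepoints)
        if any(t < 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be non-negative and ascending")
        self.timepoints = tp
        if self.design is None:
            self.design = default_design()


def default_design() -> LabelingDesign:
    """Reverse isotope dilution design: 15N baseline, 13C6 tracer, unlabeled IS."""
    return LabelingDesign(
        tracer=LabelScheme.parse("13C6"),
        baseline=LabelScheme.parse("15N1"),
        internal_standard=LabelScheme(),
    )


def default_network() -> PoolNetwork:
    """Five-pool auxin biosynthesis chain with inhibitable steps.

    anthranilate -> indole -> Trp -> IPyA -> IAA, sized and paced so that
    precursor pools turn over in roughly a minute and the IAA pool on the
    tens-of-minutes scale.  Pool sizes, retention times and peak widths are
    synthetic but plausible for seedling extracts on a short C18 gradient.
    A Trp-independent indole -> IAA shunt can be enabled by adding that
    edge with a nonzero rate.
    """
    pools = {
        "anthranilate": Pool("anthranilate", Formula.parse("C7H7NO2"), 5.0, 3.4, 0.05),
        "indole": Pool("indole", Formula.parse("C8H7N"), 10.0, 7.2, 0.05),
        "Trp": Pool("Trp", Formula.parse("C11H12N2O2"), 500.0, 1.5, 0.05),
        "IPyA": Pool("IPyA", Formula.parse("C11H9NO3"), 2.0, 6.3, 0.05),
        "IAA": Pool("IAA", Formula.parse("C10H9NO2"), 20.0, 4.5, 0.05),
    }
    # fluxes in ng/g/min; per-pool labeling rates r = flux / pool size are
    # ~0.8 (indole), 0.5 (Trp), 0.04 (IPyA) and 0.1 (IAA) per minute, giving
    # percent-scale IAA labeling within minutes and an IPyA step that
    # becomes hours-scale rate limiting when inhibited tenfold
    edges = {
        ("anthranilate", "indole"): 8.0,
        ("indole", "Trp"): 250.0,
        ("Trp", "IPyA"): 0.08,
        ("IPyA", "IAA"): 2.0,
    }
    return PoolNetwork(pools, edges)


def _channel_catalog(network: PoolNetwork, config: SimConfig):
    """Per pool x channel: m/z, satellite m/z and satellite relative abundance."""
    rows = []
    for pool in network.pools.values():
        base = ion_mz(pool.ion_formula, 1, protonated=True)
        m1 = float(isotopologue_envelope(pool.ion_formula, 1)[1]) / 100.0
        for role, scheme in config.design.channels():
            scheme.validate(pool.ion_formula)
            mz = base + scheme.mass_shift()
            rows.append((pool, role, scheme, mz, m1))
    return rows


def synthesize_run(
    network: PoolNetwork,
    label_state: LabelState,
    config: SimConfig,
    timepoint: float,
    replicate: int,
    arm: str = "mock",
    arm_index: int = 0,
) -> tuple[Run, dict]:
    """Render one sampled seedling as a centroided SIM run plus truth row."""
    t_idx = config.timepoints.index(float(timepoint))
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=int(config.seed), spawn_key=(arm_index, t_idx, int(replicate))
        )
    )
    fractions = label_state.at([timepoint]).iloc[0]
    spike_equiv = config.is_spike_ng / (config.fresh_weight_mg / 1000.0)  # ng/g

    rt_lo, rt_hi = config.rt_range
    dt = config.scan_interval_s / 60.0
    rts = np.arange(rt_lo, rt_hi + 0.5 * dt, dt)
    n_scans = rts.size

    mzs, amps, profiles = [], [], []
    truth = {
        "arm": arm,
        "timepoint": timepoint,
        "replicate": replicate,
        "window_collision": False,
    }
    catalog = _channel_catalog(network, config)
    for pool, role, scheme, mz, m1 in catalog:
        L = float(fractions[pool.name])
        if role == "endogenous":
            conc = (1.0 - L) * pool.pool_size
        elif role == "tracer":
            conc = L * pool.pool_size
        else:
            conc = spike_equiv
        amp = conc * config.response_factor
        if config.noise_mult_sd > 0:
            amp *= float(np.exp(config.noise_mult_sd * rng.standard_normal()))
        gauss = np.exp(-0.5 * ((rts - pool.rt) / pool.peak_sd) ** 2)
        for peak_mz, peak_amp in ((mz, amp), (mz + M1_OFFSET, amp * m1)):
            mzs.append(peak_mz)
            amps.append(peak_amp)
            profiles.append(gauss)
        truth[f"L_{pool.name}"] = L
        truth[f"conc_endogenous_{pool.name}"] = (1.0 - L) * pool.pool_size
        truth[f"conc_tracer_{pool.name}"] = L * pool.pool_size
        truth[f"conc_is_{pool.name}"] = spike_equiv

    mzs = np.array(mzs)
    inten = np.array(amps)[:, None] * np.vstack(profiles)  # channels x scans
    if config.poisson:
        inten = rng.poisson(inten).astype(float)
    if config.mass_error_ppm_sd > 0:
        jitter = rng.standard_normal((mzs.size, n_scans)) * (
            mzs[:, None] * config.mass_error_ppm_sd * 1e-6
        )
    else:
        jitter = np.zeros((mzs.size, n_scans))
    scan_mz = mzs[:, None] + jitter

    # additive baseline: one exponential-intensity centroid per channel window
    if config.baseline_counts > 0:
        base_int = rng.exponential(config.baseline_counts, (mzs.size, n_scans))
        base_mz = mzs[:, None] + rng.uniform(
            -config.half_width, config.half_width, (mzs.size, n_scans)
        )
    else:
        base_int = base_mz = None

    # collision bookkeeping: any two channel centers closer than a window width
    sorted_mz = np.sort(mzs)
    if np.any(np.diff(sorted_mz) < 2 * config.half_width):
        truth["window_collision"] = True

    mz_range = (float(np.floor(mzs.min() - 2)), float(np.ceil(mzs.max() + 2)))
    spectra = []
    for j in range(n_scans):
        col_mz = scan_mz[:, j]
        col_in = inten[:, j]
        if base_int is not None:
            col_mz = np.concatenate([col_mz, base_mz[:, j]])
            col_in = np.concatenate([col_in, base_int[:, j]])
        keep = col_in > 1e-9
        col_mz, col_in = col_mz[keep], col_in[keep]
        order = np.argsort(col_mz)
        col_mz, col_in = col_mz[order], col_in[order]
        # merge exact m/z ties to keep arrays strictly increasing
        if col_mz.size > 1 and np.any(np.diff(col_mz) == 0):
            uniq, inverse = np.unique(col_mz, return_inverse=True)
            col_in = np.bincount(inverse, weights=col_in)
            col_mz = uniq
        spectra.append(
            Spectrum(rt=float(rts[j]), mz=col_mz, intensity=col_in, scan_window=mz_range)
        )
    run = Run(
        spectra=spectra,
        metadata={
            "run_id": f"{arm}_t{timepoint:g}_r{replicate}",
            "arm": arm,
            "timepoint": timepoint,
            "replicate": replicate,
        },
    )
    return run, truth


def effective_rate(
    network: PoolNetwork,
    entry_pool: str,
    pool: str,
    times: np.ndarray,
    uptake_rate: float | None = None,
) -> float:
    """Effective first-order incorporation rate of a pool's label curve.

    A multi-pool cascade is not a single exponential; the *effective* rate —
    the k of the best first-order fit to the noise-free label-fraction curve
    at the sampled times — is the well-defined ground truth that a
    first-order fit of measured data estimates.
    """
    from .kinetics import TimeSeries, fit_first_order

    frac = solve_label_kinetics(network, times, entry_pool, uptake_rate=uptake_rate)
    fit = fit_first_order(TimeSeries(np.asarray(times, float), frac[pool].to_numpy()))
    if not fit.converged:
        raise ValueError(f"effective-rate fit did not converge: {fit.message}")
    return float(fit.params["k"])


def iter_samples(config: SimConfig, network: PoolNetwork):
    """Yield (arm, arm_index, network_with_inhibitors, label_state, timepoint, replicate)."""
    for arm_index, (arm, factors) in enumerate(config.treatments.items()):
        net = network.with_inhibitors(
            {tuple(edge): m for edge, m in factors.items()}
        )
        state = LabelState(net, config.entry_pool, uptake_rate=config.uptake_rate)
        for tp in config.timepoints:
            for rep in range(1, config.replicates + 1):
                yield arm, arm_index, net, state, tp, rep


def generate_experiment(
    config: SimConfig,
    network: PoolNetwork,
    outdir: str | Path,
    force: bool = False,
) -> dict:
    """Write one mzML run per (treatment x timepoint x replicate) plus truth tables.

    Returns a manifest dict (also written as ``manifest.json``) listing every
    run file with its sample coordinates, the seed and a config hash.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    truth_rows, entries = [], []
    for arm, arm_index, net, state, tp, rep in iter_samples(config, network):
        run, truth = synthesize_run(net, state, config, tp, rep, arm, arm_index)
        fname = f"{arm}_t{tp:g}_r{rep}.mzML"
        write_run(run, outdir / fname)
        truth["file"] = fname
        truth_rows.append(truth)
        entries.append(
            {"file": fname, "treatment": arm, "timepoint": tp, "replicate": rep,
             "fresh_weight_mg": config.fresh_weight_mg, "is_spike_ng": config.is_spike_ng}
        )

    truth = pd.DataFrame(truth_rows)
    for arm, factors in config.treatments.items():
        net = network.with_inhibitors({tuple(e): m for e, m in factors.items()})
        for pool in network.pools:
            try:
                k_eff = effective_rate(
                    net, config.entry_pool, pool, np.array(config.timepoints),
                    uptake_rate=config.uptake_rate,
                )
            except ValueError:
                k_eff = np.nan
            truth.loc[truth["arm"] == arm, f"k_eff_{pool}"] = k_eff
    truth.to_csv(outdir / "truth.csv", index=False)

    cfg = asdict(config)
    cfg["design"] = str(cfg["design"])
    cfg["treatments"] = {
        arm: {f"{a}->{b}": m for (a, b), m in factors.items()}
        for arm, factors in config.treatments.items()
    }
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_runs": len(entries),
        "samples": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    pd.DataFrame(entries).to_csv(outdir / "samples.csv", index=False)
    return manifest
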