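"""Tracer kinetics solver and synthetic run generation."""

import numpy as np
import pandas as pd
import pytest

from silkms.chem import Formula
from silkms.eic import extract_eic, integrate_peak
from silkms.msdata import load_run
from silkms.chem import window_for, ion_mz
from silkms.simulate import (
    LabelState,
    Pool,
    PoolNetwork,
    SimConfig,
    default_design,
    default_network,
    generate_experiment,
    solve_label_kinetics,
    synthesize_run,
)

TIMES = np.array([0.0, 1.0, 5.0, 10.0, 20.0, 50.0])


def chain(rates: dict[str, float]) -> PoolNetwork:
    """Linear chain entry -> p1 -> p2 ... with per-pool labeling rates."""
    names = ["entry"] + list(rates)
    pools = {
        n: Pool(n, Formula.parse("C10H9NO2"), 10.0, 2.0 + i, 0.05)
        for i, n in enumerate(names)
    }
    edges = {}
    for up, down in zip(names, names[1:]):
        edges[(up, down)] = rates[down] * pools[down].pool_size
    return PoolNetwork(pools, edges)


class TestSolveLabelKinetics:
    def test_single_pool_closed_form(self):
        net = chain({"p1": 0.2})
        frac = solve_label_kinetics(net, TIMES, "entry")["p1"].to_numpy()
        expected = np.where(TIMES > 0, 1 - np.exp(-0.2 * TIMES), 0.0)
        np.testing.assert_allclose(frac, expected, atol=1e-12)
        # half of the pool is labeled at t = ln2 / r
        t_half = np.log(2) / 0.2
        half = solve_label_kinetics(net, np.array([t_half]), "entry")["p1"].iloc[0]
        assert half == pytest.approx(0.5, abs=1e-12)

    def test_two_pool_cascade_closed_form(self):
        r = 0.2
        net = chain({"p1": r, "p2": r})
        frac = solve_label_kinetics(net, TIMES, "entry")["p2"].to_numpy()
        expected = np.where(TIMES > 0, 1 - (1 + r * TIMES) * np.exp(-r * TIMES), 0.0)
        np.testing.assert_allclose(frac, expected, atol=1e-9)

    def test_blocked_pathway_stays_unlabeled(self):
        net = chain({"p1": 0.2, "p2": 0.3}).with_inhibitors({("entry", "p1"): 0.0})
        frac = solve_label_kinetics(net, TIMES, "entry")
        assert not frac["p1"].to_numpy().any()
        assert not frac["p2"].to_numpy().any()

    def test_fractions_monotone_in_time(self):
        net = default_network()
        t = np.linspace(0, 300, 40)
        frac = solve_label_kinetics(net, t, "anthranilate")
        for pool in net.pools:
            assert (np.diff(frac[pool].to_numpy()) >= -1e-12).all()

    def test_inhibition_never_increases_downstream_label(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            rates = {f"p{i}": float(rng.uniform(0.01, 1.0)) for i in range(1, 5)}
            net = chain(rates)
            edge = ("p1", "p2")
            mult = float(rng.uniform(0.0, 1.0))
            base = solve_label_kinetics(net, TIMES, "entry")
            inhib = solve_label_kinetics(net.with_inhibitors({edge: mult}), TIMES, "entry")
            for pool in rates:
                assert (inhib[pool].to_numpy() <= base[pool].to_numpy() + 1e-12).all()

    def test_matches_fine_step_euler(self):
        rng = np.random.default_rng(4)
        rates = {f"p{i}": float(rng.uniform(0.05, 0.5)) for i in range(1, 6)}
        net = chain(rates)
        t_end = 30.0
        exact = solve_label_kinetics(net, np.array([t_end]), "entry").iloc[0]
        # fine-step explicit (Heun) integration as the independent integrator
        names = list(rates)
        r = np.array([rates[n] for n in names])
        L = np.zeros(len(names))
        dt = 1e-3

        def deriv(vec):
            upstream = np.concatenate([[1.0], vec[:-1]])
            return r * (upstream - vec)

        for _ in range(int(t_end / dt)):
            k1 = deriv(L)
            k2 = deriv(L + dt * k1)
            L = L + 0.5 * dt * (k1 + k2)
        for n, val in zip(names, L):
            assert exact[n] == pytest.approx(val, abs=1e-6)

    def test_finite_uptake_slows_entry(self):
        net = chain({"p1": 0.5})
        instant = solve_label_kinetics(net, TIMES, "entry")
        slow = solve_label_kinetics(net, TIMES, "entry", uptake_rate=0.1)
        assert (slow["entry"].to_numpy() <= instant["entry"].to_numpy() + 1e-12).all()
        expected_entry = np.where(TIMES > 0, 1 - np.exp(-0.1 * TIMES), 0.0)
        np.testing.assert_allclose(slow["entry"].to_numpy(), expected_entry, atol=1e-9)

    def test_cyclic_network_rejected(self):
        pools = {
            "a": Pool("a", Formula.parse("CH4"), 1.0, 1.0, 0.05),
            "b": Pool("b", Formula.parse("CH4"), 1.0, 2.0, 0.05),
        }
        with pytest.raises(ValueError, match="acyclic"):
            PoolNetwork(pools, {("a", "b"): 1.0, ("b", "a"): 1.0})


def noise_free_config(**kw) -> SimConfig:
    defaults = dict(
        seed=1, noise_mult_sd=0.0, baseline_counts=0.0, mass_error_ppm_sd=0.0,
        rt_range=(4.0, 5.0),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSynthesizeRun:
    def test_unlabeled_sample_has_empty_tracer_channel(self):
        net = default_network()
        cfg = noise_free_config(timepoints=(0.0, 1.0))
        state = LabelState(net, "anthranilate")
        run, truth = synthesize_run(net, state, cfg, 0.0, 1)
        assert truth["L_IAA"] == 0.0
        mz = ion_mz(net.pools["IAA"].ion_formula, protonated=True)
        tracer_mz = mz + cfg.design.tracer.mass_shift()
        eic = extract_eic(run, window_for(tracer_mz), (4.0, 5.0))
        assert eic.intensity.sum() == 0.0

    def test_noise_free_quantification_matches_truth(self):
        net = default_network()
        cfg = noise_free_config()
        state = LabelState(net, "anthranilate")
        run, truth = synthesize_run(net, state, cfg, 16.0, 1)
        base = ion_mz(net.pools["IAA"].ion_formula, protonated=True)
        bounds = (4.2, 4.8)
        areas = {}
        for role, scheme in cfg.design.channels():
            eic = extract_eic(run, window_for(base + scheme.mass_shift()), bounds)
            areas[role] = integrate_peak(eic, bounds).area
        spike_equiv = cfg.is_spike_ng / (cfg.fresh_weight_mg / 1000.0)
        est_tracer = areas["tracer"] / areas["internal-standard"] * spike_equiv
        est_endo = areas["endogenous"] / areas["internal-standard"] * spike_equiv
        assert est_tracer == pytest.approx(truth["conc_tracer_IAA"], rel=0.01)
        assert est_endo == pytest.approx(truth["conc_endogenous_IAA"], rel=0.01)

    def test_same_seed_reproduces_identically(self):
        net = default_network()
        cfg = SimConfig(seed=77, rt_range=(4.0, 5.0))
        state = LabelState(net, "anthranilate")
        run_a, _ = synthesize_run(net, state, cfg, 8.0, 2)
        run_b, _ = synthesize_run(net, state, cfg, 8.0, 2)
        for a, b in zip(run_a.spectra, run_b.spectra):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_m1_satellite_present_at_expected_abundance(self):
        net = default_network()
        cfg = noise_free_config(timepoints=(0.0, 1.0))
        state = LabelState(net, "anthranilate")
        run, _ = synthesize_run(net, state, cfg, 0.0, 1)
        base = ion_mz(net.pools["IAA"].ion_formula, protonated=True)
        mono = extract_eic(run, window_for(base), (4.2, 4.8))
        sat = extract_eic(run, window_for(base + 1.00335), (4.2, 4.8))
        from silkms.chem import isotopologue_envelope

        expected = isotopologue_envelope(net.pools["IAA"].ion_formula, 1)[1] / 100
        assert sat.intensity.max() / mono.intensity.max() == pytest.approx(expected, rel=1e-6)


class TestGenerateExperiment:
    def test_run_count_and_manifest(self, tmp_path):
        net = default_network()
        cfg = SimConfig(
            seed=5, timepoints=(0.0, 4.0, 16.0), replicates=3,
            rt_range=(4.0, 5.0), scan_interval_s=2.0,
            treatments={"mock": {}, "inhibitor": {("Trp", "IPyA"): 0.1}},
        )
        manifest = generate_experiment(cfg, net, tmp_path / "exp")
        assert manifest["n_runs"] == 3 * 3 * 2
        assert len(list((tmp_path / "exp").glob("*.mzML"))) == 18
        truth = pd.read_csv(tmp_path / "exp" / "truth.csv")
        assert len(truth) == 18
        # inhibitor arm never exceeds mock in IAA label fraction
        for tp in (4.0, 16.0):
            mock = truth[(truth.arm == "mock") & (truth.timepoint == tp)]["L_IAA"]
            inh = truth[(truth.arm == "inhibitor") & (truth.timepoint == tp)]["L_IAA"]
            assert inh.iloc[0] < mock.iloc[0]
        back = load_run(tmp_path / "exp" / "mock_t4_r1.mzML")
        assert len(back) > 0

    def test_refuses_nonempty_directory(self, tmp_path):
        target = tmp_path / "exp"
        target.mkdir()
        (target / "existing.txt").write_text("data")
        cfg = SimConfig(seed=5, timepoints=(0.0, 1.0), replicates=1, rt_range=(4.0, 4.2))
        with pytest.raises(FileExistsError):
            generate_experiment(cfg, default_network(), target)
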