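# silkms

**Stable Isotope Labeled Kinetics (SILK) for auxin biosynthesis** — a Python
toolkit for designing narrow-window isotopologue extraction targets,
quantifying labeled and unlabeled metabolite channels from high-resolution
LC-MS runs by isotope dilution, and fitting rapid (seconds-to-minutes)
tracer-incorporation kinetics. A built-in simulator renders complete
labeling experiments as mzML runs with ground truth, so the whole pipeline
is testable without instrument data.

## Who it is for

Plant metabolism groups running stable-isotope labeling time courses on
indole-3-acetic acid (IAA) and its biosynthetic precursors (anthranilate,
indole, tryptophan, indole-3-pyruvate), and more generally anyone doing
targeted isotopologue quantification with multiplexed tracers on an
Orbitrap-class instrument.

## The method

**Channels.** Each monitored species is one isotopologue channel of a
diagnostic ion — e.g. the quinolinium fragment C₉H₈N⁺ of IAA at *m/z*
130.0651 — extracted in a narrow window (±0.0010 *m/z* by default). Channel
*m/z* values are computed from elemental formulas, heavy-isotope
substitutions ([¹³C₆], [¹⁵N₁], [²H₄], [¹³C₈,¹⁵N₁]) and the electron-mass
correction for cations. High resolution separates Δm(¹³C) = 1.00335,
Δm(²H) = 1.00628 and Δm(¹⁵N) = 0.99703, so a structural ¹⁵N atom can mark
pre-existing pools while a ¹³C tracer marks new synthesis.

**Quantification.** For channels *y* (trace) and *x* (monoisotopomer or
internal standard) sampled scan-by-scan over a peak, the isotopologue ratio
is either the area ratio ∫y/∫x or the slope of the ordinary least-squares
regression y = a + b·x; the intercept absorbs constant background, which is
why the slope is preferred at low analyte abundance. Concentrations follow
from isotope dilution,

    C [ng/g FW] = ratio × q_IS [ng] / fresh weight [g],

and *reverse* isotope dilution (unlabeled standard spiked into labeled
tissue) quantifies the endogenous ¹⁵N pool and the tracer-derived pool
concurrently.

**Kinetics.** Under step labeling a steady-state pool incorporates label
first-order, y(t) = y∞(1 − e^(−kt)) with half-time t½ = ln 2/k; a
3-parameter sigmoid and the 4-parameter logistic cover lag-phase curves.
Treatment arms are compared per timepoint with an equal-variance Student's
t test.

**Simulator.** Label transport through an acyclic pool network
(anthranilate → indole → Trp → IPyA → IAA, with inhibitable steps) follows
dLᵢ/dt = (kᵢ/Pᵢ)(L_up − Lᵢ), solved by matrix exponential, then rendered
as centroided SIM runs with Gaussian elution peaks, natural-abundance M+1
satellites, log-normal amplitude noise, baseline and ppm mass error.

## Worked example

Simulate a two-arm labeling experiment (mock vs a 10-fold inhibition of
the Trp → IPyA step), quantify the IAA channels and fit incorporation:

```python
import numpy as np
import pandas as pd
from silkms import (SimConfig, default_network, generate_experiment,
                    ExperimentConfig, run_quantify, run_kinetics)
from silkms.chem import Formula, build_target_table
from silkms.simulate import effective_rate

network = default_network()
config = SimConfig(
    seed=11,
    timepoints=(0.5, 1, 4, 8, 16, 32, 64, 128, 256),  # minutes
    replicates=3,
    rt_range=(4.0, 5.0),
    treatments={"mock": {}, "inhibitor": {("Trp", "IPyA"): 0.1}},
)
generate_experiment(config, network, "demo", force=True)

targets = build_target_table(
    [("IAA", Formula.parse("C10H9NO2"), (4.2, 4.8), None)],
    config.design, protonated=True,
)
samples = pd.read_csv("demo/samples.csv")
samples["file"] = "demo/" + samples["file"]
quant = run_quantify(ExperimentConfig(targets=targets, samples=samples))
fits, comparisons = run_kinetics(quant, model="first_order")

k_eff = effective_rate(network, "anthranilate", "IAA", np.array(config.timepoints))
mock = fits[(fits.treatment == "mock") & (fits.channel == "tracer")].iloc[0]
print(f"true effective k : {k_eff:.4f} /min")
print(f"fitted k (mock)  : {mock['k']:.4f} /min  (t1/2 = {mock['half_time']:.1f} min)")
print(comparisons[comparisons.channel == "tracer"][["time", "t", "p"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
```

Output:

```
true effective k : 0.0197 /min
fitted k (mock)  : 0.0177 /min  (t1/2 = 39.1 min)
 time      t         p
  0.5  1.662    0.1719
    1 0.3496    0.7443
    4  10.49 0.0004664
    8  13.53 0.0001728
   16  16.72 7.503e-05
   32  25.93 1.314e-05
   64  24.86 1.554e-05
  128  12.68 0.0002229
  256   7.89  0.001395
```

The fitted rate of the mock arm recovers the simulator's effective
incorporation rate to ~10%, and the inhibitor arm's tracer-IAA levels
separate from mock (p < 0.05) at every timepoint from 4 min onward while
the two earliest timepoints, where labeling is still below noise, do not.

There is also a CLI (`silk targets | simulate | extract | quantify |
kinetics | report`), each subcommand taking `--config`/`--out`; exit code 2
signals completed-with-flagged-rows.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults, noise
model, numerical choices and known limitations.
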