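# Methods

## Exact masses and extraction windows

Isotope masses and natural abundances are an embedded NIST/IUPAC table
(elements C, H, N, O, P, S, F, Cl). Ion *m/z* is the sum of lightest-isotope
atomic masses, plus one hydrogen if protonated, minus one electron mass
(0.000548580 Da) per positive charge. The electron correction is not
cosmetic: the published quinolinium windows are reproduced at four decimal
places only when it is applied. Window bounds are reported at 4 d.p. with
round-half-even; the default half-width is an absolute 0.0010 *m/z* (a ppm
mode exists but is off by default, since narrow absolute windows are the
convention for this assay).

Label schemes are substitution lists (element, heavy mass number, count)
validated against the ion formula. Which precursor labels survive in a
fragment ion is declared per target in configuration, not derived by atom
mapping: fragmentation chemistry is outside scope, and the ring-label
retention of the quinolinium ion is an empirical fact, not a computable one
here. Derivatized targets (e.g. methoximated indole-3-pyruvate) are
configured with the derivative's ion formula directly.

The isotopologue envelope is computed by per-element multinomial expansion:
each element contributes (Σᵢ aᵢ x^sᵢ)^n with sᵢ the nominal shift of
isotope i, the product over elements is truncated at the requested shift,
and abundances are normalized to the monoisotopic coefficient. For IAA
(C₁₀H₉NO₂) this yields M+1 ≈ 11.4% of M+0 over all CHNO contributions,
consistent with the ~11.1% figure commonly quoted for carbon-dominated
envelopes (the difference is the ²H/¹⁷O contribution). Aggregation is by
nominal mass shift; resolved fine structure is out of scope.

## Run I/O

Retention time is minutes everywhere; files recorded in seconds convert at
parse time. mzXML is read through pyteomics. mzML is read by a compact
lxml-based incremental parser covering the standard spectrum / cvParam /
binaryDataArray vocabulary (32/64-bit floats, zlib or uncompressed) as
emitted by the usual converters, and written as minimal mzML 1.1.0
(uncompressed 64-bit arrays by default); write→read round trips are
bit-faithful and covered by tests. Centroided data are assumed for
quantification; profile spectra are accepted with a warning. PRM scans
match their precursor within ±1.0 *m/z* (half of a 2.0 *m/z* isolation
window); a SIM scan matches a query *m/z* when its scan window contains it.

## Extraction and integration

An EIC has one point per scan: the **sum** of centroid intensities inside
the closed window (summing, not taking the maximum, keeps channel signals
proportional to amounts when a satellite shares the window; boundary ties
are included deterministically). Integration is trapezoidal between
configured RT bounds; the optional linear baseline subtracts the chord
between the boundary intensities and clips negative residuals at zero. The
default baseline is "none" — narrow windows already suppress background,
and a constant offset is instead absorbed by the regression intercept (see
below). Peak bounds normally come from each target's configured RT window;
an apex ± 2·FWHM automatic mode exists for simulated peaks.

## Ratio estimation and isotope dilution

The regression ratio is the OLS slope of trace intensity on denominator
intensity over the scans in the RT window, **with intercept** by default.
The intercept makes the slope exactly invariant to constant background,
which is the documented reason slope-based quantification beats area
ratios on noisy low-abundance signals; a zero-intercept mode and intensity
weighting are available but off by default. The regression denominator may
be the monoisotopomer (relative-abundance mode) or the internal-standard
channel (isotope-dilution mode); both channels must share one RT grid, and
a denominator that is identically zero or constant is rejected rather than
fitted.

Isotope dilution multiplies the analyte/IS ratio by the spiked amount per
gram fresh weight (inputs: ng spike, mg tissue). Reverse isotope dilution
applies the same arithmetic per channel against one unlabeled spiked
standard, reporting the endogenous and tracer pools side by side. No
natural-abundance cross-channel correction is applied by default: with
±0.0010 windows the ¹³C₁ satellite of one channel falls well clear of the
¹⁵N₁ window (separation 0.0063 *m/z*), so the correction would be a no-op;
the quantification layer accepts wider windows, where a user-supplied
correction would become relevant, but does not implement one.

## Kinetic fitting

Three models: first-order incorporation y∞(1 − e^(−kt)) (k ≥ 0 enforced;
t½ = ln 2/k reported), the 3-parameter sigmoid a/(1 + e^(−(t−t0)/b))
(b < 0 allowed, meaning a decreasing curve), and the 4-parameter logistic
d + (a − d)/(1 + (t/c)^b) with c > 0. Initialisation: y∞ from max(y) and k
from a log-linear regression of log(1 − y/ŷ∞) on t; sigmoid/logistic
start from response-range quartiles. Fits run through lmfit
(Levenberg–Marquardt) with tolerances 1e-8 and at most 10,000 evaluations.
Degenerate inputs (constant or all-zero series) are flagged as
unidentifiable rather than fitted. When no model is named the lowest AICc
among converged fits wins — the original curve families used by
point-and-click fitting software are proprietary, so these three
well-defined models are the documented stand-ins.

Group comparison is a two-sided **equal-variance** Student's t test per
shared timepoint (Welch behind a flag), replicates treated as independent
observations, and **no multiplicity correction by default** — matching the
per-timepoint reporting convention of labeling time courses; a Holm option
exists. Timepoints with fewer than two replicates in either group are
skipped with a note. Noise-free groups with zero variance are handled
explicitly (p = 1 if means are equal, p = 0 otherwise).

## Simulator

Pools sit at metabolic steady state: sizes Pᵢ (ng/g FW) are constant and
only label fractions Lᵢ(t) evolve, obeying dLᵢ/dt = (kᵢ/Pᵢ)(L_up − Lᵢ)
where kᵢ sums the inbound edge flux constants times their inhibitor
multipliers and L_up is the flux-weighted upstream label. The entry pool
steps to L = 1 at t = 0 (instantaneous uptake; an optional first-order
uptake rate models slower tracer entry). The linear system is solved
exactly via the matrix exponential of the augmented system, and agrees
with a fine-step explicit integrator to 1e-6 in tests. Edge fluxes need
not balance across pools — constant pool sizes are an assumption, not a
consequence, which is the simplest model consistent with near-constant
endogenous pools during short labeling windows.

The default network is the five-pool chain anthranilate → indole → Trp →
IPyA → IAA. Per-pool labeling rates are ~0.8 (indole), 0.5 (Trp), 0.04
(IPyA) and 0.1 (IAA) min⁻¹: percent-scale IAA labeling within minutes, an
IAA half-time in the tens of minutes (inside the minutes-to-hours range
reported for IAA turnover), and an IPyA step that becomes hours-scale rate
limiting when inhibited tenfold — the regime in which an inhibitor arm
separates from mock from a few minutes onward while remaining suppressed
for hours. Pool sizes (5/10/500/2/20 ng/g FW), retention times and 3-s
peak widths are synthetic but plausible for seedling extracts on a short
C18 gradient. A Trp-independent indole → IAA shunt can be added as an
extra edge. These defaults are illustrative study conditions, not
calibrated to any measured dataset.

Rendering: each sample becomes a centroided SIM run. Per pool and channel
(endogenous ¹⁵N channel scaled by (1−L)·P, tracer channel by L·P,
unlabeled internal-standard channel by the spike equivalent q_IS/FW), a
Gaussian elution profile is laid down at the pool's RT with amplitude
`response_factor` counts per ng/g, plus an M+1 satellite at +1.00335 *m/z*
(the dominant ¹³C shift; the small exact-mass spread of ²H/¹⁵N/¹⁷O
contributions within nominal M+1 is not resolved) with the envelope's
M+1/M+0 abundance. Noise model: one log-normal amplitude factor per
channel per run (σ = 5% by default — biological plus injection
variability), optional Poisson counting noise per scan, an additive
exponential-intensity baseline centroid (mean 20 counts) in every channel
window, and Gaussian *m/z* jitter (2 ppm sd, comfortably inside the
±0.0010 windows). All randomness derives from one seed through per-sample
spawned generators, so runs are byte-identical across repeats.

Ground truth per sample records each pool's label fraction and channel
concentrations, plus an **effective incorporation rate** per pool: the
first-order k fitted to the noise-free label curve at the experiment's
timepoints. A multi-pool cascade is not a single exponential, so this
effective rate — not the pool's own rate constant — is the well-defined
quantity that a first-order fit of measured data estimates, and it is the
reference for recovery studies.

## Validation studies and problem sizes

The studies module (run by the test suite and `scripts/acceptance.py`)
uses: a 9-timepoint (0.5–256 min, geometric), 3-replicate design with 5%
multiplicative noise; an IAA-targeted acquisition segment (RT 4–5 min at
1 s scan interval), mirroring segmented SIM acquisition and keeping the
200-experiment rate-recovery study to tens of seconds; isotope-dilution
round trips scored on replicate-mean concentrations (the quantity one
reports) against truth; and a vectorised 10,000-repetition null
calibration of the per-timepoint t test at n = 3, whose equivalence to the
package's comparison routine is asserted separately in unit tests.

## What the simulator does and does not establish

Passing recoveries show the pipeline is self-consistent: signals generated
under the model's assumptions are extracted, quantified and fitted back to
their generating parameters. Real chromatograms have asymmetric peaks, RT
drift between runs, correlated matrix background, ion suppression and
detector saturation — none of which are emulated — so simulator recoveries
bound algorithmic error, not total analytical error. Wet-lab accuracy
still depends on standards, spike calibration and chromatography.

## Known limitations

- Singly charged positive ions only; no adducts beyond protonation.
- No RT alignment, automatic peak picking, smoothing, or calibration
  curves; peak bounds come from configuration.
- The label model is linear and first-order: no Michaelis–Menten
  saturation, compartmentation, isotope effects, or pool-size dynamics.
- mzML support covers the common converter output subset, not the full
  PSI vocabulary (no chromatogram-type entries, ion mobility or vendor
  formats).
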