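# Methods

## The physical model

Magnetization dynamics of an n-pool spin system under off-resonant RF
irradiation follow the Bloch–McConnell equations.  Per pool i with
transverse/longitudinal relaxation rates R2ᵢ = 1/T2ᵢ, R1ᵢ = 1/T1ᵢ,
chemical-shift offset Δωᵢ relative to the saturation frequency, and RF
nutation rate ω₁ = γB₁ (γ/2π = 42.577 Hz/µT):

    dMxᵢ/dt = −R2ᵢ Mxᵢ + Δωᵢ Myᵢ                + exchange
    dMyᵢ/dt = −Δωᵢ Mxᵢ − R2ᵢ Myᵢ + ω₁ Mzᵢ       + exchange
    dMzᵢ/dt = −ω₁ Myᵢ − R1ᵢ (Mzᵢ − M0ᵢ)          + exchange

Each labile pool exchanges with water only; the pool→water rate is k and
the water→pool rate k·f (detailed balance through the relative proton
fraction f, with M0ᵢ = fᵢ and water f ≡ 1).  The system is written as a
homogeneous affine ODE of dimension 3n+1 (the extra component carries the
M0 recovery terms), so evolution over any interval of constant B₁ is a
single matrix exponential and a pulse train is a product of precomputed
propagators.

Conventions: positive ppm offsets are downfield of water (amine at +2.8,
NOE-mediated aliphatic pool at −3.5); ppm→rad/s conversion is
2π·(Larmor MHz)·ppm with 400 MHz (9.4 T) as default.

### Saturation schemes

The default protocol is 300 truncated-Gaussian pulses (±3σ,
σ = duration/6) of 26 ms and 180° flip angle at 50% duty cycle — 15.6 s
total — sampled at 85 offsets evenly spaced over ±10 ppm with ±100 ppm
reference acquisitions for normalization.  A configuration switch
(`compressed=True`) selects the alternative reading of the duty cycle in
which the pulses run back-to-back for a 7.8 s train.  Each offset is
simulated from thermal equilibrium: the repetition time (7.85 s) is far
above every phantom T1, so inter-offset saturation carry-over is
negligible and no readout physics is modelled.

The root-mean-square B₁ of the default train over a full pulse+gap
period (power-equivalence convention) is 0.417 µT, and 0.589 µT over the
RF-on fraction alone.  Protocols of this family are often quoted with a
nominal CW-equivalent power that does not match either convention;
`cw_equivalent_b1` computes and logs the rms value, which is also the
power used by the fit's CW warm start, where only convergence speed —
not the converged answer — depends on it.

### Discretization

The Gaussian envelope is discretized into piecewise-constant segments
sampled at segment midpoints and scaled to preserve the flip angle.  A
staircase waveform carries spurious sidebands at multiples of
1/(segment duration): 32 segments of a 26 ms pulse put them at ±3.1 ppm
and its multiples — inside the sampled band, perturbing Z by up to
4×10⁻³.  Acquisition-grade simulation therefore uses **128 segments**
(sidebands at ±12.4 ppm, outside the band; doubling to 256 changes any
simulated Z by <10⁻⁴).  The model fit uses a **64-segment analysis
model** (sidebands at ±6.2 ppm, away from the 1.4/2.8/4.2 ppm offsets the
metrics read); the resulting cross-fidelity bias of the recovered
rate×fraction product is ≤2% over the study's exchange-rate range, small
against its 5% accuracy target.  Fourth-order Magnus integrators were
evaluated and rejected: at the large off-resonance frequencies of the
outer offsets the commutator expansion diverges unless steps are far
smaller than the midpoint rule needs.

Matrix exponentials are evaluated for whole batches of offsets at once
by solve-free Taylor-16 scaling-and-squaring (Paterson–Stockmeyer form),
grouping matrices by required squarings so the two far-off-resonance
reference offsets do not inflate the cost of the whole batch; agreement
with scipy's Padé implementation is at the 10⁻¹² level.

## Metrics

All metrics are evaluated at ω = 2.8 ppm, δω = 1.4 ppm, on a common %M0
scale so sensitivity coefficients are comparable across metrics:
MTRasym = 100·(Z(−ω)−Z(ω))/Z₀; APT\* = 100·(Zref−Z(ω))/Z₀ with Zref the
mean of the two flanking offsets; MTRRex = 100·(1/Z(ω)−1/Zref);
AREX = MTRRex/T1.  The flanking-mean Zref follows the three-offset
convention; a half-difference form (which would vanish for symmetric
lines) is available behind a flag for audit.  Spectra are interpolated
onto the exact target offsets with cubic splines, since the 85-point grid
does not contain 2.8/1.4/4.2 ppm exactly.

B0 correction shifts the sub-sample minimum of a cubic-spline
interpolant (search window ±1.5 ppm) to 0 ppm and re-interpolates onto
the original grid; a minimum on the window boundary leaves the spectrum
unshifted with a warning.

Negative APT\*/MTRRex/AREX values — no discernible exchange peak, e.g.
when a short water T2 broadens the direct-saturation line across the
flanks — are unphysical and set to zero.  Clipping is applied **after**
ROI averaging of unclipped voxel values; voxel-level clipping would bias
ROI means upward.  ROI statistics use the sample (n−1) standard
deviation.

## The Bayesian 3-pool fit and CESTR*

Three pools are fitted: water (0 ppm), amine (+2.8 ppm), NOE (−3.5 ppm).
Free parameters: log₁₀ rate and log₁₀ fraction per labile pool
(log-normal priors, one-decade sd, means 1000 s⁻¹ / 10⁻³ for the amine
pool and 20 s⁻¹ / 2×10⁻³ for the NOE pool), water T1 and T2 (normal
priors), and a global B0 shift (normal, sd 0.3 ppm).  Labile-pool
relaxation times are held at their prior means (amine 1.0 s/10 ms, NOE
1.0 s/5 ms): they are not identifiable from a single spectrum at this
SNR.  Generic ("default") water prior means are 1.8 s and 100 ms;
"measured" priors replace the means with relaxometry values while the
parameters remain free — the defining difference between the two CESTR*
variants.

Water relaxation prior sds are 5% of the generic means.  This encodes the
defining behaviour of reference Bayesian saturation-transfer fits: a
single Z-spectrum does not determine water T1/T2 reliably, so the
posterior tracks the relaxation priors, and supplying measured values is
what makes the fit relaxation-compensated.  In a clean noise-only
simulation the likelihood carries more relaxation information than real
spectra (no B₀/B₁ systematics, no drift, Gaussian rather than Rician
noise), so a weaker prior would be overridden and the prior-mode
distinction would disappear; see Limitations.

Inference is penalized nonlinear least squares (priors as whitened
residual rows; the data rows are whitened by the acquisition noise sd,
so fitting an ROI-mean spectrum reproduces the prior weight of
voxelwise fitting).  Optimization proceeds in two stages: a multi-start
(3 seeded starts) trust-region fit of the CW steady-state approximation
at the train's rms B₁ (a linear solve per offset), then damped
Gauss–Newton refinement on the exact pulsed-train objective.  Refinement
Jacobians come from the defect-corrected CW surrogate for the
amplitude-like parameters and from exact pulsed finite differences for
water T1/T2 and B0, whose pulsed-train sensitivity (inter-pulse
recovery, line shape near water) the CW steady state misrepresents —
without those exact columns the iteration stalls or zigzags.
Uncertainties are a Laplace approximation at the optimum; an emcee MCMC
backend (sampling the defect-corrected surrogate frozen at the MAP
point) is available behind `backend="mcmc"` for audit.  Non-convergence
is flagged on the result, never silent.

The fitted rate and fraction are correlated; downstream analysis uses
only their product, whose uncertainty is computed in log space from the
joint covariance.

**CESTR\*** re-simulates a water-only and a water+CEST system from the
fitted amine rate and fraction (the NOE pool excluded from both) and
reports 100·(S₁pool − S₂pool) at 2.8 ppm.  All relaxation times in the
reconstruction are held constant — by default the same generic water
template (1.8 s/100 ms) for every fit — so the metric is a fixed
monotone transform of the fitted exchange parameters and carries no
direct relaxation dependence; any residual T1/T2 sensitivity of CESTR*
reflects bias in the fitted exchange parameters, which is exactly what
the default-vs-measured prior comparison measures.  `relaxation_source`
can instead take the fit's prior means or posterior water values for
audit.  The fitted B0 shift is handled inside the fit, so the
reconstruction is evaluated at the nominal offset.  The reported sd
propagates the joint log-rate/log-fraction uncertainty (delta method);
with default priors at odds with the data it is honestly large, and the
plug-in estimate is correspondingly noisy — a real property of the
estimator, visible in the study results.

## Relaxometry

T1 from nine-point inversion recovery (TI 13.14 ms – 8 s, log-spaced —
the spacing scheme is not dictated by the protocol and is configurable)
fitted to M0(1−2e^(−TI/T1)); magnitude data lose the recovery sign, so
every plausible zero-crossing polarity is tried and the best residual
kept.  T2 from ten-point spin echo (TE 30–160 ms, linear) fitted to
M0·e^(−TE/T2) with log-linear initialization.  Fits whose time constant
falls far outside the sampled window are flagged ill-conditioned.
At 1% noise the T1 median error is <1% over the 0.3–1.7 s range; T2 at
the 29 ms end of its range is recovered within ~10% (the decay is barely
sampled by echoes starting at 30 ms — a limit of the design, not the
fitter).

## The synthetic study

52 phantoms: two tissue-extract models (metastatic tumour, naive brain)
× four serial-variation arms — pH 6.0–7.6 (n=6), protein 4–16% w/v
(n=7), T1 0.3–1.7 s (n=7), T2 29–140 ms (n=6), evenly spaced, others at
baseline (pH 7.4, 8% w/v).  Mechanistic mappings, deliberately isolated
in two functions:

* **pH → amine rate**: pure base catalysis, one decade per pH unit,
  anchored at pH 7.4 with k_ref = 1600 s⁻¹ (tumour) / 2200 s⁻¹ (brain).
  This is the largest modelling liberty in the package (acid- and
  water-catalysed terms omitted).  The anchors keep the whole pH arm at
  or above the pulsed-train labeling optimum (≈60–90 s⁻¹ at this power),
  which is what makes the direct metrics decrease monotonically with pH
  — the qualitative regime protein-phantom studies at this saturation
  power report; slower anchors would put the acidic arm below the
  optimum and produce a non-monotone response.  The two models differ
  because the extracts' metabolite amine content differs.
* **protein → fractions**: linear, anchored at 8% w/v with amine
  fraction 2×10⁻³ and NOE fraction 2×10⁻³.  2×10⁻³ of water protons is
  ≈220 mM labile protons, consistent with proton counting for 8% w/v
  albumin side chains plus extract amines, and produces %M0-scale
  effects with clearly positive three-offset metrics at baseline.
* **baseline relaxation** is model-specific (tumour 1.7 s/140 ms, brain
  1.35 s/100 ms): the two extracts are compositionally different
  tissues.  This is what makes the raw metrics' pH responses differ
  between models while the relaxation-compensated CESTR* stays
  model-consistent — the structural reason pooling both models
  penalizes contaminated metrics in the specificity analysis.
* NOE pool: rate 20 s⁻¹, pH-independent (dipolar relay, not base
  catalysis).

Acquisition noise is additive Gaussian on normalized Z (sd 0.005,
references included), 21 voxels per ROI (disc ROIs of radius 2.5 px on
the 32×32 matrix); relaxometry series carry 1% noise.  Contrast-agent
cross-relaxation — the gadolinium used to sweep T1 also shortens T2 (by
up to 34% at full agent load) and the iron particles used to sweep T2
also shorten T1 (up to 18%) — is available behind
`build_design(cross_effect=True)`; the default treats the arms as
independent, the usual approximation when the target relaxation time
changes at least twice as much as the other.  One
seeded RNG drives everything; identical (design, seed) pairs reproduce
datasets bit for bit, and every dataset carries its generating ground
truth.

### Pipeline problem sizes

The driver fits the ROI-mean spectrum once per phantom and prior mode
(104 fits per study) rather than voxelwise; with data residuals whitened
at the per-voxel noise level this reproduces both the prior influence
and, to first order, the estimator scatter of voxelwise fitting at ~1%
of its cost.  A full study — simulation, relaxometry, metrics, 104
Bayesian fits, statistics — takes about one minute on one CPU.  The
accuracy benchmarks use 200 noisy spectra (fit recovery) and 280 noisy
series (relaxometry).

## Statistics

Per-arm, per-model OLS regressions of each metric on the varied
parameter with two-sided slope tests.  Cross-model comparison of
absolute slopes by Welch t using the regression standard errors
(Welch–Satterthwaite df), corrected over the 6-metric × 4-parameter
family (m = 24 by default, configurable; a 16-test family would give a
rank-1 effective level of ~0.0032) by Holm–Šidák step-down: rank-i
threshold 1−(1−α)^(1/(m−i)), adjusted p values as running maxima of
1−(1−p₍ᵢ₎)^(m−i).

Specificity: data from both models pooled and fitted to
α·pH + β·[BSA] + ε by least squares; the theoretical effect is evaluated
for **all** phantoms (constant over the relaxation arms) and its squared
Pearson correlation with the measured effects is the specificity R².
Metrics contaminated by T1/T2 decorrelate over the relaxation arms and
score low.

ΔpH: for every within-model phantom pair, ΔCEST = CEST₁ − CEST₂ is
significant when it exceeds the two measurement sds in quadrature;
significant pairs are inverted through ΔpH = (ΔCEST − β·Δ[BSA])/α.
Sign accuracy is grouped by the experimental ΔpH at a ±0.6 threshold.

## What passing tests do and do not show

The generator emulates ideal spectra: Gaussian (not Rician) noise, no B₀
or B₁ inhomogeneity beyond the fitted global shift, no macromolecular
magnetization-transfer pool (deliberately absent from the emulated
phantoms), no readout physics, single Lorentzian-like labile pools
rather than distributed metabolite resonances, and exact model nesting
between generator and fitter (up to the discretization-fidelity split).
Consequences worth keeping in mind:

* Clean spectra carry more water-relaxation information than real ones,
  so the contamination of CESTR* with default priors — while present,
  directional, and highly significant on noise-free data — is weaker
  here than on real phantoms, and its per-seed 0.05-level significance
  fluctuates; the acceptance tests therefore assert the pattern over a
  fixed ten-seed ensemble with binomial thresholds rather than at a
  single seed.
* The specificity R² values are much higher across the board than real
  phantom studies report (0.82–0.94 versus 0.07–0.88): the synthetic
  study lacks the inter-phantom preparation variability and model
  mismatch of real data.  The *ranking* — CESTR* with measured priors
  first — is the transferable result, and it is stable across seeds.
* MTRasym rises mildly with protein here, whereas broad-band NOE
  contamination can make it fall in real protein phantoms; a single
  narrow NOE pool at −3.5 ppm under-represents aliphatic linewidth.
* ΔpH sign accuracy on large differences is essentially perfect here
  (monotone metric, clean noise); real-data accuracy is bounded by
  preparation and measurement variability that this generator does not
  model.

## Other design choices

* Exchange topology: labile↔water only; no labile–labile exchange.
* `cestr_star` excludes the NOE pool from both reconstruction systems.
* Degenerate inputs fail loudly (`InvalidInputError`) rather than
  silently: constant regressors, rank-deficient ideal-model designs,
  nonpositive signals where a log or inverse is taken, spectra that do
  not cover the fitted pool offsets.
* T2 > T1 in a pool warns but does not fail (transiently reachable
  during optimization; physically marginal, not impossible to write).
* The ideal-model specificity R² is clipped to 0 with a flag when a
  metric's prediction is degenerate.
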