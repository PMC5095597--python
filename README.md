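# cestkit

Simulation and quantification of chemical exchange saturation transfer
(CEST) MRI Z-spectra, built to answer a concrete methodological question:
**which CEST quantification metric responds only to the labile-proton
exchange properties (pH, protein concentration) and not to the water
relaxation times T1 and T2?**

CEST imaging saturates labile protons (amine, amide) at their chemical
shift and detects the transferred saturation as water-signal loss.  The
normalized water signal versus saturation offset — the Z-spectrum
Z(ω)/Z₀ — mixes the exchange-mediated effect with direct water
saturation, relaxation, and aliphatic (NOE-mediated) transfer, so the
choice of quantification metric decides whether a "pH map" actually maps
pH or merely T1.

`cestkit` provides:

* a **Bloch–McConnell forward model** for multi-pool spin systems under
  continuous-wave or pulsed Gaussian-train saturation (exact
  piecewise-constant propagation via batched matrix exponentials);
* the four direct metrics, evaluated at ω = 2.8 ppm with flank spacing
  δω = 1.4 ppm and B0-corrected spectra:

  | metric | definition |
  |---|---|
  | MTRasym | (Z(−ω) − Z(ω))/Z₀ |
  | APT\* | (Zref − Z(ω))/Z₀, Zref = ½(Z(ω+δω) + Z(ω−δω)) |
  | MTRRex | 1/Z(ω) − 1/Zref |
  | AREX | MTRRex / T1 |

* **CESTR\***: a Bayesian 3-pool Bloch–McConnell fit (water at 0 ppm,
  amine pool at +2.8 ppm, NOE pool at −3.5 ppm; exchange rates and
  fractions under log-normal priors, water T1/T2 and B0 shift fitted
  under normal priors), followed by forward simulation of a water-only
  and a water+CEST system from the fitted exchange rate k and relative
  concentration f: CESTR\* = (S₁pool(ω) − S₂pool(ω))/Z₀.  Two variants:
  generic ("default") water-relaxation prior means, or phantom-specific
  ("measured") values from inversion-recovery/spin-echo relaxometry;
* a **synthetic phantom study** emulating a two-tissue-model (metastatic
  breast tumour / naive brain extract) design: 26 phantoms per model with
  serial variation of pH (6.0–7.6), protein content (4–16% w/v), T1
  (0.3–1.7 s) and T2 (29–140 ms), imaged with 300 Gaussian pulses of
  26 ms/180° at 50% duty cycle over 85 offsets in ±10 ppm;
* the **statistical engine**: per-parameter OLS regressions, cross-model
  slope comparison with Holm–Šidák correction, the ideal-metric model
  `CEST effect [%M0] = α·pH + β·[BSA] + ε` whose prediction-vs-measurement
  R² scores metric specificity, and pairwise ΔpH quantification with a
  quadrature significance gate.

## Worked example

```python
from cestkit import (ExchangePool, SpinSystem, water_pool, default_scheme,
                     simulate_zspectrum, mtr_asym, apt_star, mtr_rex,
                     fit_zspectrum, measured_priors, cestr_star)

amine = ExchangePool("amine", offset=2.8, rate=1600.0, fraction=2e-3,
                     t1=1.0, t2=0.01)
noe = ExchangePool("noe", offset=-3.5, rate=20.0, fraction=2e-3,
                   t1=1.0, t2=0.005)
system = SpinSystem((water_pool(t1=1.7, t2=0.14), amine, noe))
scheme = default_scheme()                 # 300 x 26 ms Gaussian pulses, 50% duty

spec = simulate_zspectrum(system, scheme)
print(round(mtr_asym(spec).value, 2), round(apt_star(spec).value, 2),
      round(mtr_rex(spec).value, 2))

fit = fit_zspectrum(spec, scheme, measured_priors(1.7, 0.14))
print(round(fit.exchange_flux("amine")[0], 2), round(fit.r_squared, 4))
print(round(cestr_star(fit, scheme).value, 2))
```

prints

```
1.99 1.01 1.05
3.22 1.0
2.46
```

i.e. for this baseline-like phantom (pH 7.4 at 8% w/v protein) the direct
metrics read an effect of 1–2 %M0 at 2.8 ppm, while the model fit
recovers the amine rate×fraction product (true value 3.2 s⁻¹) within
1% at goodness-of-fit R² ≈ 1 and converts it to a CESTR\* effect of
2.46 %M0 on the fixed reconstruction template.

Running the whole study from the shell:

```bash
cestkit run-all --seed 1 --out report/
```

writes `metrics.csv`, `regressions.csv`, `slope_comparisons.csv`,
`ideal_fits.csv`, `delta_ph_pairs.csv` and `summary.json`.  At seed 1
the specificity ranking places CESTR\* with measured T1/T2 priors first
(R² = 0.94 against the ideal model, versus 0.82–0.92 for the other five
metrics), and its ΔpH inversion predicts the sign of every significant
equal-protein pH difference larger than 0.6 units.

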