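# crystagg

Kinetics and statistics of oxidative γD-crystallin aggregation and its
suppression by *myo*-inositol.

Age-onset cataract is driven by light-scattering aggregation of lens
crystallins. Oxidation-mimicking variants of human γD-crystallin (HγD,
e.g. W42Q) aggregate *in vitro* when a non-native internal disulfide,
formed by exchange with the glutathione couple (GSH/GSSG), traps a
partially misfolded monomer; aggregation then proceeds through a
rate-limiting bimolecular step — a transient dimer — into short
extended chains that coalesce into globular particles. The lens
metabolite *myo*-inositol suppresses this process kinetically, without
binding the native protein, by disfavoring the bimolecular step.

`crystagg` packages that picture as a reusable toolkit for plate-reader
turbidity experiments and TEM morphometry of this system:

- **`crystagg.kinetics`** — mass-action ODE model of the redox-coupled
  aggregation network. `AggregationModel(params, initial).simulate()`
  returns a `Trajectory` with species courses, conservation
  diagnostics, and a turbidity observable τ(t) = w_P·P1 + w_G·(G1+S1).
  Inositol scales the dimerization constant by the noncompetitive
  factor 1/(1 + [Ino]/K_I). Late-addition/dilution events are
  supported (`simulate_with_events`).
- **`crystagg.plates`** — seeded synthetic data: whole plates of noisy
  sigmoidal/biphasic traces under factorial conditions, late-addition
  protocols with dead-time gaps, two-class lognormal particle tables,
  and long-format CSV I/O.
- **`crystagg.traces`** — the turbidity statistics used in this field:
  the tangent method (slope of the best-fit tangent to the steepest
  part of the curve = maximum aggregation rate; its baseline intercept
  = apparent lag time), phase segmentation for biphasic traces (rate
  and lag from the second phase), endpoint turbidity, the endpoint-vs-
  soluble-fraction correlation, and dose-response with a one-parameter
  inhibition-constant fit.
- **`crystagg.scaling`** — power-law concentration dependence
  rate = A·c^n by log-log OLS (`PowerLawModel(...).fit()`), with
  treated-vs-control comparison of A and n. A quadratic exponent
  indicates the bimolecular rate-limiting step.
- **`crystagg.redox`** — OxD = 2[GSSG]/([GSH]+2[GSSG]) arithmetic and
  speciation, PEG-maleimide gel-shift lane simulation from free-thiol
  class fractions, binomial marker lanes, and the lens free-water
  concentration estimator.
- **`crystagg.morphometry`** — rank-size distributions, per-image
  counts and combined lengths, two-sample Kolmogorov–Smirnov (exact by
  enumeration for small samples) and t tests.

A `crystagg` command-line interface wraps the pipeline
(`simulate-plate`, `late-addition`, `analyze-traces`, `dose-response`,
`powerlaw`, `redox-report`, `morphometry`, `reproduce`).

## Worked example

Simulate a noise-free inositol dose series under full oxidation
(40 μM W42Q, 0.5 mM GSSG) and extract the kinetic statistics:

```python
from crystagg import (AggregationModel, WellCondition, default_params,
                      tangent_fit, dose_response)

params = default_params()
fits = {}
for dose in (0.0, 50.0, 100.0, 250.0):
    cond = WellCondition(protein_uM=40.0, inositol_mM=dose, oxd=1.0,
                         total_glutathione_mM=1.0)   # 0.5 mM GSSG, no GSH
    trace = AggregationModel.from_condition(params, cond).simulate().turbidity()
    fits[dose] = tangent_fit(trace)

print(fits[0.0].summary())
print(dose_response(fits).summary())
```

prints

```
Tangent fit
  max rate      2.2119e-04 AU/s (at t = 1988 s)
  apparent lag  1052 s
  baseline      0.0000 AU
  phase         1 of 1
  method        discrete (rmse nan AU)

Dose-response (rates normalized to 0 mM)
       0.0 mM   rate 1.000   lag change +0.0%
      50.0 mM   rate 0.769   lag change +20.5%
     100.0 mM   rate 0.650   lag change +34.8%
     250.0 mM   rate 0.478   lag change +64.2%
  K_I = 230.7 ± 28.7 mM
```

The control trace reaches its steepest point about half an hour in with
an apparent lag of ~18 min; 100 mM inositol — the concentration
estimated for the free water of a healthy human lens — cuts the maximum
rate by 35% and lengthens the lag by a similar fraction. The K_I here
is the apparent dose-response constant of the simulated assay; the
mechanistic K_I in the parameter file is smaller because the observed
rate responds sublinearly to the dimerization rate.

The lens estimate itself:

```python
from crystagg import lens_free_water_concentration
est = lens_free_water_concentration(24.6, 6.7)   # μmol/g wet tissue, 60% water, 50% free
print(f"{est.concentration_mM:.0f} ± {est.concentration_se_mM:.0f} mM")
# 82 ± 22 mM
```

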