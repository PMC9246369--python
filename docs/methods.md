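# Methods

## The mechanistic model

The simulator (`crystagg.kinetics`) is a deterministic mass-action ODE
network for the oxidative aggregation of a destabilized two-domain
lens crystallin in a glutathione redox buffer, with *myo*-inositol as
a kinetic inhibitor of the bimolecular committed step.

Species (μM monomer-equivalents unless noted):

| symbol | meaning |
|---|---|
| N | native monomer |
| I_red | misfolded monomer, all cysteines reduced |
| I_ox | misfolded monomer locked by one internal non-native disulfide (the aggregation precursor) |
| D | transient dimer of two locked precursors (2 monomer-equivalents) |
| D_red | transient dimer of two reduced misfolded monomers |
| P0, P1 | number concentration and monomer mass of short extended chains |
| G1 | monomer mass in suspended globules |
| S1 | monomer mass in settled globules |
| GSH, GSSG | glutathione couple (mM) |

Reactions:

1. N ⇌ I_red (k_mis, k_fold) — conformational exchange.
2. I_red + GSSG → I_ox + 2 GSH (k_ox) and I_ox + GSH → I_red + GSSG
   (k_red) — a lumped one-step thiol–disulfide exchange. The
   mixed-disulfide intermediate is not resolved; the lumping preserves
   the conserved total GSH + 2·GSSG exactly.
3. 2 I_ox → D (k_dim · f) and D → 2 I_ox (k_diss), with
   f = 1/(1 + [Ino]/K_I): the rate-limiting bimolecular step and its
   noncompetitive inhibition by inositol. This one-parameter form is
   the simplest consistent with a saturating dose response; it does
   not distinguish whether the inhibitor blocks dimer formation,
   promotes dissociation, or blocks intradimer misfolding — all three
   reduce the concentration of productive dimer.
4. An alternative ordering of misfolding and oxidation
   (`dim_oxidizes`, on by default): 2 I_red → D_red (k_dim · f),
   D_red → 2 I_red (k_diss), D_red + GSSG → I_ox + I_red + 2 GSH
   (k_ox). At strongly oxidizing conditions route 2 dominates (I_red
   is trapped before it can dimerize); in mild redox buffers most
   protein stays reduced and this route carries the flux. Because
   inositol then gates the *supply* of locked precursor as well as the
   committed step, suppression is stronger in redox buffers than at
   full oxidation — the emergent synergy. The two dimer pools are kept
   separate so that a reduced dimer can never dissociate into oxidized
   monomers; collapsing them would open an oxidant-free aggregation
   route and break the redox gate (no GSSG → no aggregation).
5. Chain birth D + I_ox → trimer chain (k_elong on dimer count;
   P0 += 1, P1 += 3) and growth P + I_ox (k_elong · P0 · I_ox). Chain
   birth reuses the elongation constant — monomer addition to a dimer
   — so the parameter set stays minimal and D stays transient.
6. Coalescence on particle numbers: 2P → G
   (events k_coal·P0², mass flux 2·k_coal·P0·P1) and P + G → G
   (mass flux k_coal·G1·P1, number flux k_coal·P0·G1, treating G1 as
   the globule-number proxy so no division by P0 is needed). The P+G
   channel is autocatalytic in G1, which is what makes a delayed
   second turbidity phase possible.
7. Settling G → S (k_settle). Settled mass is chemically inert but
   remains visible to the turbidity observable (vertically oriented
   plate-reader optics).

Extended aggregates are tracked by two moments (P0, P1) rather than
full size classes; mean chain length is P1/P0. The observable is
τ(t) = w_P·P1 + w_G·(G1 + S1). With w_G = w_P this is strictly
proportional to total aggregated mass; the shipped default w_G = 2·w_P
lets coalescence produce biphasic traces, and both readings are
exposed because mass-proportionality and coalescence-driven second
phases are not simultaneously exact.

Two invariants hold along every trajectory and are enforced in tests
to ≤1e-6 relative: total monomer-equivalents
(N + I_red + I_ox + D + D_red + P1 + G1 + S1) and total glutathione
(GSH + 2·GSSG).

### Numerics

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol 1e-12 μM;
fixed output grid every 90 s over 4.5 h (the assay's read schedule).
States more negative than −1e-9 abort with a diagnostic; smaller
excursions are clipped. Zero protein short-circuits to a flat zero
trajectory. A reduced network (N ⇌ I, 2I → P) is cross-checked against
an independent fine-step explicit-Euler integration to 1e-4.

### Default parameters and calibration

Units: first-order constants 1/s; protein–protein constants 1/(μM·s);
protein–glutathione constants 1/(mM·s); K_I mM; w_P, w_G AU/μM.

The base constants were chosen once, by a constrained screen, to put
the simulated assay in the experimentally observed regime: sigmoidal
traces with maximum slope 0.5–1.5 h into the incubation at 40 μM
protein / 0.5 mM GSSG, substantial endpoint turbidity in the OxD
0.15–0.40 buffers, and a dimerization step slow enough to be
rate-limiting (power-law exponent of rate vs concentration ≈ 2 at full
oxidation). On that base, the two free knobs (K_I, k_red) are
calibrated by Gauss–Newton least squares (`crystagg.calibrate`,
`scripts/calibrate_params.py`) to the two suppression statistics that
summarize the inhibitor's effect: 35% at full oxidation and a 51% mean
across the six redox buffers. The shipped file reproduces both to
<0.03 percentage points. K_I calibrates to ≈47 mM; the *apparent*
dose-response constant of the simulated assay is larger (≈200 mM)
because the measured maximum rate responds sublinearly (roughly as
f^0.5–f^0.8) to the dimerization rate.

## Trace statistics

`smooth` is Savitzky–Golay local-quadratic filtering (window 5); it
reproduces quadratics exactly and is applied before differencing on
noisy traces.

`segment_phases` finds growth phases as maximal intervals around local
maxima of the smoothed derivative that exceed 10% of the global
maximum and are separated by a valley below 50% of the smaller
adjacent peak. Monophasic inputs always yield one phase at zero noise.

`tangent_fit` implements the tangent method. Within the selected
phase (global-max by default; the second phase when the biphasic rule
is requested) the discrete maximum of the smoothed derivative is
refined two ways: a cubic-spline interpolant maximized on a fine grid
(near-exact for smooth traces sampled well below their feature scale),
and a four-parameter logistic fit (offset, scale, rate, midpoint) that
anchors the tangent at the fitted inflection when it reproduces the
phase to better than 0.5% of its range. The logistic branch makes the
estimator exact on logistic curves regardless of the 90 s read
interval — at k = 0.02/s the growth phase spans only ~3 readings and
any finite-difference estimate is ~20% low — while the tight
acceptance threshold keeps asymmetric model traces on the consistent
spline path. The apparent lag is where the tangent crosses the
baseline (mean of the first three readings; the convention is
configurable because the assay itself defines none). Negative lags
are reported as-is with a flag.

The estimator is scale-equivariant (τ → a·τ multiplies the rate by a,
leaves lag unchanged) and time-shift-equivariant; both are tested.

`DoseResponseModel` normalizes rates to the zero-dose arm and fits
r(d) = r0/(1 + d/K_I) on the log scale (multiplicative plate-reader
noise), with both scale and K free — normalizing first and pinning the
dose-0 point would understate K's uncertainty. Flat series are flagged
saturated (K_I unidentifiable); a single nonzero dose uses the closed
form.

`PowerLawModel` fits ln rate = ln A + n·ln c by OLS (multiplicative
noise rationale; nonlinear least squares on the original scale is
available by flag). Arm comparison reports A_treated/A_control,
Δn, and normal-approximation z-scores.

## Synthetic data

`make_plate` drives the kinetic model per well and applies the noise
model: multiplicative lognormal reading noise (σ = 2% — plate-reader
turbidity noise scales with signal) plus one additive baseline offset
per well ~ N(0, 0.005 AU). Wells and replicates draw from independent
`SeedSequence`-spawned substreams, so output is bitwise reproducible
by seed and σ = 0 reproduces the noiseless model exactly.
Temperature is carried as metadata only (conditions are modeled
per-assay; no Arrhenius scaling). Late-addition runs integrate
piecewise: species are diluted by V_old/(V_old+V_add), inositol mixes
volume-weighted, an optional fraction of fragile early chain mass
returns to the precursor pool, and the reading after the event carries
a dead-time flag. Whether a quoted protein concentration is pre- or
post-addition is a protocol ambiguity; the generator treats it as
pre-addition (configurable via the design).

`synth_morphometry` emulates particle tables: Poisson per-image
counts, a Bernoulli extended/globular class mix, and class-wise
lognormal sizes with optional multiplicative treatment effects.
Medians (120 nm lengths, 300 nm globular sizes, ~8 particles/image,
60% extended) are plausible for negative-stain TEM fields of this
system. What the generator does **not** emulate: spatial correlation
within images, classification ambiguity near the extended/globular
boundary, tracing error, or finite-grid censoring of large particles
— so passing tests demonstrate correctness of the statistics, not
robustness to those real-data artefacts. The same caveat applies to
the turbidity generator, which knows nothing of evaporation, meniscus
drift, or well-to-well temperature gradients beyond the additive
offset.

## Redox tools

OxD = 2[GSSG]/([GSH]+2[GSSG]); `speciate` inverts it at fixed total.
The lens estimator converts μmol per g wet tissue to mM in the free
water as c = m/(water_fraction × free_water_fraction), assuming
free-water density 1 g/mL, with the standard error scaled by the same
factor (the inputs' relative error dominates, so linear propagation
suffices). Defaults 0.6 and 0.5 describe healthy human lens tissue.

Gel lanes: `pegylation_lane` maps free-thiol class fractions to band
fractions at the attainable PEG counts (n_cys, n_cys−2, n_cys−4 —
each internal disulfide removes two thiols); `marker_lane` models
limited PEGylation of the fully reduced six-thiol wild type as
independent per-thiol labeling, i.e. Binomial(6, p). Soluble thiol
classes from a simulation endpoint count N, I_red and D_red as fully
reduced and I_ox and D as one-disulfide; aggregated and settled mass
is excluded (aggregates contain no fully reduced protein, and settled
material is not sampled when pipetting from bulk). Comparisons
between lanes should be made on band *intensities* (fraction × soluble
concentration, i.e. per constant loaded volume): with fast thiol
exchange the within-pool fractions are pinned to the GSSG/GSH ratio,
and the inhibitor's visible effect on the fully-reduced band comes
from more protein remaining soluble.

## Morphometry statistics

KS and t tests wrap `scipy.stats` (`ks_2samp`, `ttest_ind`). The KS
p-value is exact (distribution-free enumeration) when |x|·|y| ≤ 10⁴
and otherwise uses the Kolmogorov limiting distribution evaluated at
√(nm/(n+m))·D. Two properties worth knowing: the exact p is discrete
and conservative under the null (P(p ≤ α) ≤ α; its null distribution
is *not* uniform at small n), and the limiting approximation is good
away from the deep tail but can differ from the exact value by tens of
percent for extreme D at n ≈ 20. Tests assert the defensible forms of
both statements. The default t test is Student's pooled-variance
two-sided, with Welch behind a flag. Sizes are unit-agnostic
(rank-size curves and tests are invariant to common monotone
transforms); units travel as metadata.

## Problem sizes

Default analyses use the assay's native scale: 181-point traces
(4.5 h at 90 s), plates of up to a dozen wells, dilution series of
4 concentrations, and Monte-Carlo checks with 100–200 seeds at
n ≤ 500 per sample. These sizes make every documented number
recomputable in seconds on a laptop.

## Known limitations

- The moment closure for extended chains assumes a single effective
  chain-length scale; full size distributions are out of reach.
- Turbidity weights are per-mass constants; real light scattering
  depends on particle size and shape, so w_P/w_G are effective
  parameters, not optical constants.
- The calibration pins two summary statistics; individual trace shapes
  are qualitative, and the per-buffer suppression spread (≈48–58%
  across OxD 0.15–0.40) is wider than the measured ±2% S.E.M.
- K_I is calibrated, not measured; only the product behavior
  (dose-response of the observed rate) is constrained.
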