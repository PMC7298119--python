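# Methods

## In vitro strain models

Two normalized-density models are fitted to batch-culture assays.

**Cholesterol converter (D8 model).** Density follows a plain logistic law
`dB/dt = μB(1−B)`; the growth medium is rich, so cholesterol does not
limit growth and appears only through the conversion channel
`dCl/dt = −k_cc·B·Cl/(K+B)`, `dCp/dt = +k_cc·B·Cl/(K+B)`. `Cl+Cp` is
conserved exactly. The implementation uses the logistic closed form plus a
trapezoid quadrature of the Monod integral (the cholesterol equation is
linear given `B(t)`), which is both faster and better conditioned than a
generic ODE solve inside the MCMC loop; the fast path is checked against a
tight-tolerance stiff integration in the tests.

**BS deconjugator (Xyl model).** Density follows a delayed-repression
logistic `dB/dt = μB(1−B) − βB·P(t−δ)/(K+P(t−δ))` where `P` is the
primary-BS concentration; deconjugation is quadratic in density,
`dP/dt = −k_bxyl·B²·P`. The quadratic arises because the per-cell enzyme
activity itself grows linearly with density. The delay equation is
integrated by the method of steps: fixed-step RK4 with linear
interpolation of the stored `P` history at `t−δ`. The scheme's effective
order is limited by the history interpolation; a step-halving oracle in
the test suite pins the error at `h = 0.1 h` below `1e-4` and verifies
contraction under refinement. A batched variant advances all assays of a
study simultaneously (one shared grid), which is what the likelihood
evaluates.

**Composite deconjugation constant.** Enzyme assays measure the BSH
activity `A_BSH` (nmol/min per mg protein) as a function of density;
ordinary least squares gives `A_BSH = a_BSH·B` (the intercept is dropped
when insignificant at 0.05, which is the case for the shipped default
data; outliers at |studentized residual| > 3 are removed first,
configurable). The constant

```
k_bxyl = T_k · a_BSH/[BS]₀ · C_λ·d_c·(1−c_w)·c_p·V_c·[Bxyl]_max    [1/h]
```

combines the time rescale `T_k = 60 min/h`, the assay's initial BS
concentration `[BS]₀` (nmol/mL), and the protein content per mL of a
maximal-density culture (`C_λ = 1e-9 mg·g⁻¹·mL·μm⁻³`, cell mass density
`d_c = 1.1 g/mL`, water fraction `c_w = 0.70`, protein fraction of dry
mass `c_p = 0.55`, cell volume `V_c = 1 μm³`, maximal concentration
`[Bxyl]_max = 4e9 CFU/mL`). The composition is frozen so the units
resolve to 1/h; a unit-tracking test walks the product. Because `[BS]₀`
sits in the denominator, growth media at different BS levels have
different `k_bxyl`; the synthetic generator and the inference honour this.

## Bayesian inference (DRAM)

Parameters are sampled by a delayed-rejection adaptive-Metropolis chain:

* likelihood: i.i.d. Gaussian per observation channel (density and the two
  metabolite channels), with per-channel variances refreshed each
  iteration by their conjugate inverse-gamma step (prior weight `n0 = 1`
  anchored at the least-squares residual variance);
* initialization: Nelder-Mead least squares from the prior midpoint
  (400 evaluations), clipped to the prior box;
* proposal: Gaussian, initial covariance `((hi−lo)/100)²` on the diagonal,
  adapted from 10% of the chain with the usual `2.38²/d` scaling; a second
  delayed-rejection stage shrinks the proposal 5-fold;
* priors: uniform boxes. Growth-rate priors are anchored on the log-phase
  estimate α — the slope of log-density where density lies in [0.1, 0.5]
  of its maximum — as `U(0.1α, 2α)` for the converter and `U(0.6α, 10α)`
  for the deconjugator; the delay prior is `U(15, 25) h`;
* burn-in: 50% of the chain; default length 5·10⁴ (shorter chains are used
  in the tests and the acceptance script; the posterior for these models
  is well mixed from a few thousand iterations after the optimizer start);
* convergence: Geweke score per parameter — a z-test between the first 10%
  and last 50% of the post-burn chain with Bartlett-windowed spectral
  variances, reported as the two-sided tail probability, so values near 1
  mean the segments agree (converged) and values near 0 mean drift.

The synthetic-assay generator adds zero-truncated Gaussian noise. With the
default noise SD (0.02) a 5% inoculum keeps truncation out of play, so the
Gaussian likelihood is well specified; much smaller inocula would bias the
early samples upward.

## Upscaling to the gut

In vivo guild parameters (day-based) derive from the in vitro posteriors:
`μ_guild = 24·μ·(strain max concentration / b_gut,max)` with
`b_gut,max = 5e9 CFU/mL` the small-intestine bacterial level (the printed
density-ratio orientation is ambiguous; the shipped default uses
in-vitro-max over `b_gut,max`, and a switch provides the inverse);
`d_PBSD = 24β`; `K_PBSD = w_PBS·K` with `w_PBS = 467.847 mg/mmol` (the
average conjugated-BS molecular weight — the source table's "467, 847" is
read as a decimal comma, since half a tonne per mole is impossible for a
bile salt); `k_PBSD = 24·k_bxyl·A_BSH,mic/a_BSH` scales the in vitro
constant by the ratio of fecal (in vivo) to in vitro BSH activity;
`K_CCC = K_D8·(strain max / b_gut,max)`; and the luminal conversion rate
is tied to excretion by the converter-phenotype ratio,
`k_cc = Q_col,cop·k_LCe` with `Q_col,cop = 0.1` (an intermediate phenotype
within the reported human range 0.01–4; the ratio is implemented as
coprostanol:cholesterol, the only orientation consistent with
`k_cc = Q·k_LCe`).

After the hour→day rescale the deconjugator's repression delay
(≈ 1.02 days) is dropped: starting from the calibrated steady state the
delayed and instantaneous variants differ by < 1e-6 in relative L²(0, T)
norm over 50 days (`delay_negligibility_check` integrates both with the
same fixed-step scheme so solver noise cannot masquerade as a delay
effect).

## Whole-body model

Sixteen states: guild densities CCC and PBSD (dimensionless, logistic in
the `(CAPACITY − population)` form with capacities 1 in basal runs),
luminal/intestinal/hepatic/plasmatic/peripheral concentrations (mg/L), and
four cumulative excreted amounts (mg; concentrations on demand as
amount/(V_st·t), undefined at t = 0). Structural features:

* bilinear epithelial uptake of the cholesterol/BS emulsion
  (`k_LCa·[LC]·[LPBS]`), quadratic deconjugation, Monod conversion;
* sigmoidal switches `1/(1+(x/x_t)^s)` for the three tissue syntheses and
  `1/(1+(x_t/x)^s)` for the biliary release, thresholds at the steady
  concentrations and sensitivity 5 by default;
* volume-ratio couplings so volume×concentration bookkeeping conserves
  mass; with diet, syntheses, peripheral loss and BS synthesis off, total
  sterol mass is conserved to integrator tolerance (tested);
* HDL↔LDL maturation rates exist as optional parameters defaulting to 0
  (described in the source material but absent from its balance
  equations).

**BS-synthesis feedback.** The printed hepatic balance contains the
bilinear term `+k_HBSs·[HC]·[HBS]`, under which a depleted BS pool
*reduces* synthesis — a positive feedback that contradicts the stated
"negative retro-control" and, under strong deconjugation, drives hepatic
cholesterol upward without bound. Both forms are implemented:
`hbs_feedback="as_printed"` (the default, fidelity first) and
`"saturating"`, a first-order repression
`k_HBSs·[HC]·HBS_t/(HBS_t+[HBS])` with the threshold at the steady BS
level (the Hill exponent is configurable; 1 is the minimal monotone
repression). The saturating form is the one that reproduces the reported
exploration behaviour (synthesis rising when deconjugation depletes the
BS pool) and is used by the exploration and validation examples.

## Calibration

The calibration ledger holds literature steady fluxes (mg/day) of the
cholesterol cycle plus mass-conservation (MC) identities. The calibrator:

1. checks every MC-tagged printed value against its own formula and
   reports violations without silently fixing them — the shipped table is
   internally inconsistent in three places (total fecal excretion 1.2352
   vs 0.794 from its reference value; the conversion flux likewise; the
   total blood→liver flux 2.9115 vs the 2.8398 sum of its parts). The
   printed downstream values are used, as they are evidently what the
   downstream entries were computed from;
2. completes the missing fluxes by the MC cascade (luminal balance →
   intestinal-outflow split → blood→liver/periphery split preserving the
   reference ratios → global sterol balance → BS synthesis → peripheral
   and HDL balances);
3. closes the BS cycle from two constants: the enterohepatic recycling
   fraction (default 0.95 — the textbook share of luminal BS reabsorbed
   per pass, which makes BS fluxes ~20× larger than cholesterol fluxes)
   and the basal share of BS leaving as bacterially deconjugated secondary
   BS (default 1e-4 of the synthesis flux, keeping the basal bacterial
   outflux negligible against the circulation). The luminal BS absorption
   gets its own rate constant `k_LPBSa`: the balance equations as printed
   share `k_LCa` between the cholesterol and BS uptake, which would force
   the BS absorption flux to equal the (20-fold smaller) cholesterol
   absorption flux and collapse the enterohepatic cycle to ~4% recycling —
   inconsistent with the flux nomenclature that lists the two rates
   separately and with the reported well-balanced BS cycle;
4. converts each steady flux to a rate constant by dividing by the steady
   concentration factor(s) in its rate law (bilinear terms by both
   factors, the conversion term by its Monod factor, switch terms by the
   1/2 of a threshold placed at the steady concentration). The designed
   pool vector is then an exact fixed point (residual ~1e-12 of the flux
   scale), and a long stiff integration plus damped Newton polish
   reproduces every finalized ledger flux within 1%.

Steady pool concentrations, compartment volumes and switch thresholds are
not published with the source tables; the package ships documented
mouse-scale synthetic defaults (e.g. luminal volume 1.5 mL, plasma 1.7 mL,
periphery 18 mL; luminal BS 10 mM ≈ 4678 mg/L; plasma HDL 600 and LDL
200 mg/L) and flags every calibration built on them
(`synthetic_defaults_used`). Quantities that depend only on flux ratios (the
0.1 conversion:excretion ratio, the esterification symmetry, the MC
identities) are insensitive to these choices; percent responses of the
scaling experiments are not, and are therefore validated directionally
(see below).

## Tracer layer

All cholesterol/BS pools are duplicated into labeled twins plus a labeled
peripheral-storage accumulator so the label budget closes identically.
Linear transport acts on each species with the same constant; every
nonlinear factor (bilinear partner, Monod, switches, squared deconjugator
density) is evaluated on the total concentration and the flux is split by
the labeled share of the source pool — the label is kinetically passive.
By default the dose is a massless marker (the totals stay at the basal
steady state), which makes the reported fractions exactly dose-linear; a
flag feeds the dose into the total diet instead. The dose enters as a
0.1-day square pulse on the dietary channel (the experiment is a single
oral gavage; the numerical dosing scheme is not specified by the source).
After 3 days the labeled pools are pooled into intestinal {LC, IC},
excreted {EC, ECP}, plasmatic {HDL, LDL}, hepatic {HC, HCE} and peripheral
{PC} compartments; BS-derived label is excluded by default (the
experimental distribution counts sterols), with an alternative pooling
that folds it into the hepatic/excreted compartments. Comparison with the
observed three-group distribution (feces / host tissues / intestinal) is
by Pearson correlation; the shipped calibration gives r ≈ 0.999, though
with a far more excretion-dominated distribution than observed — the
published fluxes put ~90% of luminal cholesterol into the feces per pass,
so quantitative agreement would require the unpublished pool values.

## Exploration

**Capacity scaling.** Multiplying a guild capacity re-solves the steady
state (Newton continuation from the basal fixed point, stiff-integration
fallback) and reports percent changes of every named flux and pool. With
the saturating feedback, 20× the deconjugator capacity depletes luminal
BS by ~24%, cuts epithelial BS absorption ~30%, raises BS synthesis ~10%
and hepatic cholesterol synthesis ~13%, and lowers HDL/LDL by 2–3% — the
reported direction on every axis, with magnitudes within a factor ~2 of
the published ones given the synthetic pool values. 20× the converter
capacity lowers luminal cholesterol by only ~3%: with
`k_cc = Q_col,cop·k_LCe` the conversion flux is bounded by `Q` times the
excretion flux for any converter level, so the reported ~47% luminal
depletion is not reachable from the printed rate definitions; this is a
structural property, not a calibration artifact.

**Global sensitivity.** Eleven parameter groups (dietary intake, biliary
release, epithelial cholesterol uptake, liver→blood transport, the
blood→liver pair, the synthesis trio, epithelial BS uptake, BS release,
BS synthesis, and the two capacities) are sampled with the fast99
frequency design — each group in turn rides the highest admissible
frequency `(n−1)/2M` (M = 4 harmonics) while the complementary groups are
spread evenly over the low-frequency band, with random phases; the
first-order Sobol index is the spectral mass at the driver's first M
harmonics over the total. Flux groups range over ±50% of basal;
capacities log-uniformly over 0.01–100× (log chosen so both decades
around basal are represented; linear sampling is a switch). Failed steady
solves are interpolated along the sweep (so they do not inject spurious
spectral mass) and counted. PCCs come from an independent uniform sample
via the residual-correlation definition, robust to exact collinearity.
The estimator reproduces the Ishigami indices within 0.02 at n ≈ 3·10³
per parameter and is seed-stable (SD < 0.02 over 5 seeds). The default
budget is 10⁴ model evaluations (~15 s), which already resolves the
reported ranking: blood↔liver transport dominates the plasmatic pools
with synthesis second, and the deconjugator capacity dominates the
enterohepatic pools; first-order indices sum to ≈1 for most compartments
with a visible interaction residual for the enterohepatic pools.

## Numerical choices

* Whole-body integration: LSODA at rtol 1e-8–1e-10; steady-state
  criterion max |dx/dt|/(|x|+1) < 1e-8 over the non-cumulative states,
  excreted pools excluded (they grow forever); Newton polish on the
  12-dim live subsystem.
* Negative states are clipped to zero inside the right-hand side
  (integrator safety) with a debug log.
* Switches are evaluated in the overflow-safe form (`x_t^s/(x_t^s+x^s)`
  equivalents) so zero concentrations are exact limits, not NaNs.
* All randomness flows from a single integer seed per entry point
  (generators, sampler, sensitivity phases); outputs record it.

## Problem sizes

The shipped defaults are desk-scale: DRAM chains of 5·10⁴ draws (2.5–6·10³
in the tests and the reproduction script, which the optimizer start makes
sufficient), 10⁴-evaluation sensitivity sweeps, 20-replicate recovery
studies. The full-size global design (1.1·10⁶ samples) is available by
setting `exploration.n_samples` in the run configuration.

## Known limitations

* Calibrated on mouse data; no human-parameterized variant.
* Single functional guild per conversion; no spatial structure along the
  intestine, no colonic vs ileal populations.
* Pool concentrations, volumes and switch thresholds are synthetic
  defaults (flagged in every calibration); percent responses of the
  exploration layer therefore carry the directional, not numerical,
  weight of evidence.
* The as-printed BS-synthesis term is unstable under strong deconjugation
  (see above); exploration results are reported for the saturating form.
* Deuterated and normal cholesterol are assumed kinetically identical (no
  isotope effect).
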