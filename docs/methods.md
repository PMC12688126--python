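# Methods

## Model

The package simulates gibberellin (GA) homeostasis in a single
well-mixed compartment and asks how that homeostat responds when a
synthetic, GA-degradable transcriptional repressor (a dCas9–degron–
repression-domain fusion, "GAHACR") is wired into one of its feedback
arms.

The baseline network follows the canonical relief-of-repression
architecture of GA signaling:

* **Biosynthesis.** GA12 enters at a constant rate and is oxidized
  through GA15 and GA24 to GA9 by the GA20ox enzyme, then to bioactive
  GA4 by GA3ox. Each oxidation is mass-action in substrate and enzyme
  (`k·[E]·[S]`); intermediates and GA4 carry first-order turnover.
* **Perception.** GA4 binds the GID1 receptor reversibly
  (`ga4_gid1_on`/`ga4_gid1_off`). The GA4·GID1 complex captures DELLA;
  capture is modeled as committed to degradation — the ternary complex
  only resolves by destroying its DELLA (`ternary_decay`), recycling
  GA4·GID1. DELLA's GA-induced removal flux is therefore
  `della_ga_decay·[GA4·GID1]·[DELLA]`.
* **Transcriptional feedback.** DELLA activates GA20ox, GA3ox and GID1
  transcription through activating Hill functions
  `D^n/(K^n + D^n)` and represses its own transcription through the
  complementary repressive Hill `K^n/(K^n + D^n)`. mRNAs decay
  first-order and are translated first-order; proteins carry basal decay.

The synthetic repressor's gene model is, term for term, the DELLA gene
model evaluated with its own constants: production scaled by `hacr_tx`
with the same DELLA-dependent input, first-order mRNA decay and
translation, basal protein decay, and GA4·GID1-complex-catalyzed decay
with its own rate `hacr_ga_decay` (the degron is DELLA-derived, so the
complex recognizes it the same way; the repressor's complex intermediate
is lumped out). This literal mirroring is asserted as a structural
property in the test suite.

Repression of the target promoter (GA20ox by default; GA3ox and GID1
targeting are provided but experimental) enters as an additive term in
the Hill denominator of the target's activation:

    act = D^n / (K^n + D^n + (repstr · [HACR])^q)

with the exponent `q` defaulting to 1 (linear promoter occlusion) and
exposed as `hacr_rep_exponent`. The term vanishes when the repressor or
its strength is zero, so all variants collapse onto the baseline model
in that limit — a tested invariant.

### Regulatory variants

* `wildtype` — repressor transcription zeroed and its species forced to
  zero at setup; no repression term.
* `no_degron_cr` — `hacr_ga_decay = 0` only: the repressor lacking the
  GA degron accumulates free of hormone control (the open-loop control).
* `gahacr` — the full construct; identity on the parameters.

## Parameters

All quantities are nondimensional; the time unit is the mRNA-lifetime
scale (all mRNA decay rates default to 1). The defaults were fixed once
as a homeostatic O(1) baseline: transcription/translation scales 1,
enzyme decay 0.5, DELLA basal decay 0.1 (proteins outlive their mRNAs),
receptor binding fast (`on=10`, `off=1`), GA-induced DELLA decay strong
(10), GA12 influx 1, intermediate turnover 0.1, bioactive GA4 turnover 1,
all Hill thresholds 1 and coefficients 2. The repressor block mimics the
DELLA constants field-by-field (`hacr_tx = della_tx`, etc.), and the
repression strength defaults to 1 — the log-midpoint of the standard
sweep range. These choices give a unique, quickly reached positive
steady state (GA4 ≈ 0.163 for wildtype) and are deliberately not tuned
to any particular wet-lab quantity; every scientific claim the package
makes about them is qualitative (orderings, monotonicity, reductions)
and re-verified numerically by the test suite.

## Numerics

* Integration: `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  `rtol=1e-8`, `atol=1e-10` by default; all overridable per run config.
  Negative excursions below `-atol` are clipped to zero with a logged
  warning; smaller ones silently.
* Steady states: integrate-then-polish. The trajectory is advanced over
  doubling horizons (50, 100, …, up to `t_max=5000`) until the RHS
  max-norm residual relaxes below 1e-3, then a hybrid (damped Newton)
  root solve is seeded at the endpoint. A result is marked converged
  only if its certified residual is below the tolerance (default 1e-8);
  otherwise the best state seen is returned flagged, so a sweep never
  aborts on one bad cell. A pure-integration mode (`method=
  "integration"`) exists and is cross-validated against the polished
  route to 1e-6 relative in the tests. Integration is preferred for
  branch selection because the system could in principle be multistable;
  at the defaults it is observed to be monostable (five random positive
  starts agree to 1e-6 relative).
* Steady-state comparisons (monotonicity, orderings) use a fixed
  absolute slack of 1e-7 — ten times the residual tolerance — chosen
  from the solver tolerances, not fitted to any observed surface.
* Sweeps warm-start each cell from the previous cell's solution along
  the row (the surface is continuous in the parameters) and fall back to
  the default start on non-convergence; unconverged cells carry NaN and
  a False flag, never a silent number.

## Scenarios and the parameter ensemble

The three bundled scenarios mirror the model-prediction figures of the
study design: `fig1D_dynamics` (the three variants' GA4 time courses),
`fig1E_sweep` (steady GA4 surface for the non-degradable repressor) and
`fig1F_sweep` (the same for the GAHACR). Sweep axes default to 8
log-spaced points spanning 1e-2–1e2 × the default value of repression
strength and degradation rate. The no-degron surface uses the basal
protein decay as its degradation axis, because that variant has its
GA-dependent decay disabled by definition.

`perturb_parameters` builds seeded ensembles in which every rate and
threshold is multiplied by an independent log-normal factor with median
1 and a chosen coefficient of variation; Hill coefficients stay fixed.
Log-normal multiplicative noise is the natural perturbation for
positive-scale kinetic constants and guarantees every member is a valid
parameter set. The robustness harness (cv = 0.2, n = 50) tallies the
fraction of members preserving the monotone surface and the variant
ordering; at the defaults that fraction is 1.0.

## What the generator does and does not emulate

The scenarios and ensembles exercise the model's qualitative claims —
they are not synthetic wet-lab data. Passing tests show that the
*model* has the advertised structure (reduction to baseline, monotone
response to repression strength and degradation rate, the
wildtype ≥ gahacr ≥ no-degron GA4 ordering, robustness of those
orderings under parameter noise). They say nothing about transcriptome,
growth or flowering readouts, which live outside the model's state
space, nor about absolute GA concentrations, which the
nondimensionalization deliberately leaves unanchored.

## Known limitations and flagged observations

* Single compartment, deterministic; no tissue structure, no stochastic
  (SSA) dynamics, no delays, no bifurcation continuation.
* The linearity contrast diagnostic comes out *reversed* at the default
  constants: the degradable repressor's expression ramp is the more
  linear one (score ≈ 0.005 vs ≈ 0.34 for the non-degradable control),
  because homeostatic feedback buffers the GAHACR while the no-degron
  repressor saturates the Hill denominator hyperbolically. The
  diagnostic is computed and reported either way, and the reversal is
  surfaced as a flagged discrepancy rather than silently passed or
  hard-asserted.
* GA20ox is a single lumped node; the five Arabidopsis GA20ox paralogs
  are not modeled individually.
* GA3ox/GID1 targeting reuses the same repression insertion on their
  transcription terms but is exercised only by unit tests, not by the
  bundled scenarios.
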