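# Methods

## Model structure

The unit of selection is the colonic crypt. Because crypts carry few stem
cells and are effectively homogeneous with respect to driver mutations, the
evolutionary dynamics are described at the crypt level: a crypt's genotype
changes when a mutant stem cell arises and fixates within the crypt
(*conversion*), and partially transformed crypts multiply by *fission*
subject to niche competition.

Six genotypes are tracked (APC 0/1/2 hits × KRAS wild/activated). The
mutation graph has seven edges; type 6 (APC-/- KRAS+, the advanced-adenoma
type) is absorbing. Conversion rates compose three independently testable
factors — stem-cell divisions per crypt-year (n_sc · r1 · F_i), the
per-division mutation probability (u for an APC hit, mu for KRAS activation),
and the Moran fixation probability rho(F_j/F_i, n_sc) of a single mutant.
This composition is the package's design choice for a layer whose published
description states only the dependencies (population size, mutation rate,
relative fitness); it reduces to the standard neutral result
R = r1 · u (population-size independent) when fitnesses are equal. An
`apc_first_hit_multiplicity` switch (default 1, settable to 2) covers the
per-gene vs per-allele convention for the first APC hit, which the available
description leaves open.

Selection acts on the stem-cell division rate, so the invader/resident
fitness ratio F_j/F_i enters rho.

## Deterministic layer

Expected crypt counts follow the ODE system in the package docstrings, with
logistic fission terms γ_i n_i (1 − (n3+n4+n5)/K) using K_A for type 3 and
K_R for types 4–5 (a shared competitor pool with type-specific ceilings).
The flux form conserves total crypt number when fission, death and outflow to
type 6 are removed; a non-conservative variant that circulated in print is
retained behind `printed_variant=True` for comparison only and is excluded
from every invariant. The adenoma-generation probability P(t) uses the
filtered-hazard equation dP/dt = (R36 n3 + R56 n5)(1 − P); the pathway
decomposition assigns each path its own influx term, which is the unique
splitting that sums to the printed total. The solver is LSODA with
rtol 1e-8 / atol 1e-12 and dense output.

Detected incidence is P(t − ΔT). ΔT is the expected first-passage time of a
linear birth–death colony (rates γ_6 k, δ_6 k) from 1 to the detection size
N, **conditioned on reaching N** — only surviving colonies are ever detected.
The default estimator simulates 10^4 seeded first-passage paths using the
embedded-jump-chain representation (with linear rates the jump chain is a
simple ±1 random walk, so paths vectorise); `method="analytic"` provides the
fast unconditional approximation Σ_{k<N} 1/(k(γ6−δ6)), exact in expectation
for δ6 = 0.

## Stochastic layer

The exact simulation (Gillespie) treats conversions, fissions (propensity
clamped at zero above capacity) and deaths of types 3–6 as discrete events.
Types 1–2, whose dynamics are linear, autonomous and of order 10^7 crypts,
evolve as a deterministic two-compartment pool (piecewise closed form across
treatment segments) that feeds time-inhomogeneous Poisson influx of type
3/4/5 crypts; influx is sampled by thinning against a short-lookahead bound
(n1 is non-increasing and dn2/dt ≤ R12 n1). A full-SSA mode simulates types
1–2 explicitly and is used to validate the hybrid on small systems; in the
linear regime both modes agree with the ODE means within Monte-Carlo error.
Each run draws its own substream via `numpy.random.SeedSequence(master)`, so
ensembles are reproducible run-by-run and arms of a trial can share
randomness (common random numbers). Runs stop when the type-6 colony reaches
N or at the censoring age t_max = 80.

The mean-field curve P(t − ΔT) is a *law-of-large-numbers* object: it tracks
the stochastic detection CDF when mutated-crypt seeding is plentiful relative
to the nonlinearity (the validation scenario inflates u on a 10^3-crypt
system). At fully physiological rates the first type-3 lineages arrive
stochastically and fission amplifies the timing noise, so means and the
mean-field curve separate; the package treats the stochastic layer as the
ground truth there, mirroring the split between fitted ODE curves and
simulated predictions.

## Parameters

Published point values: u = 1e-7 and mu = 1e-9 per division,
δ = δ_6 = 0.05 /yr, γ_6 = 1.01 /yr, detection size N = 100, five 5-year age
bins spanning 55–79, censoring at 80 years.

The stem-cell fitnesses F_2..F_6, n_sc, r1, N_crypt and the fission rates of
types 3–5 are configuration-level placeholders: the source's parameter table
is not reproduced here, so defaults were chosen once from the field's usual
ranges — n_sc = 5 stem cells per crypt, r1 = 150 divisions/yr (a division
every ~2.4 days), N_crypt = 1e7, modest fitness advantages increasing along
the graph (1, 1.4, 2.2, 1.6, 2.0, 3.0), γ_3 = 0.5 /yr, γ_4 = γ_5 = 0.35 /yr,
K_A = 5000, K_R = 2500 (capacities within the supported 100–5000 band,
K_A > K_R as the biologically relevant ordering). Under these defaults the
synthetic screening table rises from ~5% at ages 55–59 to ~10% at 75–79 with
the APC path dominant, i.e. the structure of the real study input, and both
carrying capacities genuinely shape the curve (so recovery tests are
informative). Every acceptance-level property is written to be independent of
these placeholder values.

## Fitting and model selection

The loss is unweighted SSE between model cumulative incidence at bin
midpoints (57.5, …, 77.5) and observed cumulative incidence;
binomial-variance weighting is available. Free parameters (any subset of r1,
γ_3, γ_4=γ_5, K_A, K_R) are evaluated on an exhaustive grid — the surface is
multimodal, cheap (one ODE solve per point, memoized across refits) and the
full surface is part of the result. ΔT depends only on (γ_6, δ_6, N), never
on free parameters, and is computed once per fit. Grid points whose
integration explodes (unlimited fission at high r1) are recorded with
infinite loss. Boundary flags report optima at grid edges and at exactly zero
fission.

Model selection fits the no-competition model (K_A = K_R = ∞) against the
finite-K model and reports whether the linear optimum sits at the
zero-fission boundary. The packaged study condition for this diagnostic uses
inflated mutation rates on a 10^3-crypt system with δ = 0, so that the
no-fission model has honest amplitude (adjustable through r1) while any
positive fission rate on a log-spaced grid oversteepens the curve; the
rejection then reproduces robustly across sampling seeds.

## Aspirin intervention

Dose translation uses body-surface-area scaling (mg/kg ÷ 12.3, scaled to a
70 kg adult dosed daily, 325 mg pills); constants are exposed as arguments.
The stem-cell fitness factor is F_r / ((1−a) + a·F_d) with apoptosis fraction
a = 0.1 by default. It enters conversion rates by multiplying the invading
type's fitness inside the fixation probability (default); a mode that
multiplies R_ij directly is provided since the published account does not
settle the convention. At the inter-crypt level γ → F_r γ and δ → F_d δ for
affected types. Scope options: type 6 only vs all mutated types 2–6;
intra-crypt only vs both levels. Outside the window all parameters revert
exactly.

Relative risk uses paired ensembles with shared per-run seeds **and shared
segment boundaries** (the control arm runs with the same switching times but
unchanged parameters), which makes the two arms event-for-event identical
until treatment starts; RR is exactly 1 for null regimens or assessments
before treatment, and dose ladders are paired. The 95% CI uses the delta
method on log RR with the paired-binary covariance.

## Numerical choices and degenerate inputs

- Moran fixation: r = 1 returns 1/n exactly (tolerance 1e-12 on r); n = 1
  returns 1; strongly deleterious invaders switch to a log-space form and may
  underflow to 0 below ~1e-308, which downstream code treats as rate 0.
- ODE solutions are clipped of solver-level negative round-off (beyond a
  tolerance scaled to the system size an error is raised instead).
- The SSA influx bound refreshes every candidate event over a 2-year
  lookahead; thinned candidates advance time without touching state.
- Ties on the fitting grid resolve to the first point in row-major grid
  order (sorted ascending per axis).
- Wilson intervals for simulated incidence come from statsmodels.

## Scope and limitations

The model stops at advanced adenoma: progression to carcinoma, mortality,
sex stratification, inflammation and microbiome mechanisms are out of scope.
The synthetic generator emulates prevalence-style screening data with
binomial noise and a single sex-averaged cohort per bin; it does not emulate
screening compliance or detection sensitivity, so passing recovery tests
speak to estimator correctness under the stated sampling model, not to
robustness against real-world ascertainment. Fitted values from the default
grids are not expected to coincide numerically with any previously reported
fit, because the loss convention, bin placement and the physiological r1
range are package choices. Headline relative-risk magnitudes depend on the
(unavailable) fitted parameter set and real incidence data; the package
asserts the directional and structural properties (null identity, dose
monotonicity, scope ordering at long follow-up, persistence) on its own
reduced study conditions instead.
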