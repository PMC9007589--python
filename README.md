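# cryptevol

Crypt-scale evolutionary dynamics of advanced colorectal adenoma: a multistage
carcinogenesis model with the colonic crypt as the unit of selection, plus the
machinery to fit it to age-incidence data and to simulate how aspirin-induced
changes in cell kinetics translate into population-level risk reduction.

The package is aimed at mathematical oncologists and cancer epidemiologists
who want a tested, reusable implementation of this model class: deterministic
(ODE) and exact stochastic (Gillespie) dynamics, grid fitting with
linear-vs-nonlinear model selection, pathway decomposition, and
chemoprevention relative-risk simulation.

## The model

Six crypt genotypes are tracked, indexed by APC hits (0, 1, 2 copies
inactivated) and KRAS status (wild type / activated):

```
1: APC+/+ KRAS-    2: APC+/- KRAS-    3: APC-/- KRAS-
4: APC+/+ KRAS+    5: APC+/- KRAS+    6: APC-/- KRAS+   (advanced adenoma)
```

A crypt of type *i* converts to type *j* when a mutant stem cell arises (APC
hit rate *u* = 1e-7 per division, KRAS activation rate *mu* = 1e-9) and
fixates among the crypt's *n_sc* stem cells via a Moran process:

    R_ij = n_sc · r1 · F_i · u_ij · rho(F_j / F_i, n_sc),
    rho(r, n) = (1 − 1/r) / (1 − r^−n)

Mutated crypts multiply by fission (rates γ_i) under logistic competition
with carrying capacities K_A (type 3) and K_R (types 4–5). Expected crypt
counts n_1..n_5 follow a conservation-respecting ODE system, and the
probability that a type-6 crypt has been generated by age *t* obeys

    dP/dt = (R36 n3 + R56 n5)(1 − P),    P(0) = 0,

splitting exactly into the APC path (3→6) and KRAS path (5→6). Detected
incidence is P(t − ΔT), where ΔT is the expected time for one type-6 crypt to
grow by fission/death (γ_6, δ_6) to the detection size N = 100, conditioned
on non-extinction. The exact stochastic counterpart simulates every
conversion, fission and death event (types 1–2 handled as a deterministic
pool feeding Poisson influx; a full-SSA mode exists for validation) and stops
at detection or age 80.

Aspirin enters through measured fold-changes in cell division (F_r ≤ 1) and
death (F_d ≥ 1): the stem-cell fitness factor F_r / (0.9 + 0.1 F_d)
multiplies the invader fitness inside rho (intra-crypt level), and fission /
death rates scale by F_r / F_d (inter-crypt level), for the affected types
(type 6 only, or all mutated types 2–6) during a treatment window. Relative
risk is the ratio of cumulative detection fractions, treated vs untreated,
with common random numbers.

## Worked example

```sh
python examples/aspirin_relative_risk.py
```

prints

```
dose ladder:
  light      15 mg/kg =  1.84 pills/wk   F_r=0.90 F_d=1.50 -> fitness factor 0.86
  medium     50 mg/kg =  6.13 pills/wk   F_r=0.75 F_d=1.75 -> fitness factor 0.70
  strong    100 mg/kg = 12.26 pills/wk   F_r=0.50 F_d=2.00 -> fitness factor 0.45

treatment ages 40-50, risk assessed at 50 (zero follow-up), 3000 paired runs:
  light   RR = 0.929  (95% CI 0.897-0.962)
  medium  RR = 0.871  (95% CI 0.836-0.907)
  strong  RR = 0.811  (95% CI 0.772-0.851)
```

The first block translates xenograft doses to human pill-per-week equivalents
(body-surface-area scaling) and to stem-cell fitness factors; the second runs
paired Gillespie ensembles on a reduced test system and shows the monotone
dose–response in relative adenoma risk. The other scripts in `examples/`
cover conversion rates, the mean-field incidence curve and pathway split,
fitting with model selection, and the stochastic-vs-ODE comparison.

A thin CLI chains the same stages for batch runs:

```sh
cryptevol synth --seed 1 --out incidence.csv
cryptevol fit --data incidence.csv --out fitdir
cryptevol simulate --seed 1 --n-runs 1000 --out sim.csv
cryptevol pathways --out pathways.csv
cryptevol aspirin --seed 1 --out rr.csv
```

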