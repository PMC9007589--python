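"""Aspirin regimens: dose translation and simulated relative risk.

Prints the dose table (xenograft dose, human pill-per-week equivalent, and the
derived stem-cell fitness factor), then simulates a ten-year treatment window
at three dose levels on a reduced system and reports the relative risk of
detected advanced adenoma at the end of treatment (zero follow-up) with
common-random-number ensembles.
"""

import cryptevol as ce

print("dose ladder:")
for _, row in ce.DOSE_TABLE.iterrows():
    phi = ce.fitness_factor(row.f_r, row.f_d, 0.1)
    pills = ce.human_equivalent_dose(row.mouse_dose_mg_per_kg)
    print(f"  {row.label:7s} {row.mouse_dose_mg_per_kg:5.0f} mg/kg "
          f"= {pills:5.2f} pills/wk   F_r={row.f_r:.2f} F_d={row.f_d:.2f} "
          f"-> fitness factor {phi:.2f}")

params = ce.ModelParams(u=1e-4, mu=5e-9, n_crypt=1e3, K_A=2000.0, K_R=1000.0,
                        gamma=(0.25, 0.15, 0.15, 1.01), delta6=0.0)
rates = ce.conversion_matrix(params)

print("\ntreatment ages 40-50, risk assessed at 50 (zero follow-up), "
      "3000 paired runs:")
for label in ("light", "medium", "strong"):
    regimen = ce.regimen_for_dose(label, 40.0, 50.0)
    res = ce.relative_risk(params, rates, regimen, assessment_age=50.0,
                           n_runs=3000, seed=3)
    print(f"  {label:7s} RR = {res.rr:.3f}  (95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
print("\nstronger doses push division down and death up in mutated crypts,")
print("lowering both crypt conversion and fission, hence the monotone ladder.")
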