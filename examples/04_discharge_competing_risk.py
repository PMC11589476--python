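"""Time to discharge alive with death as a competing risk.

A synthetic cohort is generated whose high-dose arm has a slightly lower
discharge hazard; in-hospital deaths are censored at the end of the
60-day window (the subdistribution approximation), and a Bayesian Cox
model with site fixed effects estimates the hazard ratio of discharge
alive.  HR < 1 means slower discharge under high-dose (harm).
"""

from bayesrct import (
    GeneratorConfig,
    diagnose,
    fit_discharge,
    generate_cohort,
    hr_summary,
)

config = GeneratorConfig(
    n_per_arm=(500, 500), n_sites=8, largest_site_size=200,
    discharge_hazard=(0.025, 0.0228),  # true HR ~ 0.91
    seed=2,
)
cohort = generate_cohort(config)

draws = fit_discharge(cohort, seed=2)  # default 4 chains x 2500 draws
summary = hr_summary(draws)
diag = diagnose(draws)

print(f"analysed {summary.n_analysed} patients, {summary.n_events} discharges alive")
print(f"subdistribution HR {summary.hr.median:.2f} "
      f"({summary.hr.lower:.2f}-{summary.hr.upper:.2f})")
print(f"P(HR < 1) = {summary.p_hr_below_1:.0%}")
print(f"diagnostics acceptable: {diag.acceptable}")

# With a true hazard ratio near 0.91 the posterior should lean toward
# HR < 1 without excluding no-effect; the probability quantifies how
# strongly the data favour slower discharge under the high-dose arm.
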