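# ectplan

Electric-field planning for four-needle electrochemotherapy (ECT)
electrodes, plus the complete statistical toolkit of a two-arm veterinary
ECT trial -- built for researchers comparing needle-electrode designs and
for biostatisticians who want the trial's analyses reproducible end to end
without access to patient-level data.

The motivating problem: ECT of feline nasal-planum squamous cell carcinoma
delivers eight 100 µs pulses of 400 V (a 1000 V/cm voltage-to-distance
ratio over the 4 mm electrode row gap) through a four-needle array after
intravenous bleomycin.  Standard 20 G needles traumatize the sensitive
nose and prolong post-treatment anorexia; a thinner 25 G design promises
the same reversible-electroporation coverage with less irreversible damage
and lower circulating current.

## What it computes

**Physics arm.**  The tissue cross-section at needle mid-depth is modelled
as a 2-D conduction problem ∇·(σ∇φ) = 0 with the needle conductors as
Dirichlet electrodes (±V/2) and insulating far boundaries, discretized by
a finite-volume scheme with a cut-cell correction at the circular needle
surfaces.  From the solved potential the package derives |E| maps,
per-needle currents (scaled by insertion depth), reversible (≥ 480 V/cm)
and irreversible (≥ 1050 V/cm) electroporation zones, inter-needle
coverage, and a standard-vs-thin comparison report.  Analytic fixtures
(parallel plates, coaxial conductors, the two-cylinder conductance
πσ/arccosh(d/2a)) validate the solver to within 2%.

**Clinical arm.**  WHO T-category staging (stage = T for N0M0 disease),
modified RECIST response on summed lesion diameters, five-level anorexia
grading, alternating-then-capped group allocation (15/37 at n = 52),
body-surface-area bleomycin dosing, and self-implemented statistics:
two-sided exact Fisher (point-probability rule), exact/asymptotic
Mann-Whitney, Kaplan-Meier with the S(t) ≤ 0.5 median convention,
log-rank, Welch t and one-way ANOVA.  A seeded synthetic-cohort generator
reproduces the trial's published marginal structure (stage mixes, response
rates, anorexia distributions, FIV prevalence, survival medians 611/520
days with censoring at 1003 days) so every estimator can be checked
against known generating values.

## Worked example

```python
from ectplan import (build_array, SimulationGrid, compare_arrays,
                     ContingencyTable2x2, fisher_exact_two_sided,
                     generate_cohort, summarize_trial)

std, thin = build_array("standard"), build_array("thin")
grid = SimulationGrid.centered(40.0, 0.1)   # 0.05 mm for production runs
report = compare_arrays(std, thin, conductivity=0.2, grid=grid, voltage=400.0)
print(f"current ratio (standard/thin): {report.current_ratio:.3f}")
print(f"irreversible areas: {report.area_irreversible_standard:.1f} "
      f"vs {report.area_irreversible_thin:.1f} mm^2")

p = fisher_exact_two_sided(ContingencyTable2x2(36, 1, 12, 3))
print(f"Fisher exact p (responder table 36/1 vs 12/3): {p:.3f}")

cohort = generate_cohort(seed=1)
summary = summarize_trial(cohort)
print(f"synthetic cohort: OR thin {summary.response_rates['thin']['OR']}%, "
      f"standard {summary.response_rates['standard']['OR']}%")
```

prints

```
current ratio (standard/thin): 1.247
irreversible areas: 6.9 vs 4.6 mm^2
Fisher exact p (responder table 36/1 vs 12/3): 0.067
synthetic cohort: OR thin 97.3%, standard 73.3%
```

Read: the thicker standard needles draw ~25% more current and produce a
~50% larger necrotic (irreversible) zone at identical settings -- the
physical basis for the thin-needle design.  The exact Fisher p on the
reconstructed responder table (the trial's 97.3% vs 80% objective-response
contrast, non-evaluable counted as non-responder) prints as 0.067.  The
seed-1 synthetic cohort lands near its generating rates; across many
seeds the estimators recover them within Monte-Carlo error.

A `ectplan` console script exposes the same machinery
(`simulate-field`, `compare-electrodes`, `cohort generate`,
`trial analyze`, `reproduce-study`); see `ectplan --help`.

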