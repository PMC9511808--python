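# Methods

`ectplan` couples a 2-D electrostatic model of four-needle electroporation
electrodes to the statistical machinery of a two-arm veterinary
electrochemotherapy (ECT) trial.  This note records the models, their
assumptions, the constants that matter, and the choices made where the
design was genuinely open.

## 1. Electrode model

Both electrodes are four hypodermic needles at the corners of a rectangle:
two rows 4 mm apart (the inter-row distance that defines the nominal
1000 V/cm voltage-to-distance ratio at 400 V), needles 4 mm apart within a
row.  The standard electrode uses 20 G needles, the thin-needle electrode
25 G needles; following the ISO 9626 nominal outer diameters these are
0.9 mm and 0.5 mm conductors (radii 0.45 / 0.25 mm).  One row is wired as
the anode, the other as the cathode, matching a monopolar pulse generator
with two terminals.

Unknowns settled as package defaults:

* **Within-row spacing (4 mm).**  Not reported for the clinical device; a
  square layout matches common commercial four-needle ECT arrays and keeps
  the defining 4 mm row gap.  It is an explicit parameter everywhere.
* **Insertion depth (5 mm).**  The needles are 25 mm long but the treated
  nasal planum is shallow; 5 mm of conducting contact is a plausible
  mid-range value and only scales currents linearly.  Also a parameter.

The pulse train (8 x 100 µs, 400 V, 5 kHz) enters the physics only through
the applied voltage; `delivered_charge` offers Q = nP·tP·I as a coarse
proxy for the electrolytic load at the electrode surfaces (the
electrochemistry itself -- pH fronts, gas evolution -- is out of scope).

## 2. Field solver

The tissue cross-section at needle mid-depth is modelled as a 2-D
conduction problem, div(sigma grad phi) = 0, with Dirichlet potentials
±V/2 on the needle conductors and insulating outer boundaries.  The
symmetric ±V/2 split pins the solution mean; any other split differs by an
additive constant only.

Discretization is a cell-centred 5-point finite-volume scheme on a uniform
grid (default 40 x 40 mm, 0.05 mm spacing) with harmonic averaging of the
conductivity on faces.  Needles are rasterized by the cell-centre-in-disk
rule; faces crossing a needle surface use a cut-cell (Shortley-Weller)
conductance h/delta, where delta is the distance from the circular surface
to the neighbouring cell centre (clipped to [0.1h, 2h]).  This removes the
first-order staircase bias of the rasterized disks while keeping all
off-diagonal weights negative, so the matrix stays an M-matrix and the
discrete maximum principle holds exactly.  A resolution guard requires
every needle disk to cover at least 4 cells, and the domain side must be
at least 5x the array extent so the insulating boundary sits in the far
field.

The linear system is solved directly (SuperLU, minimum-degree ordering) up
to 2 x 10^6 grid cells and by Jacobi-preconditioned conjugate gradients
above that; either way the relative residual must reach 1e-8 or the solve
raises.  Per-needle currents are the discrete flux integrals over the
faces surrounding each needle's cells, times the insertion depth; because
the interior stencil is an exact conservation law, the signed currents sum
to zero to solver precision.

Accuracy, measured against closed forms: the parallel-plate fixture is
exact (the discrete solution is linear); the coaxial conductance
2·pi·sigma/ln(b/a) converges monotonically under refinement (errors +0.53%,
+0.28%, +0.16% at 0.2/0.1/0.05 mm); the two-parallel-cylinder conductance
pi·sigma/arccosh(d/2a) agrees to 1.2% at 0.025 mm spacing on a 30 mm
domain.  The residual two-wire error is domain truncation (the closed form
assumes an infinite medium), constant in h -- which is why grid-convergence
is demonstrated on the closed-boundary coaxial fixture, where refinement
monotonicity is well defined.

**Conductivity.**  Homogeneous sigma = 0.2 S/m by default, a typical
soft-tissue magnitude; the measured tumour impedance behind the study's
simulations is unpublished.  Because the problem is linear in sigma,
`calibrate_conductivity` matches any measured current or resistance with a
single unit-conductivity solve, and the calibrated value reproduces the
measurement exactly on re-solve.  Electroporation *areas* are independent
of homogeneous sigma (the field depends only on geometry and voltage);
only currents scale.

## 3. Electroporation mapping

|E| (central differences, masked inside conductors) is thresholded at
480 V/cm (reversible) and 1050 V/cm (irreversible), both inclusive upward;
a cell exactly at a threshold joins the higher class.  Areas are planar
(mm^2) class counts times the cell area.  `interneedle_coverage` reports
the fraction of cells inside the convex hull of the needle centres
(needle interiors excluded) at or above the reversible threshold.

At the defaults (400 V, homogeneous sigma), the standard array draws
~24% more current than the thin array (ratio 1.24) and produces a ~54%
larger irreversible area (7.1 vs 4.7 mm^2) -- the qualitative contrast the
thin-needle design was built to exploit.  The measured in-vivo excess was
44%; a single linear 2-D solve is not expected to reproduce it exactly,
since the measurement includes field-dependent conductivity rise, contact
impedance and 3-D tip effects that the model deliberately omits.

**A genuine model limitation:** with both needles of a row at the same
potential, the tangential field midway between them largely cancels; in
this single-energization model the hull-edge strips between same-polarity
needles stay below 480 V/cm at any realistic spacing (a four-line-charge
estimate puts |E| there at ~270-310 V/cm), capping hull coverage at ~0.94
(standard) / 0.89 (thin) rather than 1.0.  Full coverage of the strict
centres-hull would require sequential pair energization (rotating which
needles are paired), which the modelled two-terminal generator does not do.
The coverage number is reported honestly rather than redefined.

## 4. Clinical scoring rules

Deterministic and total on valid inputs:

* **Staging** (WHO T category; stage = T because all patients were N0M0):
  T1 < 2 cm; T2 2-5 cm (closed interval) or minimally invasive; T3 > 5 cm
  or subcutis invasion; T4 deep (fascia/muscle/bone) invasion.  Deeper
  invasion dominates size.  N1/M1 and Tis raise errors rather than guess.
* **Response** (modified RECIST on the sum of lesion diameters): CR
  requires eradication with re-epithelialization; PR at change <= -30%,
  PD at change >= +20%, SD between.  Cut-offs are inclusive and applied
  before any rounding.
* **Anorexia grade** (1-5): death -> 5; parenteral nutrition or complete
  anorexia > 5 d -> 4; anorexia >= 3 d with >= 10% weight loss or feeding
  support -> 3; complete anorexia >= 2 d -> 2; else 1.  Lower bounds are
  closed and upper ends open so that worsening any field can never lower
  the grade (a property the suite checks by construction).
* **Allocation**: alternate standard/thin from patient 1 (standard first;
  totals are invariant to the starting arm) until the standard arm holds
  15, then thin for everyone -- 52 patients yield exactly 15/37.
* **Bleomycin dose**: 15,000 IU/m^2 with the feline allometric surface
  area BSA = 10.1·(weight_g)^(2/3)·1e-4 m^2; a 4 kg cat gets 3818 IU.

## 5. Synthetic cohort generator

The generator emulates the *published marginal structure* of the 52-cat
trial; per-patient data are unpublished, so several distributions are
model constants chosen once to match printed summaries:

| quantity | source | default |
|---|---|---|
| arm sizes | printed | 15 / 37 |
| stage mix per arm | printed percentages, renormalized | (26.7, 26.7, 20.0, 26.7)% / (43.2, 40.5, 13.5, 2.7)% |
| response given arm x early/late | derived so arm-level rates match printed; CR only at stages I-II | standard early (74.9% CR, 25.1% PR), late (57.1% PR, 28.6% SD, 14.3% NE); thin early (84% CR, 16% PR), late (83% PR, 17% SD) |
| anorexia grades | categorical matching printed mean/median/range | standard (0.10, 0.20, 0.30, 0.30, 0.10) on 1-5, mean 3.1; thin (0.75, 0.20, 0.05) on 1-3, mean 1.3 |
| sessions | categorical matching printed mean/median/range | standard (0.45, 0.45, 0.05, 0.03, 0.02) on 1-5; thin (0.40, 0.50, 0.10) on 1-3 |
| FIV | printed counts | 7/15, 6/37 |
| survival | exponential per stage class; late-stage hazard x4; arm mixture median solved to the printed 611 / 520 d | censoring at 1003 d |

The late/early hazard ratio 4 is a modelling constant (per-stage medians
are unpublished) chosen so the early-vs-late log-rank contrast is decisive
at the full cohort size, mirroring the study's stage-grouped survival
finding.  Administrative censoring uses the longest printed follow-up
(1003 d) as a fixed horizon; the generator does not model staggered
accrual, so its censoring fraction (~30-35% alive in the thin arm) is
lower than the study's 54%.

Baseline lesion sizes are drawn inside the stage's size band and the best
follow-up measurement is sampled inside the sampled response's band with a
safety margin, so re-classifying the written measurements always returns
the stored response (the CSV round-trips losslessly at its 0.1 mm
precision).

What passing the recovery checks shows -- and does not.  500 replicates
recover the generating OR rates, anorexia means, stage mixes and KM
medians within their Monte-Carlo intervals, and the anorexia Mann-Whitney
contrast is significant (p < 0.001) in ~99% of replicates.  This validates
the estimators and the pipeline plumbing on data with the trial's
marginal structure; it says nothing about covariate correlations,
per-lesion dynamics, or accrual patterns, none of which are modelled.

## 6. Trial statistics

All test statistics are implemented in-package; `scipy`/`lifelines`
appear only as independent cross-checks in the test suite.

* **Fisher's exact test** is two-sided by the point-probability rule, with
  integer hypergeometric weights (exact for any realistic table size).  On
  the responder table implied by the printed arm sizes and OR rates --
  36/1 vs 12/3, counting the standard arm's non-evaluable patient as a
  non-responder -- it gives p = 0.0672, printing as the study's 0.067.
* **Mann-Whitney** is exact by full enumeration of the U distribution when
  the smaller sample has <= 8 untied observations, otherwise a normal
  approximation with tie and continuity corrections (U = mean returns
  p = 1 exactly).
* **Kaplan-Meier** is the product-limit estimator; the median is the first
  time with S(t) <= 0.5 and is undefined if the curve never crosses.
* **Log-rank** is the standard two-group statistic with the
  hypergeometric variance, 1 df.
* **Welch t / one-way ANOVA** serve only the cohort balance checks.

Percentages are reported to one decimal, matching the trial's style.

## 7. Problem sizes and numerical tolerances

Default analyses use the 800x800 (0.05 mm) grid for electrode comparison,
a 1200x1200 (0.025 mm) 30 mm domain for the two-cylinder validation, and
500 cohort replicates; together they run in about a minute on one CPU.
Linear solves demand a 1e-8 relative residual; charge-conservation checks
use 1e-6; closed-form field/conductance comparisons use 2%; calibration
round-trips 0.1%.  Degenerate inputs (non-positive conductivity,
under-resolved needles, empty survival samples, tables with empty margins,
N1/M1 staging) raise informative errors rather than returning defaults,
except the empty-margin Fisher table, which returns p = 1 by convention.
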