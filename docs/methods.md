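# Methods

## Overview

`hemodose` estimates the radiation dose delivered to circulating blood
during fractionated external photon radiotherapy.  Blood is represented by
discrete particles (default 100 000) moving between physiological
compartments; treatment delivery is a timed sequence of beam-on windows
derived from the plan; each particle accrues dose according to where it is
while the beam is on.  The per-particle cumulative dose distribution is
then reduced to summary metrics (D_mean, D_X%, V_YGy) which feed a
standard survival-analysis stage (Kaplan–Meier, log-rank, Cox
proportional-hazards) and a compartment-relevance analysis (Pearson
correlation of compartment DVH dose with the blood dose across a cohort).
Static comparators — mean body dose, mean dose over the union of all
compartment structures, and the effective dose to immune cells (EDIC) —
are computed alongside.

## Compartmental circulation model

Each compartment `c` holds a fraction `f_volume_c` of the total blood
volume and receives a fraction `f_flow_c` of the cardiac output.  Sex-
specific whole-body values follow the ICRP-89 reference: total blood
volume 3.9 L and cardiac output 5.9 L/min for female patients; 5.3 L and
6.5 L/min for male patients.  The mean residence time of one visit is

    t_c = (f_volume_c · V_blood) / (f_flow_c · CO)

**Topology.** Connectivity between compartments is modelled as a flat,
flow-weighted mixing pool: on leaving any compartment a particle picks its
next compartment with probability proportional to `f_flow`.  This is an
explicit stand-in — it is the simplest topology whose stationary occupancy
equals the blood-volume fractions and whose transit flux through each
compartment equals its share of cardiac output, which are the two
constraints the dose model actually uses.  Real serial structure
(pulmonary circulation carrying the full cardiac output) is not
represented; the shipped `f_flow` values for heart and lungs are therefore
effective mixing weights, not physiological perfusion fractions, chosen to
keep residence times on the physiological scale of seconds to minutes.

**Residence sampling.** Default `exponential` (memoryless), which makes
the `f_volume` initialisation exactly stationary from t = 0 and makes the
steady-state properties provable.  `fixed` (deterministic `t_c` per visit,
uniform residual for the first visit) is retained for sensitivity runs.
The engine is event-driven and exact; the `dt` parameter only documents
the resolution a time-stepped implementation would be held to.

**Fractions.** Each fraction is an independent circulation realization
with fresh stationary initialisation (fractions are hours apart; blood
fully remixes).  Particles are matched across fractions by index, so the
cumulative dose is a sum of independent per-fraction draws — this is what
produces the narrowing of the dose distribution with increasing fraction
number at fixed total dose.  Per-fraction RNG streams are spawned
deterministically from the single root seed.

## Delivery and scoring

Beam-on time per field is `(fraction dose / fields) / dose rate` with a
default dose rate of 3 Gy/min and a 10 s beam-off gap between fields;
fraction dose defaults to prescription / n_fractions.  During a visit that
overlaps beam-on, a particle accrues dose at a rate obtained by drawing
**one voxel dose per visit** uniformly from the compartment's voxel-dose
sample and spreading that whole-course dose evenly over the course's total
beam-on time.  Per-visit (rather than per-time-step) sampling captures
intra-organ dose heterogeneity without voxel-level particle tracking; the
choice affects the spread but not the mean of the distribution, since the
expected rate is the same either way.  Fields within a fraction are not
spatially differentiated.

A compartment only partially inside the CT field of view carries a
`coverage` fraction: each visit is irradiated with probability `coverage`
and cold otherwise, encoding the assumption that the out-of-view portion
is far from the target and receives no dose.  Coverage defaults to 1 and
is configured per compartment (`data/coverage.yaml`); the shipped values
(0.30 for skeletal muscle, fat and skin) are representative of a
site-limited scan and are meant to be overridden per site — the
configuration file makes the correction factors explicit rather than
hard-coding them.

Two exact identities anchor the scorer and are enforced by tests:

* uniform bath: if every compartment's voxel doses equal the prescription
  and coverage is 1, every particle receives exactly the prescription;
* mean conservation: E[D_mean] = Σ_c f_volume_c · coverage_c ·
  mean(voxel_doses_c), independent of the residence sampler and of the
  per-visit sampling rule.

## Patient model assembly

Structures are binary label maps congruent with the dose grid (external
masks are nearest-neighbour–resampled onto it, assuming axis-aligned
grids).  An irradiated surgical cavity is subtracted from its organ before
the voxel-dose sample is taken.  Masks may overlap; each compartment
samples its own mask independently.  A `rest_of_body` remainder
compartment absorbs the unassigned volume and flow fractions and samples
body-minus-compartments voxels, so Σ f_volume = 1 exactly by
construction.  Per-compartment `f_volume`/`f_flow` live in
`data/physiology.yaml`; the blood-volume fractions follow the ICRP-89
reference distribution of blood volume, the flow weights are the adapted
mixing weights described above.

## Blood-dose metrics and static models

* `D_mean`: arithmetic mean over particles.
* `D_X%`: minimum dose among the top `ceil(X%·N)` highest-dose particles;
  ties at the threshold all count as "top".  `D_100%` is the minimum.
* `V_YGy`: percentage of particles with dose ≥ Y (inclusive).  The
  analysed Y levels are configurable; defaults are 1, 5 and 10 Gy.
* `D_static,body`: mean dose over the body mask.  "Integral body dose" is
  ambiguous between the mean and mean × volume; both are computed, and the
  mean (Gy) form is used as the Cox covariate so that all dose covariates
  share Gy units and hazard ratios are per Gy.
* `D_static,HEDOS-like`: mean dose over the voxel-wise union of all
  compartment label maps.
* EDIC: weighted mean lung/heart/liver/body doses with the body weight
  growing with fraction number (`data/edic.yaml`; coefficients transcribed
  from the published immune-cell dose model).  When any required organ is
  outside the field of view the result is explicitly not-applicable,
  never zero.

## Survival stage

Fitting is delegated to lifelines; the module surface adds the designs
used here.  The quartile log-rank contrasts patients above the 75th
percentile of a metric against those below the 25th, discarding the middle
half.  Cox models are complete-case with dummy-coded categoricals and Wald
inference; ordinal staging variables are entered as numeric trend
covariates so each variable yields a single hazard ratio; no univariable
pre-screening is applied before the multivariable model.  `lifelines`
handles ties by the Efron method; ties are rare with continuous dose
covariates, and the package's own score test at the null (used for the
score/log-rank identity) is implemented with the Breslow convention, under
which it reduces exactly to the log-rank χ² for one binary covariate
without ties.  Degenerate (zero-variance) covariates are reported with
coefficient 0 / HR 1 instead of breaking the fit; non-convergence is
flagged, not raised.  Proportional hazards are checked via scaled
Schoenfeld residuals against rank-transformed time.  p < 0.05 is the
significance convention throughout; raw p-values are reported alongside
Holm-adjusted values, and Bonferroni/Holm/Benjamini–Hochberg corrections
are available.

## Synthetic data

The generator produces the two inputs real studies would supply.

**Phantoms.** A small grid (default 24³ voxels at 5 mm) with geometric
compartments (spheres, boxes, tubes) and a spherical target.  The dose
field is a Gaussian fall-off beyond the target surface (penumbra σ = 8 mm)
plus a Gaussian beam track along one axis (relative weight 0.25),
normalised so the target mean equals the prescription.  Optional
multiplicative lognormal noise adds voxel-scale heterogeneity.  Site
templates place different compartments near the target — large vessels for
the head-and-neck-like template, brain for the brain-tumour-like one,
heart/lungs for the lung-like one — plus an `isolated` template in which
exactly one compartment is irradiated, used for relevance sanity checks.
Prescriptions are drawn per site (68.7 ± 2.7 Gy head-and-neck, 59.8 ± 8.8
Gy brain, 66.1 ± 6.9 Gy lung) with 2 Gy fractions; geometry is jittered
per patient.

**Outcomes.** Event times are exponential with hazard
`h0 · exp(Σ β·x)` (default baseline 1/1000 per day and β = 0.2 per Gy of
blood D_90%), drawn by closed-form inverse transform so the generator is
oracle-checkable.  Censoring is an independent exponential with rate
`h·c/(1−c)`, which makes every patient's censoring probability exactly
`c` regardless of their hazard — the declared rate is recovered without
calibration.  Declared coefficients are returned as ground truth.

`dose_mode="simulate"` runs the full phantom → transport → metrics chain
per patient; `dose_mode="surrogate"` draws blood D_90% from a truncated
normal (mean 3 Gy, SD 1.5 Gy) for statistics-only studies where the
spatial chain would add cost but no information.

**What the generator does not emulate:** real CT appearance, segmentation
uncertainty, anatomy change over the course, correlated censoring,
lymphoid-organ or bone-marrow kinetics, and realistic inter-patient
variation in plan geometry beyond the jitter described.  Passing tests
therefore demonstrate internal consistency and statistical calibration of
the pipeline, not clinical validity on patient data.

## Problem sizes and numerical choices

Tests and the acceptance script run 10 000 particles for transport
properties (Monte-Carlo standard errors ≤ 0.5% of the quantities checked),
2 000 particles and 24³ grids for end-to-end cohort runs, 100 replicate
cohorts of n = 500 for parameter recovery, and 400 null cohorts for
log-rank calibration; these sizes make every statistical tolerance a
3-standard-error band or wider.  Exponential residence draws are floored
at 1e-12 s to rule out zero-length visits; the remainder compartment's
volume fraction is adjusted by the accumulated floating-point closure
error (≈1e-16) so fractions sum to exactly 1; D_X% uses `ceil` for the
top-group size; V_Y thresholds are inclusive.  All randomness flows from
one root seed through `numpy` `SeedSequence` spawning, so every output is
bit-reproducible under a fixed seed.

## Known limitations

* The flat mixing topology and exponential residence are stand-ins for
  the true circulatory connectivity; they reproduce occupancy and flux
  constraints but not serial transit correlations.
* Only circulating blood is modelled; lymphocyte recirculation through
  lymphoid organs and bone marrow is out of scope.
* Dose rate is constant (3 Gy/min) within beam-on; sub-fraction dose-rate
  variation is not modelled.
* DICOM-RT ingestion is not implemented; inputs are NIfTI grids and masks
  plus JSON plan metadata.
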