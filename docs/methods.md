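# Methods

## Scope and model class

`ctffr` implements the calibration layer of a CT-derived fractional flow
reserve (CT-FFR) pipeline as a self-contained, testable artifact. A
production system segments the coronary tree from CT angiography and
runs a 3-D finite-element Navier–Stokes solve; the boundary-condition
parameters that drive such solves, however, are naturally tuned on
reduced-order (0-D/1-D network) models, and it is this reduced-order
layer that the package makes primary. Everything downstream of the
geometry — flow solve, FFR extraction, parameter optimization, virtual
cohort, diagnostic statistics — is implemented in full; everything
upstream of the geometry (image segmentation, centerline tracing,
Agatston scoring from Hounsfield units) is out of scope, and vessel
trees are taken as given inputs.

## Hemodynamic model

A coronary artery system is a rooted tree of centerline segments, each
sampled as (arc length s in mm, lumen radius, disease-free reference
radius). Blood is an incompressible Newtonian fluid, density
ρ = 1060 kg/m³ and dynamic viscosity μ = 0.004 Pa·s. Flow is steady
(hyperemic mean flow); pulsatility, vessel compliance, autoregulation
and non-Newtonian rheology are deliberately absent.

Each segment imposes a pressure loss

    ΔP = a·Q + b·Q·|Q|

* `a = ∫ 8μ/(π r(s)⁴) ds` — the Poiseuille (viscous) coefficient,
  integrated by the trapezoidal rule over the sampled lumen, so a
  stenosis raises `a` through its r⁻⁴ dependence;
* `b = K_t (ρ/2) (1/A_throat − 1/A_ref)²` — the irreversible expansion
  loss of the post-stenotic jet, with A_throat the minimal lumen area
  inside the lesion and A_ref the local reference area. This is the
  standard reduced-order stenosis form; K_t (default 1.0) is a
  calibratable shape coefficient. The quadratic term is written Q|Q| so
  the law stays well-defined under flow reversal; on the acyclic trees
  used here converged flows are checked non-negative rather than
  assumed.

Each outlet i drains through a lumped microvascular resistance to zero
venous pressure,

    R_i = (R_ref / h) · (d_i / d_ref)^(−k)

with d_i the outlet's distal reference diameter. Defaults: reference
diameter d_ref = 3.0 mm; resting resistance scale R_ref = 248 mmHg·s/mL,
chosen so that a healthy 3.0 mm outlet at mean aortic pressure carries
≈1.5 mL/s under hyperemia; hyperemia factor h = 4 (maximal vasodilation
quarters resting microvascular resistance); diameter exponent k = 2.7,
between pure area scaling (k = 2) and Murray's law (k = 3). The ostium
is held at a known mean aortic pressure P_a = 93 mmHg; since FFR is a
pressure ratio normalized by P_a, P_a is treated as a per-run input,
not a calibrated parameter. All interface units are mmHg, mL/s and mm
(1 mmHg = 133.322 Pa); conversions happen once inside the loss
coefficients.

FFR at any point is local pressure over aortic pressure. Point
measurements emulate catheter practice: the probe sits 25 mm (2–3 cm)
distal to the lesion's distal end, walking into the largest-calibre
child at junctions and clipping (flagged) at the terminal node if the
vessel ends sooner.

### Solver

The nodal system (one pressure unknown per segment's distal junction)
is solved by damped successive substitution: the quadratic term is
folded into an effective linear resistance a + b|Q| at the previous
iterate, and the resulting linear network is solved *exactly* per pass
by tree elimination — an upward sweep collapses every subtree into a
conductance to ground, a downward sweep assigns pressures — which is
O(n) and keeps junction mass balance at machine precision by
construction. Damping 0.5 on the linearization point, convergence when
the maximum relative flow change falls below 10⁻⁸, at most 200
iterations (typical trees converge in ~20); non-convergence raises an
error carrying the residual, and FFR extraction refuses unconverged
solutions. Segment pressure profiles distribute the viscous loss
cumulatively along the samples and apply the expansion loss as a step
at the throat.

Geometry-only quantities (a, the unit-K_t b, outlet diameters) are
precompiled per tree and reused across solves, which is what makes the
calibration inner loop (thousands of objective evaluations) cheap.

## Stenosis geometry and plaque metrics

Lesions narrow the lumen multiplicatively by 1 − (degree/100)·w(s),
where w is by default a C¹ cosine-squared bump peaking at the lesion
center (a rectangular profile is available), so the minimal lumen
diameter is exactly reference × (1 − degree/100). Samples are refined
inside the lesion (≥40 intervals, throat included exactly; base
sampling step 0.25 mm) so that short throats stay resolved and
trapezoidal plaque integrals are accurate to well under 0.5%. The
disease-free reference wall is the linear taper of the healthy
segment — a geometric definition, standing in for the plaque-software
delineation a clinical core lab would use. Plaque volume is
∫(A_ref − A_lumen) ds over the lesion; plaque burden is its ratio to
∫A_ref ds, in percent.

## Calibration

Training cases pair a vessel tree and target lesion with a measured
FFR. The objective is the mean squared error between computed and
measured FFR on the natural FFR scale (no logit transform). The free
subset defaults to {R_ref, k, K_t}: the hyperemia factor h enters only
through R_ref/h and is therefore excluded as non-identifiable; P_a is a
known input. Optimization is derivative-free (the solver sits inside
the objective): bounded Nelder–Mead in unit-normalized coordinates from
n = 8 Latin-hypercube starts (seeded, hence deterministic), followed by
a tight polish of the best start. Default bounds: R_ref ∈ [60, 900]
mmHg·s/mL, k ∈ [0, 6], K_t ∈ [0, 5]. A warning is raised when the
training lesions span less than 20 percentage points of stenosis
degree, where K_t is poorly identified.

**Training-set design.** With one FFR per vessel and measurement noise
SD 0.02, R_ref and K_t are strongly collinear: the turbulent drop
scales as K_t/R², so severe lesions constrain only that combination,
and mild lesions (whose viscous drops are of the order of the noise)
barely pin R_ref. A Cramér–Rao analysis at the default θ shows that
cohorts with trial-like severity marginals leave K_t with a standard
error of 12–16% at n = 80. The packaged retrospective design
(`CALIBRATION_DESIGN`) therefore mixes two complementary severe
archetypes — long 75% lesions, whose loss is viscosity-dominated, and
focal 84% lesions dominated by jet expansion — across proximal calibres
2.4–4.3 mm (which identify k), plus a tenth of moderate 55% lesions for
degree span. This drives the bound down to ≈2.7% (R_ref), 1.3% (k) and
5.7% (K_t), making recovery within a few percent routine; empirically
the noiseless design recovers the generating parameters to optimizer
precision.

## The virtual cohort: what it emulates and what it does not

Each synthetic vessel is a three-segment tree (proximal trunk carrying
one target lesion, main distal continuation, one side branch) with
label-dependent calibre (LAD/LCX/RCA mix 0.55/0.22/0.23, proximal
diameters ≈2.3–4.5 mm) and one lesion of 30–90% diameter stenosis in a
vessel ≥2.0 mm — the CTA inclusion window. "Invasive" FFR comes from
the reference model with (i) a per-vessel log-normal perturbation of
microvascular resistance (SD 0.15 on the log scale) representing
physiological variability the anatomical model cannot see, and (ii)
additive measurement noise (SD 0.02), truncated to (0, 1]. CTA percent
stenosis is the true degree plus reader noise (SD 8 percentage points,
truncated to [0, 100)), thresholded at 50%/70% — chosen so the
angiographic comparator's specificity lands far below the index test's,
as in real trials.

The generator targets the trial's stratum marginals directly: each
vessel draws its FFR stratum (below gray zone / gray zone [0.76, 0.80)
/ non-ischemic) from the configured multinomial (defaults 32.5 / 13.7 /
53.8%, i.e. 46.2% ischemic), draws the measured value uniformly within
the reachable part of the stratum, and inverts the monotone
degree→FFR map of that vessel (Brent bisection) for the realizing
stenosis degree. This guarantees the configured ischemic and gray-zone
fractions up to multinomial sampling error while keeping every degree
inside [30, 90]; geometries that cannot reach a drawn stratum are
redrawn, and a configuration that keeps failing raises a diagnostic
error. The gray zone is treated as the half-open interval [0.76, 0.80)
and as part of the ischemic class, matching how gray-zone lesions are
tabulated clinically (a CT-FFR > 0.80 there is a false negative).

Plaque covariates are generated to reproduce rank structure, not
absolute dispersions: per-stratum median lesion lengths (22.3 / 21.3 /
17.6 mm for below-gray / gray / non-ischemic) and calcified fractions
of plaque volume (0.08 / 0.135 / 0.087) are log-normal, so gray-zone
lesions are longer and more calcified than non-ischemic ones; plaque
volume, lumen area and lumen diameter follow from the geometry itself;
the calcium score is a log-normal surrogate scaled to calcified volume,
*not* an Agatston score.

Consequently the cohort reproduces the *structure* a trial analysis
assumes — stratum fractions, a U-shaped accuracy profile across FFR
bins with its minimum in the gray zone, covariate rank ordering — but
not the numerical agreement statistics of any real dataset: the
synthetic CT-FFR-vs-FFR correlation is far tighter than real-world
values because segmentation error, image artifacts and model
misspecification are absent. Passing tests therefore validate the
machinery, not clinical performance.

## Evaluation conventions

Ischemia is FFR < 0.80; the index test is positive at CT-FFR ≤ 0.80;
CTA is positive at ≥50% stenosis. Proportion metrics are reported in
percent, rounded half-up to one decimal, with Wilson score 95%
intervals (a normal-approximation option exists); zero-denominator
metrics are flagged undefined, never fabricated. AUC is the rank-based
concordance probability with ties counted ½, oriented for a
lower-is-diseased index, with a DeLong placement-variance interval.
Bland–Altman reports both the 95% limits of agreement (mean ± 1.96 SD)
and the 95% CI of the mean difference — two different quantities that
are easily conflated in print. FFR bins follow the printed 2-decimal
clinical labels (<0.66, 0.66–0.70, …, >0.90) realized as contiguous
half-open intervals, with the bin above the gray zone starting at the
0.80 threshold so the bins partition (0, 1]. Group comparisons use the
tie-corrected asymptotic Mann–Whitney U without continuity correction
(so identical groups give p = 1) for continuous covariates and
chi-square — switching to Fisher's exact test when any expected cell is
below 5 — for categorical ones. Risk-factor screening is univariate
logistic regression (IRLS via statsmodels) with Wald intervals;
constant covariates and complete separation are flagged non-estimable.
Paired classifier comparisons use the exact McNemar test on discordant
pairs within the relevant truth stratum. No multiple-testing correction
is applied, and the report footer says so. Per-patient aggregation is
intentionally absent: the analysis unit is the vessel.

## Determinism and problem sizes

Every stochastic component takes a `numpy` Generator or an integer
seed; the end-to-end trial derives per-stage substreams from one run
seed via `SeedSequence.spawn`, so toggling one stage does not perturb
another, and identical configurations produce byte-identical CSV
outputs. Default study sizes — 80 retrospective calibration vessels,
2000-vessel virtual trials for marginal checks, 100 random trees of up
to 50 segments for solver cross-validation — were chosen so the full
cycle runs in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* One target lesion per vessel; serial/diffuse disease and multi-lesion
  interaction are not modelled.
* The 1-D loss law ignores curvature, bifurcation angle losses and
  entrance effects; K_t absorbs them only on average.
* Outlet resistances are static; no autoregulation or zero-flow
  pressure offset.
* The reference ("disease-free") wall is a linear taper, so plaque
  metrics on genuinely ectatic or diffusely diseased vessels would be
  biased.
* The calcium-score covariate is a scaled surrogate; image-based
  calcium scoring is out of scope.
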