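# Methods

`qmritrack` re-implements, as one tested pipeline, a longitudinal
multiparameter-mapping (MPM) analysis of multiple-sclerosis brain: map
estimation from multi-echo FLASH, tissue/lesion mask algebra, volumetrics,
a rule-based disease-activity score, permutation inference on annual rates
of change in normal-appearing tissue, and a per-lesion area x time mixed
model.  Because no public dataset accompanies this design, every stage is
exercised on a synthetic two-timepoint phantom cohort with known ground
truth; this note records the models, the defaults, and the design choices
that were genuinely open.

## Signal model and map estimation

Each session consists of three spoiled gradient-echo (FLASH) series with
predominantly MT, PD and T1 weighting.  The forward model for the PDw and
T1w series is the exact steady state

    S(TE) = A sin(a) (1 - E1) / (1 - cos(a) E1) * exp(-TE * R2*),
    E1 = exp(-TR * R1),

with nominal flip angle `a` and repetition time `TR`.  The MTw series uses
the rational small-angle amplitude with an extra saturation term `d`
(MTsat as a fraction),

    S_MT(0) = A a (TR R1) / (TR R1 + d + a^2/2),

which is by construction the exact inverse of the MTsat estimator, so a
noiseless simulate-estimate round trip recovers `d` up to the error of the
R1/A step alone.

Estimation proceeds in the standard order:

1. **ESTATICS.**  A single R2* is fitted per voxel by least squares on the
   log signal with the slope shared across the three series and one TE=0
   intercept per series.  Unweighted least squares is the default;
   `weighted=True` weights by S^2, approximating signal-domain least
   squares (the choice matters only at low SNR).  Voxels with any
   non-positive sample are flagged invalid; negative fitted R2* (possible
   under noise) is clipped to zero and flagged, not erased.
2. **R1 and A.**  The PDw/T1w intercepts are inverted through the rational
   small-flip-angle approximation `S = A a u / (a^2/2 + u)`, `u = TR R1`,
   whose two-equation system has the closed-form solution implemented in
   `compute_r1_amplitude`.  Voxels whose intercept ratio admits no positive
   (R1, A) are flagged invalid.
3. **MTsat.**  `d = (A a / S_MT(0) - 1) TR R1 - a^2/2`, reported in percent
   units (100 d).
4. **PD.**  A is proportional to proton density; the global factor is fixed
   by scaling the median over a reference mask (by convention NAWM) to 69
   p.u.  The calibration leaves all voxel ratios unchanged.

Accuracy: the rational approximation is exact only as `a -> 0`.  With all
angles at or below 10 degrees and `TR*R1 <= ~0.05`
(`AcquisitionProtocol.small_angle()`), the noiseless round trip recovers
R1/A/MTsat to better than 1% and R2* to machine precision; the `default()`
protocol's 21-degree T1w angle, which mirrors common 3T sessions, degrades
R1 to the 2% level.  B1+/B1- inhomogeneity and imperfect RF spoiling are
deliberately out of scope: the phantom simulates none, and the estimators
assume nominal angles.

## Phantom cohort

Anatomy is schematic by design: a skull ellipsoid containing a CSF shell, a
cortical gray ribbon, a white-matter core and two deep-gray blobs, with
spherical white-matter lesions.  Each lesion has a focal core (default
radius 2 mm), a T0 envelope (3 mm) and a T1 envelope (4 mm >= 3 mm, so
lesions enlarge monotonically).  Parameter values in the two peripheral
shells interpolate between lesion-core and NAWM truth values at fractions
`g` and `g + (1-g)g` of the way to NAWM (`peripheral_gradient g = 0.4`), so
the periplaque gradient focal < initial < later < NAWM (reversed for PD) is
present at both timepoints — including at T0 in the not-yet-lesional later
shell, emulating pre-lesional microstructural change.

Default tissue truth values are plausible literature-like settings (config
data, not claims): NAWM MTsat 1.9 p.u., PD 69 p.u., R1 1.05 /s, R2* 21 /s,
with analogous values for cortical/deep gray matter, CSF and lesion core.
Longitudinal structure:

- **Atrophy** (-0.67 %/year of parenchymal volume, all subjects): the
  parenchyma and white-matter ellipsoids shrink by the corresponding linear
  factor at T1; CSF fills the difference, so TIV is constant.  Recovery of
  the programmed rate is limited by rasterization of sub-voxel boundary
  shifts.
- **Repair drift** (`status_effect`, default +0.039 p.u./year MTsat and
  +0.295 /s/year R2*): added to NAWM and cortical-GM truth values at T1,
  only for subjects whose derived disease-activity status is 1
  (stable/improving).  These magnitudes are the effect sizes the inference
  stage is meant to detect; setting `status_effect={}` gives null cohorts.
- **Noise**: per-visit tissue-level multiplicative jitter (sd 0.5%),
  voxel-level multiplicative jitter of the truth maps (sd 2%), and additive
  Gaussian noise on simulated FLASH signals (sd 0.05 signal units; a Rician
  option exists since magnitude data are Rician, but map-level bias is not
  the object of study here).  The visit jitter is what gives the annual
  rates of change a realistic between-visit variance.

Posterior probability volumes assign 0.9 to the generating class and 0.05
to a plausible competitor, so binarization at the 0.2 threshold is
exercised non-trivially and per-voxel sums stay at or below 1.  FLAIR
images are not synthesized: the phantom emits the focal lesion mask
directly, because the upstream lesion-growth segmentation that would
produce it from FLAIR is outside the pipeline.

The clinical generator draws an EDSS trajectory and activity flags per
half-interval (activity probability 0.3 per half by default, interval
uniform on 14-61 months) and derives the status label with the same scoring
chain used downstream, so labels are self-consistent by construction.
Progression chosen at mid-interval persists into the end evaluation
(sustained disability), which makes end-interval activity positively
correlated with mid-interval activity, as in real cohorts.

What the phantom does **not** emulate: realistic brain geometry and partial
volume, B0/B1 field effects, registration error between sessions,
segmentation error beyond the posterior softening, cortical lesions, and
treatment heterogeneity.  Passing tests therefore validate the *pipeline
arithmetic and inference machinery* under the stated statistical structure,
not the upstream acquisition/segmentation chain.

## Masks and lesion areas

- Binarization: a voxel is assigned to the argmax posterior class only when
  that probability strictly exceeds 0.2; exact ties are resolved by a fixed
  priority (lesion > NAWM > NACGM > NADGM > CSF) so results are
  deterministic.
- Lesion cleaning: connected components (26-connectivity by default;
  6-connectivity available) with volume strictly below 10 mm^3 are removed.
  The boundary is strict: a 10 mm^3 component survives.
- Areas: focal = FLAIR core (intersected with the T0 lesion mask first, so
  containment can never be violated); initial peripheral = T0 lesion minus
  core; later peripheral = T1 lesion minus T0 lesion; NAWM = white matter
  minus all three.  Disjointness holds by construction.  The same
  lesion-excluded NAWM definition is used for the tissue-median stage (the
  alternative — full NAWM including periplaque voxels — would leak lesion
  gradient into the "normal-appearing" medians).
- Enlarging lesions: connected components of the union of the three lesion
  areas that overlap each area by at least one voxel.  Presence is
  evaluated per component because lesions are analysed individually.

## Disease-activity score

NEDA-3 fails in a half-interval when there is a relapse, a new/enlarged
lesion, or EDSS progression; the final status is 0 only when both
half-intervals fail; "NA" flags contribute no evidence.  Both evaluations
use the T0 EDSS as the progression baseline, so disability accumulated
across the whole interval is counted at the end evaluation.

The progression threshold is 1.0 EDSS points when the baseline is below the
4.0 ambulation milestone and 0.5 points at or above it.  Placing the
boundary *at* 4.0 (rather than strictly above) is a deliberate choice: it
is the only placement consistent with the bundled reference cohort, whose
subject sub-015 (EDSS 4 -> 4.5 with no other activity) is recorded as
showing activity.  The scoring chain reproduces all 17 reference rows —
NEDA flags and final scores — exactly.

## Normal-appearing-tissue inference

For each subject, tissue (NAWM/NACGM/NADGM) and parameter (MTsat/PD/R1/
R2*), the median map value over the tissue mask is extracted at both
timepoints and converted to an annual rate of change.  The default ARoC is
absolute, `(m_T1 - m_T0)/years` — consistent with reporting regression
coefficients in parameter units per year; a relative %/year mode exists as
a switch.

Each of the 12 ARoC vectors is regressed on the binary status,
`Y = b0 + b1 X + e`.  Significance uses a permutation test on R^2: labels
are shuffled `n = 5000` times, every draw is required to differ from the
observed labelling (collisions are re-drawn; duplicate draws among the n
are allowed), and

    p = #(R_perm > R_obs) / (n + 1)

with a strict inequality, so ties — e.g. the label complement, which yields
exactly the observed R^2 — never count.  The observed R^2 is evaluated
through the same centered-covariance arithmetic as the permuted ones so
such ties cancel exactly in floating point.  An exhaustive mode enumerates
all distinct binary labelings other than the observed one (feasible up to
10^6 arrangements) and uses their count as `n`.  Note the two modes share
the exceedance probability but not the `+1` offset: comparisons between
them should compare `count/n`, not the reported p directly.

The 12 p-values are corrected with Benjamini-Hochberg at q = 0.05 (the
family is exactly these 12 tests), and Welch two-sample t-tests (pooled
variances not assumed) are applied post hoc to rejected results.  With a
status group smaller than two subjects the post-hoc test is skipped with a
warning rather than failing the stage.

Operating characteristics are measured on replicated reduced phantoms
(24 x 28 x 24 grid, truth maps, no lesions, 17 subjects) — the stage under
study reads only normal-appearing tissue medians, so lesion rendering and
map re-estimation are omitted from these replicates for speed.  Over 200
null cohorts the post-FDR rejection fraction stays below the nominal 5%;
with the default repair effect the NAWM-MTsat test rejects in essentially
every replicate.

## Per-lesion mixed model

Each enlarging lesion contributes per-area, per-timepoint medians of each
parameter; NAWM contributes one series per subject.  Medians are positive
and right-skewed, so the model works on natural logs:

    log(median) ~ area * time + (1 | participant),

a Gaussian linear mixed model (the log link plus identity-family GLMM
reduce to exactly this).  Only the participant is a random factor — lesions
are nested but deliberately not modelled with their own random effect, so
between-lesion variability within a subject loads on the residual; the
consequence is mildly conservative lesion-level inference.  The T0/T1
residuals of one measurement series (one lesion area, or a subject's NAWM)
share a correlation `rho` estimated in (-0.95, 0.95); with exactly two
timepoints this is the full content of a first-order autoregressive
residual model, and it is applied per series rather than per subject
because series, not subjects, are the repeatedly measured units.

Estimation is REML with the residual variance profiled out, optimized over
(random-intercept ratio, rho) by L-BFGS-B; the random-intercept variance
may land on its zero boundary.  Fixed effects use deviation (sum-to-zero)
coding, so the Wald F-tests coincide with the classical two-way ANOVA
decomposition; with the random intercept and residual correlation disabled
the fit collapses to OLS and the F statistics equal the fixed-effects
ANOVA oracle to machine precision (this degenerate configuration is a unit
check of the machinery, not an analysis mode).

Denominator degrees of freedom use a Satterthwaite approximation evaluated
numerically: the variance of the variance-parameter estimates comes from
the inverse observed information (finite-difference Hessian of the REML
deviance), the sensitivity of each contrast variance from central
differences, and multi-df hypotheses combine per-eigen-contrast dfs.
Kenward-Roger is not implemented; when the information matrix is degenerate
(e.g. parameters on the boundary) the code falls back to residual df, and
the method actually used is reported in every output row.  Pairwise area
contrasts at each timepoint (6 pairs for 4 areas) are adjusted with Tukey's
studentized-range procedure at the family size of 4 means, using the same
per-contrast df.

## Pipeline defaults and reproducibility

All analysis constants sit in `PipelineConfig` and reproduce the intended
defaults: binarization threshold 0.2, lesion cleaning below 10 mm^3,
26-connectivity, 5000 permutations, FDR q = 0.05, absolute ARoC.  A single
master seed feeds every stage through SHA-256-derived per-stage seeds;
rerunning with the same seed is bit-identical, and each run writes a
manifest with the configuration, stage seeds and SHA-256 hashes of all
output tables.  The full-size cohort (48 x 56 x 48 grid at 1 mm, 17
subjects, 3 lesions each, map re-estimation from simulated FLASH) runs in
well under a minute; the replicated-experiment problem sizes quoted above
were chosen so the whole validation suite remains desk-scale.

## Known limitations

- Nominal flip angles throughout; no field-inhomogeneity or spoiling
  corrections (and no simulation thereof).
- The small-angle estimator bias at realistic T1w angles (~2% in R1) is
  inherent to the rational approximation, not a bug; quantitative work in
  the validity regime should use the small-angle protocol.
- Satterthwaite (not Kenward-Roger) df; for the balanced, moderately sized
  designs here the difference is small, and the df method is always
  labelled in the output.
- Fixed lesion-area masks combined with programmed atrophy leak a small
  systematic timepoint effect into boundary voxels of the NAWM series —
  visible as a nonzero time effect even when lesion values are stationary.
  Real pipelines face the same issue through registration error.
- The phantom's statistical structure (Gaussian noise, multiplicative
  jitter, spherical lesions) is far simpler than real MS data; conclusions
  about operating characteristics transfer only to the extent that the
  real data meet the stage's assumptions.
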