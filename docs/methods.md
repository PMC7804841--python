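# Methods

## Scope and data model

`debm` consumes a flat cohort table: one row per subject with a diagnostic
group (healthy control `HC` or patient `MS`), covariates (age in years, sex
coded 0/1, education on an ordinal 1–7 scale), an EDSS disability score
(patients), seven cognitive-domain scores, and numeric biomarker columns
drawn from a fixed vocabulary of 28 candidates: 10 regional grey-matter
volumes, mean upper cervical cord area (MUCCA), 3 white-matter lesion-load
bands (inner/deep/outer; present only in patients), eigenvector centrality
of 3 resting-state networks, fractional anisotropy of 4 tract groups, and
the 7 cognitive domains. Each biomarker class carries a default abnormality
direction: volumes, FA and cognition *decrease* with disease; lesion loads
and network centrality *increase*. Missing values are the literal `NA`;
image processing, longitudinal joins and treatment-effect modelling are out
of scope.

## Preprocessing

One ordinary-least-squares model per biomarker is fitted **on the reference
(control) rows only** with intercept, age, sex and education. Residuals are
computed for every subject, centred on the reference residual mean and
scaled by the reference residual SD (ddof = 1), so corrected control values
have mean 0 and SD 1 by construction. Sex enters as a 0/1 indicator and
education as a numeric 1–7 trend. Biomarkers with no reference values
(lesion loads) cannot be anchored and instead use a robust patient-only
standardisation (median, MAD x 1.4826), flagged `anchored = False`.
A Kolmogorov–Smirnov normality screen is computed per biomarker as a
reported diagnostic only; nothing is gated on it.

Patients are banded by disability (minimal: EDSS 0.0–2.5; moderate:
3.0–3.5; severe: >= 4.0; EDSS must lie on the half-point grid) and
classified cognitively from the corrected domain z-scores: impaired (CI)
when z <= −2 on >= 2 of 7 domains, mildly impaired (MCI) when z <= −1.5 on
>= 2 domains without meeting CI, else preserved (CP).

Biomarker post-selection keeps candidates whose two-sided **Welch** t-test
between the recipe's two anchor groups gives p <= 0.1 (no multiplicity
correction — this is a deliberate low-bar screen for mixture separation,
not an inference step). Markers that cannot be tested (absent in a group,
zero variance) are excluded with a warning; a recipe-level `force_include`
list can bypass the screen, routing control-free markers to unanchored
mixtures.

## Mixture model

Each selected biomarker gets a two-component Gaussian mixture in z-space,
fitted by constrained EM on the pooled disease + reference values:

- **Per-population priors in the E-step.** Disease subjects use the fitted
  prevalence `pi`; reference subjects use a small fixed abnormality prior
  (default 0.01 — screened healthy controls may contain the odd outlier but
  are the normal anchor). The reported `mixing_fraction` is the mean
  abnormal responsibility over disease subjects only. A larger reference
  prior measurably drags the abnormal mean toward the normal flank and
  inflates the prevalence estimate.
- **Anchoring.** For anchored markers the normal mean is clamped to within
  0.5 reference SD of the reference mean and the normal SD to
  [0.5, 1.5] x the reference SD; the abnormal SD is kept within
  [0.5, 1.5] x the normal SD. A component much wider than its counterpart
  is modelling the mixture rather than a disease state.
- **Unanchored (lesion-class) markers** are fitted homoscedastic (tied
  component SDs): the two states are a mean shift with common scatter.
  With two free SDs and no anchor, EM on modes ~2.5 SD apart regularly
  lets one component swallow the other.
- **Multi-start.** Two deterministic initialisations — (reference mean/SD,
  most-abnormal decile) and a 1-d 2-means split — are run to convergence;
  the best final likelihood wins. Convergence: relative log-likelihood
  change <= 1e-6, max 500 iterations; SD floor 1e-3 z-units (clamped and
  flagged, never an error).
- **Separability gate.** The two-component fit must beat a single-Gaussian
  fit by a BIC margin (3 extra parameters, i.e. 1.5 ln n). Otherwise the
  abnormal component is collapsed onto the normal one, posteriors reduce to
  the prior, and the mixture is flagged non-separable. This is what null
  biomarkers (disease ≈ reference) produce.

The abnormality direction is inferred from the disease-vs-reference mean
difference, overridable per biomarker; markers with no reference values
default to their class direction (increasing for lesions).

Known estimator behaviour: at extreme prevalence (~0.1 or ~0.9) with
moderate separation, maximum-likelihood mixture weights are biased toward
0.5 at n of a few hundred. An unconstrained `sklearn` GMM reproduces the
same fits on identical draws — this is a property of the estimator class,
and posterior-derived prevalences for very early or very late events should
be read accordingly.

## Ordering, uncertainty, staging

With posterior matrix P (subjects x events, clamped to [1e-6, 1 − 1e-6]
before likelihood evaluation), the ordering objective is the stage-
marginalised likelihood given in the README. The search initialises at the
Borda consensus of per-subject orderings (events sorted by posterior,
descending; ties broken by the canonical column order) and greedily applies
the best of all pairwise swaps and single-event reinsertions until no move
improves by more than 1e-10. The ascent is finite and monotone; on random
instances with N <= 6 it attains the exhaustive-search maximum in >= 95%
of cases (enumeration is exposed as `exhaustive_ordering`, guarded at
N <= 8).

Bootstrap uncertainty: B resamples (default 1000) drawn with replacement
**within each role group** (reference / disease / held-out), so every
replicate preserves the two-population premise; mixtures and the ordering
are refitted per replicate, while the event set and directions stay fixed
from the full-data fit (the PVD describes positional uncertainty of one
event list, not selection uncertainty). Each replicate contributes one full
permutation, so every row and column of the count matrix sums to B — an
invariant checked on every run. Rendering caps intensity at 500 counts; the
TSV always holds uncapped counts. A replicate whose refit fails is redrawn,
capped at 10 retries.

Staging assigns each subject the likelihood-argmax stage in 0..N, with ties
resolved to the **lower** stage (stage 0 is the null state); because exact
float ties are unattainable, "tie" means within 1e-9 of the profile
maximum. Held-out subjects (moderate EDSS in `model2`, MCI in `model3`)
are excluded from mixture initialisation but fully included in the
posterior matrix, the ordering and the staging. In `model1`, controls are
staged too, on the events they have values for.

## Synthetic cohorts

The generator plants a known cascade: patients draw a latent stage from a
configurable distribution (default uniform on {0..N}); biomarker j is drawn
from its abnormal component iff the subject's stage has reached event j's
position in the true ordering; controls sit at stage 0 exactly. Defaults —
12 events of mixed classes, 300 patients, 100 controls, 2.5-SD separation
with unit component SDs, modest linear confound effects (−0.02/year age,
0.20 sex, 0.05/level education), lesion-class events blanked in controls —
define the reference conditions used by the test suite and the acceptance
script; they were chosen once as a realistic mid-difficulty regime for a
single-centre cohort of this size. A label rule paints EDSS (linear in
stage, rounded to the half-point grid, clipped to [0, 10]) and cognitive
z-scores (linear decline, default −0.25 z per stage) onto the table.

What the generator does **not** emulate: sigmoidal within-subject
trajectories, correlated biomarker noise, measurement floor/ceiling
effects, skewed lesion-load distributions, subtype heterogeneity, or
treatment effects. Passing recovery tests therefore show the estimator
chain is correct under its own generative assumptions — they do not certify
performance on real cohorts, where mixture misspecification is the dominant
risk.

## Reference problem sizes

The test suite and `scripts/acceptance.py` run the recovery experiments at
the generator defaults over 20 seeds, the oracle comparison on 50 random
instances with 3–6 events, mixture recovery at n = 500 per group over 20
seeds, selection calibration on 1000 null markers of 100 + 100 subjects,
and bootstrap conservation at B = 25–50 on a 5-event cohort; these sizes
give stable Monte-Carlo estimates while keeping a full run in the minutes
range. Production analyses should keep B = 1000.

## Design choices that were genuinely open

- The aggregation statistic combining individual orderings is not uniquely
  fixed by the discriminative-EBM idea; this package optimises an explicit
  posterior-space marginal likelihood, keeping the per-subject sort as the
  Borda initialisation, because it yields a single testable objective with
  an exhaustive-search oracle.
- Whether staging should threshold posteriors or maximise the stage
  likelihood is similarly open; likelihood-argmax is implemented (a
  threshold variant can be emulated by clamping posteriors to {0,1}).
- `model3`'s candidate list excludes the cognitive domains by default: they
  define the CP/CI contrast itself, and letting them double as events would
  build the answer into the question. A recipe can re-include them
  explicitly.
- Chi-square group comparisons are computed without continuity correction;
  percentages are reported to one decimal, medians with (Q1 – Q3).
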