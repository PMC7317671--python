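# Methods

## Scope and data model

`mtakit` analyses long-format longitudinal cohort tables: one row per
(subject, visit, rater, hemisphere) carrying an MTA rating, per-hemisphere
hippocampal (HC) and inferior lateral ventricle (ILV) volumes in mm³, CSF
chemistry, cognition (MMSE, ADAS delayed word recall), a QC flag per image
and a dementia-diagnosis flag. Hemispheres are a keyed dimension throughout;
no operation averages left/right implicitly — where a headline number needs
a single value (e.g. progression times), the hemisphere averaging is
explicit and documented at the call site.

### CSF A/T stratification

A subject is amyloid-positive when the Aβ42/Aβ40 ratio is *below* its
cut-off (default 0.10) and tau-positive when phosphorylated tau is *above*
its cut-off (default 72 pg/ml). Both inequalities are strict, so a value
exactly on a cut-off maps to the normal side; cut-offs are configurable.
The A⁻T⁺ combination is accepted but triggers a warning, since tau-first
profiles are atypical in amyloid-stratified memory-clinic cohorts.

### QC handling

Quality control failures of automated segmentation affect volumes, not
ratings. `qc_filter` therefore produces two provenance-tracked views: a
*volume view* restricted to QC-pass visits (used by every volume-based
analysis) and a *rating view* retaining all visits. No imputation is
performed anywhere; each analysis drops rows missing its required fields
and logs the counts.

## Agreement statistics

Cohen's weighted kappa is computed from the 5×5 observed proportion matrix
O, the chance matrix E (outer product of the marginals), and disagreement
weights w: κ_w = 1 − Σ w O / Σ w E, with linear weights |i−j|/4 (default),
quadratic ((i−j)/4)², or 0/1. The weighting convention is reported next to
every kappa because the conventional Landis–Koch bands (<0 poor, [0,0.2)
slight, [0.2,0.4) fair, [0.4,0.6) moderate, [0.6,0.8) substantial, [0.8,1]
almost perfect; right-open as listed) are applied to either in the
literature. Continuous automated ratings are rounded half-away-from-zero
and clipped to [0,4] before entering a kappa; they enter rank correlations
as-is. Degenerate case: when both raters are constant on the same category
the chance-disagreement denominator vanishes and κ is reported as 1.

Correlations between measures use Spearman's rank correlation on exactly
one visit per subject so observations are independent. The default
selection rule is the baseline visit (deterministic); a seeded
uniform-random-visit rule is available. Ties receive average ranks.

## Atrophy-rate estimation

Per subject and measure, the annual change is the closed-form OLS slope of
the values against age at scan (slope = Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²), requiring at
least two points with distinct ages. Volume rates are additionally
expressed in percent per year as 100·slope/baseline per subject before
averaging, so the group %/year spread reflects between-subject baseline
variation.

Group comparisons use the tie-corrected Kruskal–Wallis H with the
chi-square approximation (df = groups − 1). For total n ≤ 10 an exact
permutation p-value is computed by enumerating every partition of the
pooled values into the observed group sizes, which keeps tiny test fixtures
honest where the asymptotic approximation is poor. The multiple-comparison
threshold is Bonferroni α/m with m = 66 comparisons taken as configurable
input rather than recomputed, since the comparison inventory depends on
which measure × stratum tables a study reports.

The discrete-slope enumeration formalises why integer ratings cannot
measure individual atrophy rates over short follow-ups: over visits at
0/2/4/6 years, a rating that rises by at most one step yields OLS slopes in
exactly {0, 0.15, 0.2}/year, regardless of the subject's true trajectory.
The implementation enumerates all monotone non-decreasing 0/1 (or 0/1/2)
sequences over arbitrary visit offsets and de-duplicates slopes at 1e−12.

## Sensitivity of discrete ratings

For each rater, every follow-up visit is paired with baseline per
(subject, hemisphere), giving volume changes ΔHC, ΔILV (mm³ and percent of
baseline) labelled by the rating change ΔMTA. Classes 0, +1, +2 are
retained (changes above +2 pool into +2; negative changes — rating
decreased — are excluded from threshold estimation and counted separately,
since decreasing atrophy is biologically implausible and such pairs reflect
rating noise). A class below the minimum size (default 5) triggers an
upward merge of all ≥1 pairs. Hemispheres are pooled by default;
per-hemisphere use is possible by filtering the pair table.

Each class receives a Gaussian KDE (Scott's rule by default) evaluated on
a shared 512-point grid spanning the pooled data ± 3 maximal bandwidths.
The **crossover threshold** scans from the grid centre outward (toward
losses for HC, gains for ILV) for the point past which the higher-rating
curve exceeds the unchanged-rating curve all the way to the grid edge, with
linear interpolation between bracketing grid points; if no such region
exists an explicit no-crossover result is returned rather than an error.

Two comparison modes are provided because the underlying decision rule can
be read two ways:

- **weighted** (default): compares p₀f₀ against Σ_{k≥1} p_k f_k — the point
  where the posterior probability of "rated higher" passes 1/2;
- **unweighted**: compares the raw densities f₀ against the normalised ≥1
  mixture.

They differ systematically: as rater noise grows, the unchanged-rating
density widens, which pushes the *unweighted* crossing monotonically toward
larger losses; but noise also inflates the ≥1 class prior, which pulls the
*weighted* crossing back toward zero. Both behaviours are asserted in the
test suite; reports label the mode used.

## Progression-time arithmetic

- Full-score time: 1/rate years for a continuous rating rate > 0, infinite
  otherwise (negative fitted rates occur in slow groups and are not an
  error).
- Threshold time: |threshold|/|ΔHC per year| years.
- Latent-uniform mean: an integer score k is read as a continuous trait
  uniform on [k, k+1), mean k + 0.5; under this view the full-score time
  should be roughly twice the threshold time, and `reconciliation_ratio`
  reports the observed ratio.
- For headline per-group numbers, left/right rates and the per-rater
  thresholds are arithmetically averaged before division; this convention
  reproduces the published 25/13.3/8.3-year and 6.2/4.3/2.5-year figures
  from their printed inputs to within rounding.

## Synthetic cohort generator

No patient-level data accompany the analyses, so the generator encodes the
study conditions directly: group sizes 54/18/21 (A⁻T⁻/A⁺T⁻/A⁺T⁺) with
SCD/MCI splits 42/12, 8/10, 11/10; baseline age ~ N(70.1, 5.4²) truncated
to [60, 80]; visits at 0/2/4/6 years; per-image QC failure probability
33/372.

Per subject i and hemisphere h a latent continuous MTA trait progresses
linearly: m_ih(t) = m₀ + r·t, with (m₀, r) drawn per CSF group and
hemisphere from the observed continuous-rating baseline and annual-change
distributions (A⁻T⁻: m₀ ≈ 1.26 ± 0.58, r ≈ 0.04 ± 0.04; A⁺T⁻: ≈ 1.40 ± 0.7,
0.075 ± 0.05; A⁺T⁺: ≈ 1.24 ± 0.6, 0.12 ± 0.08; exact per-hemisphere values
in `default_group_params`). Left and right share a subject-level component
giving correlation 0.8 (configurable). Baselines are truncated to [0, 4].

Observables per image:

- HC = 4800 − 900·m + ε (σ = 150 mm³, floored at 50): the linear link and
  its slope were calibrated once so that group baseline volumes
  (≈ 3700 mm³) and group ΔHC/year means (≈ −36/−68/−108 mm³/yr) land near
  the observed study values given the latent defaults.
- ILV = 170·exp(1.2·m) + ε (σ = 80 mm³, floored at 1): exponential because
  the ventricle–rating relationship is clearly convex — a unit of rating
  change costs far more ILV volume at high scores than at low ones.
- Automated rating = clip(m + ε, 0, 4), σ = 0.15 — continuous.
- Human rating k = clip(round(m + bias_k + ε), 0, 4), rounding half away
  from zero; default biases +0.1 (rater 1) and −0.55 (rater 2) reproduce
  the observed "one rater systematically higher" pattern, and noise
  σ = 0.3 latent units is a calibration chosen so that simulated rating
  trajectories are rarely lower at follow-up, matching the qualitative
  behaviour of experienced raters.
- CSF values are group-conditional truncated normals centred on the
  observed group means, rejection-bounded to respect the A/T cut-offs.
- MMSE/ADAS-DWR are linear in time with group-specific baselines and rates
  plus noise (σ = 0.8); MMSE is rounded and clipped to [0, 30].
- Within each group the subjects with the most advanced baseline latent
  trait are labelled MCI (a deliberate, simple coupling that reproduces the
  "MCI more pathological than SCD" pattern without a cognition model).
- The dementia flag is simply mean latent trait ≥ 2.5 at a visit — an
  arbitrary placeholder; the generator contains no conversion hazard model.

What the generator does **not** emulate: scanner/protocol effects,
non-linear latent trajectories, informative dropout (all subjects complete
four visits), measurement-error correlation between volumes and ratings
beyond the shared latent trait, and any real-world rater drift. Tests
passing on these cohorts therefore validate the *statistical machinery*
(estimators, thresholds, test statistics), not claims about real scanner
data.

## Numerical choices

- Rounding of latents to integer ratings is half-away-from-zero (NumPy's
  default rounds half to even, which would bias the zero-noise limit).
- Slope enumeration de-duplicates at 1e−12; crossover interpolation is
  linear between grid points; KDE grids have 512 points.
- Exact Kruskal–Wallis enumeration is limited to n ≤ 10 (≈ 4 000
  partitions at the worst split), beyond which the chi-square
  approximation is accurate and fast.
- CSV outputs are written at 6 significant digits; in-memory results keep
  full double precision; the cohort CSV itself is written at full `repr`
  precision so read/write round-trips are bit-exact.
- Problem sizes in tests and the acceptance script: study-scale cohorts
  (93 subjects), 10–20× inflations for parameter recovery and group
  separation, 1e5 draws for the analytic crossover recovery, 100 seeded
  replicates for the group-separation rate — sizes at which the checked
  quantities' Monte-Carlo error is comfortably below the asserted
  tolerances.

## Known limitations

- All trajectory models are linear in age; no mixed-effects or spline
  fits.
- The crossover threshold depends on the follow-up mix (pairs pool 2-, 4-
  and 6-year intervals), so it is a cohort-design-dependent quantity, not a
  pure rater property.
- Threshold-based conversion-time validation against simulated first
  rating increases is only measurable in fast-progressing groups; in slow
  groups the median first increase is censored by a six-year follow-up.
- The agreement module offers no intra-rater (test–retest) statistics and
  no ICC/Krippendorff alternatives.
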