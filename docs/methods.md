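# Methods

## Scoring model

A lesion–artery relationship is one of five categories; only encasement,
displacement and penetration carry an ordinal mass-effect rank (3 > 2 > 1).
When several arteries relate to one lesion, the relation with the most mass
effect represents the lesion; a lesion whose arteries are all "in the
margin" or "disconnected" is excluded from the contingency analysis but kept
in the exclusion bookkeeping. A lesion may carry up to two distinct final
relations, and each analyzable relation contributes one count to the
relation × diagnosis table — the table therefore counts *records*, not
lesions, and the package tracks `analyzed + excluded = total` and
`records = analyzed + dual_count` explicitly.

The degree of encasement is `(1 − CD/ref) · 100` percent. The reference
`ref` depends on where the narrowest point sits relative to arterial
bifurcations inside the encased segment: proximal normal diameter `AB`
(types A and B), distal normal diameter `EF` (type C), or the linear
interpolation `CD′ = EF + (EC/EA)(AB − EF)` (type D), with `EC`, `EA` arc
lengths along the centerline measured from the distal normal point. The
interpolation is exact for a linearly tapering vessel, which is why the
type-D formula removes the taper bias that a purely proximal reference would
introduce. Amputation (a vessel too faint to measure) is 100% by
definition. Degrees live on the 0–100 percent scale everywhere — never 0–1 —
to avoid silent factor-100 bugs against printed percentages.

Numerical choices:

- A raw degree below 0 (CD above the reference, e.g. post-stenotic
  dilation) clamps to 0 with a warning; the score presupposes narrowing and
  the [0, 100] contract is kept.
- `worst_encasement` ties break toward the larger reference diameter (the
  more proximal vessel), then lexicographic vessel id, making the result
  deterministic.
- A narrowest point lying exactly at a bifurcation is conventionally
  `proximal_to_bifurcation` (type B); with ≥2 bifurcations and the narrowest
  point outside the inter-bifurcation span, the proximal/distal reference is
  used accordingly.
- The qualitative relationship rules are thresholded: caliber loss ≥ 10%
  (`tau_caliber = 0.10`) counts as "decreasing the caliber", and a course
  deviation beyond one local vessel diameter (`tau_deviation_diameters = 1`,
  local diameter defaulting to 5 mm, a typical segmental pulmonary artery)
  counts as displacement. Both are configurable; the source definitions are
  qualitative and give no numbers.

## Statistical battery

- **Exact test**: two-sided Fisher exact P by full enumeration of all
  r × c tables with the observed margins, summing (multivariate)
  hypergeometric probabilities ≤ that of the observed table (probability-mass
  rule, 1e-7 relative tolerance). The relation × diagnosis test uses the
  2 × 3 analyzable table. Counts here are small enough that enumeration is
  instantaneous.
- **Odds ratios** vs. the penetration baseline: `OR = ad/bc` with the Wald
  log-scale CI `exp(ln OR ± 1.96·SE)`, `SE = √(1/a+1/b+1/c+1/d)`; this
  reproduces the published intervals from the published counts to printed
  precision. No continuity correction by default; Haldane–Anscombe +0.5 by
  flag for zero cells.
- **Degrees**: Wilcoxon rank-sum, exact for small untied samples
  (n ≤ 20 combined), otherwise normal approximation with tie and continuity
  corrections (scipy's Mann–Whitney implementation).
- **Ages**: pooled-variance two-sample t by default, Welch by flag.
- **Agreement**: Cohen's kappa with the Fleiss–Cohen–Everitt large-sample
  variance and Wald 95% CI, graded poor (≤0.20), fair (≤0.40), moderate
  (≤0.60), substantial (≤0.80), very good (>0.80). Agreement is computed on
  one category per lesion (the dominant relation; in-margin before
  disconnection for unclassifiable sets).
- **ROC**: candidate cutoffs are the distinct observed degrees plus a +∞
  sentinel; predicted malignant ⟺ degree ≥ cutoff (this orientation is
  forced by the published operating point, where 40% lesions are false
  negatives under a 44.4% cutoff and 71–100% benign lesions false
  positives). AUC is the trapezoidal area and equals the Mann–Whitney
  U/(n₁n₀) with ties worth half — an invariant the tests check against an
  independent pair-counting oracle. The "best" cutoff maximizes Youden's
  J = sensitivity + specificity − 1, ties broken toward higher sensitivity
  then lower cutoff; a closest-to-(0,1) criterion is available.

## Synthetic cohort generator

The generator reproduces the *published statistical structure* of the
reference cohort, since per-patient data are unpublished:

- Group sizes default to 23 benign / 77 malignant lesions.
- Relationship frequencies: each lesion draws a primary final relation with
  probabilities proportional to the published final tallies (benign
  8/2/10/0/3 over 23; malignant 58/27/4/1/2 over 92). Malignant lesions with
  an encasement or displacement primary add a second, lower-mass-effect
  relation with probability 15/74 (the published dual-relationship rate);
  which pairs co-occurred is unpublished, so the secondary is drawn from the
  lower-ranked options. Consequently the *primary* draw frequencies match
  the published tallies; record-level frequencies sit slightly below them
  for displacement/penetration because dual records add counts on top — the
  frequency tests and acceptance checks therefore target the primary draws,
  which is what the configuration specifies.
- Degree of encasement: mixture of a point mass at 100% (amputation, mass
  1/8 benign and 11/58 malignant from the published type table) and a
  continuous component on (0, 100), scaled Beta by default (truncated normal
  by flag), moment-matched so the *population* mean and sd equal the
  published 52.1 ± 27.3% (benign) and 71.8 ± 18.8% (malignant) exactly:
  `m_c = (mean − 100w)/(1−w)`, `s_c² = (sd² + mean² − 10⁴w)/(1−w) − m_c²`,
  Beta shapes by method of moments on the unit scale. Infeasible targets
  raise with both feasibility bounds. The published benign group contains
  tuberculosis lesions with 71–100% encasement; whether that group is
  bimodal is unknowable from printed moments, so the generator matches
  moments only — a unimodal Beta may understate benign tail mass.
- Second observer: keeps observer 1's label set with probability `a`, else
  redraws from the empirical marginal. Under this symmetric-confusion model
  the expected kappa equals `a` exactly (the chance term cancels), so
  calibrating to a requested kappa is the identity; the default 0.639
  matches the published agreement.
- Attributes (age, size, location, sex) follow the published group
  summaries with truncation to plausible ranges; they are descriptive
  plumbing, not part of the diagnostic signal.
- One seed drives a hierarchical stream (cohort → lesion → observer), so
  cohorts are byte-identical under a fixed seed and per-lesion draws do not
  shift when group sizes change.

What the generator does *not* emulate: CT noise, partial-volume and
contrast-enhancement physics, reader-specific biases beyond symmetric
confusion, and any benign-degree bimodality. Passing tests therefore
demonstrate correctness of the scoring and inference machinery under the
published summary structure, not clinical performance on real CT data; in
particular the published AUC 0.738 and kappa 0.639/0.612 depend on the
unpublished per-patient values and are not reproduction targets.

## Vessel phantoms

Phantoms realise the measurement geometry with known truth: a straight
centerline through a spherical lesion, a linear diameter taper, and a
Gaussian stenotic dip (σ = lesion radius / 3) whose floor encodes the true
degree against the taper baseline; depth 100% drives the minimum diameter
below a 0.25 mm visibility floor, i.e. amputation. `measure_phantom`
re-derives everything from geometry alone: it fits the taper baseline to
the vessel far from the lesion (beyond 1.3 radii, where the dip is
negligible), calls "normal" any diameter within 5% of that baseline, and
reads off CD, AB, EF, EC, EA and the bifurcation bookkeeping. With two
bifurcations straddling the narrowest point (type D), the interpolated
reference cancels the taper and the scoring recovers the constructed truth
within 2 percentage points across a 10–90% depth × 0–0.05 mm/mm taper grid
(tested); with a purely proximal reference the taper would bias the degree,
which is the failure mode the type-D formula exists to fix.

## Fixtures and reconstructions

The published summary tables ship as CSV fixtures. Two printings of the
relationship table disagree in the benign observer columns; both variants
ship and neither is "corrected". Similarly, kappa is printed as 0.639 in one
place and 0.612 in another with an identical CI; the package takes no side —
both grade "substantial". Where per-lesion inputs are needed (contingency
construction, the 44.4% operating point), the package builds *synthetic
reconstructions* exactly consistent with the published margins: the
dual-relationship split (13 encasement+displacement, 2
encasement+penetration) and the filler degrees on the correct side of the
cutoff are deterministic choices among the many assignments with identical
margins, and are labelled synthetic in code.

## Problem sizes

Test and acceptance runs use: 5000 draws for mixture-mean checks (≈3
standard errors ≈ 0.8 points for the malignant group), 4000 lesions per
group for frequency checks (3 binomial SE), 8000 lesions for kappa
calibration (±0.05), 27 phantoms for the recovery grid, and 1000 random
instances for the AUC/Mann–Whitney equivalence. These sizes make the
stochastic tolerances tight while keeping the whole suite fast on one CPU.
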