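# Methods

## Study design implemented

The package implements a multiple-choice perceptual study on 3D spatial
connectivity. A cylindrical chain is divided into `n_segments` (default
8) alternately shaded segments, exactly one pair of which forms a spatial
contact. The admissible contact family is every pair with sequence
separation at least `min_separation` (default 3), which on 8 segments
yields 15 contacts. Each question offers `n_options` (default 5) answers:
the correct contact, the *inverted answer* when it exists, and random
distractors drawn without replacement from the same family. The inverted
answer is the contact read in the opposite chain direction (`i → n+1−i`,
re-sorted ascending); a contact whose endpoints satisfy `a + b = n + 1`
is self-symmetric and has none — on 8 segments these are 3–6, 2–7 and
1–8. Every question is duplicated (repeat fraction 1.0), question order,
duplicate placement and option slots are independently randomized per
participant, and all three layout arms receive the same question bank —
only the rendering differs.

Distractors are drawn from the enumerated family (separation ≥
`min_separation`) rather than from all pairs: distractors outside the
stimulus family would be visually implausible answers for stimuli that
never show short-separation contacts. The scoring functions nevertheless
accept arbitrary contacts (the worked example 1–3 vs 2–5 has separation
2), so response tables from studies with a wider answer pool analyze
fine.

## Layout geometry

All three encodings live on the unit square and are rendered as
deterministic SVG (no timestamps; identical geometry gives identical
bytes). Conventions the underlying visual language leaves open were fixed
as follows: the circular layout places segment 1 at the top and proceeds
clockwise, with the contact drawn as a straight chord between arc
midpoints; the half-matrix is the upper triangle rotated 45° onto a
horizontal shaded base row; matrix and half-matrix diagonals alternate
light/dark starting light at segment 1. Only category-level fills
(light gray, dark gray, contact green) are contracted; exact colors and
stroke widths are cosmetic constants.

## Behavioral model of the synthetic respondents

Each simulated participant answers per the mixture:

1. With probability `memory` (ρ), a duplicated question receives the
   participant's earlier answer verbatim. Answer memory is explicit
   rather than emergent because layout differences in duplicate
   consistency cannot be expressed by accuracy alone.
2. A fresh answer is correct with the question's success probability.
3. An error goes to the inverted answer with probability
   `p_invert_given_error` when one exists; otherwise to a distractor `d`
   drawn with weight
   `exp(−β·MinDistance(d, correct) − γ·(sep(d) − sep(correct)))`.
   γ > 0 skews errors toward contacts too close in sequence (the
   negative inter-segment-distance skew real participants show); β > 0
   favors near misses.

Error probability is `(1 − p_correct)`, scaled on self-symmetric
questions by `symmetric_error_scale` (default 1). The scale exists
because a participant who misreads the chain direction still lands on
the correct answer when the contact is symmetric, so symmetric questions
are genuinely easier; mechanically, with a uniform error rate the
expected inversion share of errors is capped at 12/15 = 80%, below the
~85% circular-layout shares real cohorts reach.
`calibrate_inversion_probability` inverts the closed form
`share = n_inv · p / (n_inv + n_sym · s)` so cohorts can be parameterized
directly by a target inversion share; the presets use `s = 0.5`.

Response time at presentation `k` is
`(plateau + amplitude · e^{−λ(k−1)}) · e^{σZ}` with standard-normal `Z`:
an exponential decay to a plateau (learning) with multiplicative
lognormal noise, keeping times positive and right-skewed. No
quantitative response-time model exists for this task; the decay form
reproduces the qualitative decay-to-plateau learning curves and is
validated only at that level. `simulate_study` can inject a single
`rt_outlier` (e.g. 5001 s) to exercise the slow-response filter.

### Preset cohorts

The `mturk` preset (50 participants × 3 layouts, 4,500 responses) and
`expert` preset (10 × 3, 900 responses) encode per-layout profiles with
the qualitative structure such studies report: for crowdworkers the
circular layout is the most accurate (p_correct 0.93 vs 0.82/0.80), most
consistent (ρ 0.75 vs 0.55/0.68), fastest (plateau 6 s vs 9/9.5 s,
near-flat learning curve, λ 0.5 vs 0.12) and nearly all its errors are
inversions (target share 0.845 vs 0.566/0.605); experts are more
accurate throughout, equally consistent across layouts, and fastest on
the matrix despite being least accurate with it. These values are
package defaults chosen once to emulate that structure; they are
recovered, not asserted, by the parameter-recovery tests.

What the simulator does *not* model: qualification-test attrition,
participant-level heterogeneity beyond the shared cohort profile,
within-survey fatigue, option-position biases, and any dependence of
accuracy on the specific contact beyond the symmetric/invertible split.
Passing tests therefore show that the pipeline recovers known generating
parameters and is calibrated under a true null — not that real cohorts
behave like the generator.

## Analysis pipeline

Order of operations: (1) remove responses slower than `rt_cutoff`
(default 5000 s, logged individually); (2) score duplicate consistency
per participant; (3) exclude participants at or below
`consistency_threshold` (default 0.20, the five-option uniform-guessing
baseline; the bound is inclusive) and drop all their responses; (4) run
the battery on the retained data. Consistency is exact-match agreement
on duplicate pairs — the natural reading of a replicated-question
consistency score.

Test families: consistency and response times use one-way ANOVA with
Tukey HSD (Tukey p-values are family-wise adjusted by construction and
are reported as both raw and adjusted); accuracy uses pairwise Pearson
chi-squared without continuity correction (cell counts far exceed 5 in
the designed cohort sizes); the inter-segment distance distribution
(errors only) and the MinDistance distribution (all answers) use a
tie-corrected Kruskal–Wallis omnibus with Dunn pairwise z tests.
Pairwise p-value families are adjusted with Benjamini–Hochberg by
default (`holm` and `bonferroni` are available), α = 0.05.

**First-presentation rule.** Duplicated questions exist to measure
consistency and learning. Because a participant frequently repeats an
earlier answer verbatim, the two answers of a pair are strongly
correlated; pooling all 30 presentations into tests that assume
independent responses overcounts evidence (in null simulations the
MinDistance Kruskal–Wallis rejected at ~4× the nominal rate). The
accuracy and score-distribution analyses therefore use each question's
first presentation only. Response-time comparisons keep all
presentations: their noise is independent across presentations and the
learning-curve analysis needs both occurrences.

Learning curves average the two response times of each duplicate pair
and place the pair at the rank of its earlier presentation index — the
closest monotone analogue of "question 1 through 15" when duplicates are
scattered through the survey; the layout comparison on the curves is an
ANOVA + Tukey on the pair-averaged times.

Degenerate inputs are defined rather than crashed on: all-identical
values give statistic 0 and p = 1 in ANOVA and Kruskal–Wallis; a 2×2
table with a zero margin is reported as not-applicable (NaN, never
significant); a cohort with zero errors reports empty fractions with
n = 0.

## Numerical conventions

- Contacts are 1-based and stored ascending everywhere; the inverted
  term of MinDistance re-sorts after inversion, which makes the fixed
  first-with-first endpoint pairing optimal (asserted exhaustively
  against a brute-force pairing/inversion minimizer in the tests).
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (bank → cohorts → participants),
  so tables are bit-reproducible and participant streams independent.
- Simulation scale in the test suite: cohorts of 6–50 participants and
  40 null replicates for the type-I calibration, sizes at which the
  Monte-Carlo bounds used by the tests (3 standard errors) are
  informative while the whole suite stays interactive.

## Known limitations

- The generator's cohort profiles are point parameterizations, not fits
  to human data; analyses of real response tables should treat the
  presets only as power-analysis stand-ins.
- Dunn's test uses the normal approximation; at very small group sizes
  (< ~5 per group) its p-values are approximate.
- The first-presentation rule is possible only because the response
  schema records `is_repeat`; exports that cannot distinguish
  occurrences would need the pooled (anticonservative) analysis.
- Contact strength is not encoded: the design is one unweighted contact
  per model, and heat-map/arc-thickness strength encodings are out of
  scope.
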