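# Methods

## Model

An assessment is a vague fuzzy number ã = (t, 1−f): t ∈ [0, 1] is the
truth-membership, f the false-membership, and consistency demands
t + f ≤ 1, i.e. the pair is a sub-interval [t, 1−f] of the unit line.
The representation stores exactly (t, 1−f) — the pair the assessment
tables print — rather than the equivalent intuitionistic (μ, v) pair, to
remove a sign-flip bug class when loading tabulated data.

Defuzzification uses the score S(ã) = t − f ∈ [−1, 1]; ties are resolved by
the accuracy t + f ∈ [0, 1] (the Xu–Yager convention: of two equally-scored
assessments the more committed one ranks higher). `score` is implemented
literally as `t - (1 - one_minus_f)` so that the identity against that
expression is bitwise exact. Comparisons use an absolute tolerance of
1e−12 on score and accuracy; ordered aggregation additionally breaks exact
ties by original input position (stable sort), which makes results
deterministic across platforms. With symmetric ordered weights the
operators are insensitive to the tie convention: permuting tied elements
does not change the product.

## Aggregation operators

All three operators are geometric (products of powers), so a zero
component anywhere with positive weight annihilates that component — a
deliberate property of geometric consensus: a single total veto (t = 0)
cannot be outvoted. The convention 0⁰ = 1 makes a zero-weight assessment
vacuous instead of annihilating.

- IFWG(ω; ã₁…ãₙ) = (∏ t_j^{ω_j}, ∏ (1−f_j)^{ω_j}).
- IFOWG(w; …) sorts the values by decreasing (score, accuracy) before
  applying w positionally.
- IFHG(ω, w; …) forms ã̇_j = ã_j^{n ω_j}, sorts the ã̇ by decreasing
  (score, accuracy), and applies the *same* ordered weight w_j to both
  components at each sorted position. Some statements of the hybrid
  operator show mixed exponents (w on one component, ω on the other); that
  form does not preserve t ≤ 1−f and does not reproduce the reference
  tables, so the common-exponent form is used.

Closure holds for all three: identical exponents on both components of
each factor preserve t ≤ 1−f. IFWG is idempotent and bounded by the
componentwise extremes. IFHG is idempotent only when the importance
weights are uniform (every exponent n ω_j is then exactly 1); with
non-uniform ω even unanimous inputs are sharpened or flattened, because
the exponents at the sorted positions sum to n Σ ω_σ(j) w_j ≠ 1 in
general. The uniform-ω case reduces IFHG to IFOWG exactly, and is asserted
to 1e−12 in the tests.

Ordered position weights use the normal-distribution method: for n
positions, μₙ = (1+n)/2, σₙ² = (1/n) Σᵢ (i−μₙ)² (population form, the
canonical statement), w_j ∝ exp(−(j−μₙ)²/2σₙ²), normalized. The vector is
symmetric and unimodal, discounting the most extreme opinions; symmetry is
enforced exactly by averaging the vector with its reversal before the
final normalization.

## Pipeline

- **Expert weighting** aggregates, per expert, the n−1 assessments
  *received* (the peer matrix column, in row order) with IFOWG under
  normal ordered weights for n−1. Aggregating received opinions (not
  issued ones) is what "the group's view of this expert" means; the
  row-wise alternative also reproduces the reference values worse.
- **Criteria weighting** and the **collective matrix** use IFHG with the
  expert weights as importance weights, so a heavyweight expert both
  sharpens their own assessments and keeps their position in the ordered
  discount.
- **Patient aggregation** applies IFWG across criteria with the *criteria*
  weight vector, positionally. Dimensional analysis forces this choice:
  each patient column holds one value per criterion.
- **Normalization** of scores into weights is plain s/Σs and requires all
  scores strictly positive, because scores live in [−1, 1] and silently
  normalizing mixed signs would invert priorities. An explicit opt-in
  shift mode translates by x → x − min(x) + δ, δ = (max−min)/100 (δ = 1 if
  all equal), and the result records that the shift was applied. δ keeps
  the worst performer at a small positive weight instead of exactly zero.

Problems may carry `fixed_expert_weights` / `fixed_criteria_weights`;
`use_fixed_weights=True` substitutes them for the derived vectors while
still reporting the derived aggregates and scores for audit. This supports
reproducing published end-results whose intermediate weighting tables
contain printing errata (see below), and more generally running a problem
under externally imposed weights.

## Bundled case study and its errata

The bundled five-expert, five-criterion, five-patient case study
(`data/case_study.json`) stores the raw assessment tables together with
the published 2-decimal expert and criteria weight vectors as fixed
weights. Under those weights the pipeline reproduces the published
collective matrix and patient aggregates to within 1.5e−3 (3-decimal
printing) and the exact ranking P5 > P4 > P3 > P2 > P1.

The published intermediate weighting tables are only partially
self-consistent: of the five printed expert aggregates only E4's
(0.84, 0.98) is reproducible from the peer assessments under any ordering
convention tried, and four of the five printed criterion aggregates
violate t + f ≤ 1 outright (e.g. (0.71, 0.56)), so they cannot be the
output of a closure-preserving operator. The score→weight normalizations
downstream of those tables are internally consistent as printed. The
implementation does not emulate the inconsistent values: a
fixture-documentation test pins the discrepancies, lenient construction
(`VagueNumber(..., lenient=True)`) exists solely so such values can be
represented and flagged, and the fixed-weight path carries the published
normalization outputs into the hierarchy block.

## Synthetic problems

`generate_problem(GeneratorConfig(...))` draws every cell on a grid of
step 0.1 by default — matching the one-decimal elicitation of the case
study — by first drawing 1−f uniformly on the grid points of [0, 1] and
then t uniformly on the grid points of [0, 1−f], so validity holds by
construction. All randomness flows through one seeded
`numpy.random.Generator`; equal configs give byte-identical problems. The
generator emulates the *structure* of elicited data (shapes, grid,
validity), not its statistics: real expert panels produce correlated,
optimism-biased, mostly-positive-score assessments, while the generator's
cells are independent with median score well below the case study's.
Passing tests on generated problems therefore demonstrate algorithmic
correctness and invariance properties, not clinical validity. Generated
problems routinely contain non-positive aggregate scores, which is why the
pipeline's strict-positivity guard matters and the property tests opt into
shift mode.

Problem sizes used in the test suite are desk-scale throughout (n ≤ 8
values per aggregation, 100 seeded 5×4×5 problems for ranking-recovery,
ordered-weight checks up to n = 10⁴); the full case study runs in well
under a second.

## Known limitations

- Geometric aggregation is annihilating at t = 0; panels that use 0 as an
  ordinary scale point will zero out patients. Elicitation should reserve
  t = 0 for genuine vetoes.
- Strict-mode weighting fails (by design) when a fused score is ≤ 0; the
  shift mode is a pragmatic, not principled, repair — the resulting
  weights depend on the translation δ.
- Scores compare cardinally after normalization although the underlying
  elicitation is ordinal-ish; no robustness analysis of the ranking to
  assessment perturbations is provided.
- The final admission decision, re-evaluation scheduling and the clinical
  content of the criteria are out of scope: the package computes the
  recommendation and its audit trail only.
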