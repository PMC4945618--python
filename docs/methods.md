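# Methods

## The elicitation and aggregation model

The package operationalizes a four-stage pipeline for interval-valued
expert judgement on a bounded likelihood scale.

**Elicited intervals.** An expert's response to an item is a quadruple
(low, best, high, confidence) with 0 ≤ low ≤ best ≤ high ≤ 1 and
confidence ∈ [0.5, 1.0]. The confidence is the expert's own probability
that the true value lies inside [low, high]; the protocol floor of 50%
reflects that an expert should not be less sure than a coin toss about
their own interval.

**Derived confidence intervals.** Because experts state different
confidences, raw intervals are not comparable. Each side of the
interval is linearly rescaled about the best estimate by the factor
*target / confidence*:

    low'  = best − (best − low)  · target/confidence
    high' = best + (high − best) · target/confidence

The target coverage defaults to 0.80 and is configurable. The scaling
uses all three elicited points and treats the two sides independently,
so asymmetric intervals stay asymmetric. When confidence equals the
target, the elicited endpoints are returned verbatim (the scale factor
is exactly one; recomputing them through the formula would not be
bit-exact in floating point). Results outside [0, 1] are clipped —
the likelihood scale is physically bounded — and each clip event is
logged at INFO level. Whether clipping or some other truncation best
matches practice is an open modelling question; clipping is the
package's documented choice. A degenerate zero-width response is legal
and derives to a zero-width interval.

**Calibration.** Each expert answers known-answer questions; the score
per question is the proportion of the expert's derived CI that overlaps
the correct-answer interval, |CI ∩ truth| / |CI| (closed intervals),
and the weight is the arithmetic mean of the scores. Two degenerate
cases are scored by membership: a zero-width expert CI scores 1 exactly
when the point lies in the truth interval, and a zero-width (point)
truth scores 1 exactly when it lies in the expert CI. Note the
denominator is the *expert's* width, not the truth's: an interval
wholly inside the truth scores 1 however narrow it is. This convention
rewards informative answers that land inside the accepted range; it is
deliberate and is not "corrected". A consequence, verified both
analytically and by simulation, is that with positive-width truths and
unbiased experts the expected score is weakly *higher* for narrower
intervals, so interval-valued truths do not penalize overconfidence.
Point truths do: an honest expert's derived CI contains the answer at
roughly its nominal coverage, while an overconfident expert's
too-narrow CI misses more often. Weights are absolute (a perfectly
calibrated expert weighs 1); they are never re-normalized across the
panel.

**Interval agreement aggregation.** The agreement function is the sum
of the experts' interval indicator functions, each scaled by the
expert's weight. It is represented exactly: the breakpoints are the
union of all interval endpoints, each open piece between consecutive
breakpoints carries the summed weight of the intervals covering it, and
each breakpoint carries its own level under the closed-endpoint
convention (both endpoints of every interval are included, so two
abutting intervals agree at their shared point only). The closed
convention means the level at a breakpoint is never below the level of
an adjacent piece, so the global maximum is always attained at a
breakpoint — a fact the extraction statistics rely on. Grids are used
only in test oracles and plots, never in the canonical representation.
Only the basic (type-1) construction is implemented; higher-order
fuzzy generalizations are out of scope.

**Crisp extraction.** Three statistics summarize an agreement function:
min-max and max-max (smallest/largest likelihood attaining the global
maximum, found by scanning breakpoint levels with a relative tolerance
of 1e-9 for plateau membership) and the centroid
(∫x·A(x)dx / ∫A(x)dx, integrated exactly piece by piece; point levels
have measure zero and do not contribute). A maximum attained only at an
isolated breakpoint gives min-max = max-max = that point. The headline
statistic defaults to min-max — the conservative choice, reporting the
lowest likelihood at which agreement peaks — and is configurable to
max-max or centroid. An identically-zero function (all weights zero)
has no statistics and raises; a zero-area function with point masses
(all zero-width intervals) supports min-max/max-max but not the
centroid.

**Screening and ranking.** The factor × element cross-product is
enumerated in full; the preliminary screening that removes combinations
judged to have at most a 5% chance of causing target failure is a group
judgement supplied as an input mask, which the package validates and
bookkeeps (retained and screened-out sets always partition the
cross-product). A factor's affected-element count is the number of
retained pairs whose headline statistic strictly exceeds the threshold
(default 0.05, matching the screening level so sub-threshold results
are treated like screened-out pairs). Ranking sorts by count
descending, then by the factor's maximum headline likelihood
descending, then by name; the tie-break beyond the count is this
package's own convention. The report labels which estimate variant
(raw / ci / calibrated) produced it.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `target_level` | 0.80 | nominal coverage of derived CIs (dimensionless proportion); 0.8 eases comparison across studies but any level in (0, 1] is accepted |
| `variant` | `calibrated` | `raw` (elicited endpoints, unit weight), `ci` (derived endpoints, unit weight) or `calibrated` (derived endpoints, calibration weights); computing all three and comparing is informative |
| `headline_statistic` | `min_max` | which crisp statistic drives screening counts and rankings |
| `headline_threshold` | 0.05 | likelihood above which a pair counts as "affected"; equals the screening level |
| `missing` (calibration) | `error` | an expert missing a calibration answer is a hard error; `ignore` averages over answered questions |

## The synthetic panel generator

The generator exists so that every stage is testable without any
workshop data; its distributional choices are fixture conventions, not
claims about real experts.

*Behavioural panels* (`generate_panel`): each of n experts (default 10,
the protocol's panel size) holds a normal belief N(true_value + bias,
spread) about the latent likelihood; the best estimate is one draw from
it, clipped to [0, 1]. A stated confidence is drawn uniformly on
[0.5, 1.0] — the protocol's allowed range — and the interval half-width
is spread · z((1 + coverage)/2), where coverage equals the stated
confidence for honest experts and sits 0.3 below (above) it for
overconfident (underconfident) ones. Coverage is capped at 0.995 when
computing the quantile, since a coverage of exactly 1 has no finite
normal quantile. Default spread is 0.1, a moderately informative panel
on a 0–1 scale. All draws flow from a single seed.

*Constructed truth sets* (`generate_truth_set`): calibration responses
are built backwards from prescribed overlap fractions, with every
endpoint and overlap snapped to multiples of 1/64. Binary-fraction
arithmetic keeps each construction step exact in IEEE floating point,
and the expected weight is computed with the same summation order the
calibration code uses, so weight-recovery tests can assert bit-exact
equality rather than approximate closeness. Stated confidence equals
the target level, making CI derivation the identity.

*Behavioural calibration exercises*
(`generate_calibration_exercise`): latent true answers are drawn per
question and panels respond behaviourally. Truths default to points
(zero width) — the natural encoding for factual questions whose answer
is a single value, and, per the scoring analysis above, the regime in
which calibration actually discriminates overconfidence. The
`truth_width` parameter restores interval truths when wanted.

What passing tests on these fixtures do **not** show: real experts are
not normal, unbiased or independent; anchoring, correlated knowledge
gaps and framing effects are outside the generator. Statistical
assertions (e.g. centroid recovery of the true value) are claims about
the fixture model, not about workshops.

## Problem sizes and numerical choices

The test suite works at the study's natural scale: ten-expert panels, a
23 × 14 factor–element matrix for bookkeeping checks, panels of at most
12 intervals for the brute-force grid oracle (10⁻³ grid), 200-seed
Monte-Carlo for centroid recovery and 100-seed comparisons for the
calibration behaviour contrast — sizes at which the whole suite runs in
well under a minute. Area conservation (∫A = Σ wᵢ·|Iᵢ|) is asserted to
10⁻¹² absolute; plateau detection uses a 10⁻⁹ relative tolerance;
centroid cross-checks against trapezoidal quadrature on a 10⁻⁴ grid are
asserted to 10⁻³ on representative panels (panels of near-zero area are
excluded: the quadrature comparison is dominated by discretization
noise there, not by the statistic).

## Known limitations

- The extrapolation formula is one reading of "simple linear
  extrapolation" from three elicited points; other readings (e.g.
  normal-quantile scaling) would give different derived widths for
  asymmetric intervals.
- The overlap-proportion calibration score rewards narrow intervals
  inside the truth; with interval-valued truths it cannot penalize
  overconfidence in expectation (see above).
- Interactions among risk factors are not modelled; each factor ×
  element pair is aggregated independently.
- The screening mask is taken on faith from the group judgement; the
  package checks its bookkeeping, not its substance.
- Item identifiers join factor and element with `|`, so identifiers
  containing that character cannot be used in the risk-matrix pipeline.
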