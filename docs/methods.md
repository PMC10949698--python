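# Methods

## Task protocol and scoring

The engine reproduces a five-level café serving task. Level *L*'s
memory load is the number of ordered items: 2, 4, 6, 8 and 16, with
levels 1–4 food-only and level 5 giving each of eight customers one
food and one drink. Customers occupy `min(4, ceil(orders/2))` tables of
two seats, filled in order: one table at level 1, up to four tables of
two at levels 4–5, consistent with a four-table café at the top of the
ladder. Each level runs through a fixed phase order — presentation,
immediate recall, distraction, delayed recall, counter selection,
service — enforced by the state machine; out-of-order submissions are
errors, not warnings, so recorded logs are structurally valid by
construction.

Scoring is one point per ordered item per metric, five metrics per
item (immediate, delayed, recognition, table, customer), giving level
maxima 10/20/30/40/80, per-metric subdomain totals of 36, a combined
serving subdomain of 72, and a 0–180 grand total. Claims are matched by
item-id set intersection: duplicates collapse, wrong claims earn
nothing, and nothing is ever negative. Phases with no submitted
response score zero ("no attempt").

Two genuinely open design points and how they were resolved:

- **Four metrics vs five point columns.** The discontinuation rule
  speaks of four metrics while the score sheet has five columns (table
  and customer are separate). We score the five columns independently —
  a customer point needs only the correct seat index, a table point
  only the correct table — but compute the *serving accuracy* used by
  the discontinuation rule conjunctively: an item counts only when both
  table and customer are right. Reports expose the combined spatial
  subdomain (table + customer, max 72) alongside the raw columns.
- **Discontinuation strictness.** The rule fires only when all four
  accuracies are *strictly* below the threshold (default 0.5); a level
  at exactly 50 % on every metric continues. This makes the rule
  monotone: improving any single response can never turn a continue
  into a discontinue.

The distraction interlude is an unscored timed phase; its duration is a
level-config constant (default 120 s) and the simulated clock advances
by exactly that amount. Other simulated phase durations (presentation
10 s per table, 30 s per recall/counter/service phase) are plausible
placeholders: timing is recorded in the event log and reported in
minutes but never scored. Interactive play uses a wall clock and emits
format-identical logs.

## Menu and counter lineups

The packaged menu carries 31 foods and 9 beverages. Three items are
counter-only fillers (smoothie bowl; smoked salmon and poached egg on
toast; cranberry juice); the handful of publicly named items appear
under their own names and the remaining entries are invented but
plausible café dishes — the testable claims attach to the counts and
filler behaviour, not the identities. Each level's counter lineup is
the ordered items plus four distractors drawn fillers-first (so all
three fillers always appear) and then from unused menu items, shuffled.
Optional per-item recognition metadata is carried as documentation only
and never influences sampling or scoring. Orders within a level are
distinct items, which keeps recognition and per-item credit
unambiguous.

## Respondent model

The simulator's memory model is invented for pipeline exercise; no
parameter is an empirical estimate. Per ordered item at load *k*:

| stage | rule | parameter (default) |
| --- | --- | --- |
| encoding | `p_imm = clip(θ·exp(−λ·max(0, k−2)), 0, 1)` | θ ability; λ load penalty per extra item (0.03) |
| immediate recall | claim iff encoded | — |
| delayed recall | encoded ∧ Bern(ρ) | ρ retention (0.88) |
| recognition | delayed ∨ Bern(γ·p_imm) | γ recognition boost (0.70) |
| serving | correct seat with prob. β, else uniform wrong seat | β binding fidelity (0.82) |

Each scored phase is attempted with probability
`attempt_probability` (default 1). All Bernoulli draws come from a
pre-laid uniform grid whose shape depends only on the script — four
attempt uniforms plus five uniforms per item per level — never on the
parameters. Two consequences hold pathwise, not just in expectation:
recognition picks are a superset of delayed recalls (recognition
superiority, mirroring the empirical pattern that cued recognition is
the least age-sensitive metric), and under common random numbers
raising θ never lowers any score component, because every threshold
comparison moves one way.

Cohort presets encode direction only: the younger group draws
θ ~ N(0.80, 0.08) with λ ~ N(0.02, 0.01); the older group
θ ~ N(0.62, 0.12) with λ ~ N(0.05, 0.02) (all draws clipped to legal
ranges; group sizes default to 56 and 75). The reference-screener link
is `screener = clip(round(μ₀ + μ₁·θ + N(0, σ)), 0, 39)` with
μ₀ = 18, μ₁ = 18, σ = 3, spanning plausible screener totals with a
moderate module–screener correlation. These are tunable presets, not
estimates — the real cohort's magnitudes (means, SDs, the published
correlation) depend on the human sample and are deliberately not
targeted; tests assert directions (younger > older, positive
module–screener association) and recovery properties (rank correlation
between true θ and grand total above 0.5 in a 200-agent cohort, a
significantly positive regression slope), nothing more. Per-agent
streams derive from a seed sequence keyed on (master seed, agent
index), so results are reproducible and independent of iteration
order. Passing these tests shows the pipeline is coherent end to end;
it says nothing about how real respondents distribute.

## Reference screener

The screener is a 23-item, 39-point instrument with an impairment
cutoff of ≤ 21 covering orientation, attention/working memory,
language, and immediate plus delayed recall of a 10-word list. The
published description fixes those anchors but not the per-item point
split, so the default form uses a documented stand-in allocation — 10
orientation × 1, attention 2 + 5 + 1, language 2 + 1 + 1 + 1, five
2-point word-pair items (the 10-word list), one 6-point delayed-recall
item — and any JSON form satisfying the same invariants can replace
it. Scoring consumes already-marked per-item points; administration is
out of scope.

## Statistics

Group comparisons use Welch's *t* (safer than Student's with unequal
group sizes such as 56 vs 75); categorical comparisons use Fisher's
exact test with the small-p two-sided convention (sum of all
margin-consistent table probabilities ≤ the observed one);
associations use Pearson's *r* with the *t*-transform p-value on n − 2
degrees of freedom; agreement uses Cohen's κ with half-open-upward
bands (κ = 0.8 is already "almost perfect"). Computation is delegated
to scipy and scikit-learn; the test suite checks every routine against
independent oracles — exhaustive hypergeometric enumeration for all
2×2 tables with margins ≤ 12, and direct closed-form evaluation of the
*r* and Welch formulas to 1e-10. Degenerate inputs are policy, not
crashes: two constant groups with equal means give t = 0, p = 1, with
different means a signed infinite statistic and p = 0; perfect
agreement with a single shared label defines κ = 1; zero-variance
correlations raise a degenerate-input error that the cohort report
catches and prints as "not computed". No multiple-testing correction
is applied; reports state how many tests were run.

## Problem sizes and determinism

Default verification runs use a 200-agent cohort (100 + 100, fixed
master seed), which separates the direction properties cleanly while
keeping the whole suite fast; a full five-level session is ~36 scored
items, so even the exhaustive scoring-oracle sweeps (all 2^k patterns
per metric at k ≤ 4) are cheap. All randomness everywhere flows
through numpy `default_rng` / `SeedSequence` from a single seed, and
file outputs support `--no-timestamp` for byte-identical reruns.

## Known limitations

- The respondent model has no learning, fatigue, speed–accuracy
  trade-off, or intrusion errors (it never claims un-ordered items or
  picks fillers), so specificity-style analyses of recognition are
  degenerate.
- The simulated clock is schematic; total-minutes summaries of
  simulated cohorts reflect configuration, not behaviour.
- Whether the original task re-samples counter distractors per level,
  and how the real instrument splits its points across items, are
  unknowable from public descriptions; both are configurable here and
  the defaults are documented stand-ins.
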