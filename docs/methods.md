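# Methods

## The model

The two-high-threshold source-monitoring model (2HTSM) is a multinomial
processing tree over the 3×3 contingency table of a source-monitoring test.
Each of the three item classes (old items from Source A, old items from
Source B, new items) heads a processing tree whose branches are sequences of
Bernoulli states, and each category probability is the sum of its branch
products. The branch table lives in `sourcemem.core.BRANCHES`; for Source-A
items,

```
P(respA) = D·d_A + D·(1−d_A)·g + (1−D)·b·g
P(respB) = D·(1−d_A)·(1−g) + (1−D)·b·(1−g)
P(respNew) = (1−D)·(1−b)
```

with the Source-B tree symmetric (`d_B`; source guessing g toward A, 1−g
toward B) and the new-item tree detecting newness with the same `D`. The
single `D` per tree set is the standard identifiability restriction
`D_A = D_B = D_New`; an unrestricted three-`D` variant is expressible only by
overriding the constraint map, which is deliberate — the analyses this
package implements all use the restricted model.

Because no parameter appears twice on a branch, every category probability
is multilinear in the parameters. The fitting machinery exploits this:
gradients and the observed information matrix are exact closed forms of the
branch representation (`CompiledModel.loglik_and_grad`,
`.observed_information`), with `∂²p/∂θ²_s = 0` on the diagonal and mixed
second derivatives given by pairwise edge factors.

## Estimation

A model (`ModelSpec`) is a set of condition-labelled tree sets plus a map
from each (condition, parameter) slot to a shared free symbol, optionally
with symbols fixed to constants. The joint multinomial log-likelihood over
all tables is maximized by bounded (projected) L-BFGS-B on the probability
scale with analytic gradients, bounds [1e−8, 1−1e−8], and a log-likelihood
tolerance of 1e−13 per restart. Ten seeded restarts are the default (first
start at 0.5 everywhere, the rest uniform on [0.05, 0.95]); ties are broken
by highest log-likelihood, then lowest restart index, making `fit`
deterministic given (data, spec, seed). Fits that only matter through their
likelihood (recovery and calibration simulations) use fewer restarts — the
likelihood is well behaved at these sample sizes, and the suite verifies the
optimum against a brute-force grid.

Fit statistics: `G² = 2(logL_saturated − logL_model)` with the 0·ln 0 := 0
convention (equivalently the cellwise deviance), `df = 6·(tree sets) − (free
symbols)` since each 3-row table contributes 3×(3−1) independent categories,
`p` from the central χ² upper tail, and `w = √(G²/N)` with N the total
number of test responses (participants × test trials — every reported
(ΔG², w) pair is consistent with this N).

Confidence intervals are Wald on the probability scale: estimate ±1.96·SE
from the inverse observed information over free symbols, clipped to [0, 1].
This is an assumption — the reference GUI tool's CI method is not documented
— and is flagged as such rather than tuned to match anything. Estimates
within 1e−6 of a bound are flagged `boundary_symbols` and snap the adjacent
interval endpoint to the bound; a singular information matrix yields
deliberately wide intervals and a `singular_information` flag instead of an
exception.

Nested comparisons (`compare`) require the nested spec to be a refinement
(merge/fix only) of the full spec on the same data. Small negative ΔG² (to
−1e−4) from finite optimizer tolerance is clipped to zero with a warning;
anything more negative raises, since it indicates a failed fit. Significance
is .05 throughout the model-based tests; the Bonferroni-corrected .025 level
applies only to the two ANOVA simple-effect follow-ups.

## The analysis plan

`run_expectancy_analysis` executes, in order: (1) the base model (one D,
d_A, d_B, b, g per tree set; df 4 for four sets); (2) D equated across item
types within group (Δdf 2) and (3) across groups within item type (Δdf 2),
both against the base model; (4) the expectancy-equated base model — within
each group one `d_expected` shared across item types and one `d_unexpected`
(df 8) — which then serves as the reference for (5) `d_expected =
d_unexpected` within each group (Δdf 1 each), (6) both d symbols equated
across groups (Δdf 2), and (7) g equated across item types within each group
(Δdf 1 each). Expected pairings are kitchen-item-in-kitchen /
bathroom-item-in-bathroom in the rooms design and trustworthy-cooperate /
untrustworthy-cheat in the faces design; Source A is the kitchen and
cheating, respectively. Steps (2)–(3) are referenced to the first base model
(the Results-order reading of the plan), a documented choice.

## Power

`sensitivity_w` inverts the noncentral-χ² power function: the critical value
is the central χ² 1−α quantile, and λ\* solves P(χ²_nc(df, λ\*) > crit) =
power by Brent root bracketing on the survival function (monotone in λ;
tolerance 1e−8), giving w\* = √(λ\*/N). The df entering a sensitivity
analysis of a model-comparison test is a reporting choice, and the two
experiments' quoted minimal w values are not consistent with any single df;
the package therefore exposes `sensitivity_sweep` over df rather than
asserting one value.

## The synthetic generator

`generate` emulates both designs at trial level. Rooms design: three
counterbalanced lists of 16 bathroom + 16 kitchen items rotate through the
roles kitchen-source / bathroom-source / distractor with participant index,
so across any three consecutive participants each list serves each role
once; 64 study trials (32 expected, 32 unexpected pairings) plus two flagged
buffer trials, and 96 test trials. Faces design: 20 trustworthy and 20
untrustworthy partners, half of each cheating, with investments (15/30
cents), payoffs (±5/±10), two flagged practice trials, 40 new faces at test,
and 1–6 likability ratings from a simple two-mean model. Participants
alternate between the without- and with-judgments groups. Test responses are
multinomial draws from the category probabilities of each item's condition;
buffer/practice rows are generated for schema fidelity and excluded from
aggregation.

Judgments (0–100) follow an additive Gaussian model: grand mean +
participant effect (SD 12) + expectancy effect + residual (SD 16), clipped
to the scale. Defaults: grand mean 55, +5 points for expected pairings in
judgments of item learning, +8 in judgments of source learning and post-test
judgments (the latter in the with-judgments group only), and a configurable
behavior main effect for post-test judgments and the vignette-based beliefs
generator. The true per-cell judgment means of the motivating experiments
exist only as figures, so these values are declared synthetic — chosen to
produce effect sizes of the order seen in such studies — and are never
presented as estimates.

The default memory parameters (`default_theta`) encode the qualitative
structure the analyses target: better item memory with judgments (D 0.55 vs
0.72 in the rooms design; 0.48–0.64 in the faces design), an
expectancy-violation advantage in source memory present only without
judgments (d 0.20/0.35 vs 0.35/0.35; 0.15/0.35 vs 0.30/0.35), and a
schematic guessing bias (g ≈ 0.37–0.40 toward the atypical room's competitor
vs ≈ 0.60; 0.38–0.45 vs 0.66–0.71 toward cheating for untrustworthy faces),
with b in the 0.22–0.37 range. These are synthetic ground truths, not
estimates. What passing tests show is therefore that the *machinery* —
likelihood, optimizer, df bookkeeping, test calibration, ANOVA algebra — is
correct and that the pipeline detects effects of realistic size; they say
nothing about any real dataset, whose raw frequencies the generator does not
reproduce. Real data also contain participant heterogeneity in the memory
parameters, which the per-condition multinomial generator deliberately omits
(the fitted model is the aggregate-data model, so the recovery study matches
its assumptions).

## ANOVAs

Every judgment factor has two levels, so each within effect is carried by an
exact per-participant contrast score and F = (squared paired t) with
df = (1, n−1); in the mixed design, within effects use the unweighted mean
of group contrast means over the pooled variance (df2 = n1+n2−2, the
Type-III solution), interactions with group are two-sample contrasts, and
the between effect is a two-sample test on participant means. Partial η² is
F/(F+df2) for these 1-df effects. Participants with any missing cell are
listwise-excluded with a reported count. Zero contrast variance yields a
flagged NaN F (or F = 0 when the contrast mean is also zero). No sphericity
correction exists at two levels, by construction.

## Numerical choices and limitations

- Optimizer bounds keep parameters off 0/1 by 1e−8; boundary detection uses
  1e−6. Degenerate inputs (counts all in one cell) drive estimates to the
  bounds and are flagged, not raised.
- `g_squared` returns `inf` (a flag, not an exception) when a positive count
  meets zero model probability; `log_likelihood` returns −inf.
- CSV round trips use `float_precision="round_trip"` so a written trial file
  re-reads to identical bytes.
- CLI exit codes: 0 success, 1 handled input errors, 2 click usage errors
  and internal failures.
- Problem sizes in the test suite and acceptance script: recovery uses 200
  replicates at the faces-experiment scale; ΔG² null calibration uses 600
  (tests) / 400 (script) replicates; ANOVA calibration uses 1500–2000
  simulated datasets. These sizes give binomial/Monte-Carlo error small
  enough for 3-SE checks while keeping a full run to a few minutes.
- Not implemented (out of scope by design): Bayesian/hierarchical or
  latent-trait MPT variants, bootstrap CIs, ROC/signal-detection
  alternatives, AIC/BIC selection, sphericity corrections, and inferential
  modelling of the game-investment/likability columns (emitted for schema
  fidelity only).
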