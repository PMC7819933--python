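# sourcemem

Multinomial-processing-tree modelling of source monitoring, with the
metamemory analyses that accompany it.

Source-monitoring experiments ask whether people remember not only *that*
they encountered an item (item memory) but also the *context* it was paired
with (source memory) — a word studied "in the kitchen" vs. "in the
bathroom", or a face paired with cheating vs. cooperation in an economic
game. Raw source-attribution rates confound memory with guessing, so the
field's standard tool is the **two-high-threshold source-monitoring model
(2HTSM)**, a multinomial processing tree that decomposes the 3×3 table of
response frequencies (Source-A items, Source-B items, new items × responses
"A" / "B" / "new") into discrete states:

- `D` — probability of detecting an old item as old (and, under the standard
  identifiability restriction `D_A = D_B = D_New`, a new item as new);
- `d_A`, `d_B` — conditional probabilities of remembering the source of a
  detected item;
- `b` — probability of guessing "old" for an undetected item;
- `g` — probability of guessing Source A when source memory fails.

For Source-A items, e.g., P(respond "A") = `D·d_A + D·(1−d_A)·g + (1−D)·b·g`.
Models spanning several conditions (tree sets) are fitted jointly by maximum
likelihood under equality constraints; substantive questions (is source
memory better for schema-*unexpected* pairings? does it differ between
groups?) become nested-model tests on the likelihood-ratio statistic,
ΔG² ~ χ²(Δdf), with effect size Cohen's **w = √(G²/N)**.

The package is aimed at memory/metamemory researchers and provides:

- `sourcemem.core` / `sourcemem.fit` — the 2HTSM category probabilities,
  joint ML fitting with equality constraints and fixed values, G²/df/p,
  Cohen's w, and Wald 95% CIs from the analytic observed information;
- `sourcemem.compare` — nested ΔG² tests and the ordered expectancy analysis
  for 2 (item type) × 2 (judgment group) designs;
- `sourcemem.power` — noncentral-χ² sensitivity power analysis (minimal
  detectable w given α, power, N, df);
- `sourcemem.simulate` — a seeded generator for both experimental designs
  (rooms × objects, 60+60 participants, 96 test trials; faces ×
  cheating/cooperation, 93+92 participants, 80 test trials) including 0–100
  metamemory judgments with a configurable expectancy effect;
- `sourcemem.anova` — exact contrast-score 2×2(×group) repeated-measures and
  mixed ANOVAs with partial η² and Bonferroni-corrected simple effects.

## Worked example

Fit the model to a single condition's frequency table
(`examples/fit_source_monitoring_model.py`):

```python
from sourcemem import FrequencyTable, ModelSpec, fit

table = FrequencyTable([[60, 25, 15], [25, 60, 15], [20, 20, 60]], "demo")
result = fit(ModelSpec.base(["demo"]), [table], seed=0)
print(result.to_frame())
```

prints

```
   symbol  estimate       se   ci_low  ci_high  boundary
  D[demo]  0.450000 0.055114 0.341979 0.558021     False
d_A[demo]  0.777778 0.270766 0.247087 1.000000     False
d_B[demo]  0.777778 0.270766 0.247087 1.000000     False
  b[demo]  0.727273 0.041289 0.646347 0.808198     False
  g[demo]  0.500000 0.079057 0.345051 0.654949     False

G2(1) = 0.00, p = 1.000, N = 300, w = 0.00
```

Here 45% of items are detected; detected items' sources are remembered with
probability 0.78; undetected items are called "old" 73% of the time with
source guessing at chance. G²(1) ≈ 0 says the model reproduces the table.

The other example scripts run one capability each on synthetic data:
`expectancy_analysis.py` (the full ordered model-comparison plan — base
model df 4, expectancy-equated model df 8, then the 2/2/1/1/2/1/1-df
tests), `metamemory_judgments.py` (judgment ANOVAs), and
`power_sensitivity.py` (minimal detectable w as a function of df).

A thin CLI mirrors the stages: `sourcemem simulate | fit | compare | anova |
power | report | fixtures` (see `sourcemem --help`).

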