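"""Full expectancy analysis on a synthetic rooms-x-objects experiment.

Simulates the word/room source-monitoring design (60 + 60 participants, 32
expected and 32 unexpected study pairs, 32 distractors), aggregates the test
responses into four frequency tables (item type x judgment group), and runs
the ordered model-comparison plan: base-model fit, item-memory tests,
expectancy-equated base model, expectancy-violation tests of source memory
per group, the group comparison, and the schematic-guessing tests.
"""

from sourcemem import (
    EXP1,
    aggregate_frequencies,
    default_config,
    generate,
    run_expectancy_analysis,
)

trials = generate(default_config("exp1", seed=42))
tables, n_total = aggregate_frequencies(trials, EXP1)
report = run_expectancy_analysis(tables, "exp1", seed=42)

print(f"N_total = {n_total} test responses\n")
print(report.to_frame().to_string(index=False))
print("\nGuessing parameters (expectancy-equated base model):")
print(report.guessing_table().to_string(index=False))
print(
    "\nThe generator's default ground truth makes source memory better for\n"
    "unexpected pairings in the without-judgments group only, and biases g\n"
    "toward the item-typical room in both groups.  The guessing tests reject\n"
    "reliably; the 1-df expectancy-violation effect is small (w ~ 0.02), so\n"
    "at this sample size any single synthetic run detects it with only\n"
    "moderate power -- rerun with other seeds to see the rejection rate."
)
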