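"""Metamemory-judgment ANOVAs on a synthetic faces-x-behaviors experiment.

Simulates the prisoner's-dilemma design with judgments of item and source
learning at encoding, then runs (a) the within-subject 2x2 ANOVA of judgments
of source learning (facial trustworthiness x behavior) in the with-judgments
group, and (b) the mixed 2x2xgroup ANOVA of post-test source-memory
judgments.  Expected pairings (trustworthy-cooperate, untrustworthy-cheat)
receive higher judgments -- the metamemory expectancy illusion the generator
plants by default.
"""

from sourcemem import (
    anova_table,
    cell_matrix_from_long,
    default_config,
    generate,
    generate_postdictions,
    judgment_cell_means,
    mixed_anova_2x2x2,
    rm_anova_2x2,
)

config = default_config("exp2", seed=7)
trials = generate(config)

means = judgment_cell_means(trials, "jos")
x, _, _, _ = cell_matrix_from_long(means, "participant_id", "item_type", "source", "value")
print("Judgments of source learning (with-judgments group, n = %d):" % len(x))
print(anova_table(rm_anova_2x2(x, "trustworthiness", "behavior")).to_string(index=False))

post = generate_postdictions(config)
xp, groups, _, _ = cell_matrix_from_long(
    post, "participant_id", "item_type", "source", "source_postdiction", group="group"
)
print("\nPost-test source-memory judgments (mixed design, n = %d):" % len(xp))
print(anova_table(mixed_anova_2x2x2(xp, groups, "trustworthiness", "behavior")).to_string(index=False))
print(
    "\nThe trustworthiness x behavior interaction carries the expectancy\n"
    "illusion; in the post-test judgments its three-way interaction with\n"
    "group reflects that the generator plants the effect only in the\n"
    "with-judgments group."
)
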