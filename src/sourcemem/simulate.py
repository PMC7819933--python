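"""Synthetic source-monitoring experiments with known ground truth.

Generates trial-level data with the statistical structure of the two
source-monitoring designs in :mod:`sourcemem.designs` (rooms x objects;
faces x cheating/cooperation) plus a vignette-style beliefs survey, so that
every analysis stage -- model fitting, nested comparisons, metamemory ANOVAs
-- can be exercised end to end with no external data.

Test responses are drawn per item from the 2HTSM category probabilities of
that item's condition; 0-100 metamemory judgments follow an additive Gaussian
model (grand mean + participant effect + expectancy effect + residual noise,
clipped to the scale).  All judgment-scale parameters are synthetic defaults,
not estimates from any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ITEM_CLASSES, RESPONSES, FrequencyTable, ParameterVector, category_probabilities
from .designs import EXP1, EXP2, ExperimentDesign, get_design

__all__ = [
    "JudgmentModel",
    "DesignConfig",
    "TrialRecord",
    "default_theta",
    "default_config",
    "generate",
    "simulate_frequency_tables",
    "aggregate_frequencies",
    "corrected_item_recognition",
    "judgment_cell_means",
    "generate_postdictions",
    "generate_beliefs",
    "trials_to_frame",
    "write_trials",
    "read_trials",
]

WITHOUT, WITH = "without_judgments", "with_judgments"


@dataclass(frozen=True)
class JudgmentModel:
    """Additive Gaussian model for 0-100 metamemory judgment scales.

    ``jol_expectancy_effect`` / ``jos_expectancy_effect`` are the points added
    to judgments of item/source learning for expected item-source pairings
    (the metamemory expectancy illusion).  ``postdiction_expectancy_effect``
    plays the same role for post-test judgments and applies only in the
    with-judgments group; ``behavior_main_effect`` shifts source judgments for
    Source-A (e.g. cheating) cells in post-test judgments and beliefs.
    Generated values are clipped to [0, 100].
    """

    grand_mean: float = 55.0
    jol_expectancy_effect: float = 5.0
    jos_expectancy_effect: float = 8.0
    postdiction_expectancy_effect: float = 8.0
    behavior_main_effect: float = 0.0
    participant_sd: float = 12.0
    residual_sd: float = 16.0

    def __post_init__(self) -> None:
        if self.participant_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def default_theta(design: ExperimentDesign) -> dict[str, ParameterVector]:
    """Synthetic ground-truth parameter vectors per condition.

    The values encode the qualitative structure the analyses are designed to
    detect -- better item memory in the with-judgments group, an
    expectancy-violation advantage in source memory that is attenuated when
    judgments are made at encoding, and a schematic source-guessing bias --
    at magnitudes typical of source-monitoring studies.  They are synthetic
    defaults, not estimates from any dataset.
    """
    if design.name == "exp1":
        D = {WITHOUT: 0.55, WITH: 0.72}
        d_exp = {WITHOUT: 0.20, WITH: 0.35}
        d_unexp = {WITHOUT: 0.35, WITH: 0.35}
        b = {("bathroom", WITHOUT): 0.37, ("kitchen", WITHOUT): 0.26,
             ("bathroom", WITH): 0.36, ("kitchen", WITH): 0.32}
        g = {("bathroom", WITHOUT): 0.37, ("kitchen", WITHOUT): 0.60,
             ("bathroom", WITH): 0.40, ("kitchen", WITH): 0.60}
        D_by_cond = {(it, gr): D[gr] for it in design.item_types for gr in design.groups}
    elif design.name == "exp2":
        d_exp = {WITHOUT: 0.15, WITH: 0.30}
        d_unexp = {WITHOUT: 0.35, WITH: 0.35}
        b = {("trustworthy", WITHOUT): 0.24, ("untrustworthy", WITHOUT): 0.22,
             ("trustworthy", WITH): 0.30, ("untrustworthy", WITH): 0.29}
        g = {("trustworthy", WITHOUT): 0.38, ("untrustworthy", WITHOUT): 0.71,
             ("trustworthy", WITH): 0.45, ("untrustworthy", WITH): 0.66}
        D_by_cond = {("trustworthy", WITHOUT): 0.48, ("untrustworthy", WITHOUT): 0.52,
                     ("trustworthy", WITH): 0.60, ("untrustworthy", WITH): 0.64}
    else:
        raise ValueError(f"no default parameters for design {design.name!r}")

    theta: dict[str, ParameterVector] = {}
    for itype in design.item_types:
        for group in design.groups:
            cond = design.condition(itype, group)
            de, du = d_exp[group], d_unexp[group]
            if design.expected_source[itype] == "A":
                d_A, d_B = de, du
            else:
                d_A, d_B = du, de
            theta[cond] = ParameterVector(
                D=D_by_cond[(itype, group)], d_A=d_A, d_B=d_B,
                b=b[(itype, group)], g=g[(itype, group)],
            )
    return theta


@dataclass(frozen=True)
class DesignConfig:
    """Full specification of one synthetic experiment run."""

    experiment: str
    n_per_group: tuple[int, int] | None = None
    seed: int = 0
    theta_by_condition: dict[str, ParameterVector] | None = None
    judgment_model: JudgmentModel = field(default_factory=JudgmentModel)
    include_buffers: bool = True

    def resolve(self) -> tuple[ExperimentDesign, tuple[int, int], dict[str, ParameterVector]]:
        design = get_design(self.experiment)
        n_per_group = self.n_per_group or design.n_per_group
        if len(n_per_group) != 2 or any(n < 1 for n in n_per_group):
            raise ValueError(f"invalid n_per_group {n_per_group}")
        theta = self.theta_by_condition or default_theta(design)
        missing = set(design.conditions) - set(theta)
        if missing:
            raise ValueError(f"theta_by_condition missing conditions: {sorted(missing)}")
        return design, tuple(n_per_group), theta


def default_config(experiment: str, seed: int = 0, **overrides) -> DesignConfig:
    return replace(DesignConfig(experiment=experiment, seed=seed), **overrides)


@dataclass
class TrialRecord:
    """One synthetic study or test event."""

    participant_id: int
    group: str
    phase: str  # "study" or "test"
    item_id: str
    item_type: str | None
    source: str | None  # meaning label of the studied source; None for new items
    expectancy: str | None  # "expected" / "unexpected"; None for new/buffer items
    item_class: str | None  # test rows: sourceA_old / sourceB_old / new
    old: bool
    is_buffer: bool = False
    list_id: int | None = None
    jol: float | None = None
    jos: float | None = None
    test_response: str | None = None
    investment: int | None = None
    payoff: int | None = None
    likability: int | None = None


def _clip_judgment(value: float) -> float:
    return float(np.clip(value, 0.0, 100.0))


def _source_meaning(design: ExperimentDesign, abstract: str) -> str:
    return design.source_A_meaning if abstract == "A" else design.source_B_meaning


def _expectancy(design: ExperimentDesign, item_type: str, abstract_source: str) -> str:
    return "expected" if design.expected_source[item_type] == abstract_source else "unexpected"


def _participant_groups(design: ExperimentDesign, n_per_group: tuple[int, int]) -> list[str]:
    """Alternating group assignment, first arrival to the without group."""
    counts = {design.groups[0]: n_per_group[0], design.groups[1]: n_per_group[1]}
    order: list[str] = []
    next_group = 0
    while sum(counts.values()) > 0:
        group = design.groups[next_group]
        if counts[group] > 0:
            order.append(group)
            counts[group] -= 1
        next_group = 1 - next_group
        if counts[design.groups[next_group]] == 0 and counts[group] > 0:
            next_group = 1 - next_group
    return order


def _exp1_study_plan(design: ExperimentDesign, pidx: int) -> tuple[list[tuple], list[tuple]]:
    """Counterbalanced study/distractor item assignment for one participant.

    Three stimulus lists of 16 bathroom + 16 kitchen items rotate through the
    roles (Source-A source, Source-B source, distractor) with participant
    index, so across any 3 consecutive participants each list serves each
    role once.
    """
    rotation = pidx % 3
    roles = {"A": rotation % 3, "B": (rotation + 1) % 3, "new": (rotation + 2) % 3}
    studied, new = [], []
    for itype in design.item_types:
        for i in range(design.items_per_cell):
            for abstract, list_id in roles.items():
                item_id = f"{itype}_{list_id}_{i}"
                if abstract == "new":
                    new.append((item_id, itype, None, list_id))
                else:
                    studied.append((item_id, itype, abstract, list_id))
    return studied, new


def _exp2_study_plan(design: ExperimentDesign, rng: np.random.Generator) -> tuple[list[tuple], list[tuple]]:
    """Random partner assignment: per face type, half cheat and half cooperate;
    an equal number of same-type faces is held out as new test faces."""
    studied, new = [], []
    for itype in design.item_types:
        n_old = 2 * design.items_per_cell
        ids = rng.permutation(n_old + design.new_per_type)
        behaviors = ["A"] * design.items_per_cell + ["B"] * design.items_per_cell
        for j, abstract in enumerate(behaviors):
            studied.append((f"{itype}_face_{ids[j]}", itype, abstract, None))
        for j in range(n_old, n_old + design.new_per_type):
            new.append((f"{itype}_face_{ids[j]}", itype, None, None))
    return studied, new


def generate(config: DesignConfig) -> list[TrialRecord]:
    """Generate the full trial-level dataset for one synthetic experiment.

    Reproducible given ``config.seed``; study order and test order are
    randomized per participant, test responses are multinomial draws from the
    2HTSM category probabilities of each item's condition, and metamemory
    judgments follow the additive judgment model (with-judgments group only).
    """
    design, n_per_group, theta = config.resolve()
    jm = config.judgment_model
    rng = np.random.default_rng(config.seed)
    prob_rows = {
        cond: category_probabilities(th).to_numpy() for cond, th in theta.items()
    }
    trials: list[TrialRecord] = []
    for pidx, group in enumerate(_participant_groups(design, n_per_group)):
        part_effect = rng.normal(0.0, jm.participant_sd)
        if design.name == "exp1":
            studied, new_items = _exp1_study_plan(design, pidx)
        else:
            studied, new_items = _exp2_study_plan(design, rng)

        # -- study phase -----------------------------------------------------
        study_order = rng.permutation(len(studied))
        study_rows: list[TrialRecord] = []
        if config.include_buffers:
            for bi in range(2):  # buffer/practice trials, excluded from analysis
                study_rows.append(
                    TrialRecord(
                        participant_id=pidx, group=group, phase="study",
                        item_id=f"buffer_{bi}", item_type=None,
                        source=_source_meaning(design, "A" if bi == 0 else "B"),
                        expectancy=None, item_class=None, old=True, is_buffer=True,
                    )
                )
        for j in study_order:
            item_id, itype, abstract, list_id = studied[j]
            expectancy = _expectancy(design, itype, abstract)
            rec = TrialRecord(
                participant_id=pidx, group=group, phase="study",
                item_id=item_id, item_type=itype,
                source=_source_meaning(design, abstract),
                expectancy=expectancy, item_class=None, old=True, list_id=list_id,
            )
            if group == WITH:
                bump = 1.0 if expectancy == "expected" else 0.0
                rec.jol = _clip_judgment(
                    jm.grand_mean + part_effect + bump * jm.jol_expectancy_effect
                    + rng.normal(0.0, jm.residual_sd)
                )
                rec.jos = _clip_judgment(
                    jm.grand_mean + part_effect + bump * jm.jos_expectancy_effect
                    + rng.normal(0.0, jm.residual_sd)
                )
            if design.name == "exp2":
                rec.investment = int(rng.choice([15, 30]))
                gain = 5 if rec.investment == 15 else 10
                rec.payoff = gain if abstract == "B" else -gain
            study_rows.append(rec)
        trials.extend(study_rows)

        # -- test phase ------------------------------------------------------
        test_items = [(iid, itype, abstract, lid) for iid, itype, abstract, lid in studied]
        test_items += [(iid, itype, None, lid) for iid, itype, _, lid in new_items]
        for j in rng.permutation(len(test_items)):
            item_id, itype, abstract, list_id = test_items[j]
            cond = design.condition(itype, group)
            if abstract is None:
                item_class = "new"
            else:
                item_class = "sourceA_old" if abstract == "A" else "sourceB_old"
            row = prob_rows[cond][ITEM_CLASSES.index(item_class)]
            response = RESPONSES[rng.choice(3, p=row)]
            rec = TrialRecord(
                participant_id=pidx, group=group, phase="test",
                item_id=item_id, item_type=itype,
                source=None if abstract is None else _source_meaning(design, abstract),
                expectancy=None if abstract is None else _expectancy(design, itype, abstract),
                item_class=item_class, old=abstract is not None,
                list_id=list_id, test_response=response,
            )
            if design.name == "exp2":
                base = 3.6 if itype == "trustworthy" else 2.5
                shift = 0.15 if abstract == "B" else (-0.05 if abstract == "A" else 0.0)
                rec.likability = int(np.clip(round(rng.normal(base + shift, 1.0)), 1, 6))
            trials.append(rec)
    return trials


def simulate_frequency_tables(
    design: ExperimentDesign | str,
    theta_by_condition: dict[str, ParameterVector],
    n_per_group: tuple[int, int] | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[list[FrequencyTable], int]:
    """Draw aggregated 3x3 response counts directly, without trial records.

    Row totals follow the design arithmetic (participants per group times
    items per row); this is the fast path for recovery and calibration
    simulations and is distributionally identical to aggregating
    :func:`generate` output.
    """
    if isinstance(design, str):
        design = get_design(design)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_per_group = n_per_group or design.n_per_group
    n_by_group = dict(zip(design.groups, n_per_group))
    tables = []
    for itype in design.item_types:
        for group in design.groups:
            cond = design.condition(itype, group)
            probs = category_probabilities(theta_by_condition[cond]).to_numpy()
            n = n_by_group[group]
            row_totals = (
                n * design.items_per_cell,
                n * design.items_per_cell,
                n * design.new_per_type,
            )
            counts = np.vstack(
                [rng.multinomial(total, probs[i]) for i, total in enumerate(row_totals)]
            )
            tables.append(FrequencyTable(counts, cond))
    return tables, sum(t.total for t in tables)


def aggregate_frequencies(
    trials: Iterable[TrialRecord],
    design: ExperimentDesign | str | None = None,
) -> tuple[list[FrequencyTable], int]:
    """Aggregate test-phase trials into one 3x3 table per condition.

    Buffer/practice rows are excluded.  Tables are ordered by the design's
    condition order when a design is given, otherwise by first appearance.
    """
    counts: dict[str, np.ndarray] = {}
    n_total = 0
    for rec in trials:
        if rec.phase != "test" or rec.is_buffer:
            continue
        if rec.test_response not in RESPONSES:
            raise ValueError(f"unknown response code {rec.test_response!r}")
        if rec.item_class not in ITEM_CLASSES:
            raise ValueError(f"unknown item class {rec.item_class!r}")
        cond = f"{rec.item_type}:{rec.group}"
        table = counts.setdefault(cond, np.zeros((3, 3), dtype=np.int64))
        table[ITEM_CLASSES.index(rec.item_class), RESPONSES.index(rec.test_response)] += 1
        n_total += 1
    if n_total == 0:
        raise ValueError("no test-phase trials to aggregate")
    if design is not None:
        if isinstance(design, str):
            design = get_design(design)
        order = [c for c in design.conditions if c in counts]
    else:
        order = list(counts)
    return [FrequencyTable(counts[c], c) for c in order], n_total


def corrected_item_recognition(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Per-participant, per-item-type corrected hit rate (hits - false alarms).

    Under the 2HTSM this estimates D: the hit rate is D + (1-D)b and the
    false-alarm rate is (1-D)b.  Zero denominators yield NaN.
    """
    rows: dict[tuple, dict] = {}
    for rec in trials:
        if rec.phase != "test" or rec.is_buffer:
            continue
        key = (rec.participant_id, rec.group, rec.item_type)
        acc = rows.setdefault(key, {"hits": 0, "old": 0, "fa": 0, "new": 0})
        called_old = rec.test_response != "respNew"
        if rec.old:
            acc["old"] += 1
            acc["hits"] += called_old
        else:
            acc["new"] += 1
            acc["fa"] += called_old
    out = []
    for (pid, group, itype), acc in sorted(rows.items()):
        hit_rate = acc["hits"] / acc["old"] if acc["old"] else np.nan
        fa_rate = acc["fa"] / acc["new"] if acc["new"] else np.nan
        out.append(
            {
                "participant_id": pid,
                "group": group,
                "item_type": itype,
                "hit_rate": hit_rate,
                "false_alarm_rate": fa_rate,
                "corrected_hit_rate": hit_rate - fa_rate,
            }
        )
    if not out:
        raise ValueError("no test-phase trials present")
    return pd.DataFrame(out)


def judgment_cell_means(trials: Iterable[TrialRecord], judgment: str = "jos") -> pd.DataFrame:
    """Per-participant mean judgment in each item-type x source cell.

    Long format with columns participant_id, group, item_type, source, value;
    only study-phase rows of the with-judgments group carry judgments.
    """
    if judgment not in ("jol", "jos"):
        raise ValueError("judgment must be 'jol' or 'jos'")
    rows = [
        {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "item_type": rec.item_type,
            "source": rec.source,
            "value": getattr(rec, judgment),
        }
        for rec in trials
        if rec.phase == "study" and not rec.is_buffer and getattr(rec, judgment) is not None
    ]
    if not rows:
        raise ValueError("no judgment-bearing study trials present")
    frame = pd.DataFrame(rows)
    return (
        frame.groupby(["participant_id", "group", "item_type", "source"])["value"]
        .mean()
        .reset_index()
    )


def generate_postdictions(config: DesignConfig) -> pd.DataFrame:
    """Post-test aggregated judgments of item and source memory, per cell.

    The expectancy effect applies only in the with-judgments group (the
    post-test counterpart of the metamemory expectancy illusion);
    ``behavior_main_effect`` shifts source judgments for Source-A cells in
    both groups.  Long format: one row per participant x item type x source.
    """
    design, n_per_group, _ = config.resolve()
    jm = config.judgment_model
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for pidx, group in enumerate(_participant_groups(design, n_per_group)):
        part_effect = rng.normal(0.0, jm.participant_sd)
        for itype in design.item_types:
            for abstract in ("A", "B"):
                expected = design.expected_source[itype] == abstract
                bump = jm.postdiction_expectancy_effect if (expected and group == WITH) else 0.0
                behav = jm.behavior_main_effect if abstract == "A" else 0.0
                rows.append(
                    {
                        "participant_id": pidx,
                        "group": group,
                        "item_type": itype,
                        "source": _source_meaning(design, abstract),
                        "item_postdiction": _clip_judgment(
                            jm.grand_mean + part_effect + bump + rng.normal(0, jm.residual_sd)
                        ),
                        "source_postdiction": _clip_judgment(
                            jm.grand_mean + part_effect + bump + behav
                            + rng.normal(0, jm.residual_sd)
                        ),
                    }
                )
    return pd.DataFrame(rows)


def generate_beliefs(
    n: int = 100,
    judgment_model: JudgmentModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Vignette-based beliefs about the faces design, without any encoding.

    One row per respondent x face type x behavior; ``behavior_main_effect``
    raises judgments for cheating (Source A) cells.
    """
    jm = judgment_model or JudgmentModel(behavior_main_effect=6.0)
    design = EXP2
    rng = np.random.default_rng(seed)
    rows = []
    for pidx in range(n):
        part_effect = rng.normal(0.0, jm.participant_sd)
        for itype in design.item_types:
            for abstract in ("A", "B"):
                behav = jm.behavior_main_effect if abstract == "A" else 0.0
                rows.append(
                    {
                        "participant_id": pidx,
                        "item_type": itype,
                        "source": _source_meaning(design, abstract),
                        "item_belief": _clip_judgment(
                            jm.grand_mean + part_effect + behav + rng.normal(0, jm.residual_sd)
                        ),
                        "source_belief": _clip_judgment(
                            jm.grand_mean + part_effect + behav + rng.normal(0, jm.residual_sd)
                        ),
                    }
                )
    return pd.DataFrame(rows)


_TRIAL_COLUMNS = [
    "participant_id", "group", "phase", "item_id", "item_type", "source",
    "expectancy", "item_class", "old", "is_buffer", "list_id", "jol", "jos",
    "test_response", "investment", "payoff", "likability",
]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in _TRIAL_COLUMNS} for t in trials])


def write_trials(trials: Sequence[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path) -> list[TrialRecord]:
    frame = pd.read_csv(Path(path), float_precision="round_trip")
    missing = set(_TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {}
        for c in _TRIAL_COLUMNS:
            value = getattr(row, c)
            if isinstance(value, float) and np.isnan(value):
                value = None
            kwargs[c] = value
        for int_col in ("investment", "payoff", "likability", "list_id"):
            if kwargs[int_col] is not None:
                kwargs[int_col] = int(kwargs[int_col])
        kwargs["participant_id"] = int(kwargs["participant_id"])
        kwargs["old"] = bool(kwargs["old"])
        kwargs["is_buffer"] = bool(kwargs["is_buffer"])
        records.append(TrialRecord(**kwargs))
    return records
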