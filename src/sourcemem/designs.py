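"""Descriptors of the two source-monitoring experimental designs.

Both designs cross an item-type factor with a between-subjects judgment-group
factor and pair each studied item with one of two sources, one of which is
schematically expected given the item type:

* rooms experiment (``EXP1``): words for bathroom/kitchen items studied "in
  the kitchen" (Source A) or "in the bathroom" (Source B); a kitchen item in
  the kitchen is an expected pairing.
* faces experiment (``EXP2``): trustworthy/untrustworthy-looking partners who
  cheat (Source A) or cooperate (Source B) in a sequential prisoner's dilemma
  game; an untrustworthy-looking cheater is an expected pairing.

Condition labels are ``"<item_type>:<group>"`` and name one model tree set.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ExperimentDesign", "EXP1", "EXP2", "get_design"]

GROUPS = ("without_judgments", "with_judgments")


@dataclass(frozen=True)
class ExperimentDesign:
    name: str
    item_types: tuple[str, str]
    source_A_meaning: str
    source_B_meaning: str
    #: which abstract source ("A" or "B") is schematically expected per item type
    expected_source: dict[str, str]
    n_per_group: tuple[int, int]
    #: studied items per (item type x source) cell, per participant
    items_per_cell: int
    #: new test items per item type, per participant
    new_per_type: int
    groups: tuple[str, str] = GROUPS

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(
            f"{itype}:{group}" for itype in self.item_types for group in self.groups
        )

    def condition(self, item_type: str, group: str) -> str:
        return f"{item_type}:{group}"

    @property
    def test_trials_per_participant(self) -> int:
        # two sources per item type, plus new items, over both item types
        return len(self.item_types) * (2 * self.items_per_cell + self.new_per_type)

    def expected_d(self, item_type: str) -> str:
        """Parameter name (d_A or d_B) measuring the expected pairing."""
        return "d_A" if self.expected_source[item_type] == "A" else "d_B"

    def unexpected_d(self, item_type: str) -> str:
        return "d_B" if self.expected_source[item_type] == "A" else "d_A"


EXP1 = ExperimentDesign(
    name="exp1",
    item_types=("bathroom", "kitchen"),
    source_A_meaning="kitchen",
    source_B_meaning="bathroom",
    expected_source={"bathroom": "B", "kitchen": "A"},
    n_per_group=(60, 60),
    items_per_cell=16,
    new_per_type=16,
)

EXP2 = ExperimentDesign(
    name="exp2",
    item_types=("trustworthy", "untrustworthy"),
    source_A_meaning="cheating",
    source_B_meaning="cooperation",
    expected_source={"trustworthy": "B", "untrustworthy": "A"},
    n_per_group=(93, 92),
    items_per_cell=10,
    new_per_type=20,
)

_DESIGNS = {"exp1": EXP1, "exp2": EXP2}


def get_design(name: str) -> ExperimentDesign:
    try:
        return _DESIGNS[name]
    except KeyError:
        raise ValueError(f"unknown experiment {name!r}; expected one of {sorted(_DESIGNS)}")
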