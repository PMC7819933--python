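"""Two-high-threshold source-monitoring (2HTSM) model: data structures and
exact category probabilities.

The 2HTSM is a multinomial processing tree (MPT) model for a source-monitoring
test in which each test item belongs to one of three classes -- old items from
Source A, old items from Source B, and new items -- and draws one of three
responses ("Source A", "Source B", "new").  The model decomposes response
probabilities into discrete detection and guessing states:

* ``D``   -- probability of detecting an old item as old (and, under the
  standard identifiability restriction, a new item as new),
* ``d_A`` / ``d_B`` -- conditional probability of remembering the source of a
  detected Source-A / Source-B item,
* ``b``   -- probability of guessing "old" for an undetected item,
* ``g``   -- probability of guessing "Source A" when source memory fails.

Each tree set (one per experimental condition) shares a single ``D`` across
the Source-A, Source-B, and new trees; an unrestricted three-``D`` variant is
expressible only through :class:`~sourcemem.fit.ModelSpec` overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_CLASSES",
    "RESPONSES",
    "PARAM_NAMES",
    "BRANCHES",
    "ParameterVector",
    "FrequencyTable",
    "TreeSetAssignment",
    "category_probabilities",
    "log_likelihood",
    "g_squared",
    "read_frequency_tables",
    "write_frequency_tables",
]

#: Fixed enumeration of item classes (rows), in serialization order.
ITEM_CLASSES: tuple[str, ...] = ("sourceA_old", "sourceB_old", "new")

#: Fixed enumeration of test responses (columns), in serialization order.
RESPONSES: tuple[str, ...] = ("respA", "respB", "respNew")

#: Parameter names of one tree set, in canonical order.
PARAM_NAMES: tuple[str, ...] = ("D", "d_A", "d_B", "b", "g")

# Branch table of the 2HTSM.  Each branch is
# (item_class, response, ((parameter, sign), ...)) where sign +1 takes the
# parameter edge with probability theta and -1 with probability 1 - theta.
# No parameter occurs twice on one branch, so every category probability is
# multilinear in the parameters.
BRANCHES: tuple[tuple[str, str, tuple[tuple[str, int], ...]], ...] = (
    # Source-A items
    ("sourceA_old", "respA", (("D", +1), ("d_A", +1))),
    ("sourceA_old", "respA", (("D", +1), ("d_A", -1), ("g", +1))),
    ("sourceA_old", "respB", (("D", +1), ("d_A", -1), ("g", -1))),
    ("sourceA_old", "respA", (("D", -1), ("b", +1), ("g", +1))),
    ("sourceA_old", "respB", (("D", -1), ("b", +1), ("g", -1))),
    ("sourceA_old", "respNew", (("D", -1), ("b", -1))),
    # Source-B items (d_B detects the source; failed source memory guesses
    # Source A with g, Source B with 1-g, exactly as for Source-A items)
    ("sourceB_old", "respB", (("D", +1), ("d_B", +1))),
    ("sourceB_old", "respA", (("D", +1), ("d_B", -1), ("g", +1))),
    ("sourceB_old", "respB", (("D", +1), ("d_B", -1), ("g", -1))),
    ("sourceB_old", "respA", (("D", -1), ("b", +1), ("g", +1))),
    ("sourceB_old", "respB", (("D", -1), ("b", +1), ("g", -1))),
    ("sourceB_old", "respNew", (("D", -1), ("b", -1))),
    # New items: D here is the probability of detecting the item as new.
    ("new", "respNew", (("D", +1),)),
    ("new", "respA", (("D", -1), ("b", +1), ("g", +1))),
    ("new", "respB", (("D", -1), ("b", +1), ("g", -1))),
    ("new", "respNew", (("D", -1), ("b", -1))),
)


@dataclass(frozen=True)
class ParameterVector:
    """The five probabilities of one 2HTSM tree set.

    Parameters
    ----------
    D : float
        Item recognition/detection probability, shared by old and new items.
    d_A, d_B : float
        Conditional source-memory probabilities for Source-A / Source-B items.
    b : float
        Probability of guessing "old" for an undetected item.
    g : float
        Probability of guessing Source A when source memory fails.
    """

    D: float
    d_A: float
    d_B: float
    b: float
    g: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0) or not math.isfinite(value):
                raise ValueError(
                    f"parameter {name}={value!r} outside the unit interval"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class TreeSetAssignment:
    """Meaning of the abstract sources and the condition labels they span."""

    source_A_meaning: str
    source_B_meaning: str
    sets: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sets)) != len(self.sets):
            raise ValueError("tree-set condition labels must be unique")


class FrequencyTable:
    """Observed 3x3 response counts (item class x response) for one tree set.

    Rows follow :data:`ITEM_CLASSES`, columns follow :data:`RESPONSES`.
    """

    __slots__ = ("counts", "label")

    def __init__(self, counts, label: str = "") -> None:
        arr = np.asarray(counts)
        if arr.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {arr.shape}")
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("counts must be finite")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = arr.astype(np.int64)
        self.label = label

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns condition,item_class,response,count."""
        rows = [
            (self.label, ic, resp, int(self.counts[i, j]))
            for i, ic in enumerate(ITEM_CLASSES)
            for j, resp in enumerate(RESPONSES)
        ]
        return pd.DataFrame(rows, columns=["condition", "item_class", "response", "count"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str) -> "FrequencyTable":
        sub = frame[frame["condition"] == label]
        if len(sub) == 0:
            raise ValueError(f"no rows for condition {label!r}")
        counts = np.zeros((3, 3), dtype=np.int64)
        for _, row in sub.iterrows():
            i = ITEM_CLASSES.index(row["item_class"])
            j = RESPONSES.index(row["response"])
            counts[i, j] = int(row["count"])
        return cls(counts, label)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FrequencyTable(label={self.label!r}, total={self.total})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrequencyTable)
            and other.label == self.label
            and np.array_equal(other.counts, self.counts)
        )


def write_frequency_tables(tables: Iterable[FrequencyTable], path) -> None:
    """Serialize tables as delimited text (condition,item_class,response,count)."""
    frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    frame.to_csv(path, index=False)


def read_frequency_tables(path) -> list[FrequencyTable]:
    frame = pd.read_csv(Path(path))
    required = {"condition", "item_class", "response", "count"}
    if not required.issubset(frame.columns):
        raise ValueError(f"frequency file must have columns {sorted(required)}")
    labels = list(dict.fromkeys(frame["condition"]))
    return [FrequencyTable.from_frame(frame, label) for label in labels]


def _branch_probability(theta: dict[str, float], edges) -> float:
    prob = 1.0
    for name, sign in edges:
        value = theta[name]
        prob *= value if sign > 0 else 1.0 - value
    return prob


def category_probabilities(theta: ParameterVector) -> pd.DataFrame:
    """Exact 3x3 response-probability table implied by ``theta``.

    Probabilities are obtained by summing branch products over the model's
    processing-tree branches; each row (item class) sums to one.
    """
    values = theta.as_dict()
    table = np.zeros((3, 3))
    for item_class, response, edges in BRANCHES:
        i = ITEM_CLASSES.index(item_class)
        j = RESPONSES.index(response)
        table[i, j] += _branch_probability(values, edges)
    return pd.DataFrame(table, index=list(ITEM_CLASSES), columns=list(RESPONSES))


def log_likelihood(freqs: FrequencyTable, theta: ParameterVector) -> float:
    """Multinomial log-likelihood sum(n * ln p), with 0 * ln 0 := 0.

    Returns ``-inf`` when a cell has positive count but zero model
    probability.
    """
    probs = category_probabilities(theta).to_numpy()
    counts = freqs.counts
    mask = counts > 0
    if np.any(probs[mask] <= 0.0):
        return -math.inf
    return float(np.sum(counts[mask] * np.log(probs[mask])))


def g_squared(freqs: FrequencyTable, theta: ParameterVector) -> float:
    """Likelihood-ratio statistic 2 * sum(n * ln(n / (N_row * p))).

    Zero counts contribute nothing; a positive count on a zero-probability
    cell yields ``inf`` (an infinite-statistic flag, not an exception).
    """
    probs = category_probabilities(theta).to_numpy()
    counts = freqs.counts.astype(float)
    expected = freqs.row_totals[:, None] * probs
    mask = counts > 0
    if np.any(expected[mask] <= 0.0):
        return math.inf
    return float(2.0 * np.sum(counts[mask] * np.log(counts[mask] / expected[mask])))
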