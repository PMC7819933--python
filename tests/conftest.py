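"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sourcemem import EXP1, EXP2, FrequencyTable, ModelSpec


def oracle_probabilities(D, d_A, d_B, b, g):
    """Independent closed-form 3x3 probability table of the 2HTSM.

    Hand-written algebra for each item class (detect -> source memory ->
    guessing), kept deliberately separate from the package's branch-table
    implementation.
    """
    row_A = np.array(
        [
            D * d_A + D * (1 - d_A) * g + (1 - D) * b * g,
            D * (1 - d_A) * (1 - g) + (1 - D) * b * (1 - g),
            (1 - D) * (1 - b),
        ]
    )
    row_B = np.array(
        [
            D * (1 - d_B) * g + (1 - D) * b * g,
            D * d_B + D * (1 - d_B) * (1 - g) + (1 - D) * b * (1 - g),
            (1 - D) * (1 - b),
        ]
    )
    row_new = np.array(
        [
            (1 - D) * b * g,
            (1 - D) * b * (1 - g),
            D + (1 - D) * (1 - b),
        ]
    )
    return np.vstack([row_A, row_B, row_new])


def oracle_loglik(counts, probs):
    """Cell-by-cell multinomial log-likelihood summation."""
    total = 0.0
    for i in range(3):
        for j in range(3):
            n = counts[i][j]
            if n > 0:
                if probs[i][j] <= 0:
                    return -np.inf
                total += n * np.log(probs[i][j])
    return total


def grid_search_loglik(counts, step=0.02):
    """Best log-likelihood over a full 5-parameter grid of resolution ``step``.

    Exploits the fact that, given (D, b, g), the Source-A row depends only on
    d_A and the Source-B row only on d_B, so the maximum over the full
    5-dimensional grid equals a maximum over (D, b, g) of independently
    maximized row terms.  Vectorized over the (D, b, g) grid.
    """
    counts = np.asarray(counts, dtype=float)
    axis = np.arange(0.0, 1.0 + step / 2, step)
    D, b, g = np.meshgrid(axis, axis, axis, indexing="ij")
    D, b, g = D.ravel(), b.ravel(), g.ravel()

    def row_ll(n_row, cols):
        total = np.zeros_like(D)
        for n, p in zip(n_row, cols):
            if n > 0:
                with np.errstate(divide="ignore"):
                    total += n * np.log(p)
        return total

    # new-item row: no d parameter
    best = row_ll(
        counts[2], [(1 - D) * b * g, (1 - D) * b * (1 - g), D + (1 - D) * (1 - b)]
    )
    for row_idx in (0, 1):
        row_best = np.full_like(D, -np.inf)
        for d in axis:
            if row_idx == 0:
                cols = [
                    D * d + D * (1 - d) * g + (1 - D) * b * g,
                    D * (1 - d) * (1 - g) + (1 - D) * b * (1 - g),
                    (1 - D) * (1 - b),
                ]
            else:
                cols = [
                    D * (1 - d) * g + (1 - D) * b * g,
                    D * d + D * (1 - d) * (1 - g) + (1 - D) * b * (1 - g),
                    (1 - D) * (1 - b),
                ]
            row_best = np.maximum(row_best, row_ll(counts[row_idx], cols))
        best = best + row_best
    return float(np.max(best[np.isfinite(best)]))


@pytest.fixture
def grid_example_table() -> FrequencyTable:
    return FrequencyTable([[60, 25, 15], [25, 60, 15], [20, 20, 60]], "c")


@pytest.fixture
def exp1_design():
    return EXP1


@pytest.fixture
def exp2_design():
    return EXP2


@pytest.fixture
def exp2_base_spec() -> ModelSpec:
    return ModelSpec.base(EXP2.conditions)
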