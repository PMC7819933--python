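"""Nested-model likelihood-ratio tests and the standard expectancy analysis.

Nested 2HTSM models are compared by the difference of their likelihood-ratio
statistics, Delta G^2 = G^2(nested) - G^2(full), referred to a central
chi-square distribution with Delta df degrees of freedom, with effect size
Cohen's w = sqrt(Delta G^2 / N).

:func:`run_expectancy_analysis` executes the canonical sequence of model
comparisons for a 2 (item type) x 2 (judgment group) source-monitoring
design: item-memory tests against the base model, an expectancy-equated base
model with one expected-pairing and one unexpected-pairing source-memory
parameter per group, expectancy-violation tests of source memory within each
group, a group comparison of source memory, and schematic-guessing tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import FrequencyTable
from .designs import ExperimentDesign, get_design
from .fit import FitResult, ModelSpec, SpecificationError, chi2_sf, cohens_w, fit

__all__ = [
    "ComparisonResult",
    "AnalysisReport",
    "compare",
    "expectancy_base_spec",
    "run_expectancy_analysis",
]

#: Negative Delta G^2 larger than this tolerance indicates an optimizer
#: failure rather than rounding noise.
NEGATIVE_TOL = 1e-4

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one nested-model likelihood-ratio test."""

    nested_label: str
    full_label: str
    delta_G2: float
    delta_df: int
    p_value: float
    w: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def compare(nested: FitResult, full: FitResult, *, labels: tuple[str, str] | None = None) -> ComparisonResult:
    """Likelihood-ratio test of ``nested`` against ``full`` on the same data."""
    if not nested.spec.is_refinement_of(full.spec):
        raise SpecificationError("nested model is not a refinement of the full model")
    if nested.N_total != full.N_total:
        raise ValueError("models were fitted to different data (N_total differs)")
    delta = nested.G2 - full.G2
    if delta < 0:
        if delta < -NEGATIVE_TOL:
            raise RuntimeError(
                f"Delta G2 = {delta:.6g} < 0 beyond tolerance; refit with more restarts"
            )
        warnings.warn(
            f"small negative Delta G2 ({delta:.2e}) clipped to 0", RuntimeWarning
        )
        delta = 0.0
    delta_df = nested.df - full.df
    if delta_df < 1:
        if delta_df == 0 and nested.spec == full.spec:
            # identical specs: degenerate comparison, p = 1 by convention
            nested_label, full_label = labels or ("nested", "full")
            return ComparisonResult(nested_label, full_label, 0.0, 0, 1.0, 0.0)
        raise SpecificationError("nested model must have fewer free symbols")
    nested_label, full_label = labels or ("nested", "full")
    return ComparisonResult(
        nested_label=nested_label,
        full_label=full_label,
        delta_G2=float(delta),
        delta_df=int(delta_df),
        p_value=chi2_sf(delta, delta_df),
        w=cohens_w(delta, nested.N_total),
    )


def expectancy_base_spec(design: ExperimentDesign) -> ModelSpec:
    """Base model with source memory equated by expectancy within each group.

    Within each judgment group the two parameters measuring source memory for
    expected pairings share one symbol (``d_expected[group]``), and likewise
    for unexpected pairings; D, b, and g stay separate per tree set.  For a
    four-set design this model has df = 8.
    """
    base = ModelSpec.base(design.conditions)
    groups_map: dict[str, list[str]] = {}
    for group in design.groups:
        exp_syms = []
        unexp_syms = []
        for itype in design.item_types:
            cond = design.condition(itype, group)
            exp_syms.append(f"{design.expected_d(itype)}[{cond}]")
            unexp_syms.append(f"{design.unexpected_d(itype)}[{cond}]")
        groups_map[f"d_expected[{group}]"] = exp_syms
        groups_map[f"d_unexpected[{group}]"] = unexp_syms
    return base.equate(groups_map)


@dataclass
class AnalysisReport:
    """Ordered fit and comparison results of the expectancy analysis."""

    design_name: str
    N_total: int
    base_fit: FitResult
    expectancy_fit: FitResult
    comparisons: list[tuple[str, ComparisonResult]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test": "base_model_fit",
                "label": "base model (single D per tree set)",
                "delta_G2": round(self.base_fit.G2, 6),
                "delta_df": self.base_fit.df,
                "p": round(self.base_fit.p_value, 3),
                "w": round(self.base_fit.w, 2),
                "decision": "retain" if self.base_fit.p_value >= ALPHA else "reject",
            }
        ]
        for test, comp in self.comparisons[:2]:
            rows.append(self._row(test, comp))
        rows.append(
            {
                "test": "expectancy_base_fit",
                "label": "expectancy-equated base model",
                "delta_G2": round(self.expectancy_fit.G2, 6),
                "delta_df": self.expectancy_fit.df,
                "p": round(self.expectancy_fit.p_value, 3),
                "w": round(self.expectancy_fit.w, 2),
                "decision": "retain" if self.expectancy_fit.p_value >= ALPHA else "reject",
            }
        )
        for test, comp in self.comparisons[2:]:
            rows.append(self._row(test, comp))
        return pd.DataFrame(rows)

    @staticmethod
    def _row(test: str, comp: ComparisonResult) -> dict:
        return {
            "test": test,
            "label": f"{comp.nested_label} vs {comp.full_label}",
            "delta_G2": round(comp.delta_G2, 6),
            "delta_df": comp.delta_df,
            "p": round(comp.p_value, 3),
            "w": round(comp.w, 2),
            "decision": "reject" if comp.significant else "retain",
        }

    def guessing_table(self) -> pd.DataFrame:
        """b and g estimates (with 95% CIs) by condition, from the
        expectancy-equated base model."""
        fitres = self.expectancy_fit
        rows = []
        for param in ("b", "g"):
            for cond in fitres.spec.tree_sets:
                symbol = fitres.spec.constraint_map[(cond, param)]
                rows.append(
                    {
                        "parameter": param,
                        "condition": cond,
                        "estimate": round(fitres.estimates[symbol], 6),
                        "ci_low": round(fitres.ci_low[symbol], 6),
                        "ci_high": round(fitres.ci_high[symbol], 6),
                    }
                )
        return pd.DataFrame(rows)


def run_expectancy_analysis(
    data: Sequence[FrequencyTable],
    experiment: str | ExperimentDesign,
    seed: int = 0,
    n_restarts: int = 10,
) -> AnalysisReport:
    """Run the ordered model-comparison plan on four frequency tables.

    Steps, in order: (1) base-model fit; (2) item memory D equated across
    item types within group; (3) D equated across groups within item type;
    (4) expectancy-equated base model; (5) expected = unexpected source
    memory within each group; (6) source memory equated across groups;
    (7) source guessing g equated across item types within each group.
    Steps 2-3 are tested against the base model, steps 5-7 against the
    expectancy-equated base model.
    """
    design = get_design(experiment) if isinstance(experiment, str) else experiment
    labels = {t.label for t in data}
    missing = set(design.conditions) - labels
    if missing:
        raise ValueError(f"missing condition tables: {sorted(missing)}")

    def do_fit(spec: ModelSpec) -> FitResult:
        return fit(spec, data, seed=seed, n_restarts=n_restarts)

    base = ModelSpec.base(design.conditions)
    base_fit = do_fit(base)

    comparisons: list[tuple[str, ComparisonResult]] = []

    # (2) item memory by item type: D equated across item types within group
    spec2 = base.equate(
        {
            f"D[{group}]": [
                f"D[{design.condition(itype, group)}]" for itype in design.item_types
            ]
            for group in design.groups
        }
    )
    comparisons.append(
        (
            "item_memory_by_item_type",
            compare(do_fit(spec2), base_fit, labels=("D equal across item types", "base model")),
        )
    )

    # (3) item memory by group: D equated across groups within item type
    spec3 = base.equate(
        {
            f"D[{itype}]": [
                f"D[{design.condition(itype, group)}]" for group in design.groups
            ]
            for itype in design.item_types
        }
    )
    comparisons.append(
        (
            "item_memory_by_group",
            compare(do_fit(spec3), base_fit, labels=("D equal across groups", "base model")),
        )
    )

    # (4) expectancy-equated base model
    exp_base = expectancy_base_spec(design)
    exp_fit = do_fit(exp_base)

    # (5) expectancy-violation test of source memory within each group
    for group in design.groups:
        spec5 = exp_base.equate(
            {f"d[{group}]": [f"d_expected[{group}]", f"d_unexpected[{group}]"]}
        )
        comparisons.append(
            (
                f"source_memory_expectancy_{group}",
                compare(
                    do_fit(spec5),
                    exp_fit,
                    labels=(f"d expected = unexpected ({group})", "expectancy base"),
                ),
            )
        )

    # (6) source memory equated across groups
    spec6 = exp_base.equate(
        {
            "d_expected": [f"d_expected[{g}]" for g in design.groups],
            "d_unexpected": [f"d_unexpected[{g}]" for g in design.groups],
        }
    )
    comparisons.append(
        (
            "source_memory_by_group",
            compare(do_fit(spec6), exp_fit, labels=("d equal across groups", "expectancy base")),
        )
    )

    # (7) schematic source guessing: g equated across item types within group
    for group in design.groups:
        spec7 = exp_base.equate(
            {
                f"g[{group}]": [
                    f"g[{design.condition(itype, group)}]" for itype in design.item_types
                ]
            }
        )
        comparisons.append(
            (
                f"guessing_by_item_type_{group}",
                compare(
                    do_fit(spec7),
                    exp_fit,
                    labels=(f"g equal across item types ({group})", "expectancy base"),
                ),
            )
        )

    return AnalysisReport(
        design_name=design.name,
        N_total=base_fit.N_total,
        base_fit=base_fit,
        expectancy_fit=exp_fit,
        comparisons=comparisons,
    )
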