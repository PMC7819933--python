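"""Sensitivity power analysis for chi-square tests on Cohen's w scale.

For a chi-square test with ``df`` degrees of freedom at level ``alpha`` and
total sample size ``N``, the minimal detectable effect at power ``1 - beta``
is ``w* = sqrt(lambda* / N)`` where ``lambda*`` is the noncentrality at which
the noncentral chi-square distribution puts probability ``power`` above the
central critical value.  ``lambda*`` is found by root bracketing on the
noncentral survival function, which is strictly increasing in ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "PowerQuery",
    "noncentrality_for_power",
    "sensitivity_w",
    "achieved_power",
    "sensitivity_sweep",
]

_TOL = 1e-8


@dataclass(frozen=True)
class PowerQuery:
    alpha: float
    power: float
    N_total: int
    df: int

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0.0 < self.power < 1.0):
            raise ValueError(f"power must be in (0,1), got {self.power}")
        if self.power <= self.alpha:
            raise ValueError(
                f"requested power {self.power} not attainable: must exceed alpha {self.alpha}"
            )
        if self.N_total < 1:
            raise ValueError("N_total must be positive")
        if self.df < 1:
            raise ValueError("df must be >= 1")


def achieved_power(lam: float, df: int, alpha: float) -> float:
    """Rejection probability of the level-``alpha`` test at noncentrality ``lam``."""
    crit = scipy.stats.chi2.ppf(1.0 - alpha, df)
    return float(scipy.stats.ncx2.sf(crit, df, lam)) if lam > 0 else float(alpha)


def noncentrality_for_power(df: int, alpha: float, power: float) -> float:
    """Noncentrality lambda* with rejection probability exactly ``power``."""
    if power <= alpha:
        raise ValueError("power must exceed alpha")
    hi = 1.0
    while achieved_power(hi, df, alpha) < power:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable for valid queries
            raise RuntimeError("failed to bracket the noncentrality root")
    lam = scipy.optimize.brentq(
        lambda l: achieved_power(l, df, alpha) - power, 0.0, hi, xtol=_TOL, rtol=1e-12
    )
    return float(lam)


def sensitivity_w(q: PowerQuery) -> float:
    """Minimal detectable Cohen's w for the given query."""
    lam = noncentrality_for_power(q.df, q.alpha, q.power)
    return float(np.sqrt(lam / q.N_total))


def sensitivity_sweep(
    N_total: int,
    df_values=range(1, 25),
    alpha: float = 0.05,
    power: float = 0.95,
) -> pd.DataFrame:
    """Minimal detectable w across a range of df.

    The df entering a sensitivity analysis of a model-comparison test is a
    reporting choice; the sweep makes the dependence explicit instead of
    asserting a single value.
    """
    rows = []
    for df in df_values:
        q = PowerQuery(alpha=alpha, power=power, N_total=N_total, df=df)
        lam = noncentrality_for_power(df, alpha, power)
        rows.append(
            {
                "df": df,
                "noncentrality": lam,
                "min_detectable_w": float(np.sqrt(lam / N_total)),
                "alpha": alpha,
                "power": power,
                "N_total": N_total,
            }
        )
    return pd.DataFrame(rows)
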