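"""Maximum-likelihood fitting, fit statistics, and Wald intervals."""

import math

import numpy as np
import pytest
import scipy.stats

from sourcemem import (
    EXP2,
    FrequencyTable,
    ModelSpec,
    ParameterVector,
    SpecificationError,
    category_probabilities,
    chi2_sf,
    cohens_w,
    fit,
)
from sourcemem.fit import CompiledModel
from conftest import grid_search_loglik


class TestModelSpec:
    def test_base_spec_df_bookkeeping(self):
        # 4 tree sets x 6 independent categories = 24; 20 free symbols -> df 4
        spec = ModelSpec.base(EXP2.conditions)
        assert len(spec.free_symbols) == 20
        assert spec.df == 4

    def test_equate_merges_symbols(self):
        spec = ModelSpec.base(["a", "b"])
        merged = spec.equate({"D": ["D[a]", "D[b]"]})
        assert merged.df == spec.df + 1
        assert merged.is_refinement_of(spec)
        assert not spec.is_refinement_of(merged)

    def test_non_identified_spec_rejected(self):
        cmap = {("a", p): f"{p}[a]" for p in ("D", "d_A", "d_B", "b", "g")}
        cmap[("a", "D")] = "Dx"
        spec = ModelSpec(("a",), cmap)  # 5 symbols <= 6 categories: fine
        with pytest.raises(SpecificationError):
            ModelSpec(("a",), {("a", p): f"{p}" for p in ("D", "d_A", "d_B", "b")})

    def test_missing_table_rejected(self, grid_example_table):
        spec = ModelSpec.base(["c", "other"])
        with pytest.raises(ValueError, match="missing"):
            CompiledModel(spec, [grid_example_table])

    def test_config_round_trip(self):
        spec = ModelSpec.base(["a", "b"]).equate({"D": ["D[a]", "D[b]"]}).fix({"g[a]": 0.5})
        assert ModelSpec.from_config(spec.to_config()) == spec


class TestFit:
    def test_recovers_truth_from_exact_expected_counts(self, exp2_design):
        # parameters chosen so every category probability has at most three
        # decimals: counts at row total 8000 are then exact expected counts
        nice = [
            ParameterVector(0.6, 0.5, 0.25, 0.5, 0.5),
            ParameterVector(0.5, 0.25, 0.5, 0.25, 0.75),
            ParameterVector(0.75, 0.5, 0.5, 0.5, 0.25),
            ParameterVector(0.25, 0.75, 0.25, 0.5, 0.5),
        ]
        theta = dict(zip(exp2_design.conditions, nice))
        tables = []
        for cond, th in theta.items():
            probs = category_probabilities(th).to_numpy()
            counts = np.round(probs * 8000).astype(int)
            assert np.allclose(counts, probs * 8000, atol=1e-9)
            tables.append(FrequencyTable(counts, cond))
        spec = ModelSpec.base(exp2_design.conditions)
        result = fit(spec, tables, seed=1, n_restarts=3)
        assert result.converged
        assert result.G2 < 1e-6
        for cond, th in theta.items():
            for param, value in th.as_dict().items():
                symbol = spec.constraint_map[(cond, param)]
                assert result.estimates[symbol] == pytest.approx(value, abs=1e-4)

    def test_optimum_beats_every_grid_point(self, grid_example_table):
        spec = ModelSpec.base(["c"])
        result = fit(spec, [grid_example_table], seed=0)
        grid_best = grid_search_loglik(grid_example_table.counts, step=0.02)
        assert result.logL >= grid_best - 1e-9

    def test_nesting_monotonicity_fixed_d_fits_worse(self, grid_example_table):
        free = ModelSpec.base(["c"])
        fixed = free.fix({"d_A[c]": 0.0, "d_B[c]": 0.0})
        free_fit = fit(free, [grid_example_table], seed=0)
        fixed_fit = fit(fixed, [grid_example_table], seed=0)
        assert fixed_fit.G2 >= free_fit.G2 - 1e-8

    def test_deterministic_given_seed(self, grid_example_table):
        spec = ModelSpec.base(["c"])
        r1 = fit(spec, [grid_example_table], seed=42)
        r2 = fit(spec, [grid_example_table], seed=42)
        assert r1.estimates == r2.estimates and r1.logL == r2.logL

    def test_w_and_N_total_populated(self, grid_example_table):
        spec = ModelSpec.base(["c"])
        result = fit(spec, [grid_example_table], seed=0)
        assert result.N_total == 300
        assert result.w == pytest.approx(math.sqrt(result.G2 / 300))


class TestChi2Survival:
    @pytest.mark.parametrize(
        "x, df, expected",
        [
            (3.71, 4, 0.446),
            (11.68, 8, 0.166),
            (0.0, 3, 1.0),
        ],
    )
    def test_reference_values(self, x, df, expected):
        # the reference statistics are themselves printed to 2 decimals, so
        # +-0.005 in x propagates up to ~1e-3 into the tail probability
        assert chi2_sf(x, df) == pytest.approx(expected, abs=1.5e-3)

    def test_closed_forms_for_even_df(self):
        for x in (0.3, 1.7, 6.4, 20.0):
            assert chi2_sf(x, 2) == pytest.approx(math.exp(-x / 2), abs=1e-12)
            assert chi2_sf(x, 4) == pytest.approx(
                math.exp(-x / 2) * (1 + x / 2), abs=1e-12
            )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            chi2_sf(1.0, 0)
        with pytest.raises(ValueError):
            chi2_sf(-1.0, 2)


class TestCohensW:
    @pytest.mark.parametrize(
        "G2, N, printed",
        [(124.37, 11520, 0.10), (57.17, 14800, 0.06), (0.0, 500, 0.0)],
    )
    def test_reference_values(self, G2, N, printed):
        assert round(cohens_w(G2, N), 2) == printed

    def test_requires_positive_N(self):
        with pytest.raises(ValueError):
            cohens_w(1.0, 0)


class TestWaldIntervals:
    def test_ci_width_shrinks_with_sqrt_N(self):
        theta = ParameterVector(0.6, 0.4, 0.5, 0.3, 0.55)
        spec = ModelSpec.base(["c"])
        widths = []
        for scale in (10**3, 10**4, 10**5):
            probs = category_probabilities(theta).to_numpy()
            counts = np.round(probs * scale).astype(int)
            result = fit(spec, [FrequencyTable(counts, "c")], seed=0, n_restarts=3)
            widths.append(result.ci_high["D[c]"] - result.ci_low["D[c]"])
        assert widths[0] / widths[1] == pytest.approx(math.sqrt(10), rel=0.05)
        assert widths[1] / widths[2] == pytest.approx(math.sqrt(10), rel=0.05)

    def test_boundary_estimate_gets_degenerate_upper_limit(self):
        # data generated at d_A = d_B = 1: source memory estimates on boundary
        theta = ParameterVector(0.7, 1.0, 1.0, 0.3, 0.5)
        probs = category_probabilities(theta).to_numpy()
        counts = np.round(probs * 1000).astype(int)
        result = fit(ModelSpec.base(["c"]), [FrequencyTable(counts, "c")], seed=0)
        assert result.estimates["d_A[c]"] > 0.999
        assert result.ci_high["d_A[c]"] == 1.0
        assert "d_A[c]" in result.boundary_symbols

    def test_matches_finite_difference_hessian_oracle(self, grid_example_table):
        spec = ModelSpec.base(["c"])
        result = fit(spec, [grid_example_table], seed=0)
        model = CompiledModel(spec, [grid_example_table])
        symbols = model.symbols
        theta = np.array([result.estimates[s] for s in symbols])
        h = 1e-5
        k = len(theta)
        hess = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += h
                tpp[j] += h
                tmm[i] -= h
                tmm[j] -= h
                tpm[i] += h
                tpm[j] -= h
                tmp[i] -= h
                tmp[j] += h
                hess[i, j] = (
                    model.loglik(tpp) - model.loglik(tpm) - model.loglik(tmp) + model.loglik(tmm)
                ) / (4 * h * h)
        se = np.sqrt(np.diag(np.linalg.inv(-hess)))
        z = scipy.stats.norm.ppf(0.975)
        for i, s in enumerate(symbols):
            assert result.ci_low[s] == pytest.approx(
                np.clip(theta[i] - z * se[i], 0, 1), abs=1e-3
            )
            assert result.ci_high[s] == pytest.approx(
                np.clip(theta[i] + z * se[i], 0, 1), abs=1e-3
            )
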