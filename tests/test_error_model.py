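import itertools

import numpy as np
import pytest

from dmsfit import (
    DimsumErrorModel,
    FitConfig,
    SyntheticSpec,
    compute_fit_weights,
    compute_fitness,
    enumerate_subsets,
    fit_error_model,
    generate_counts,
    merge_replicates,
    model_variance,
    normalize_scale_shift,
    objective,
    predict_variant_error,
    select_high_confidence,
)
from dmsfit.error_model import _class_weights

from conftest import make_fitness_table


class TestModelVariance:
    def test_closed_form(self):
        assert model_variance(3.0, 1.0, 0.01, 100.0, 50.0) == pytest.approx(0.06, abs=1e-12)

    def test_lower_bounds_recover_poisson(self):
        n_in, n_out = np.array([100.0, 20.0]), np.array([50.0, 5.0])
        assert np.allclose(
            model_variance(1.0, 1.0, 0.0, n_in, n_out), 1 / n_in + 1 / n_out
        )

    def test_additive_floor_at_infinite_counts(self):
        assert model_variance(2.0, 2.0, 0.05, 1e15, 1e15) == pytest.approx(0.05, rel=1e-9)

    def test_zero_counts_undefined(self):
        assert np.isnan(model_variance(1.0, 1.0, 0.0, 0.0, 50.0))


class TestSubsetEnumeration:
    def test_three_replicates(self):
        subsets = enumerate_subsets(3)
        assert sorted(len(s) for s in subsets) == [2, 2, 2, 3]
        assert set(subsets) == {(0, 1, 2), (0, 1), (0, 2), (1, 2)}

    def test_two_replicates(self):
        assert enumerate_subsets(2) == [(0, 1)]

    def test_four_replicates_counts(self):
        subsets = enumerate_subsets(4)
        assert len(subsets) == 11
        sizes = [len(s) for s in subsets]
        assert sizes.count(4) == 1 and sizes.count(3) == 4 and sizes.count(2) == 6

    def test_single_replicate_is_error(self):
        with pytest.raises(ValueError):
            enumerate_subsets(1)


class TestFitWeights:
    def test_stated_arithmetic(self):
        # n_R / mean_poisson_var^2 / sqrt(max(n_m, sqrt(n_total)))
        w = compute_fit_weights(3, np.array([0.03]), 100, 10_000)
        assert w[0] == pytest.approx(3 / 0.03**2 / 10.0, rel=1e-9)

    def test_small_class_uses_sqrt_total_floor(self):
        w = compute_fit_weights(3, np.array([0.03]), 5, 10_000)
        assert w[0] == pytest.approx(3 / 0.03**2 / 10.0, rel=1e-9)

    def test_doubling_counts_quadruples_weight(self):
        """Relative-deviation weighting: halving the Poisson variance scale
        multiplies the weight by four."""
        w1 = compute_fit_weights(2, np.array([0.03]), 100, 10_000)
        w2 = compute_fit_weights(2, np.array([0.015]), 100, 10_000)
        assert np.allclose(w2, 4 * w1)

    def test_class_weights_match_formula(self):
        ns = np.array([1] * 90 + [2] * 10)
        cw = _class_weights(ns)
        assert cw[0] == pytest.approx(1 / np.sqrt(90))
        assert cw[-1] == pytest.approx(1 / np.sqrt(10))  # 10 = max(10, sqrt(100))


class TestObjective:
    def test_zero_at_perfect_parameters(self):
        # two replicates, one subset; make empirical variance equal the model mean
        rng = np.random.default_rng(0)
        n = 30
        n_in = rng.integers(50, 500, (n, 2)).astype(float)
        n_out = rng.integers(50, 500, (n, 2)).astype(float)
        m_in, m_out, a = np.array([2.0, 1.5]), np.array([1.0, 1.0]), np.array([0.01, 0.02])
        target = (
            m_in / n_in + m_out / n_out + a
        ).mean(axis=1)
        d = np.sqrt(2 * target)  # var of (x, -x) pair with ddof=1 is 2x^2... use +-d/2
        F = np.column_stack([d / 2, -d / 2])
        val = objective(m_in, m_out, a, F, n_in, n_out)
        assert val == pytest.approx(0.0, abs=1e-18)

    def test_single_term_arithmetic(self):
        # one variant pair with known weight: check the squared-deviation term
        n_in = np.array([[100.0, 100.0], [100.0, 100.0]])
        n_out = np.array([[100.0, 100.0], [100.0, 100.0]])
        F = np.array([[0.0, 0.0], [0.1, -0.1]])
        # empirical variances: 0 and 0.02; model mean with m=1, a=0 is 0.02,
        # so only the first variant contributes; its weight is n_R / pois / cw
        val = objective(np.ones(2), np.ones(2), np.zeros(2), F, n_in, n_out)
        w = 2 / 0.02**2 / np.sqrt(max(2, np.sqrt(2)))
        assert val == pytest.approx(w * (0.0 - 0.02) ** 2, rel=1e-12)

    def test_order_independence_against_loop_oracle(self):
        """The vectorized objective matches a reversed-order scalar loop."""
        rng = np.random.default_rng(1)
        n, reps = 25, 3
        F = rng.normal(0, 0.3, (n, reps))
        n_in = rng.integers(30, 800, (n, reps)).astype(float)
        n_out = rng.integers(30, 800, (n, reps)).astype(float)
        ns = rng.integers(1, 3, n)
        m_in = np.array([1.5, 1.0, 2.0])
        m_out = np.array([1.0, 1.2, 1.0])
        a = np.array([0.0, 0.01, 0.005])
        fast = objective(m_in, m_out, a, F, n_in, n_out, n_subs=ns)

        cw = _class_weights(ns)
        total = 0.0
        for R in reversed(enumerate_subsets(reps)):
            for i in reversed(range(n)):
                cols = list(R)
                emp = np.var(F[i, cols], ddof=1)
                model = np.mean(
                    [m_in[r] / n_in[i, r] + m_out[r] / n_out[i, r] + a[r] for r in cols]
                )
                pois = np.mean([1 / n_in[i, r] + 1 / n_out[i, r] for r in cols])
                total += len(R) / pois**2 * cw[i] * (emp - model) ** 2
        assert fast == pytest.approx(total, rel=1e-9)


def _make_toy_pair(seed, n=50, m_in=1.4, m_out=1.2, a=0.004):
    """Two replicates with identical counts; variance carried by the score gap."""
    rng = np.random.default_rng(seed)
    n_in = rng.integers(80, 2000, n).astype(float)
    n_out = rng.integers(80, 2000, n).astype(float)
    sigma2 = m_in / n_in + m_out / n_out + a
    gap = rng.normal(0, np.sqrt(2 * sigma2))
    F = np.column_stack([gap / 2, -gap / 2])
    Nin = np.column_stack([n_in, n_in])
    Nout = np.column_stack([n_out, n_out])
    return F, Nin, Nout


class TestFit:
    def test_matches_grid_search_oracle(self):
        """With identical counts in both replicates the objective depends only
        on the parameter sums; the exact solver must agree with an exhaustive
        grid over tied (m_in, m_out, a) to within one grid step."""
        F, Nin, Nout = _make_toy_pair(seed=5)
        est = DimsumErrorModel(n_bootstraps=0).fit(F, Nin, Nout)
        fitted = (
            est.m_input_.mean(),
            est.m_output_.mean(),
            est.a_.mean(),
        )
        grid_m = np.arange(1.0, 2.0001, 0.05)
        grid_a = np.arange(0.0, 0.02001, 0.001)
        best, best_val = None, np.inf
        for mi, mo, aa in itertools.product(grid_m, grid_m, grid_a):
            val = objective(
                np.array([mi, mi]), np.array([mo, mo]), np.array([aa, aa]), F, Nin, Nout
            )
            if val < best_val:
                best, best_val = (mi, mo, aa), val
        assert abs(fitted[0] - best[0]) <= 0.05 + 1e-9
        assert abs(fitted[1] - best[1]) <= 0.05 + 1e-9
        assert abs(fitted[2] - best[2]) <= 0.001 + 1e-9

    def test_bounds_respected_on_pure_poisson_data(self):
        spec = SyntheticSpec(seed=11, n_doubles=800, depth=1e6)
        table, design, _ = generate_counts(spec)
        ft = compute_fitness(table, design)
        ft, _ = normalize_scale_shift(ft)
        params = fit_error_model(ft, table, design, FitConfig(n_bootstraps=20, random_seed=0))
        assert (params.m_input >= 1.0).all()
        assert (params.m_output >= 1.0).all()
        assert (params.a >= 0.0).all()
        # truth lies on the boundary: fitted terms should sit near it
        assert params.m_input.max() < 1.5
        assert np.sqrt(params.a).max() < 0.05

    def test_fitted_objective_never_exceeds_truth(self):
        """Optimizer adequacy: the exact solve is at least as good as the
        generating parameters on every synthetic dataset."""
        for seed in range(1, 11):
            spec = SyntheticSpec(seed=seed, n_doubles=1000, depth=2e6, m_input=(3, 1, 1))
            table, design, _ = generate_counts(spec)
            ft = compute_fitness(table, design)
            sel = select_high_confidence(table, design)
            pool = sel.mask & ~table.is_wildtype
            F = ft.fitness.to_numpy()[pool]
            Nin = table.input_counts(design)[pool]
            Nout = table.output_counts(design)[pool]
            ns = table.n_subs[pool]
            est = DimsumErrorModel(n_bootstraps=0).fit(F, Nin, Nout, n_subs=ns)
            obj_fit = objective(est.m_input_, est.m_output_, est.a_, F, Nin, Nout, n_subs=ns)
            obj_truth = objective(
                np.array([3.0, 1, 1]), np.ones(3), np.zeros(3), F, Nin, Nout, n_subs=ns
            )
            assert obj_fit <= obj_truth * (1 + 1e-9)

    @pytest.mark.parametrize("m_true", [1.0, 3.0, 10.0])
    def test_multiplicative_recovery_median_within_20pct(self, m_true):
        fitted = []
        for seed in range(1, 21):
            spec = SyntheticSpec(seed=seed, m_input=(m_true, 1, 1))
            table, design, _ = generate_counts(spec)
            ft = compute_fitness(table, design)
            ft, _ = normalize_scale_shift(ft)
            params = fit_error_model(ft, table, design, FitConfig(n_bootstraps=0))
            fitted.append(params.m_input[0])
        assert abs(np.median(fitted) - m_true) <= 0.2 * m_true

    def test_manipulated_replicate_identified(self):
        """Over-dispersion injected into replicate 1 only lands on that
        replicate's input term; the others stay near the Poisson bound."""
        spec = SyntheticSpec(seed=3, m_input=(3, 1, 1))
        table, design, _ = generate_counts(spec)
        ft = compute_fitness(table, design)
        ft, _ = normalize_scale_shift(ft)
        params = fit_error_model(ft, table, design, FitConfig(n_bootstraps=0))
        assert 2.0 < params.m_input[0] < 4.0
        assert params.m_input[1] < 1.4 and params.m_input[2] < 1.4

    def test_two_replicates_split_additive_error(self):
        """With only two replicates the additive contribution cannot be
        attributed and is split roughly equally."""
        rng = np.random.default_rng(9)
        fitted = []
        for seed in range(4):
            spec = SyntheticSpec(seed=seed + 50, n_replicates=2, n_doubles=1500, depth=2e6)
            table, design, _ = generate_counts(spec)
            ft = compute_fitness(table, design)
            ft, _ = normalize_scale_shift(ft)
            # inject additive noise into replicate 1 only
            ft.fitness.iloc[:, 0] += rng.normal(0, 0.2, len(ft.fitness))
            params = fit_error_model(ft, table, design, FitConfig(n_bootstraps=0))
            fitted.append(params.a)
        a = np.array(fitted).mean(axis=0)
        assert a.sum() == pytest.approx(0.04, rel=0.35)  # total variance recovered
        assert 0.25 < a[0] / a.sum() < 0.75  # split between the two replicates

    def test_bootstrap_reproducible_and_summarized(self):
        F, Nin, Nout = _make_toy_pair(seed=2, n=200)
        est1 = DimsumErrorModel(n_bootstraps=15, random_state=7).fit(F, Nin, Nout)
        est2 = DimsumErrorModel(n_bootstraps=15, random_state=7).fit(F, Nin, Nout)
        assert np.allclose(est1.m_input_, est2.m_input_)
        params = est1.to_params(["1", "2"])
        summ = params.summary()
        assert set(summ["term"]) == {"m_input", "m_output", "a"}
        assert (summ["p5"] <= summ["p95"]).all()
        d = params.to_dict()
        assert set(d) == {"1", "2"} and "ci90" in d["1"]

    def test_single_replicate_is_error(self):
        with pytest.raises(ValueError):
            DimsumErrorModel().fit(np.zeros((5, 1)), np.ones((5, 1)), np.ones((5, 1)))


class TestPrediction:
    def test_deterministic_on_identical_counts(self):
        est = DimsumErrorModel()
        est.m_input_ = np.array([2.0, 2.0])
        est.m_output_ = np.array([1.5, 1.5])
        est.a_ = np.array([0.01, 0.01])
        v = est.predict_variance(np.array([[100.0, 100.0]]), np.array([[50.0, 50.0]]))
        assert v[0, 0] == v[0, 1] == pytest.approx(0.06, abs=1e-12)

    def test_monotone_in_m_input(self):
        base = model_variance(1.0, 1.0, 0.0, 100.0, 50.0)
        higher = model_variance(2.0, 1.0, 0.0, 100.0, 50.0)
        assert higher > base

    def test_merged_errors_reproduce_harmonic_formula(self):
        ft = make_fitness_table(
            np.array([[0.0, 0.0], [0.4, 0.6]]), variance=np.array([[0.01, 0.01], [0.02, 0.05]])
        )
        merged = merge_replicates(ft)
        assert merged.loc["v1", "variance"] == pytest.approx(1 / (1 / 0.02 + 1 / 0.05), rel=1e-12)
        assert merged.loc["v1", "fitness"] == pytest.approx(
            (0.4 / 0.02 + 0.6 / 0.05) / (1 / 0.02 + 1 / 0.05), rel=1e-12
        )

    def test_predict_variant_error_frame(self, design3, table3):
        ft = compute_fitness(table3, design3)
        rng = np.random.default_rng(0)
        est = DimsumErrorModel(n_bootstraps=0).fit(
            rng.normal(0, 0.2, (40, 3)), np.full((40, 3), 200.0), np.full((40, 3), 300.0)
        )
        frame = predict_variant_error(est.to_params(design3.replicate_ids), table3, design3)
        assert frame.shape == (len(table3), 3)
        assert (frame.to_numpy() > 0).all()
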