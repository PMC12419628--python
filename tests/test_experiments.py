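"""LHS stratification, PRCC correctness, grid and factorial harnesses."""

import numpy as np
import pytest
from scipy.stats import kstest, rankdata

import lhnabm as L
from lhnabm.experiments import LHN_PRESETS, prcc, prcc_bootstrap_ci
from lhnabm.params import ParamRange


class TestLHS:
    def test_one_sample_per_stratum(self):
        r = ParamRange("patient_network_edges", 0.0, 1.0)
        design = L.lhs_sample([r], 10, seed=3)
        v = np.sort(design.values["patient_network_edges"].to_numpy())
        assert np.all((v >= np.arange(10) / 10) & (v < (np.arange(10) + 1) / 10))

    def test_values_within_ranges(self, ranges):
        design = L.lhs_sample(ranges, 50, seed=1)
        for r in ranges:
            col = design.values[r.name]
            assert col.min() >= r.lower and col.max() <= r.upper

    def test_triangle_mean_matches_moment_oracle(self):
        # triangle(0, 1, mode 0.5) has mean 0.5
        r = ParamRange("patient_network_edges", 0.0, 1.0, dist="triangle", mode=0.5)
        design = L.lhs_sample([r], 10_000, seed=5)
        v = design.values["patient_network_edges"].to_numpy()
        se = np.sqrt(1 / 24) / 100  # var of this triangle is 1/24
        assert abs(v.mean() - 0.5) < 3 * se

    def test_marginals_pass_ks_against_target(self):
        ru = ParamRange("patient_network_edges", 2.0, 8.0)
        rt = ParamRange("clinician_network_edges", 0.0, 4.0, dist="triangle", mode=1.0)
        design = L.lhs_sample([ru, rt], 10_000, seed=9)
        u = design.values["patient_network_edges"].to_numpy()
        assert kstest(u, lambda x: (x - 2) / 6).pvalue > 0.001
        t = design.values["clinician_network_edges"].to_numpy()

        def tri_cdf(x):
            x = np.asarray(x, dtype=float)
            return np.where(x < 1.0, x ** 2 / 4, 1 - (4 - x) ** 2 / 12)

        assert kstest(t, tri_cdf).pvalue > 0.001


def _prcc_bruteforce(x, y):
    """Independent oracle: explicit rank regression via normal equations."""
    rx = rankdata(x, axis=0)
    ry = rankdata(y)
    n, p = rx.shape
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(rx, j, axis=1)])
        gram = others.T @ others
        bx = np.linalg.solve(gram, others.T @ rx[:, j])
        by = np.linalg.solve(gram, others.T @ ry)
        ex = rx[:, j] - others @ bx
        ey = ry - others @ by
        out[j] = np.corrcoef(ex, ey)[0, 1]
    return out


class TestPRCC:
    def test_agrees_with_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.random((50, 5))
            y = rng.random(50)
            assert np.allclose(prcc(x, y), _prcc_bruteforce(x, y), atol=1e-10)

    def test_exact_unity_for_rank_monotone_single_driver(self):
        rng = np.random.default_rng(1)
        x = rng.random((200, 4))
        y = np.exp(x[:, 0])           # strictly increasing in x0 only
        coef = prcc(x, y)
        assert coef[0] == pytest.approx(1.0, abs=1e-12)

    def test_null_columns_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.random((1000, 4))
        y = rng.random(1000)
        assert np.all(np.abs(prcc(x, y)) < 0.1)   # ~3/sqrt(n) scale

    def test_sign_recovery_on_constructed_data(self):
        rng = np.random.default_rng(3)
        x = rng.random((500, 3))
        y = np.sqrt(x[:, 0]) - x[:, 1] ** 3 + 0.1 * rng.random(500)
        coef = prcc(x, y)
        assert coef[0] > 0 > coef[1]
        assert abs(coef[2]) < 0.2

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(4)
        x = rng.random((300, 4))
        y = x[:, 0] - x[:, 2] + 0.5 * rng.random(300)
        base = prcc(x, y)
        xt = x.copy()
        xt[:, 0] = np.exp(5 * xt[:, 0])
        xt[:, 2] = np.log(xt[:, 2] + 1e-9)
        assert np.allclose(prcc(xt, np.sqrt(y - y.min())), base, atol=1e-12)

    def test_constant_outcome_flagged_not_zero(self):
        rng = np.random.default_rng(5)
        x = rng.random((50, 3))
        with pytest.warns(UserWarning, match="constant"):
            coef = prcc(x, np.ones(50))
        assert np.isnan(coef).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            prcc(np.random.default_rng(0).random((5, 5)), np.arange(5))


class TestBootstrapCI:
    def test_exact_driver_ci_collapses(self):
        rng = np.random.default_rng(6)
        x = rng.random((100, 3))
        y = 2 * x[:, 0] ** 3
        res = prcc_bootstrap_ci(x, y, n_boot=30, seed=1)
        assert res.ci_lo[0] == pytest.approx(1.0, abs=1e-9)
        assert res.ci_hi[0] == pytest.approx(1.0, abs=1e-9)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(7)
        x = rng.random((150, 4))
        y = x[:, 0] - 0.5 * x[:, 1] + 0.3 * rng.random(150)
        res = prcc_bootstrap_ci(x, y, n_boot=50, seed=2)
        assert np.all(res.ci_lo <= res.coefficients + 1e-12)
        assert np.all(res.ci_hi >= res.coefficients - 1e-12)

    def test_bonferroni_level(self):
        rng = np.random.default_rng(8)
        x = rng.random((100, 4))
        res = prcc_bootstrap_ci(x, rng.random(100), n_boot=20, seed=3)
        assert res.alpha == pytest.approx(0.05 / 4)

    def test_ci_covers_large_n_oracle(self):
        """Percentile CIs cover a brute-force large-n PRCC most of the time."""
        big = np.random.default_rng(100)
        xb = big.random((20_000, 3))
        yb = xb[:, 0] - xb[:, 1] + big.normal(0, 0.3, 20_000)
        truth = _prcc_bruteforce(xb, yb)
        covered = 0
        reps = 25
        for k in range(reps):
            rng = np.random.default_rng(200 + k)
            x = rng.random((400, 3))
            y = x[:, 0] - x[:, 1] + rng.normal(0, 0.3, 400)
            res = prcc_bootstrap_ci(x, y, n_boot=100, seed=k)
            covered += np.all((res.ci_lo <= truth) & (truth <= res.ci_hi))
        assert covered / reps >= 0.9


@pytest.fixture(scope="module")
def small_template():
    return L.ScenarioConfig(n_care_centers=2, clinicians_per_center=2,
                            patients_per_clinician=5, horizon_steps=52)


class TestSensitivityHarness:
    def test_smoke_run_shape(self, ranges, small_template):
        res = L.run_sensitivity(ranges, n_samples=40, template=small_template,
                                seed=5, n_boot=10)
        assert res.n_failed == 0
        for name in ("health", "praxis", "knowledge"):
            assert len(res.prcc[name].coefficients) == 30
        assert len(res.design) == 40
        assert set(res.design.columns) >= {"health", "praxis", "knowledge", "row_seed"}

    def test_fewer_encounters_reduce_iri_and_praxis(self, ranges, small_template):
        """Longer encounter periods starve the encounter-fed IRI stock."""
        outs = []
        for period in (4, 26):
            s = small_template.replace(params=small_template.params.replace(
                encounter_period=period))
            vals = [L.compute_outcomes(L.simulate(s.replace(seed=30 + k))).praxis
                    for k in range(8)]
            outs.append(np.mean(vals))
        assert outs[0] > outs[1]


class TestGrid:
    def test_two_increment_grid_hits_range_corners(self, ranges, small_template):
        res = L.grid_explore("selection_efficiency_maximum",
                             "evaluation_accuracy_minimum_praxis",
                             ranges, n_increments=2, template=small_template,
                             seed=2, replicates_per_cell=1)
        assert res.mean.shape == (2, 2)
        assert list(res.x_values) == [10.0, 1000.0]
        assert list(res.y_values) == [0.001, 0.5]
        assert len(res.to_frame()) == 4

    def test_cell_count_matches_increments(self, ranges, small_template):
        res = L.grid_explore("selection_efficiency_maximum",
                             "shared_knowledge_half_life", ranges,
                             n_increments=3, template=small_template,
                             seed=2, replicates_per_cell=1)
        assert res.to_frame().shape[0] == 9
        assert np.isfinite(res.mean).all()

    def test_same_parameter_twice_rejected(self, ranges):
        with pytest.raises(ValueError):
            L.grid_explore("encounter_period", "encounter_period", ranges)

    def test_half_life_monotone_on_knowledge_grid(self, ranges, small_template):
        """Knowledge rises along the half-life axis, paired seeds, 3-SE slack."""
        res = L.grid_explore("shared_knowledge_half_life",
                             "patient_influence_activation_probability",
                             ranges, n_increments=3, outcome="knowledge",
                             template=small_template, seed=4, replicates_per_cell=4)
        se = res.sd / np.sqrt(res.n_replicates)
        diffs = np.diff(res.mean, axis=1)
        slack = 3 * np.sqrt(se[:, 1:] ** 2 + se[:, :-1] ** 2)
        assert np.all(diffs > -slack)


class TestFactorial:
    def test_27_cells_with_preset_parameters(self, small_template):
        res = L.factorial_experiment(template=small_template, preset="accurate-eval",
                                     n_replicates=2, seed=3)
        assert len(res.table) == 27
        assert set(res.table.lhn) == {"low", "medium", "high"}
        assert res.table.n.eq(2).all()

    def test_preset_values(self):
        assert LHN_PRESETS["accurate-eval"]["low"] == (10.0, 0.001)
        assert LHN_PRESETS["accurate-eval"]["high"] == (1000.0, 0.01)
        assert LHN_PRESETS["graded-eval"]["medium"] == (200.0, 0.10)

    def test_unknown_preset_rejected(self, small_template):
        with pytest.raises(ValueError, match="preset"):
            L.factorial_experiment(template=small_template, preset="huge")

    def test_missing_level_rejected(self, small_template):
        with pytest.raises(ValueError, match="high"):
            L.factorial_experiment(template=small_template,
                                   levels={"low": (10, 0.1), "medium": (100, 0.1)})
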