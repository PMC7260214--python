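import numpy as np
import pandas as pd
import pytest

from methylkin.error_models import ErrorModelSpec
from methylkin.model_core import ModelConfig, build_trace_bank
from methylkin.rate_inference import (
    CpGTimeCourse,
    ReplicateFit,
    UnfittableError,
    build_grid,
    combine_replicates,
    credible_interval,
    filter_counts,
    fit_replicate,
    infer_rates,
    is_identifiable,
    summarize_replicate,
)
from methylkin.synthetic_data import SyntheticCohortSpec, simulate_counts


class TestBuildGrid:
    def test_default_dimensions(self, grid):
        assert grid.n == 80
        assert grid.n_combos == 6400
        assert grid.combos.shape == (6400, 2)

    def test_three_orders_of_magnitude(self, grid):
        assert grid.values[0] == 2.0
        assert grid.values[-1] == pytest.approx(2.0 / 1.1**79)
        assert grid.values[-1] == pytest.approx(1.07e-3, rel=1e-2)

    def test_constant_ratio(self, grid):
        ratios = grid.values[:-1] / grid.values[1:]
        np.testing.assert_allclose(ratios, 1.1, rtol=1e-12)

    def test_combo_layout(self, grid):
        idx = grid.combo_index(3, 7)
        assert grid.combos[idx, 0] == grid.values[3]  # k_de
        assert grid.combos[idx, 1] == grid.values[7]  # k_me

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_grid(ModelConfig(grid_step_factor=0.9))


def _counts_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["cpg_id", "chrom", "pos", "condition", "replicate", "day",
                 "coverage", "meth_count"],
    )


def _full_cpg(cpg_id, pos, coverage=200, days=(0, 4, 8, 10, 13, 17, 29), reps=(1,)):
    rows = []
    for r in reps:
        for d in days:
            rows.append((cpg_id, "chr1", pos, "cre", r, d, coverage, coverage // 2))
    return rows


class TestFilterCounts:
    def test_amplicon_low_coverage_midcourse_retained(self):
        rows = _full_cpg("a", 100)
        # drop day-8 row to 99x: becomes NA but CpG is retained
        rows = [
            (c, ch, p, cond, r, d, 99 if d == 8 else cov, m // 2 if d == 8 else m)
            for (c, ch, p, cond, r, d, cov, m) in rows
        ]
        out = filter_counts(_counts_frame(rows), "amplicon")
        assert set(out["cpg_id"]) == {"a"}
        assert 8 not in set(out["day"])

    def test_amplicon_low_coverage_day0_dropped(self):
        rows = _full_cpg("a", 100)
        rows = [
            (c, ch, p, cond, r, d, 99 if d == 0 else cov, m)
            for (c, ch, p, cond, r, d, cov, m) in rows
        ]
        out = filter_counts(_counts_frame(rows), "amplicon")
        assert out.empty

    def test_amplicon_two_nas_dropped(self):
        rows = _full_cpg("a", 100)
        rows = [
            (c, ch, p, cond, r, d, 50 if d in (8, 13) else cov, m)
            for (c, ch, p, cond, r, d, cov, m) in rows
        ]
        out = filter_counts(_counts_frame(rows), "amplicon")
        assert out.empty

    def test_sureselect_low_coverage_dropped(self):
        rows = _full_cpg("a", 100, coverage=60, reps=(1, 2))
        rows[10] = ("a", "chr1", 100, "cre", 2, 13, 49, 20)
        rows += _full_cpg("b", 200, coverage=60, reps=(1, 2))
        out = filter_counts(_counts_frame(rows), "sureselect")
        assert set(out["cpg_id"]) == {"b"}

    def test_unknown_assay(self):
        with pytest.raises(ValueError):
            filter_counts(_counts_frame(_full_cpg("a", 1)), "wgbs")


class TestFitReplicate:
    def test_self_consistency_on_grid_combo(self, grid, bank, bb_error):
        # pseudo-counts from a grid combo recover that combo as the MLE
        idx = grid.combo_index(25, 25)  # k_de = k_me ~ 0.183
        n = np.full(7, 3997.0)
        c = np.rint(3997 * bank[idx])
        post = fit_replicate(n, c, bank, bb_error, grid)
        assert post.mle_index == idx

    def test_posterior_normalized(self, grid, bank, bb_error):
        n = np.full(7, 500.0)
        c = np.rint(500 * bank[1000])
        post = fit_replicate(n, c, bank, bb_error, grid)
        assert post.joint.sum() == pytest.approx(1.0, abs=1e-9)
        assert post.marginal_de.sum() == pytest.approx(1.0, abs=1e-9)
        assert post.marginal_me.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(post.joint >= 0)

    def test_na_timepoints_skipped(self, grid, bank, bb_error):
        idx = grid.combo_index(30, 30)
        n = np.full(7, 3997.0)
        c = np.rint(3997 * bank[idx])
        n_masked, c_masked = n.copy(), c.copy()
        n_masked[3] = np.nan
        c_masked[3] = np.nan
        post = fit_replicate(n_masked, c_masked, bank, bb_error, grid)
        keep = np.ones(7, dtype=bool)
        keep[3] = False
        direct = fit_replicate(
            n[keep], c[keep], bank[:, keep], bb_error, grid
        )
        np.testing.assert_allclose(post.joint, direct.joint, atol=1e-12)

    def test_too_few_timepoints(self, grid, bank, bb_error):
        n = np.full(7, np.nan)
        n[0] = 100.0
        c = np.full(7, np.nan)
        c[0] = 50.0
        with pytest.raises(UnfittableError):
            fit_replicate(n, c, bank, bb_error, grid)

    def test_flat_half_with_low_rates_has_wide_marginals(self, grid, bank, bb_error):
        # constant 50% data: turnover magnitude is poorly constrained
        n = np.full(7, 3997.0)
        c = np.full(7, np.rint(3997 * 0.5))
        post = fit_replicate(n, c, bank, bb_error, grid)
        ci_de = credible_interval(post.marginal_de, grid.values, 0.95)
        sharp = fit_replicate(n, np.rint(3997 * bank[grid.combo_index(25, 25)]),
                              bank, bb_error, grid)
        ci_sharp = credible_interval(sharp.marginal_de, grid.values, 0.95)
        assert ci_de.width_log10 > ci_sharp.width_log10

    def test_timepoint_order_invariance(self, grid, bank, bb_error, rng):
        idx = 3000
        n = np.full(7, 800.0)
        c = np.rint(800 * bank[idx])
        perm = rng.permutation(7)
        post = fit_replicate(n, c, bank, bb_error, grid)
        post_perm = fit_replicate(n[perm], c[perm], bank[:, perm], bb_error, grid)
        np.testing.assert_allclose(post.joint, post_perm.joint, atol=1e-12)

    def test_binomial_large_n_converges_to_nearest_grid_point(self, grid, bank,
                                                              binom_error, config):
        from methylkin.model_core import RateParams, expected_trace

        # off-grid truth: MLE lands on the nearest grid values
        k_de_true, k_me_true = 0.21, 0.34
        tr = expected_trace(RateParams(k_me=k_me_true, k_de=k_de_true), config)
        n = np.full(7, 2_000_000.0)
        c = np.rint(n * tr.levels)
        post = fit_replicate(n, c, bank, binom_error, grid)
        k_de_hat, k_me_hat = post.mle
        assert k_de_hat == grid.values[grid.nearest_index(k_de_true)]
        assert k_me_hat == grid.values[grid.nearest_index(k_me_true)]


class TestCredibleInterval:
    def test_point_mass_zero_width(self, grid):
        m = np.zeros(80)
        m[37] = 1.0
        ci = credible_interval(m, grid.values, 0.95)
        assert ci.lo_index == ci.hi_index == 37
        assert ci.width_log10 == 0.0

    def test_uniform_retains_76_points(self, grid):
        m = np.full(80, 1 / 80)
        ci = credible_interval(m, grid.values, 0.95)
        assert ci.hi_index - ci.lo_index + 1 == 76

    def test_contains_marginal_mode(self, grid, rng):
        for _ in range(20):
            center = rng.integers(5, 75)
            x = np.arange(80.0)
            m = np.exp(-0.5 * ((x - center) / rng.uniform(1, 10)) ** 2)
            m /= m.sum()
            ci = credible_interval(m, grid.values, 0.95)
            assert ci.lo_index <= np.argmax(m) <= ci.hi_index

    def test_invalid_level(self, grid):
        with pytest.raises(ValueError):
            credible_interval(np.full(80, 1 / 80), grid.values, 1.5)


class TestIdentifiability:
    def _point_posterior(self, grid, de_idx, me_idx, bank, bb_error):
        n = np.full(7, 3997.0)
        c = np.rint(3997 * bank[grid.combo_index(de_idx, me_idx)])
        return fit_replicate(n, c, bank, bb_error, grid)

    def test_interior_point_identifiable(self, grid, bank, bb_error):
        post = self._point_posterior(grid, 40, 40, bank, bb_error)
        assert is_identifiable(post, 0.08)

    def test_border_mass_rule(self, grid):
        from methylkin.rate_inference import PosteriorGrid

        joint = np.zeros((80, 80))
        joint[40, -1] = 0.1  # 0.1 mass at the k_me lower border
        joint[40, 40] = 0.9
        post = PosteriorGrid(
            grid=grid, joint=joint.ravel() / joint.sum(),
            log_like=np.zeros(6400), mle_index=grid.combo_index(40, 40),
        )
        assert not is_identifiable(post, 0.08)
        assert not is_identifiable(post, 0.05)
        assert is_identifiable(post, 0.15)


class TestCombineReplicates:
    def test_identical_replicates(self):
        f = ReplicateFit(k_de=0.3, k_me=0.2, ci_de_log10=0.6, ci_me_log10=0.9,
                         identifiable=True)
        est = combine_replicates([f, f, f])
        assert est.k_de_hat == 0.3
        assert est.ci_de == pytest.approx(0.6 / np.sqrt(3))
        assert est.ci_me == pytest.approx(0.9 / np.sqrt(3))
        assert est.identifiable

    def test_median_rates(self):
        fits = [
            ReplicateFit(k_de=r, k_me=r, ci_de_log10=0.1, ci_me_log10=0.1,
                         identifiable=True)
            for r in (0.1, 0.2, 0.4)
        ]
        assert combine_replicates(fits).k_de_hat == pytest.approx(0.2)

    def test_any_unidentifiable_replicate_fails(self):
        good = ReplicateFit(0.3, 0.2, 0.1, 0.1, True)
        bad = ReplicateFit(0.3, 0.2, 0.1, 0.1, False)
        assert not combine_replicates([good, bad, good]).identifiable

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_replicates([])


class TestInferRates:
    def test_end_to_end_recovery(self, config, grid, bb_error):
        rates = pd.DataFrame(
            {
                "cpg_id": ["x1", "x2"],
                "chrom": "chr1",
                "pos": [100, 200],
                "k_de": [grid.values[30], grid.values[45]],
                "k_me": [grid.values[35], grid.values[20]],
            }
        )
        spec = SyntheticCohortSpec(n_cpgs=2, coverage=4000, replicates=3, seed=5)
        table = simulate_counts(rates, spec, config, bb_error)
        est = infer_rates(table, config, bb_error)
        assert len(est) == 2
        assert set(est.columns) >= {
            "cpg_id", "chrom", "pos", "k_me", "k_de", "ci_me_log10",
            "ci_de_log10", "steady_state", "identifiable",
        }
        merged = est.merge(rates, on="cpg_id", suffixes=("_hat", "_true"))
        for _, row in merged.iterrows():
            assert abs(np.log10(row.k_de_hat / row.k_de_true)) < 3 * np.log10(1.1)
            assert abs(np.log10(row.k_me_hat / row.k_me_true)) < 3 * np.log10(1.1)
        assert est["steady_state"].between(0, 1).all()
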