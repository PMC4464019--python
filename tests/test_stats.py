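"""Ensemble statistics against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajstat import (
    BinningSpec,
    Ensemble,
    TimeGrid,
    Trajectory,
    ensemble_mean,
    ensemble_sd,
    gaussian_fit,
    master_equation,
    pdf_at,
    pdf_multi,
    phase_space,
    phase_space_avg,
    summary,
    total_variation,
    total_variation_from_pmf,
)
from trajstat.errors import ParameterError, VariableNameError

from conftest import random_ensemble


def constant_ensemble(levels, t_last=10.0):
    return Ensemble(
        [
            Trajectory([0.0, t_last], [[lv], [lv]], ["X"])
            for lv in levels
        ]
    )


class TestMeanSd:
    def test_mean_of_two_constant_runs(self):
        ens = constant_ensemble([4.0, 6.0])
        mean = ensemble_mean(ens, TimeGrid(0.0, 10.0, 5))
        assert np.array_equal(mean.column("X"), np.full(5, 5.0))

    def test_single_run_mean_is_the_run_itself(self, rng):
        ens = random_ensemble(rng, n_runs=1)
        grid = TimeGrid(0.0, ens.t_last, 9)
        mean = ensemble_mean(ens, grid)
        assert mean.equals(ens[0].resampled(grid))

    def test_identical_runs_have_zero_sd(self):
        ens = constant_ensemble([4.0, 4.0, 4.0])
        sd = ensemble_sd(ens, TimeGrid(0.0, 10.0, 4))
        assert np.array_equal(sd.column("X"), np.zeros(4))

    def test_population_convention(self):
        # sqrt(((4-5)^2 + (6-5)^2) / 2) = 1
        ens = constant_ensemble([4.0, 6.0])
        sd = ensemble_sd(ens, TimeGrid(0.0, 10.0, 3))
        assert np.array_equal(sd.column("X"), np.ones(3))
        unbiased = ensemble_sd(ens, TimeGrid(0.0, 10.0, 3), unbiased=True)
        assert np.allclose(unbiased.column("X"), np.sqrt(2.0))

    def test_mean_sd_match_naive_double_loop(self, rng):
        """Vectorised mean/SD equal an independent per-run per-point loop."""
        ens = random_ensemble(rng, n_runs=10)
        grid = TimeGrid(0.0, ens.t_last, 13)
        mean = ensemble_mean(ens, grid)
        sd = ensemble_sd(ens, grid)
        for vi, var in enumerate(ens.var_names):
            for pi, t in enumerate(grid.points):
                samples = [tr.sample_at(t, var) for tr in ens]
                m = sum(samples) / len(samples)
                v = sum((s - m) ** 2 for s in samples) / len(samples)
                assert abs(mean.values[pi, vi] - m) < 1e-12
                assert abs(sd.values[pi, vi] - np.sqrt(v)) < 1e-12


class TestGaussianFit:
    @pytest.mark.parametrize(
        "samples, mu, sigma2",
        [
            ([0.0, 0.0], 0.0, 0.0),
            ([2.0, 4.0], 3.0, 1.0),
            ([1.0, 2.0, 3.0, 4.0], 2.5, 1.25),
        ],
    )
    def test_closed_form_exact(self, samples, mu, sigma2):
        fit = gaussian_fit(samples)
        assert fit.mu == mu
        assert fit.sigma2 == sigma2

    def test_unbiased_switch(self):
        fit = gaussian_fit([2.0, 4.0], unbiased=True)
        assert fit.mu == 3.0
        assert fit.sigma2 == 2.0

    def test_large_sample_recovery(self):
        """MLE converges to the true parameters on a large normal sample."""
        rng = np.random.default_rng(12345)
        draws = rng.normal(5.0, 2.0, size=100_000)
        fit = gaussian_fit(draws)
        assert abs(fit.mu - 5.0) < 0.05
        assert abs(fit.sigma2 - 4.0) < 0.1

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_fit([])


class TestPdf:
    def test_counting(self):
        ens = constant_ensemble([1.0, 1.0, 2.0, 2.0])
        est = pdf_at(ens, 5.0, "X")
        assert np.array_equal(est.bin_edges, [0.5, 1.5, 2.5])
        assert np.array_equal(est.mass, [0.5, 0.5])
        assert est.sample_min == 1.0 and est.sample_max == 2.0

    def test_degenerate_range_single_bin(self):
        ens = constant_ensemble([7.0, 7.0, 7.0])
        est = pdf_at(ens, 1.0, "X")
        assert np.array_equal(est.bin_edges, [6.5, 7.5])
        assert np.array_equal(est.mass, [1.0])

    def test_counts_mode(self):
        ens = constant_ensemble([1.0, 1.0, 2.0, 2.0])
        est = pdf_at(ens, 5.0, "X", normed=False)
        assert est.kind == "counts"
        assert np.array_equal(est.mass, [2.0, 2.0])

    def test_density_mode_integrates_to_one(self, rng):
        ens = random_ensemble(rng, n_runs=40, n_vars=1)
        est = pdf_at(ens, 5.0, "S0", bins=BinningSpec(n_bins=7), density=True)
        assert abs(float(np.sum(est.mass * est.bin_widths)) - 1.0) < 1e-12

    def test_fit_attached_and_matches_samples(self, rng):
        ens = random_ensemble(rng, n_runs=25, n_vars=1)
        est = pdf_at(ens, 3.0, "S0", fit=True)
        samples = ens.samples_at(3.0, "S0")
        assert est.fit is not None
        assert est.fit.mu == pytest.approx(samples.mean(), abs=1e-12)
        assert est.fit.sigma2 == pytest.approx(samples.var(), abs=1e-12)

    def test_edge_values_go_right_and_last_bin_closed(self):
        ens = constant_ensemble([0.0, 1.0, 2.0])
        est = pdf_at(ens, 1.0, "X", bins=BinningSpec(n_bins=2, integer_aligned=False))
        # edges [0, 1, 2]: the value 1.0 belongs to the right bin; 2.0 is
        # included by the closed last bin
        assert np.array_equal(est.bin_edges, [0.0, 1.0, 2.0])
        assert np.array_equal(est.mass, [1 / 3, 2 / 3])

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1), n_bins=st.integers(1, 40))
    def test_normalization_property(self, seed, n_bins):
        """Every mass-normalised histogram sums to 1 regardless of binning."""
        rng = np.random.default_rng(seed)
        ens = random_ensemble(rng, n_runs=8, n_vars=1)
        est = pdf_at(ens, 4.0, "S0", bins=BinningSpec(n_bins=n_bins))
        assert abs(float(est.mass.sum()) - 1.0) < 1e-12


class TestPdfMulti:
    def test_repeated_time_gives_identical_estimates(self, rng):
        ens = random_ensemble(rng, n_runs=10, n_vars=1)
        a, b = pdf_multi(ens, [4.0, 4.0], "S0")
        assert np.array_equal(a.bin_edges, b.bin_edges)
        assert np.array_equal(a.mass, b.mass)

    def test_shared_edges_across_times(self, rng):
        ens = random_ensemble(rng, n_runs=10, n_vars=1)
        ests = pdf_multi(ens, [1.0, 4.0, 8.0], "S0")
        for est in ests[1:]:
            assert np.array_equal(est.bin_edges, ests[0].bin_edges)

    def test_constant_ensemble_two_times(self):
        ens = constant_ensemble([3.0, 3.0])
        a, b = pdf_multi(ens, [1.0, 9.0], "X")
        assert np.array_equal(a.mass, [1.0])
        assert np.array_equal(b.mass, [1.0])


class TestMasterEquation:
    def test_constant_ensemble_concentrates_in_one_bin(self):
        ens = constant_ensemble([5.0, 5.0, 5.0])
        meq = master_equation(ens, "X", 0.0, 10.0, 6)
        assert meq.prob.shape == (6, 1)
        assert np.array_equal(meq.prob, np.ones((6, 1)))

    def test_rows_sum_to_one(self, rng):
        ens = random_ensemble(rng, n_runs=15, n_vars=1)
        meq = master_equation(ens, "S0", 0.0, 8.0, 20)
        assert np.allclose(meq.prob.sum(axis=1), 1.0, atol=1e-12)

    def test_start_must_precede_stop(self, rng):
        ens = random_ensemble(rng, n_runs=3)
        with pytest.raises(ParameterError):
            master_equation(ens, "S0", 5.0, 5.0, 10)

    def test_monotone_refinement(self, rng):
        """Refining the time grid never changes slices at shared grid times."""
        ens = random_ensemble(rng, n_runs=12, n_vars=1)
        bins = BinningSpec(n_bins=10, range=(0.0, 30.0))
        coarse = master_equation(ens, "S0", 0.0, 8.0, 5, bins)
        fine = master_equation(ens, "S0", 0.0, 8.0, 9, bins)  # supergrid
        assert np.array_equal(fine.prob[::2], coarse.prob)


class TestPhaseSpace:
    def test_projection_round_trip(self, toy_traj):
        path = phase_space(toy_traj, ["A", "B"])
        for k in range(len(toy_traj)):
            assert path.points[k, 0] == toy_traj.values[k, 0]
            assert path.points[k, 1] == toy_traj.values[k, 1]

    def test_column_order_follows_request(self, rng):
        from conftest import random_step_trajectory

        traj = random_step_trajectory(rng, n_vars=3)
        path = phase_space(traj, ["S2", "S0"])
        assert np.array_equal(path.points[:, 0], traj.column("S2"))
        assert np.array_equal(path.points[:, 1], traj.column("S0"))

    def test_constant_trajectory_collapses_to_a_point(self):
        traj = Trajectory([0.0, 1.0], [[2.0, 3.0], [2.0, 3.0]], ["A", "B"])
        path = phase_space(traj, ["A", "B"])
        assert np.array_equal(path.points, [[2.0, 3.0], [2.0, 3.0]])

    def test_duplicate_or_unknown_names_rejected(self, toy_traj):
        with pytest.raises(VariableNameError):
            phase_space(toy_traj, ["A", "A"])
        with pytest.raises(VariableNameError):
            phase_space(toy_traj, ["A", "Z"])
        with pytest.raises(ParameterError):
            phase_space(toy_traj, ["A"])

    def test_avg_composes_mean_and_projection(self, rng):
        """phase_space_avg equals composing the two public operations."""
        ens = random_ensemble(rng, n_runs=6, n_vars=3)
        grid = TimeGrid(0.0, ens.t_last, 11)
        composed = phase_space(ensemble_mean(ens, grid), ["S0", "S2"])
        direct = phase_space_avg(ens, grid, ["S0", "S2"])
        assert np.array_equal(direct.points, composed.points)
        assert np.array_equal(direct.times, composed.times)

    def test_single_run_ensemble(self, rng):
        ens = random_ensemble(rng, n_runs=1, n_vars=2)
        grid = TimeGrid(0.0, ens.t_last, 7)
        direct = phase_space_avg(ens, grid, ["S0", "S1"])
        member = phase_space(ens[0].resampled(grid), ["S0", "S1"])
        assert np.array_equal(direct.points, member.points)


class TestSummary:
    def test_constant_run(self):
        ens = constant_ensemble([4.0])
        summ = summary(ens)
        assert summ.minima["X"] == 4.0 and summ.maxima["X"] == 4.0
        assert summ.n_runs == 1

    def test_temporal_span(self):
        a = Trajectory([0.0, 10.0], [[1.0], [1.0]], ["X"])
        b = Trajectory([3.0, 7.0], [[2.0], [2.0]], ["X"])
        summ = summary(Ensemble([a, b]))
        assert summ.t_first == 0.0 and summ.t_last == 10.0

    def test_matches_flat_scan(self, rng):
        ens = random_ensemble(rng, n_runs=7, n_vars=3)
        summ = summary(ens)
        for vi, var in enumerate(ens.var_names):
            flat = np.concatenate([tr.values[:, vi] for tr in ens])
            assert summ.minima[var] == flat.min()
            assert summ.maxima[var] == flat.max()


class TestBinning:
    def test_auto_integer_alignment(self):
        edges = BinningSpec().resolve_edges(np.array([1.0, 2.0, 5.0]))
        assert np.array_equal(edges, [0.5, 1.5, 2.5, 3.5, 4.5, 5.5])

    def test_auto_continuous_falls_back_to_30_bins(self):
        edges = BinningSpec().resolve_edges(np.array([0.25, 7.6, 3.3]))
        assert edges.size == 31
        assert edges[0] == 0.25 and edges[-1] == 7.6

    def test_explicit_range(self):
        edges = BinningSpec(n_bins=4, range=(0.0, 8.0)).resolve_edges(
            np.array([3.0, 5.0])
        )
        assert np.array_equal(edges, [0.0, 2.0, 4.0, 6.0, 8.0])

    def test_invalid_specs(self):
        with pytest.raises(ParameterError):
            BinningSpec(n_bins=0)
        with pytest.raises(ParameterError):
            BinningSpec(range=(2.0, 1.0))


class TestTotalVariation:
    def test_identical_pmfs_have_zero_distance(self):
        assert total_variation([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint_pmfs_have_distance_one(self):
        assert total_variation([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_binned_pmf_comparison_recovers_zero(self):
        """A histogram built exactly from a pmf has zero TV distance to it."""
        from scipy import stats as ss

        lam = 4.0
        support = np.arange(0, 16)
        pmf = ss.poisson.pmf(support, lam)
        from trajstat import DensityEstimate

        est = DensityEstimate(
            var_name="X",
            time=1.0,
            bin_edges=np.arange(-0.5, 16.0, 1.0),
            mass=pmf / pmf.sum(),
            kind="mass",
            n_samples=1,
            sample_min=0.0,
            sample_max=15.0,
        )
        tv = total_variation_from_pmf(est, lambda k: ss.poisson.pmf(k, lam))
        # the only discrepancy is the renormalised truncated tail
        assert tv < 1e-4
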