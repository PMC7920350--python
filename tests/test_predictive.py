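"""Posterior-predictive summaries, CrI coverage, distance profiles,
power-law fits and the OD symmetry statistic."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mobfit.flows import FlowMatrix, ModelParams
from mobfit.inference import Chain, ConvergenceResult, PosteriorChains
from mobfit.likelihood import FlowDataset
from mobfit.model import MobilityModel, MobilityResults
from mobfit.predictive import (
    DistanceProfile,
    cri_coverage,
    distance_profile,
    posterior_predictive_flows,
    powerlaw_fit,
    symmetry_statistic,
)
from mobfit.spatial import SpatialSystem
from mobfit.synthetic import CLUSTERED, scenario_dataset


def admin_system(pops, coords):
    coords = np.asarray(coords, dtype=float)
    return SpatialSystem(scale="admin", x=coords[:, 0], y=coords[:, 1],
                         population=np.asarray(pops, dtype=float),
                         admin_id=np.arange(1, len(pops) + 1))


def results_with_draws(model: MobilityModel, draws: np.ndarray) -> MobilityResults:
    """Wrap fixed parameter draws as a fitted-results object."""
    half = len(draws) // 2
    chains = [
        Chain(draws=draws[:half], loglik=np.zeros(half), accept_rate=0.3,
              proposal_scales=np.ones(draws.shape[1])),
        Chain(draws=draws[half:], loglik=np.zeros(len(draws) - half),
              accept_rate=0.3, proposal_scales=np.ones(draws.shape[1])),
    ]
    conv = ConvergenceResult(rhat={n: 1.0 for n in model.param_names},
                             converged_from=0, converged=True)
    post = PosteriorChains(chains=chains, param_names=model.param_names,
                           convergence=conv)
    return MobilityResults(model, post)


@pytest.fixture
def gm_setup():
    system = admin_system([1000, 2000, 1500, 800],
                          [(0, 0), (50_000, 0), (0, 80_000), (60_000, 60_000)])
    truth = np.array([-2.0, 1.1, 0.9, 3.0, 2.0, 0.5])
    rows = [(i, j, 5 + 10 * i + j) for i in range(1, 5) for j in range(1, 5) if i != j]
    data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                       directional=True, has_diagonal=False)
    model = MobilityModel(data, system, model="GM", symmetrised=False)
    return model, truth


class TestPosteriorPredictive:
    def test_degenerate_posterior_zero_width(self, gm_setup):
        model, truth = gm_setup
        res = results_with_draws(model, np.tile(truth, (50, 1)))
        summary = posterior_predictive_flows(res, n_draws=40, seed=1)
        assert np.allclose(summary.table["lo95"], summary.table["hi95"])
        expect = model._objective.admin_means(truth)
        np.testing.assert_allclose(summary.table["mean"], expect, rtol=1e-12)

    def test_two_distinct_draws_average(self, gm_setup):
        model, truth = gm_setup
        other = truth + np.array([0.1, 0, 0, 0, 0, 0])
        draws = np.vstack([truth, other])
        res = results_with_draws(model, draws)
        summary = posterior_predictive_flows(res, n_draws=2, seed=2)
        expect = 0.5 * (model._objective.admin_means(truth)
                        + model._objective.admin_means(other))
        np.testing.assert_allclose(summary.table["mean"], expect, rtol=1e-12)

    def test_quantiles_match_sorting_oracle(self, gm_setup):
        model, truth = gm_setup
        rng = np.random.default_rng(3)
        draws = truth + rng.normal(0, 0.02, size=(100, 6))
        res = results_with_draws(model, draws)
        summary = posterior_predictive_flows(res, n_draws=100, seed=4)
        sims = np.stack([model._objective.admin_means(d) for d in draws])
        # with n_draws == all retained draws, sampling w/o replacement uses
        # every draw: quantiles must equal the per-pair direct quantiles
        np.testing.assert_allclose(summary.table["lo95"],
                                   np.quantile(sims, 0.025, axis=0), rtol=1e-9)
        np.testing.assert_allclose(summary.table["hi95"],
                                   np.quantile(sims, 0.975, axis=0), rtol=1e-9)

    def test_symmetrised_predictive_mean_symmetric(self):
        system, data = scenario_dataset(
            dataclasses.replace(CLUSTERED, n_admin_units=4,
                                extent=(80_000.0, 80_000.0),
                                total_population=1_000_000),
            spacing=20_000, seed=5)
        model = MobilityModel(data, system, model="GM", symmetrised=True)
        truth = np.array([-4.0, 1.8, 0.6, 3.5, 2.3, 1.5])
        res = results_with_draws(model, np.tile(truth, (20, 1)))
        F = model.expected(model.unpack(truth))
        assert np.allclose(F.values, F.values.T)

    def test_empty_or_excess_draws_error(self, gm_setup):
        model, truth = gm_setup
        res = results_with_draws(model, np.tile(truth, (10, 1)))
        with pytest.raises(ValueError):
            posterior_predictive_flows(res, n_draws=11)


class TestCriCoverage:
    def _summary(self, pairs, lo, hi):
        df = pd.DataFrame(pairs, columns=["origin", "destination"])
        df["mean"] = (np.asarray(lo) + np.asarray(hi)) / 2
        df["lo95"] = lo
        df["hi95"] = hi
        from mobfit.predictive import FlowSummary

        return FlowSummary(table=df, n_draws=10)

    def test_all_inside_and_none_inside(self):
        rows = [(1, 2, 5), (2, 1, 7)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        assert cri_coverage(data, self._summary([(1, 2), (2, 1)], [0, 0], [10, 10])) == 1.0
        assert cri_coverage(data, self._summary([(1, 2), (2, 1)], [8, 8], [10, 10])) == 0.0

    def test_invariant_to_unit_relabelling(self):
        rows = [("a", "b", 5), ("b", "a", 20)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        s1 = self._summary([("a", "b"), ("b", "a")], [0, 0], [10, 10])
        rows2 = [("x", "y", 5), ("y", "x", 20)]
        data2 = FlowDataset(pd.DataFrame(rows2, columns=["origin", "destination", "count"]),
                            directional=True, has_diagonal=False)
        s2 = self._summary([("x", "y"), ("y", "x")], [0, 0], [10, 10])
        assert cri_coverage(data, s1) == cri_coverage(data2, s2) == 0.5

    def test_mask_mismatch_errors(self):
        rows = [(1, 2, 5)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        with pytest.raises(ValueError):
            cri_coverage(data, self._summary([(1, 3)], [0], [10]))


class TestDistanceProfile:
    def test_single_pair_step_function(self):
        system = admin_system([10, 10], [(0, 0), (25_000, 0)])
        rows = [(1, 2, 7)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        prof = distance_profile(data, system, bin_width=10_000)
        assert prof.frequency[2] == 7
        assert prof.cumulative[-1] == 1.0
        assert np.all(prof.cumulative[:2] == 0)

    def test_two_equal_flows_half_steps(self):
        system = admin_system([10, 10, 10], [(0, 0), (10_000, 0), (20_000, 0)])
        rows = [(1, 2, 5), (1, 3, 5)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        prof = distance_profile(data, system, bin_width=10_000)
        np.testing.assert_allclose(prof.cumulative, [0.0, 0.5, 1.0])

    def test_matrix_binning_matches_brute_force(self):
        rng = np.random.default_rng(6)
        system = admin_system(rng.uniform(10, 100, 6), rng.uniform(0, 1e5, (6, 2)))
        vals = rng.uniform(0, 5, (6, 6))
        np.fill_diagonal(vals, 0)
        F = FlowMatrix(vals, diagonal="excluded", labels=system.admin_id)
        prof = distance_profile(F, system, bin_width=7000)
        D = system.distances
        expect = np.zeros_like(prof.frequency)
        for i in range(6):
            for j in range(6):
                if i != j:
                    b = min(int(D[i, j] // 7000), len(expect) - 1)
                    expect[b] += vals[i, j]
        np.testing.assert_allclose(prof.frequency, expect, rtol=1e-12)

    def test_bad_bin_width(self):
        system = admin_system([10, 10], [(0, 0), (25_000, 0)])
        rows = [(1, 2, 7)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        with pytest.raises(ValueError):
            distance_profile(data, system, bin_width=0)

    def test_sharper_kernel_concentrates_short_distances(self):
        # larger kernel power -> cumulative distance profile dominates
        system, _ = scenario_dataset(
            dataclasses.replace(CLUSTERED, n_admin_units=6), spacing=20_000, seed=7)
        profs = {}
        for eps in (1.0, 3.0):
            p = ModelParams(kappa=-6.0, alpha=1.0, beta=1.0, gamma=3.5,
                            epsilon=eps, disp=0.0)
            from mobfit.flows import expected_flows

            F = expected_flows(system, "GM", p, symmetrised=True)
            profs[eps] = distance_profile(F, system, bin_width=10_000)
        n = min(len(profs[1.0].cumulative), len(profs[3.0].cumulative))
        assert np.all(profs[3.0].cumulative[:n] >= profs[1.0].cumulative[:n] - 1e-12)


class TestPowerLaw:
    def test_exact_inverse_square_profile(self):
        edges = np.arange(11) * 10_000.0
        centres = 0.5 * (edges[:-1] + edges[1:])
        freq = centres ** -2.0
        prof = DistanceProfile(bin_edges=edges, frequency=freq,
                               cumulative=np.cumsum(freq) / freq.sum())
        fit = powerlaw_fit(prof)
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)

    def test_constant_profile_zero_exponent(self):
        edges = np.arange(6) * 1000.0
        freq = np.full(5, 3.0)
        prof = DistanceProfile(bin_edges=edges, frequency=freq,
                               cumulative=np.cumsum(freq) / freq.sum())
        assert powerlaw_fit(prof).exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponent_recovered_within_ci(self):
        rng = np.random.default_rng(8)
        edges = np.arange(41) * 5000.0
        centres = 0.5 * (edges[:-1] + edges[1:])
        freq = 1e9 * centres ** -1.5 * np.exp(rng.normal(0, 0.1, len(centres)))
        prof = DistanceProfile(bin_edges=edges, frequency=freq,
                               cumulative=np.cumsum(freq) / freq.sum())
        fit = powerlaw_fit(prof)
        lo, hi = fit.conf_int()
        assert lo <= 1.5 <= hi

    def test_too_few_bins_error(self):
        edges = np.arange(3) * 1000.0
        prof = DistanceProfile(bin_edges=edges, frequency=np.array([1.0, 0.0]),
                               cumulative=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            powerlaw_fit(prof)


class TestPlots:
    def test_profile_and_heatmap_files_written(self, tmp_path):
        from mobfit.predictive import plot_distance_profile, plot_flow_heatmap

        edges = np.arange(6) * 10_000.0
        freq = np.array([5.0, 4.0, 0.0, 2.0, 1.0])
        prof = DistanceProfile(bin_edges=edges, frequency=freq,
                               cumulative=np.cumsum(freq) / freq.sum())
        plot_distance_profile(prof, tmp_path / "prof.png", labels=["data"])
        plot_flow_heatmap(np.random.default_rng(0).uniform(1, 9, (5, 5)),
                          tmp_path / "heat.png")
        assert (tmp_path / "prof.png").stat().st_size > 0
        assert (tmp_path / "heat.png").stat().st_size > 0


class TestSymmetryStatistic:
    def test_closed_forms(self):
        rows = [(1, 2, 50), (2, 1, 50), (1, 3, 100), (3, 1, 0)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        sym = symmetry_statistic(data)
        F = sym.pairs.set_index(["origin", "destination"])["F"]
        assert F[(1, 2)] == 0.0
        assert F[(1, 3)] == 100.0
        assert F[(3, 1)] == -100.0

    def test_antisymmetric_and_matches_oracle(self):
        rng = np.random.default_rng(9)
        units = [1, 2, 3, 4, 5]
        rows = [(i, j, int(rng.integers(0, 40)))
                for i in units for j in units if i != j]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=True, has_diagonal=False)
        sym = symmetry_statistic(data)
        F = sym.pairs.set_index(["origin", "destination"])["F"]
        counts = {(i, j): c for i, j, c in rows}
        vals = []
        for i in units:
            for j in units:
                if i < j and max(counts[(i, j)], counts[(j, i)]) > 0:
                    expect = 100.0 * (counts[(i, j)] - counts[(j, i)]) / max(
                        counts[(i, j)], counts[(j, i)])
                    assert F[(i, j)] == pytest.approx(expect)
                    assert F[(j, i)] == pytest.approx(-expect)
                    vals.append(abs(expect))
        assert sym.mean_abs == pytest.approx(np.mean(vals))

    def test_requires_directional(self):
        rows = [(1, 2, 5)]
        data = FlowDataset(pd.DataFrame(rows, columns=["origin", "destination", "count"]),
                           directional=False, has_diagonal=False)
        with pytest.raises(ValueError):
            symmetry_statistic(data)
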