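"""Gravity and radiation kernels, symmetrisation, and cell-to-admin
aggregation, checked against independent scalar evaluations."""

import numpy as np
import pytest

from mobfit.flows import (
    FlowMatrix,
    ModelParams,
    aggregate_to_admin,
    gravity_flow_directional,
    gravity_flow_symmetrised,
    radiation_flow,
    radiation_flow_symmetrised,
)
from mobfit.spatial import SpatialSystem, ring_population

from conftest import random_system

GM = ModelParams(kappa=-2.0, alpha=1.5, beta=0.7, gamma=3.2, epsilon=2.1, disp=0.0)


def scalar_gravity(mi, mj, d, p: ModelParams) -> float:
    """Literal directional gravity flow evaluated with math scalars."""
    return 10.0 ** p.kappa * mi ** p.alpha * mj ** p.beta / (
        1.0 + (d / 10.0 ** p.gamma) ** p.epsilon)


def scalar_radiation(mi, mj, r, T, theta) -> float:
    return T * (mi + theta) * mj / ((mi + theta + r + mj) * (mi + theta + r))


class TestGravityDirectional:
    def test_self_flow_at_zero_distance(self):
        s = SpatialSystem(scale="t", x=np.array([0.0, 9e9]), y=np.zeros(2),
                          population=np.array([10.0, 10.0]),
                          admin_id=np.array([1, 2]))
        p = ModelParams(kappa=0.0, alpha=1.0, beta=1.0, gamma=3.0, epsilon=2.0)
        F = gravity_flow_directional(s, p)
        assert F.values[0, 0] == pytest.approx(100.0)

    def test_kernel_halves_flow_at_its_scale(self):
        # at d = 10^gamma the kernel equals 2
        s = SpatialSystem(scale="t", x=np.array([0.0, 10.0 ** 3.0]), y=np.zeros(2),
                          population=np.array([1.0, 1.0]), admin_id=np.array([1, 2]))
        p = ModelParams(kappa=0.0, alpha=1.0, beta=1.0, gamma=3.0, epsilon=2.0)
        F = gravity_flow_directional(s, p)
        assert F.values[0, 1] == pytest.approx(0.5)

    def test_matches_scalar_oracle(self):
        s = random_system(5, 2, seed=11)
        F = gravity_flow_directional(s, GM)
        D = s.distances
        for i in range(5):
            for j in range(5):
                expect = scalar_gravity(s.population[i], s.population[j], D[i, j], GM)
                assert F.values[i, j] == pytest.approx(expect, rel=1e-12)

    def test_rewrite_identity(self):
        # 10^k m^a m^b / (1 + (d/10^g)^e) == 10^(k+g e) m^a m^b / (10^(g e) + d^e)
        s = random_system(6, 2, seed=12)
        F = gravity_flow_directional(s, GM)
        D = s.distances
        ge = GM.gamma * GM.epsilon
        alt = (10.0 ** (GM.kappa + ge)
               * np.outer(s.population ** GM.alpha, s.population ** GM.beta)
               / (10.0 ** ge + D ** GM.epsilon))
        np.testing.assert_allclose(F.values, alt, rtol=1e-12)

    def test_nonpositive_population_error(self):
        s = SpatialSystem(scale="t", x=np.array([0.0, 1.0]), y=np.zeros(2),
                          population=np.array([0.0, 1.0]), admin_id=np.array([1, 2]))
        with pytest.raises(ValueError):
            gravity_flow_directional(s, GM)

    def test_non_increasing_in_distance(self):
        s = random_system(20, 2, seed=13)
        F = gravity_flow_directional(s, GM).values
        D = s.distances
        m = s.population
        # fix populations: compare scaled flows F / (mi^a mj^b) against d ordering
        scaled = F / np.outer(m ** GM.alpha, m ** GM.beta)
        i = 0
        order = np.argsort(D[i])
        assert np.all(np.diff(scaled[i, order]) <= 1e-15)


class TestGravitySymmetrised:
    def test_exactly_symmetric(self):
        s = random_system(8, 2, seed=14)
        F = gravity_flow_symmetrised(s, GM).values
        assert np.array_equal(F, F.T)

    def test_equal_powers_double_product(self):
        p = ModelParams(kappa=0.0, alpha=1.2, beta=1.2, gamma=3.0, epsilon=2.0)
        s = random_system(4, 2, seed=15)
        F = gravity_flow_symmetrised(s, p).values
        kern = 1.0 + (s.distances / 10 ** p.gamma) ** p.epsilon
        expect = 10.0 ** (p.kappa - p.gamma * p.epsilon) * 2 * np.outer(
            s.population ** p.alpha, s.population ** p.alpha) / kern
        np.testing.assert_allclose(F, expect, rtol=1e-12)

    def test_equals_scaled_transpose_sum_of_directional(self):
        s = random_system(7, 2, seed=16)
        sym = gravity_flow_symmetrised(s, GM).values
        dire = gravity_flow_directional(s, GM).values
        np.testing.assert_allclose(
            sym, 10.0 ** (-GM.gamma * GM.epsilon) * (dire + dire.T), rtol=1e-12)

    def test_kappa_scale_factor_option(self):
        s = random_system(5, 2, seed=17)
        a = gravity_flow_symmetrised(s, GM, scale_factor="kappa").values
        b = gravity_flow_symmetrised(s, GM, scale_factor="kappa-gamma-eps").values
        np.testing.assert_allclose(a, b * 10.0 ** (GM.gamma * GM.epsilon), rtol=1e-12)


class TestRadiation:
    def test_rm1_two_location_closed_form(self):
        s = SpatialSystem(scale="t", x=np.array([0.0, 1000.0]), y=np.zeros(2),
                          population=np.array([30.0, 50.0]), admin_id=np.array([1, 2]))
        rings = ring_population(s)
        F = radiation_flow(s, rings, ModelParams(kappa=1.0), "RM1").values
        m0, m1 = 30.0, 50.0
        assert F[0, 1] == pytest.approx(m0 * m1 / (m0 + m1))
        assert F[0, 0] == 0.0

    def test_rm3_vanishes_as_theta_grows(self):
        # once theta dominates the ring populations the flow decreases
        # monotonically in theta and tends to zero (F ~ T m_j / theta)
        s = random_system(6, 2, seed=18)
        rings = ring_population(s)
        big = max(s.population.sum(), rings.max())
        thetas = [10 * big, 100 * big, 1e7 * big]
        offdiag = ~np.eye(6, dtype=bool)
        prev = None
        for th in thetas:
            F = radiation_flow(s, rings, ModelParams(kappa=0.0, theta=th), "RM3").values
            if prev is not None:
                assert np.all(F[offdiag] <= prev[offdiag])
            prev = F
        assert np.all(prev[offdiag] < 1e-3)

    def test_rm4_matches_scalar_oracle_on_line(self, line_system):
        s = line_system
        rings = ring_population(s)
        p = ModelParams(kappa=0.0, alpha=1.0, theta=100.0)
        F = radiation_flow(s, rings, p, "RM4").values
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                T = 10.0 ** p.kappa * s.population[i] ** p.alpha
                expect = scalar_radiation(s.population[i], s.population[j],
                                          rings[i, j], T, p.theta)
                assert F[i, j] == pytest.approx(expect, rel=1e-12)

    def test_rm1_negative_kappa_error(self):
        s = random_system(3, 2, seed=19)
        with pytest.raises(ValueError):
            radiation_flow(s, ring_population(s), ModelParams(kappa=-0.5), "RM1")

    def test_negative_theta_error(self):
        with pytest.raises(ValueError):
            ModelParams(kappa=0.0, theta=-1.0)

    def test_symmetrised_is_transpose_sum(self):
        s = random_system(6, 2, seed=20)
        rings = ring_population(s)
        p = ModelParams(kappa=-1.0, alpha=1.1, theta=50.0)
        dire = radiation_flow(s, rings, p, "RM4").values
        sym = radiation_flow_symmetrised(s, rings, p, "RM4").values
        np.testing.assert_allclose(sym, dire + dire.T, rtol=1e-14)
        assert np.array_equal(sym, sym.T)

    def test_symmetric_geometry_doubles_directional(self):
        # two equal-population locations: F_sym = 2 F_dir
        s = SpatialSystem(scale="t", x=np.array([0.0, 1000.0]), y=np.zeros(2),
                          population=np.array([40.0, 40.0]), admin_id=np.array([1, 2]))
        rings = ring_population(s)
        p = ModelParams(kappa=0.3, alpha=1.0, theta=10.0)
        dire = radiation_flow(s, rings, p, "RM4").values
        sym = radiation_flow_symmetrised(s, rings, p, "RM4").values
        np.testing.assert_allclose(sym, 2 * dire, rtol=1e-14)

    def test_non_increasing_in_ring_population(self):
        # same populations and T, larger intervening population -> smaller flow
        th, T, mi, mj = 10.0, 100.0, 50.0, 60.0
        vals = [scalar_radiation(mi, mj, r, T, th) for r in (0, 10, 100, 1000)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestAggregation:
    def test_one_cell_per_unit_identity(self):
        s = random_system(4, 4, seed=21)
        F = gravity_flow_directional(s, GM)
        A = aggregate_to_admin(F, s)
        order = np.argsort(s.admin_id)
        np.testing.assert_allclose(A.values, F.values[np.ix_(order, order)])

    def test_pair_counting_with_excluded_diagonal(self):
        s = SpatialSystem(scale="t", x=np.arange(4.0), y=np.zeros(4),
                          population=np.ones(4),
                          admin_id=np.array([1, 1, 2, 2]))
        F = FlowMatrix(np.ones((4, 4)), diagonal="excluded")
        A = aggregate_to_admin(F, s)
        assert A.values[0, 1] == 4.0  # 2 x 2 ordered cell pairs
        assert A.values[0, 0] == 0.0
        assert A.diagonal == "excluded"

    def test_matches_brute_force_double_loop(self):
        s = random_system(30, 4, seed=22)
        F = gravity_flow_directional(s, GM)
        A = aggregate_to_admin(F, s)
        units = list(s.unit_ids)
        for I, uI in enumerate(units):
            for J, uJ in enumerate(units):
                total = 0.0
                for i in range(30):
                    for j in range(30):
                        if s.admin_id[i] == uI and s.admin_id[j] == uJ:
                            total += F.values[i, j]
                assert A.values[I, J] == pytest.approx(total, rel=1e-12)

    def test_total_flow_conserved(self):
        # diagonal-included models conserve everything; diagonal-excluded
        # models conserve the cross-unit flows (within-unit cell pairs fall
        # into the undefined admin diagonal and are dropped)
        s = random_system(25, 3, seed=23)
        vals = np.random.default_rng(1).uniform(0, 5, (25, 25))
        A = aggregate_to_admin(FlowMatrix(vals, diagonal="included"), s)
        assert A.total == pytest.approx(vals.sum(), rel=1e-12)

        vals_x = vals.copy()
        np.fill_diagonal(vals_x, 0.0)
        A = aggregate_to_admin(FlowMatrix(vals_x, diagonal="excluded"), s)
        cross = vals_x[s.admin_id[:, None] != s.admin_id[None, :]].sum()
        assert A.total == pytest.approx(cross, rel=1e-12)
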