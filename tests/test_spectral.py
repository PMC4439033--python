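import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg, stats

from metacap import (
    KernelSpec,
    Landscape,
    ValueDistribution,
    build_dispersal_matrix,
    empirical_effective_neighbors,
    generate_random_landscape,
    localization_psi,
    metapopulation_capacity,
    pairwise_distances,
    patch_removal_impacts,
)


def two_patch_landscape(r, values=(1.0, 1.0), L=1.0, boundary="hard"):
    return Landscape(np.array([[0.0], [r]]), np.array(values), L, boundary=boundary)


class TestBuildDispersalMatrix:
    def test_two_patch_entries(self):
        land = two_patch_landscape(0.3, values=(2.0, 3.0))
        dm = build_dispersal_matrix(land, KernelSpec("gaussian", 0.1), delta=1.0)
        expected = 6.0 * math.exp(-0.5 * (0.3 / 0.1) ** 2)
        assert dm.M[0, 1] == pytest.approx(expected, rel=1e-12)
        assert dm.M[0, 0] == 0.0 and dm.M[1, 1] == 0.0
        # D_ij = A_j f; M_ij = A_i D_ij
        assert dm.D[0, 1] == pytest.approx(expected / 2.0, rel=1e-12)
        np.testing.assert_allclose(dm.extinction_rates, [0.5, 1 / 3])

    def test_three_collinear_exponential(self):
        land = Landscape(np.array([[0.0], [0.1], [0.2]]), np.ones(3), 1.0)
        dm = build_dispersal_matrix(land, KernelSpec("exponential", 0.1))
        assert dm.M[0, 2] == pytest.approx(math.exp(-2), rel=1e-12)
        assert dm.M[0, 1] == pytest.approx(math.exp(-1), rel=1e-12)
        assert dm.M[1, 2] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_symmetry(self, small_dm):
        assert np.max(np.abs(small_dm.M - small_dm.M.T)) == 0.0
        assert np.all(np.diag(small_dm.M) == 0.0)
        assert np.all(small_dm.M >= 0.0)

    def test_minimum_image_distances(self):
        land = Landscape(np.array([[0.05], [0.95]]), np.ones(2), 1.0, boundary="periodic")
        r = pairwise_distances(land)
        assert r[0, 1] == pytest.approx(0.1, abs=1e-12)
        hard = Landscape(np.array([[0.05], [0.95]]), np.ones(2), 1.0)
        assert pairwise_distances(hard)[0, 1] == pytest.approx(0.9)


class TestCapacity:
    def test_two_patch_closed_form(self):
        # 2x2 symmetric zero-diagonal matrix: lambda = f(x), w = (1,1)/sqrt(2)
        land = two_patch_landscape(0.2)
        spec = metapopulation_capacity(build_dispersal_matrix(land, KernelSpec("gaussian", 0.2)))
        assert spec.capacity == pytest.approx(math.exp(-0.5), rel=1e-12)
        np.testing.assert_allclose(spec.eigenvector, [1 / math.sqrt(2)] * 2, rtol=1e-10)

    def test_all_to_all_constant_kernel(self):
        # f = 1 between all patches, unit values: M = J - I, lambda = N - 1
        land = generate_random_landscape(6, 2, 1.0, seed=2)
        dm = build_dispersal_matrix(land, KernelSpec("rectangular", 10.0))
        spec = metapopulation_capacity(dm)
        direct = linalg.eigvalsh(dm.M)[-1]
        assert spec.capacity == pytest.approx(5.0, rel=1e-12)
        assert spec.capacity == pytest.approx(direct, rel=1e-12)

    def test_row_sum_lower_bound(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 120))
            land = generate_random_landscape(
                n, int(rng.integers(1, 4)), 1.0,
                ValueDistribution("lognormal", float(rng.uniform(0, 1))),
                seed=int(rng.integers(2**31)),
            )
            spec = metapopulation_capacity(
                build_dispersal_matrix(land, KernelSpec("gaussian", 0.1))
            )
            assert spec.capacity >= spec.mean_row_sum * (1 - 1e-12)

    def test_value_scale_equivariance(self, small_landscape):
        # M is bilinear in the values: scaling all A_i by c scales lambda by c^2
        k = KernelSpec("gaussian", 0.1)
        lam = metapopulation_capacity(build_dispersal_matrix(small_landscape, k)).capacity
        scaled = Landscape(
            small_landscape.positions, 3.0 * small_landscape.values,
            small_landscape.box_length,
        )
        lam_scaled = metapopulation_capacity(build_dispersal_matrix(scaled, k)).capacity
        assert lam_scaled == pytest.approx(9.0 * lam, rel=1e-10)

    def test_single_patch_capacity_zero(self):
        land = Landscape(np.array([[0.5, 0.5]]), np.array([2.0]), 1.0)
        dm = build_dispersal_matrix(land, KernelSpec("gaussian", 0.1))
        with pytest.warns(UserWarning, match="single"):
            spec = metapopulation_capacity(dm)
        assert spec.capacity == 0.0

    def test_iterative_path_matches_dense(self):
        # above the dense threshold the Lanczos solve must agree with eigh
        land = generate_random_landscape(450, 2, 1.0, seed=8)
        dm = build_dispersal_matrix(land, KernelSpec("gaussian", 0.08))
        spec = metapopulation_capacity(dm)
        dense = linalg.eigvalsh(dm.M)[-1]
        assert spec.capacity == pytest.approx(dense, rel=1e-10)
        resid = np.linalg.norm(dm.M @ spec.eigenvector - spec.capacity * spec.eigenvector)
        assert resid / spec.capacity < 1e-10


class TestPsi:
    def test_uniform_vector_gives_zero(self):
        n = 64
        assert localization_psi(np.full(n, n**-0.5)) == pytest.approx(0.0, abs=1e-12)

    def test_single_component_gives_one(self):
        w = np.zeros(10)
        w[3] = 1.0
        assert localization_psi(w) == pytest.approx(1.0)

    def test_half_and_half(self):
        w = np.sqrt(np.array([0.5, 0.5, 0.0, 0.0]))
        assert localization_psi(w) == pytest.approx(1 / 3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            localization_psi(np.array([1.0]))
        with pytest.raises(ValueError):
            localization_psi(np.array([1.0, 1.0]))  # not normalized

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=40))
    def test_psi_in_unit_interval(self, raw):
        w = np.asarray(raw)
        w = w / np.linalg.norm(w)
        assert -1e-12 <= localization_psi(w) <= 1.0 + 1e-12


class TestRemovalImpacts:
    def test_two_patches_total_loss(self):
        land = two_patch_landscape(0.2)
        dm = build_dispersal_matrix(land, KernelSpec("gaussian", 0.2))
        imp = patch_removal_impacts(dm)
        np.testing.assert_allclose(imp.exact_relative_drop, [1.0, 1.0])

    def test_approx_sums_to_one(self, small_dm):
        imp = patch_removal_impacts(small_dm, exact=False)
        assert imp.exact_relative_drop is None
        assert imp.approx.sum() == pytest.approx(1.0, rel=1e-10)

    def test_rank_agreement_moderate_n(self):
        land = generate_random_landscape(100, 2, 1.0, seed=21)
        xi = math.sqrt(20 / (100 * 2 * math.pi))  # n_e ~ 20
        dm = build_dispersal_matrix(land, KernelSpec("gaussian", xi))
        imp = patch_removal_impacts(dm)
        rho = stats.spearmanr(imp.exact_relative_drop, imp.approx).statistic
        assert rho > 0.9
        assert np.all(imp.exact_relative_drop >= -1e-12)
        assert np.all(imp.exact_relative_drop <= 1.0 + 1e-12)


class TestEmpiricalNeighbors:
    def test_edge_of_rectangular_kernel_excluded(self):
        land = two_patch_landscape(0.2)
        assert empirical_effective_neighbors(land, KernelSpec("rectangular", 0.2)) == 0.0

    def test_all_to_all_row_sum(self):
        land = generate_random_landscape(12, 2, 1.0, seed=0)
        assert empirical_effective_neighbors(land, KernelSpec("rectangular", 5.0)) == 11.0

    def test_periodic_matches_analytic(self):
        # periodic boundaries remove the edge deficit: replicate-mean row sum
        # should sit within 3 SE of (N / L^2) G xi^2
        from metacap import effective_neighbors_analytic

        k = KernelSpec("gaussian", 0.03)
        target = effective_neighbors_analytic(1500, 2, 1.0, k)
        vals = [
            empirical_effective_neighbors(
                generate_random_landscape(1500, 2, 1.0, seed=s, boundary="periodic"), k
            )
            for s in range(8)
        ]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        # finite-N bias is (N-1)/N; fold it into the expectation
        assert abs(vals.mean() - target * 1499 / 1500) < 3 * se + 0.01 * target
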