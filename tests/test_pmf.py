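import numpy as np
import pytest

from gridbind.constants import rt
from gridbind.pmf import (
    GridPMF,
    bulk_level,
    coarsen_grid,
    grid_pmf,
    nearest_bin_indices,
    radial_profile,
    weighted_pmf,
)

RT300 = rt(300.0)


class TestWeightedPMF:
    def test_equal_split_gives_flat_pmf(self):
        w = np.full(10, 0.1)
        x = np.array([0.0] * 5 + [1.0] * 5)
        prof = weighted_pmf(w, x, np.array([0.0, 1.0]), 300.0)
        np.testing.assert_allclose(prof.pmf, [0.0, 0.0], atol=1e-12)

    def test_two_to_one_ratio_is_rt_ln2(self):
        w = np.array([2 / 3, 1 / 3])
        x = np.array([0.0, 1.0])
        prof = weighted_pmf(w, x, np.array([0.0, 1.0]), 300.0)
        assert prof.pmf[0] == 0.0
        assert prof.pmf[1] == pytest.approx(RT300 * np.log(2.0), abs=1e-12)
        assert prof.pmf[1] == pytest.approx(0.4132, abs=5e-4)

    def test_equidistant_tie_goes_to_lower_bin(self):
        idx = nearest_bin_indices(np.array([0.5]), np.array([0.0, 1.0]))
        assert idx[0] == 0

    def test_unoccupied_bins_flagged_not_faked(self):
        prof = weighted_pmf(
            np.array([1.0]), np.array([0.0]), np.array([0.0, 1.0, 2.0]), 300.0
        )
        assert prof.occupied.tolist() == [True, False, False]
        assert np.isnan(prof.pmf[1:]).all()
        assert prof.pmf[0] == 0.0

    def test_zero_total_weight_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_pmf(np.zeros(3), np.zeros(3), np.array([0.0, 1.0]), 300.0)

    def test_weight_scaling_invariance(self, rng):
        x = rng.normal(0, 1, 500)
        w = rng.random(500)
        bins = np.linspace(-3, 3, 13)
        a = weighted_pmf(w / w.sum(), x, bins, 300.0)
        b = weighted_pmf(7.3 * w / w.sum(), x, bins, 300.0)
        np.testing.assert_allclose(a.pmf[a.occupied], b.pmf[b.occupied], atol=1e-12)


class TestGridPMF:
    def test_single_voxel(self):
        g = grid_pmf(np.array([1.0]), np.zeros((1, 3)), 1.0, 300.0)
        assert g.n_voxels == 1
        assert g.dg[0] == 0.0
        np.testing.assert_array_equal(g.indices, [[0, 0, 0]])

    def test_two_voxel_ratio(self):
        w = np.array([1.0, np.exp(-1.0)])
        pos = np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5]])
        g = grid_pmf(w, pos, 1.0, 300.0)
        order = np.argsort(g.dg)
        assert g.dg[order[0]] == 0.0
        assert g.dg[order[1]] == pytest.approx(RT300, rel=1e-12)

    def test_harmonic_positions_give_harmonic_radial_pmf(self):
        """Direct Boltzmann samples of an isotropic harmonic well: the
        radially averaged grid PMF tracks kappa |x|^2 / 2."""
        kappa = 0.5
        rng = np.random.default_rng(7)
        pos = rng.normal(0.0, np.sqrt(RT300 / kappa), (100_000, 3))
        w = np.full(len(pos), 1.0 / len(pos))
        g = grid_pmf(w, pos, 1.0, 300.0)
        prof = radial_profile(g, 1.0)
        # compare where shells are well populated
        sel = (prof.shell_centers < 2.5) & (prof.n_voxels >= 8)
        expected = 0.5 * kappa * prof.shell_centers[sel] ** 2
        # allow the voxelization offset of the origin-anchored minimum
        np.testing.assert_allclose(prof.mean_pmf[sel], expected, atol=0.25)

    def test_refinement_consistency(self, rng):
        """Halving the voxel size and Boltzmann-recoarsening reproduces the
        coarse grid PMF."""
        pos = rng.normal(0, 2.0, (5000, 3))
        w = rng.random(5000)
        w /= w.sum()
        coarse = grid_pmf(w, pos, 1.0, 300.0)
        fine = grid_pmf(w, pos, 0.5, 300.0)
        recoarse = coarsen_grid(fine, 2)
        # align by absolute lattice index
        def as_dict(g):
            origin = g.origin_index
            return {tuple(i + origin): d for i, d in zip(g.indices, g.dg)}
        a, b = as_dict(coarse), as_dict(recoarse)
        assert set(a) == set(b)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-10)


class TestRadialProfile:
    def test_single_shell_constant(self):
        idx = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0]])
        g = GridPMF(1.0, np.vstack([[0, 0, 0], idx]), np.array([0.0, 3.0, 3.0, 3.0, 3.0]), 300.0)
        prof = radial_profile(g, 1.0)
        shell = prof.shell_centers == 1.5
        assert prof.mean_pmf[shell][0] == pytest.approx(3.0)
        assert prof.sd_pmf[shell][0] == 0.0

    def test_population_sd(self):
        g = GridPMF(
            1.0,
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            np.array([0.0, 1.0, 3.0]),
            300.0,
        )
        prof = radial_profile(g, 1.0)
        shell = prof.n_voxels == 2
        assert prof.mean_pmf[shell][0] == pytest.approx(2.0)
        assert prof.sd_pmf[shell][0] == pytest.approx(1.0)

    def test_linear_radial_grid_recovered(self):
        """A grid built analytically as dG = a|x| averages to a * shell
        center with only voxelization scatter."""
        a = 0.7
        m = 8
        ax = np.arange(-m, m + 1)
        idx = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        r = np.linalg.norm(idx, axis=1)
        g = GridPMF(1.0, idx, a * r, 300.0)
        prof = radial_profile(g, 1.0)
        # first shell holds only the r=0 voxel; voxel radii within a shell
        # spread +/- half a shell width around its center
        sel = (prof.shell_centers > 1) & (prof.shell_centers <= m)
        np.testing.assert_allclose(
            prof.mean_pmf[sel], a * prof.shell_centers[sel], atol=a * 0.5
        )
        assert np.all(prof.sd_pmf[sel] < a * 0.5)

    def test_empty_grid_is_error(self):
        g = GridPMF(1.0, np.empty((0, 3), dtype=int), np.empty(0), 300.0)
        with pytest.raises(ValueError, match="empty"):
            radial_profile(g, 1.0)


class TestBulkLevel:
    def test_flat_grid_recovers_level(self):
        m = 6
        ax = np.arange(-m, m + 1)
        idx = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        dg = np.where((idx == 0).all(axis=1), 0.0, 2.0)
        g = GridPMF(1.0, idx, dg, 300.0)
        assert bulk_level(g, 3.0, 5.0) == pytest.approx(2.0, abs=1e-10)

    def test_sparse_coverage_unbiased_via_geometric_count(self):
        """Half the shell voxels missing: the geometric normalization makes
        the sum smaller, i.e. the level higher by RT ln 2."""
        m = 6
        ax = np.arange(-m, m + 1)
        idx = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        r = np.linalg.norm(idx, axis=1)
        in_shell = (r >= 3.0) & (r < 5.0)
        keep = ~in_shell | (np.arange(len(idx)) % 2 == 0)
        shell_count = in_shell.sum()
        kept_count = (in_shell & keep).sum()
        dg = np.where((idx == 0).all(axis=1), 0.0, 2.0)
        g = GridPMF(1.0, idx[keep], dg[keep], 300.0)
        expected = 2.0 + RT300 * np.log(shell_count / kept_count)
        assert bulk_level(g, 3.0, 5.0) == pytest.approx(expected, abs=1e-10)
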