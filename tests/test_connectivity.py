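import math

import numpy as np
import pytest

from cfreserve import (
    GridRaster,
    KernelParams,
    accumulate_cost,
    cost_surfaces,
    patch_metrics,
    place_sources,
    resistant_kernel_density,
    threshold_core,
)

SQRT2 = math.sqrt(2)


def brute_force_costs(resistance, source, cell_size=500.0):
    """Bellman-Ford-style relaxation oracle, independent of the Dijkstra path."""
    r = resistance
    nrows, ncols = r.shape
    dist = np.full((nrows, ncols), np.inf)
    dist[source] = 0.0
    steps = [
        (dr, dc, SQRT2 if dr and dc else 1.0)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]
    for _ in range(nrows * ncols):
        changed = False
        for i in range(nrows):
            for j in range(ncols):
                if not np.isfinite(dist[i, j]):
                    continue
                for dr, dc, f in steps:
                    a, b = i + dr, j + dc
                    if 0 <= a < nrows and 0 <= b < ncols:
                        w = f * 0.5 * (r[i, j] + r[a, b]) * cell_size
                        if dist[i, j] + w < dist[a, b] - 1e-12:
                            dist[a, b] = dist[i, j] + w
                            changed = True
        if not changed:
            break
    return dist


class TestAccumulateCost:
    def test_uniform_resistance_orthogonal_step(self, uniform_resistance):
        cost = accumulate_cost(uniform_resistance, (0, 0))
        assert cost.values[0, 1] == pytest.approx(500.0)
        assert cost.values[1, 1] == pytest.approx(500.0 * SQRT2)
        assert cost.values[0, 0] == 0.0

    def test_barrier_row_blocks_at_budget(self):
        r = np.ones((7, 5))
        r[3, :] = 1e6
        cost = accumulate_cost(GridRaster(values=r, cell_size=500.0), (0, 2), max_cost=1e5)
        assert np.all(~np.isfinite(cost.values[4:, :]))
        assert np.isfinite(cost.values[2, 2])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        r = rng.uniform(1, 20, (5, 5))
        r[2, 1] = 1e5  # one barrier
        raster = GridRaster(values=r, cell_size=500.0)
        got = accumulate_cost(raster, (0, 0))
        want = brute_force_costs(r, (0, 0))
        np.testing.assert_allclose(got.values, want, rtol=1e-10)

    def test_source_outside_grid_rejected(self, uniform_resistance):
        with pytest.raises(ValueError):
            accumulate_cost(uniform_resistance, (9, 9))

    def test_subunit_resistance_rejected(self):
        with pytest.raises(ValueError):
            accumulate_cost(GridRaster(values=np.full((4, 4), 0.5)), (0, 0))


class TestKernel:
    def test_density_one_at_isolated_source(self, uniform_resistance):
        k = resistant_kernel_density(uniform_resistance, [(4, 4)], KernelParams(bandwidth=1000.0))
        assert k.values[4, 4] == pytest.approx(1.0)

    def test_linear_decay_reaches_zero_at_bandwidth(self, uniform_resistance):
        # orthogonal neighbour costs 500; bandwidth 500 puts it exactly at zero
        k = resistant_kernel_density(uniform_resistance, [(0, 0)], KernelParams(bandwidth=500.0))
        assert k.values[0, 1] == pytest.approx(0.0)
        assert k.values[0, 0] == pytest.approx(1.0)

    def test_coincident_sources_superpose(self, uniform_resistance):
        p = KernelParams(bandwidth=2000.0)
        k1 = resistant_kernel_density(uniform_resistance, [(2, 2)], p)
        k2 = resistant_kernel_density(uniform_resistance, [(2, 2), (2, 2)], p)
        np.testing.assert_allclose(k2.values, 2 * k1.values)

    def test_monotone_in_bandwidth(self, landscape):
        sources = [(8, 8), (32, 32), (50, 20)]
        k_lo = resistant_kernel_density(landscape.resistance, sources, KernelParams(bandwidth=4000.0))
        k_hi = resistant_kernel_density(landscape.resistance, sources, KernelParams(bandwidth=8000.0))
        assert np.all(k_hi.values >= k_lo.values - 1e-12)

    def test_raising_resistance_never_raises_density(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(1, 5, (12, 12))
        raised = base.copy()
        raised[5, 5] = 50.0
        p = KernelParams(bandwidth=6000.0)
        k_base = resistant_kernel_density(GridRaster(values=base), [(0, 0), (11, 11)], p)
        k_raised = resistant_kernel_density(GridRaster(values=raised), [(0, 0), (11, 11)], p)
        assert np.all(k_raised.values <= k_base.values + 1e-12)

    def test_empty_sources_rejected(self, uniform_resistance):
        with pytest.raises(ValueError):
            resistant_kernel_density(uniform_resistance, [], KernelParams())


class TestPlaceSources:
    def test_full_lattice_count(self):
        mask = GridRaster(values=np.ones((20, 20)))
        assert len(place_sources(mask, 5)) == 16

    def test_sources_confined_to_habitat(self):
        v = np.zeros((20, 20))
        v[:, 10:] = 1
        mask = GridRaster(values=v)
        sources = place_sources(mask, 5)
        assert all(v[r, c] == 1 for r, c in sources)

    def test_spacing_equal_to_grid_yields_at_most_one(self):
        mask = GridRaster(values=np.ones((10, 10)))
        assert len(place_sources(mask, 10)) == 1

    def test_no_habitat_rejected(self):
        with pytest.raises(ValueError):
            place_sources(GridRaster(values=np.zeros((5, 5))), 2)


class TestThresholdCore:
    def test_distinct_values_pass_count(self):
        v = np.zeros((10, 10))
        v.ravel()[:100] = np.arange(1, 101)  # 100 positive distinct values
        core = threshold_core(GridRaster(values=v), percentile=10)
        assert core.values.sum() == 90

    def test_percentile_zero_keeps_all_positive(self):
        v = np.array([[0.0, 0.1], [0.2, 0.3]])
        core = threshold_core(GridRaster(values=v), percentile=0)
        assert core.values.sum() == 3

    def test_constant_support_degenerates_to_empty(self):
        v = np.array([[0.0, 1.0], [1.0, 1.0]])
        core = threshold_core(GridRaster(values=v), percentile=10)
        assert core.values.sum() == 0  # strict > on a flat distribution

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            threshold_core(GridRaster(values=np.zeros((3, 3))))


class TestPatchMetrics:
    def test_all_ones_map(self):
        m = patch_metrics(GridRaster(values=np.ones((10, 10)), cell_size=500.0))
        assert m.np == 1
        assert m.pland == pytest.approx(100.0)
        assert m.lpi == pytest.approx(100.0)

    def test_two_equal_patches_awmps(self):
        v = np.zeros((5, 9))
        v[1:3, 0:2] = 1
        v[1:3, 7:9] = 1  # two 4-cell patches, separated
        m = patch_metrics(GridRaster(values=v, cell_size=1000.0))
        assert m.np == 2
        assert m.awmps == pytest.approx(4.0)  # sum a^2 / sum a with equal areas

    def test_three_by_three_gyrate(self):
        v = np.zeros((5, 5))
        v[1:4, 1:4] = 1
        m = patch_metrics(GridRaster(values=v, cell_size=1000.0))
        # distances to centre: centre 0, four at 1, four at sqrt(2)
        expected = (0 + 4 * 1.0 + 4 * SQRT2) / 9.0
        assert m.correlation_length == pytest.approx(expected)
        assert m.lpi == pytest.approx(100.0 * 9 / 25)

    def test_diagonal_cells_form_one_patch(self):
        v = np.eye(4)
        m = patch_metrics(GridRaster(values=v))
        assert m.np == 1  # 8-connectivity joins diagonals

    def test_empty_map(self):
        m = patch_metrics(GridRaster(values=np.zeros((4, 4))))
        assert (m.np, m.pland, m.lpi, m.awmps, m.correlation_length) == (0, 0.0, 0.0, 0.0, 0.0)

    def test_awmps_at_least_arithmetic_mean(self):
        rng = np.random.default_rng(4)
        v = (rng.random((30, 30)) < 0.4).astype(float)
        m = patch_metrics(GridRaster(values=v, cell_size=500.0))
        if m.np:
            from scipy import ndimage

            labels, n = ndimage.label(v, structure=np.ones((3, 3)))
            areas = np.bincount(labels.ravel())[1:] * 0.25
            assert m.awmps >= areas.mean() - 1e-12


def test_multisource_cost_surfaces_match_single_runs(uniform_resistance):
    multi = cost_surfaces(uniform_resistance, [(0, 0), (7, 7)])
    one = accumulate_cost(uniform_resistance, (7, 7))
    np.testing.assert_allclose(multi[1], one.values)
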