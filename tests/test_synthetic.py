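import numpy as np
import pytest
from scipy import ndimage

from cfreserve import (
    FOREST_CLASSES,
    LandCover,
    SyntheticConfig,
    generate_carbon,
    generate_elevation,
    generate_landcover,
    generate_landscape,
    generate_pa_mask,
    generate_resistance,
    generate_risk,
)
from cfreserve.synthetic import DEFAULT_RESISTANCE


def forest_mask(landcover):
    return np.isin(landcover.values, [int(c) for c in FOREST_CLASSES])


class TestElevation:
    def test_zero_roughness_is_flat(self):
        e = generate_elevation(16, 16, roughness=0.0, seed=1)
        assert np.ptp(e.values) == 0.0

    def test_deterministic_per_seed(self):
        a = generate_elevation(32, 32, 1.0, seed=9)
        b = generate_elevation(32, 32, 1.0, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        c = generate_elevation(32, 32, 1.0, seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_variance_increases_with_roughness(self):
        # Monte-Carlo over 20 seeds: relief amplitude scales with roughness.
        lo = [generate_elevation(64, 64, 0.5, seed=s).values.var() for s in range(20)]
        hi = [generate_elevation(64, 64, 2.0, seed=s).values.var() for s in range(20)]
        assert all(h > l for h, l in zip(hi, lo))

    def test_spatial_autocorrelation_positive(self):
        # Moran's-I-like statistic via the lag-1 correlation of rows.
        e = generate_elevation(64, 64, 1.0, seed=3).values
        r = np.corrcoef(e[:, :-1].ravel(), e[:, 1:].ravel())[0, 1]
        assert r > 0.5

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_elevation(0, 10)
        with pytest.raises(ValueError):
            generate_elevation(10, 10, roughness=-1.0)


class TestLandcover:
    def test_forest_share_tracks_request(self):
        e = generate_elevation(64, 64, 1.0, seed=2)
        lc = generate_landcover(e, 0.6, seed=5)
        share = forest_mask(lc).mean()
        assert 0.55 <= share <= 0.65

    def test_near_total_forest_limit(self):
        e = generate_elevation(32, 32, 1.0, seed=2)
        lc = generate_landcover(e, 0.999, seed=5)
        assert forest_mask(lc).mean() > 0.99

    def test_montane_classes_sit_higher_than_lowland(self):
        e = generate_elevation(64, 64, 1.0, seed=4)
        lc = generate_landcover(e, 0.6, seed=4)
        elev = e.values
        upper = elev[lc.values == int(LandCover.UPPER_MONTANE_FOREST)]
        lowland = elev[lc.values == int(LandCover.LOWLAND_FOREST)]
        assert upper.size and lowland.size
        assert upper.mean() > lowland.mean()

    def test_class_inventory(self):
        e = generate_elevation(64, 64, 1.0, seed=6)
        lc = generate_landcover(e, 0.6, seed=6)
        present = set(np.unique(lc.values).astype(int))
        assert len(present & {int(c) for c in FOREST_CLASSES}) == 5
        assert len(present - {int(c) for c in FOREST_CLASSES}) >= 2

    def test_rejects_bad_fraction(self):
        e = generate_elevation(16, 16, 1.0, seed=1)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                generate_landcover(e, bad)


class TestPaMask:
    def test_zero_fraction_gives_empty_mask(self):
        e = generate_elevation(32, 32, 1.0, seed=1)
        cover = e.like(np.ones(e.shape, dtype=int))
        pa = generate_pa_mask(e, cover, 0.0, seed=1)
        assert pa.values.sum() == 0

    def test_high_and_far_bias_across_seeds(self):
        # mean elevation inside PAs exceeds outside in >= 95% of 20 seeds
        wins = 0
        for seed in range(20):
            e = generate_elevation(64, 64, 1.0, seed=seed)
            lc = generate_landcover(e, 0.6, seed=seed)
            cover = e.like(forest_mask(lc).astype(int))
            pa = generate_pa_mask(e, cover, 0.15, seed=seed)
            inside = e.values[pa.values > 0].mean()
            outside = e.values[pa.values == 0].mean()
            wins += inside > outside
        assert wins >= 19

    def test_blob_count_bounded(self):
        e = generate_elevation(64, 64, 1.0, seed=8)
        lc = generate_landcover(e, 0.6, seed=8)
        cover = e.like(forest_mask(lc).astype(int))
        pa = generate_pa_mask(e, cover, 0.15, seed=8)
        _, n = ndimage.label(pa.values)
        assert 1 <= n <= 10

    def test_mask_respects_cover(self):
        e = generate_elevation(32, 32, 1.0, seed=3)
        cover = e.like((np.arange(32)[:, None] < 16).astype(int) * np.ones((32, 32), dtype=int))
        pa = generate_pa_mask(e, cover, 0.1, seed=3)
        assert not np.any((pa.values > 0) & (cover.values == 0))


class TestRisk:
    @staticmethod
    def _layers(seed=0):
        e = generate_elevation(48, 48, 1.0, seed=seed)
        lc = generate_landcover(e, 0.6, seed=seed)
        cover = e.like(forest_mask(lc).astype(int))
        pa = generate_pa_mask(e, cover, 0.1, seed=seed)
        return e, lc, pa

    def test_zero_coefficients_give_half_on_forest(self):
        e, lc, pa = self._layers()
        coeffs = dict(intercept=0, elevation_slope=0, edge_distance_slope=0, pa_offset=0)
        r = generate_risk(e, lc, pa, coeffs)
        f = forest_mask(lc)
        np.testing.assert_allclose(r.values[f], 0.5)
        np.testing.assert_allclose(r.values[~f], 0.0)

    def test_negative_pa_offset_lowers_risk_inside(self):
        e, lc, pa = self._layers(seed=2)
        coeffs = dict(intercept=0, elevation_slope=0, edge_distance_slope=0, pa_offset=-2.0)
        r = generate_risk(e, lc, pa, coeffs)
        f = forest_mask(lc)
        assert r.values[f & (pa.values > 0)].mean() < r.values[f & (pa.values == 0)].mean()

    def test_risk_monotone_decreasing_in_elevation(self):
        e, lc, pa = self._layers(seed=3)
        coeffs = dict(intercept=0.2, elevation_slope=-1.5, edge_distance_slope=0, pa_offset=0)
        r = generate_risk(e, lc, pa, coeffs)
        f = forest_mask(lc) & (pa.values == 0)
        elev, risk = e.values[f], r.values[f]
        order = np.argsort(elev)
        # logistic in z(elev) alone: strictly decreasing along the elevation order
        assert np.all(np.diff(risk[order]) <= 1e-12)

    def test_bounds_and_alignment(self):
        e, lc, pa = self._layers(seed=4)
        r = generate_risk(e, lc, pa, SyntheticConfig().risk_coefficients)
        assert r.values.min() >= 0.0 and r.values.max() <= 1.0
        small = generate_elevation(8, 8, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_risk(small, lc, pa, SyntheticConfig().risk_coefficients)


class TestCarbon:
    def test_zero_on_nonforest_positive_on_forest(self):
        e = generate_elevation(48, 48, 1.0, seed=5)
        lc = generate_landcover(e, 0.6, seed=5)
        c = generate_carbon(lc, e, seed=5)
        f = forest_mask(lc)
        assert np.all(c.values[~f] == 0.0)
        assert np.all(c.values[f] > 0.0)

    def test_mean_matches_class_parameter(self):
        e = generate_elevation(10, 10, 0.0, seed=1)
        lc = e.like(np.full((10, 10), int(LandCover.LOWLAND_FOREST)))
        c = generate_carbon(lc, e, seed=3, class_means={int(LandCover.LOWLAND_FOREST): 100.0})
        assert 80.0 <= c.values.mean() <= 120.0


class TestResistance:
    def test_pure_table_lookup(self):
        e = generate_elevation(8, 8, 0.0, seed=0)
        lc = e.like(
            np.where(np.arange(64).reshape(8, 8) < 32, int(LandCover.LOWLAND_FOREST), int(LandCover.PLANTATION_REGROWTH))
        )
        table = {int(LandCover.LOWLAND_FOREST): 1.0, int(LandCover.PLANTATION_REGROWTH): 10.0}
        r = generate_resistance(lc, table)
        assert set(np.unique(r.values)) == {1.0, 10.0}
        # changing only the table changes output by lookup alone
        r2 = generate_resistance(lc, {**table, int(LandCover.PLANTATION_REGROWTH): 25.0})
        assert np.all(r2.values[lc.values == int(LandCover.PLANTATION_REGROWTH)] == 25.0)

    def test_unknown_code_rejected(self):
        e = generate_elevation(8, 8, 0.0, seed=0)
        lc = e.like(np.full((8, 8), 99))
        with pytest.raises(ValueError):
            generate_resistance(lc, DEFAULT_RESISTANCE)

    def test_forest_not_costlier_than_converted_land(self):
        assert max(DEFAULT_RESISTANCE[int(c)] for c in FOREST_CLASSES) <= min(
            DEFAULT_RESISTANCE[int(LandCover.PLANTATION_REGROWTH)],
            DEFAULT_RESISTANCE[int(LandCover.URBAN)],
        )


class TestJointStructure:
    def test_fixed_seed_bit_identical(self):
        a = generate_landscape(SyntheticConfig(seed=11))
        b = generate_landscape(SyntheticConfig(seed=11))
        for layer in ("elevation", "landcover", "risk", "carbon", "pa_mask", "resistance"):
            np.testing.assert_array_equal(getattr(a, layer).values, getattr(b, layer).values)

    def test_premises_hold(self, landscape):
        land = landscape
        f = forest_mask(land.landcover)
        pa = land.pa_mask.values > 0
        assert np.corrcoef(land.risk.values[f], land.elevation.values[f])[0, 1] < 0
        assert land.risk.values[pa & f].mean() < land.risk.values[~pa & f].mean()
        assert land.elevation.values[pa].mean() > land.elevation.values[~pa].mean()
        assert np.array_equal(land.carbon.values > 0, f)
        assert land.resistance.values.min() >= 1.0
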