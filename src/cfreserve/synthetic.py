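"""Seeded synthetic landscapes with the statistical structure of insular SE-Asian
forest landscapes.

The downstream analysis (reserve prioritisation, connectivity, landscape
genetics) needs a stack of co-registered layers: elevation, categorical land
cover, per-cell probability of forest loss, above-ground biomass (AGB)
carbon, a protected-area mask, and a movement-resistance surface. Real
inputs of this kind (global forest-loss risk maps, pan-tropical AGB
benchmarks, the WDPA) are replaced here by generators that reproduce the
joint structure the analysis assumes:

* loss risk declines with elevation and with distance from existing
  non-forest (deforestation spreads from the edge of the frontier);
* protected areas are biased toward high, remote, low-risk terrain
  ("high and far" / "rocks and ice" residual reserves);
* carbon lives only on forest, with class-dependent biomass.

Every generator is deterministic for a fixed seed; a fixed
:class:`SyntheticConfig` therefore yields a bit-identical landscape.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .raster import GridRaster

__all__ = [
    "LandCover",
    "FOREST_CLASSES",
    "NONFOREST_CLASSES",
    "DEFAULT_CARBON_MEANS",
    "DEFAULT_RESISTANCE",
    "SyntheticConfig",
    "SyntheticLandscape",
    "generate_elevation",
    "generate_landcover",
    "generate_pa_mask",
    "generate_risk",
    "generate_carbon",
    "generate_resistance",
    "generate_landscape",
]


class LandCover(IntEnum):
    """Land-cover classes: five forest types plus non-forest land uses."""

    MANGROVE = 1
    PEAT_SWAMP_FOREST = 2
    LOWLAND_FOREST = 3
    LOWER_MONTANE_FOREST = 4
    UPPER_MONTANE_FOREST = 5
    WATER = 6
    PLANTATION_REGROWTH = 7
    LOWLAND_MOSAIC = 8
    URBAN = 9


FOREST_CLASSES = frozenset(
    {
        LandCover.MANGROVE,
        LandCover.PEAT_SWAMP_FOREST,
        LandCover.LOWLAND_FOREST,
        LandCover.LOWER_MONTANE_FOREST,
        LandCover.UPPER_MONTANE_FOREST,
    }
)
NONFOREST_CLASSES = frozenset(
    {LandCover.WATER, LandCover.PLANTATION_REGROWTH, LandCover.LOWLAND_MOSAIC, LandCover.URBAN}
)

# Per-cell mean AGB (Mg per 500 m cell = 25 ha). Tropical moist forest holds
# roughly 150-250 Mg/ha; montane and swamp forest less.
DEFAULT_CARBON_MEANS: dict[int, float] = {
    LandCover.MANGROVE: 2500.0,
    LandCover.PEAT_SWAMP_FOREST: 4000.0,
    LandCover.LOWLAND_FOREST: 6000.0,
    LandCover.LOWER_MONTANE_FOREST: 4500.0,
    LandCover.UPPER_MONTANE_FOREST: 3000.0,
}

# Movement resistance per class. The originating connectivity study never
# published its class table, so these are documented, configurable defaults:
# forest is the least-cost condition (1); converted land uses are costlier.
DEFAULT_RESISTANCE: dict[int, float] = {
    LandCover.MANGROVE: 2.0,
    LandCover.PEAT_SWAMP_FOREST: 1.0,
    LandCover.LOWLAND_FOREST: 1.0,
    LandCover.LOWER_MONTANE_FOREST: 1.0,
    LandCover.UPPER_MONTANE_FOREST: 2.0,
    LandCover.WATER: 20.0,
    LandCover.PLANTATION_REGROWTH: 10.0,
    LandCover.LOWLAND_MOSAIC: 7.0,
    LandCover.URBAN: 30.0,
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic landscape realisation."""

    nrows: int = 64
    ncols: int = 64
    cell_size: float = 500.0
    forest_fraction: float = 0.6
    # Existing protected estate ~6% of land: the scale implied by a locked
    # network well below the 17% design target (strict-category reserves
    # with mapped boundaries are a minority share of Bornean land).
    pa_fraction: float = 0.06
    roughness: float = 1.0
    risk_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -1.0,
            "elevation_slope": -1.5,
            "edge_distance_slope": -1.0,
            "pa_offset": -2.0,
        }
    )
    plantation_resistance: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 8 or self.ncols < 8:
            raise ValueError("grid must be at least 8x8")
        if not 0.0 < self.forest_fraction < 1.0:
            raise ValueError("forest_fraction must lie in (0, 1)")
        if not 0.0 <= self.pa_fraction < 1.0:
            raise ValueError("pa_fraction must lie in [0, 1)")
        if self.plantation_resistance < 1:
            raise ValueError("plantation_resistance must be >= 1")


@dataclass
class SyntheticLandscape:
    """The co-registered layer stack one seed produces."""

    elevation: GridRaster
    landcover: GridRaster
    risk: GridRaster
    carbon: GridRaster
    pa_mask: GridRaster
    resistance: GridRaster
    config: SyntheticConfig

    def __post_init__(self) -> None:
        self.elevation.require_aligned(
            self.landcover, self.risk, self.carbon, self.pa_mask, self.resistance
        )


def _spectral_noise(nrows: int, ncols: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance 1/f^beta Gaussian random field."""
    white = rng.standard_normal((nrows, ncols))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(nrows)[:, None]
    fx = np.fft.fftfreq(ncols)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill the DC term; mean handled separately
    spectrum *= f ** (-beta / 2.0)
    fieldv = np.real(np.fft.ifft2(spectrum))
    sd = fieldv.std()
    if sd > 0:
        fieldv /= sd
    return fieldv


def generate_elevation(
    nrows: int,
    ncols: int,
    roughness: float = 1.0,
    seed: int = 0,
    *,
    cell_size: float = 500.0,
    base: float = 400.0,
    relief: float = 600.0,
    beta: float = 2.2,
) -> GridRaster:
    """Spatially autocorrelated elevation surface via spectral (1/f^beta) synthesis.

    ``roughness`` scales the relief amplitude linearly; 0 gives a flat surface
    at ``base`` metres. ``beta`` controls spectral slope (higher = smoother).
    """
    if nrows < 1 or ncols < 1:
        raise ValueError("non-positive grid dimensions")
    if roughness < 0:
        raise ValueError("roughness must be >= 0")
    rng = np.random.default_rng(seed)
    if roughness == 0:
        values = np.full((nrows, ncols), base)
    else:
        noise = _spectral_noise(nrows, ncols, beta, rng)
        values = base + relief * roughness * noise
        values = np.maximum(values, 0.0)  # clip below sea level
    return GridRaster(values=values, cell_size=cell_size)


def generate_landcover(
    elevation: GridRaster, forest_fraction: float, seed: int = 0
) -> GridRaster:
    """Categorical land cover: forest classes stratified by elevation.

    A smooth suitability field thresholded at the ``forest_fraction`` quantile
    decides forest vs non-forest, so the realised forest share matches the
    request up to ties. Within forest, classes follow elevation quantiles
    (mangrove and peat-swamp lowest, upper montane highest); non-forest splits
    into water (lowest terrain), mosaic/plantation, and scattered urban.
    """
    if not 0.0 < forest_fraction < 1.0:
        raise ValueError("forest_fraction must lie in (0, 1)")
    if not np.all(np.isfinite(elevation.values)):
        raise ValueError("elevation must be finite")
    rng = np.random.default_rng(seed)
    nrows, ncols = elevation.shape
    elev = elevation.values

    # Forest suitability: autocorrelated noise plus a mild pull toward high
    # ground (remaining forest concentrates away from the converted lowlands).
    noise = _spectral_noise(nrows, ncols, 2.0, rng)
    elev_rank = _rankz(elev, rng)
    suitability = noise + 0.8 * elev_rank
    threshold = np.quantile(suitability, 1.0 - forest_fraction)
    forest = suitability > threshold

    codes = np.empty((nrows, ncols), dtype=np.int64)

    f_elev = elev[forest]
    if f_elev.size:
        q = np.quantile(f_elev, [0.05, 0.15, 0.70, 0.92])
        fcodes = np.full(f_elev.shape, int(LandCover.LOWLAND_FOREST))
        fcodes[f_elev <= q[0]] = int(LandCover.MANGROVE)
        fcodes[(f_elev > q[0]) & (f_elev <= q[1])] = int(LandCover.PEAT_SWAMP_FOREST)
        fcodes[(f_elev > q[2]) & (f_elev <= q[3])] = int(LandCover.LOWER_MONTANE_FOREST)
        fcodes[f_elev > q[3]] = int(LandCover.UPPER_MONTANE_FOREST)
        codes[forest] = fcodes

    nf = ~forest
    nf_elev = elev[nf]
    if nf_elev.size:
        nfcodes = np.full(nf_elev.shape, int(LandCover.PLANTATION_REGROWTH))
        water_cut = np.quantile(nf_elev, 0.08)
        nfcodes[nf_elev <= water_cut] = int(LandCover.WATER)
        mosaic = rng.random(nf_elev.shape) < 0.35
        nfcodes[mosaic & (nfcodes == int(LandCover.PLANTATION_REGROWTH))] = int(
            LandCover.LOWLAND_MOSAIC
        )
        urban = rng.random(nf_elev.shape) < 0.03
        nfcodes[urban & (nfcodes != int(LandCover.WATER))] = int(LandCover.URBAN)
        codes[nf] = nfcodes

    return elevation.like(codes)


def _rankz(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank-transform to a uniform-ish z score in [-1.73, 1.73]; random tie order."""
    flat = values.ravel()
    jitter = rng.random(flat.size) * 1e-9
    order = np.argsort(flat + jitter)
    ranks = np.empty(flat.size)
    ranks[order] = np.arange(flat.size)
    u = (ranks + 0.5) / flat.size
    return ((u - 0.5) * np.sqrt(12.0)).reshape(values.shape)


def generate_pa_mask(
    elevation: GridRaster,
    risk_free_cover: GridRaster,
    pa_fraction: float,
    seed: int = 0,
    *,
    n_blobs: int = 6,
    compactness: float = 0.35,
) -> GridRaster:
    """Protected-area mask biased toward high-elevation terrain ("high and far").

    Contiguous reserves are grown from ``n_blobs`` seeds placed on the
    highest-elevation eligible cells (spread apart), by priority-queue region
    growing on elevation rank with small noise, until ``pa_fraction`` of all
    cells is protected. Growth is restricted to ``risk_free_cover`` (the
    eligible land, typically the forest mask). ``compactness`` penalises
    growth away from the blob seed (rank units per cell of distance), so
    reserves come out as compact polygons rather than ridge-following
    filaments — gazetted reserves have drawn boundaries, not contour traces.
    """
    elevation.require_aligned(risk_free_cover)
    cover = risk_free_cover.values.astype(bool)
    n_total = elevation.values.size
    target = int(round(pa_fraction * n_total))
    mask = np.zeros(elevation.shape, dtype=np.int64)
    if target == 0:
        return elevation.like(mask)
    if target > cover.sum():
        raise ValueError("pa_fraction exceeds the eligible cover share")

    rng = np.random.default_rng(seed)
    elev = elevation.values
    nrows, ncols = elevation.shape

    # Seeds: highest eligible cells, enforcing a minimum separation so blobs
    # do not all start on one massif.
    order = np.argsort(elev[cover])[::-1]
    eligible_idx = np.flatnonzero(cover.ravel())[order]
    min_sep = max(nrows, ncols) / (n_blobs + 1)
    seeds: list[int] = []
    for idx in eligible_idx:
        r, c = divmod(int(idx), ncols)
        if all(np.hypot(r - sr, c - sc) >= min_sep for sr, sc in seeds_rc(seeds, ncols)):
            seeds.append(int(idx))
        if len(seeds) == n_blobs:
            break

    # Priority growth: always expand into the highest-ranked eligible frontier
    # cell (heapq is a min-heap, so negate elevation rank).
    rank = _rankz(elev, rng).ravel()
    seed_rc = {s: divmod(s, ncols) for s in seeds}
    in_mask = np.zeros(n_total, dtype=bool)
    queued = np.zeros(n_total, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for idx in seeds:
        heapq.heappush(heap, (-rank[idx], idx, idx))
        queued[idx] = True
    taken = 0
    cover_flat = cover.ravel()
    while heap and taken < target:
        _, idx, origin = heapq.heappop(heap)
        if in_mask[idx]:
            continue
        in_mask[idx] = True
        taken += 1
        r, c = divmod(idx, ncols)
        sr, sc = seed_rc[origin]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                j = rr * ncols + cc
                if cover_flat[j] and not in_mask[j] and not queued[j]:
                    queued[j] = True
                    prio = (
                        -rank[j]
                        + compactness * float(np.hypot(rr - sr, cc - sc))
                        + rng.normal(scale=0.05)
                    )
                    heapq.heappush(heap, (prio, j, origin))
    mask = in_mask.reshape(nrows, ncols).astype(np.int64)
    return elevation.like(mask)


def seeds_rc(seeds: list[int], ncols: int):
    return [divmod(s, ncols) for s in seeds]


def generate_risk(
    elevation: GridRaster,
    landcover: GridRaster,
    pa_mask: GridRaster,
    risk_coefficients: dict[str, float],
) -> GridRaster:
    """Probability that a forested cell is lost over the coming decade.

    A logistic model in three standardised covariates::

        risk = logistic(b0 + b_e * z(elevation)
                           + b_d * z(distance to non-forest)
                           + b_pa * protected)

    Non-forest cells carry risk 0 (there is no forest left to lose there).
    Negative ``elevation_slope`` and ``edge_distance_slope`` reproduce the
    empirical regularity that loss concentrates low and near the frontier;
    negative ``pa_offset`` encodes partial protection effectiveness.
    """
    elevation.require_aligned(landcover, pa_mask)
    coeffs = risk_coefficients
    elev = elevation.values
    forest = np.isin(landcover.values, [int(c) for c in FOREST_CLASSES])

    z_elev = _zscore(elev)
    # Euclidean distance (in cells) to the nearest non-forest cell.
    dist = ndimage.distance_transform_edt(forest)
    z_dist = _zscore(dist)

    lin = (
        coeffs["intercept"]
        + coeffs["elevation_slope"] * z_elev
        + coeffs["edge_distance_slope"] * z_dist
        + coeffs["pa_offset"] * (pa_mask.values > 0)
    )
    risk = 1.0 / (1.0 + np.exp(-lin))
    risk[~forest] = 0.0
    return elevation.like(risk)


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def generate_carbon(
    landcover: GridRaster,
    elevation: GridRaster,
    seed: int = 0,
    *,
    class_means: dict[int, float] | None = None,
    lognormal_sigma: float = 0.3,
) -> GridRaster:
    """Above-ground biomass per cell (Mg): class-dependent means, lognormal noise.

    The lognormal is parameterised so the arithmetic mean of each class equals
    its table entry. Non-forest cells carry 0.
    """
    landcover.require_aligned(elevation)
    means = DEFAULT_CARBON_MEANS if class_means is None else class_means
    rng = np.random.default_rng(seed)
    codes = landcover.values
    carbon = np.zeros(codes.shape, dtype=float)
    sigma = lognormal_sigma
    for code, mean in means.items():
        cells = codes == int(code)
        if not cells.any():
            continue
        mu = np.log(mean) - sigma**2 / 2.0
        carbon[cells] = rng.lognormal(mean=mu, sigma=sigma, size=int(cells.sum()))
    return landcover.like(carbon)


def generate_resistance(
    landcover: GridRaster, class_resistance_table: dict[int, float] | None = None
) -> GridRaster:
    """Movement resistance by pure table lookup on land-cover class."""
    table = DEFAULT_RESISTANCE if class_resistance_table is None else class_resistance_table
    codes = landcover.values
    present = np.unique(codes)
    missing = [int(c) for c in present if int(c) not in {int(k) for k in table}]
    if missing:
        raise ValueError(f"no resistance entry for land-cover code(s) {missing}")
    lut_size = int(max(int(k) for k in table)) + 1
    lut = np.ones(lut_size)
    for code, r in table.items():
        if r < 1:
            raise ValueError("resistance values must be >= 1")
        lut[int(code)] = r
    return landcover.like(lut[codes.astype(np.int64)])


def generate_landscape(config: SyntheticConfig) -> SyntheticLandscape:
    """Generate the full co-registered layer stack from one config.

    The master seed fans out to per-layer seeds by fixed offsets, so each
    layer is independently reproducible.
    """
    s = config.seed
    elevation = generate_elevation(
        config.nrows, config.ncols, config.roughness, seed=s, cell_size=config.cell_size
    )
    landcover = generate_landcover(elevation, config.forest_fraction, seed=s + 1)
    forest = landcover.like(
        np.isin(landcover.values, [int(c) for c in FOREST_CLASSES]).astype(np.int64)
    )
    pa_mask = generate_pa_mask(elevation, forest, config.pa_fraction, seed=s + 2)
    risk = generate_risk(elevation, landcover, pa_mask, config.risk_coefficients)
    carbon = generate_carbon(landcover, elevation, seed=s + 3)
    resistance_table = dict(DEFAULT_RESISTANCE)
    resistance_table[int(LandCover.PLANTATION_REGROWTH)] = config.plantation_resistance
    resistance = generate_resistance(landcover, resistance_table)
    return SyntheticLandscape(
        elevation=elevation,
        landcover=landcover,
        risk=risk,
        carbon=carbon,
        pa_mask=pa_mask,
        resistance=resistance,
        config=config,
    )
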