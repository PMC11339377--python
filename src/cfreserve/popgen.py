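"""Spatially explicit individual-based simulation of mating, dispersal and drift.

Individuals of a territorial forest carnivore occupy fixed habitat points
(one occupant per point — a home-range capacity rule), with mating and
offspring dispersal both down-weighted by least-cost distance through the
resistance surface. Generations are non-overlapping; genotypes are diploid
multi-locus with no mutation or selection, so declining allelic richness and
heterozygosity are clean signals of drift and fragmentation-induced
isolation. The design follows the fixed-locations landscape-genetics
simulation tradition (CDPOP and kin).

Model per generation:

1. every female draws, for each offspring, a father among males with
   probability proportional to ``max(0, 1 - cost / max_cost)`` (mating with
   replacement); a female with no reachable male leaves no offspring;
2. brood sizes are Poisson(``offspring_mean``); each offspring inherits one
   uniformly random allele per parent per locus and a Bernoulli(1/2) sex;
3. offspring, in random order, settle at the nearest (by cost) unoccupied
   point within ``max_cost`` of the natal point; the rest die;
4. parents die; the settled offspring are the next generation.

The panmictic limit (all costs zero) reduces to a Wright-Fisher-like
population of size equal to the number of points, whose expected
heterozygosity decays as ``H_t = H_0 (1 - 1/(2N))^t`` — the module's
quantitative calibration anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import cost_surfaces
from .raster import GridRaster

__all__ = [
    "HabitatPoints",
    "PopGenParams",
    "PopState",
    "build_points",
    "init_population",
    "step_generation",
    "summarize",
    "run_simulation",
]


@dataclass
class HabitatPoints:
    """Fixed point locations and their pairwise least-cost distances."""

    coords: np.ndarray  # (n, 2) cell indices (row, col)
    cost: np.ndarray  # (n, n) symmetric, 0 diagonal, +inf if unreachable

    def __post_init__(self) -> None:
        n = len(self.coords)
        if self.cost.shape != (n, n):
            raise ValueError("cost matrix shape does not match point count")
        if not np.allclose(np.diag(self.cost), 0.0):
            raise ValueError("cost diagonal must be 0")
        finite = np.isfinite(self.cost)
        if not np.allclose(self.cost[finite], self.cost.T[finite]):
            raise ValueError("cost matrix must be symmetric")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    @classmethod
    def panmictic(cls, n: int) -> "HabitatPoints":
        """n points at zero mutual cost — the well-mixed calibration case."""
        coords = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
        return cls(coords=coords, cost=np.zeros((n, n)))


@dataclass
class PopGenParams:
    """Genetic and demographic parameters (field-typical defaults)."""

    n_loci: int = 30
    n_alleles_init: int = 10
    generations: int = 200
    max_cost: float = 125_000.0
    offspring_mean: float = 4.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.max_cost <= 0:
            raise ValueError("max_cost must be > 0")
        if self.n_loci < 1 or self.n_alleles_init < 1:
            raise ValueError("need at least one locus and one allele")


@dataclass
class PopState:
    """Occupancy, sex and diploid genotypes at each habitat point.

    ``genotypes[p, l, :]`` are the two alleles of the occupant of point p at
    locus l (undefined where ``occupied[p]`` is False). Sex: 0 = female,
    1 = male.
    """

    occupied: np.ndarray  # (n,) bool
    sex: np.ndarray  # (n,) int8
    genotypes: np.ndarray  # (n, loci, 2) int

    @property
    def n(self) -> int:
        return int(self.occupied.sum())


def build_points(
    core_mask: GridRaster,
    spacing: int,
    resistance: GridRaster,
    seed: int = 0,
) -> HabitatPoints:
    """Lattice of home-range points on core habitat, with pairwise least-cost
    distances through the resistance surface.

    ``spacing`` is in cells; with 500 m cells, spacing 8 gives one point per
    16 km2 — one female home range per point.
    """
    core_mask.require_aligned(resistance)
    mask = core_mask.values > 0
    if not mask.any():
        raise ValueError("core mask is empty")
    nrows, ncols = mask.shape
    coords = np.array(
        [
            (r, c)
            for r in range(0, nrows, spacing)
            for c in range(0, ncols, spacing)
            if mask[r, c]
        ],
        dtype=int,
    )
    if len(coords) == 0:
        raise ValueError("no lattice point fell on core habitat; reduce spacing")
    surf = cost_surfaces(resistance, [tuple(x) for x in coords], max_cost=np.inf)
    cost = surf[:, coords[:, 0], coords[:, 1]]
    cost = 0.5 * (cost + cost.T)  # symmetrise numerical noise
    np.fill_diagonal(cost, 0.0)
    return HabitatPoints(coords=coords, cost=cost)


def init_population(points: HabitatPoints, params: PopGenParams, rng: np.random.Generator) -> PopState:
    """Fully occupied start: random sexes, alleles i.i.d. uniform per locus.

    Expected initial observed heterozygosity is ``1 - 1/n_alleles_init``.
    """
    n = points.n_points
    return PopState(
        occupied=np.ones(n, dtype=bool),
        sex=rng.integers(0, 2, size=n).astype(np.int8),
        genotypes=rng.integers(
            0, params.n_alleles_init, size=(n, params.n_loci, 2)
        ).astype(np.int16),
    )


def step_generation(
    state: PopState, points: HabitatPoints, params: PopGenParams, rng: np.random.Generator
) -> PopState:
    """Advance one non-overlapping generation (mating, birth, dispersal)."""
    n = points.n_points
    occ = np.flatnonzero(state.occupied)
    females = occ[state.sex[occ] == 0]
    males = occ[state.sex[occ] == 1]

    new = PopState(
        occupied=np.zeros(n, dtype=bool),
        sex=np.zeros(n, dtype=np.int8),
        genotypes=np.zeros_like(state.genotypes),
    )
    if females.size == 0 or males.size == 0:
        return new

    # offspring pool: (natal point, genotype, sex)
    natal: list[int] = []
    geno: list[np.ndarray] = []
    loci = params.n_loci
    for f in females:
        w = np.maximum(0.0, 1.0 - points.cost[f, males] / params.max_cost)
        wsum = w.sum()
        if wsum <= 0:
            continue  # no reachable male
        k = rng.poisson(params.offspring_mean)
        if k == 0:
            continue
        fathers = males[rng.choice(males.size, size=k, p=w / wsum)]
        m_gam = state.genotypes[f, np.arange(loci), rng.integers(0, 2, size=(k, loci))]
        p_gam = state.genotypes[fathers[:, None], np.arange(loci)[None, :], rng.integers(0, 2, size=(k, loci))]
        geno.append(np.stack([m_gam, p_gam], axis=-1))
        natal.extend([int(f)] * k)

    if not natal:
        return new
    genotypes = np.concatenate(geno, axis=0)
    natal_arr = np.array(natal)
    sexes = rng.integers(0, 2, size=len(natal_arr)).astype(np.int8)

    # dispersal: random order; settle at nearest unoccupied point within budget
    order = rng.permutation(len(natal_arr))
    taken = np.zeros(n, dtype=bool)
    for i in order:
        c = points.cost[natal_arr[i]]
        reachable = (~taken) & (c <= params.max_cost)
        if not reachable.any():
            continue  # dies
        cmin = c[reachable].min()
        candidates = np.flatnonzero(reachable & (c <= cmin + 1e-9))
        p = int(candidates[rng.integers(candidates.size)]) if candidates.size > 1 else int(candidates[0])
        taken[p] = True
        new.occupied[p] = True
        new.sex[p] = sexes[i]
        new.genotypes[p] = genotypes[i]
    return new


def summarize(state: PopState) -> tuple[float, int, int]:
    """(observed heterozygosity, total distinct alleles over loci, population size)."""
    occ = np.flatnonzero(state.occupied)
    if occ.size == 0:
        return 0.0, 0, 0
    g = state.genotypes[occ]  # (N, loci, 2)
    ho = float(np.mean(g[:, :, 0] != g[:, :, 1]))
    total_alleles = int(sum(len(np.unique(g[:, l, :])) for l in range(g.shape[1])))
    return ho, total_alleles, int(occ.size)


def run_simulation(
    points: HabitatPoints, params: PopGenParams
) -> pd.DataFrame:
    """Replicated simulation; per-generation summaries in long format.

    Columns: replicate, generation (0 = initial state), Ho, alleles, N.
    Deterministic for a fixed (seed, replicate) pair: replicate streams are
    spawned from the master seed.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.replicates)
    rows = []
    for rep, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        state = init_population(points, params, rng)
        ho, alleles, n_ind = summarize(state)
        rows.append((rep, 0, ho, alleles, n_ind))
        for t in range(1, params.generations + 1):
            state = step_generation(state, points, params, rng)
            ho, alleles, n_ind = summarize(state)
            rows.append((rep, t, ho, alleles, n_ind))
    return pd.DataFrame(rows, columns=["replicate", "generation", "Ho", "alleles", "N"])


def simulate_on_landscape(
    resistance: GridRaster, core_mask: GridRaster, params: PopGenParams, spacing: int = 8
) -> pd.DataFrame:
    """Convenience wrapper: place points on core habitat, then simulate."""
    points = build_points(core_mask, spacing, resistance)
    return run_simulation(points, params)
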