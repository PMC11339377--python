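import numpy as np
import pytest

from cfreserve import (
    GridRaster,
    SyntheticConfig,
    apply_eligibility,
    build_planning_units,
    generate_landscape,
)


@pytest.fixture(scope="session")
def landscape():
    """One 64x64 synthetic landscape shared by read-only tests."""
    return generate_landscape(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def unit_table(landscape):
    from cfreserve import KernelParams, classify_forest, place_sources, resistant_kernel_density

    kernel = resistant_kernel_density(
        landscape.resistance,
        place_sources(classify_forest(landscape.landcover), 8),
        KernelParams(bandwidth=4000.0),
    )
    table = build_planning_units(
        {
            "landcover": landscape.landcover,
            "pa_mask": landscape.pa_mask,
            "kernel": kernel,
            "carbon": landscape.carbon,
            "risk": landscape.risk,
        },
        8,
    )
    unit_area = (8 * landscape.landcover.cell_size / 1000.0) ** 2
    return apply_eligibility(table, 0.16 * unit_area, 0.16 * unit_area)


@pytest.fixture()
def uniform_resistance():
    """8x8 grid of resistance 1, 500 m cells."""
    return GridRaster(values=np.ones((8, 8)), cell_size=500.0)


def toy_problem(
    costs,
    amounts,
    targets,
    blm=0.0,
    locked=(),
    perimeter=None,
    edges=(),
    spf=2.0,
):
    """Small ReserveProblem factory for hand-checkable cases.

    ``edges`` is an iterable of (i, j, shared_length_km); ``perimeter``
    defaults to 40 km per unit (a 10 km square).
    """
    from cfreserve import ReserveProblem

    costs = np.asarray(costs, dtype=float)
    amounts = np.atleast_2d(np.asarray(amounts, dtype=float))
    if amounts.shape[0] != len(costs):
        amounts = amounts.T
    n = len(costs)
    nbrs = [[] for _ in range(n)]
    for i, j, L in edges:
        nbrs[i].append((j, float(L)))
        nbrs[j].append((i, float(L)))
    return ReserveProblem(
        ids=np.arange(n),
        cost=costs,
        amounts=amounts,
        feature_names=tuple(f"f{k}" for k in range(amounts.shape[1])),
        targets=np.asarray(targets, dtype=float),
        spf=np.full(amounts.shape[1], spf),
        blm=blm,
        locked=frozenset(locked),
        perimeter=np.full(n, 40.0) if perimeter is None else np.asarray(perimeter, dtype=float),
        neighbours=nbrs,
    )


def brute_force_optimum(problem):
    """Exhaustive search over all subsets containing the locked set."""
    import itertools

    from cfreserve import objective

    free = [int(u) for u in problem.ids if int(u) not in problem.locked]
    best = np.inf
    best_set = None
    for r in range(len(free) + 1):
        for sub in itertools.combinations(free, r):
            sel = frozenset(sub) | problem.locked
            o = objective(problem, sel)
            if o < best:
                best, best_set = o, sel
    return best, best_set
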