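"""Planning-unit data model: preprocessing, aggregation and eligibility.

Reserve selection operates on a coarse grid of square planning units (the
field convention for island-wide prioritisation is 10 x 10 km units over
500 m cells, i.e. ``unit_size_cells=20``). Each unit aggregates the cell
layers beneath it: forest area, protected area, kernel-density sum, carbon
sum, mean loss risk. Eligibility follows home-range reasoning: a unit is
*available* for selection only if it holds at least ``min_forest_km2`` of
forest (one female home range, ~16 km2), and counts as already *protected*
(locked into solutions that retain the existing network) only if it holds
more than ``min_pa_km2`` of protected area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import GridRaster
from .synthetic import FOREST_CLASSES, LandCover

__all__ = [
    "PlanningUnitTable",
    "classify_forest",
    "normalize_layer",
    "build_planning_units",
    "apply_eligibility",
    "write_marxan_files",
]


def classify_forest(
    landcover: GridRaster, forest_class_set: frozenset | set | None = None
) -> GridRaster:
    """Binary forest mask: 1 iff the land-cover class is in ``forest_class_set``."""
    classes = FOREST_CLASSES if forest_class_set is None else forest_class_set
    codes = landcover.values
    known = {int(c) for c in LandCover}
    unknown = [int(c) for c in np.unique(codes) if int(c) not in known]
    if unknown:
        raise ValueError(f"unknown land-cover code(s) {unknown}")
    mask = np.isin(codes, [int(c) for c in classes]).astype(np.int64)
    return landcover.like(mask)


def normalize_layer(raster: GridRaster) -> GridRaster:
    """Scale a non-negative layer to [0, 1] by dividing by its maximum."""
    valid = raster.valid_mask()
    vmax = raster.values[valid].max() if valid.any() else 0.0
    if vmax <= 0:
        raise ValueError("cannot normalize a layer with non-positive maximum")
    values = raster.values.astype(float).copy()
    values[valid] = values[valid] / vmax
    return raster.like(values)


@dataclass
class PlanningUnitTable:
    """Per-unit aggregates plus the symmetric shared-boundary relation.

    ``units`` columns: id, row, col, area_km2, forest_area_km2, pa_area_km2,
    kernel_sum, carbon_sum, risk_sum, mean_risk, available, locked.
    ``boundaries`` columns: id1, id2, length_km (id1 < id2, each pair once).
    ``perimeter_km`` maps id -> total exposed perimeter of the unit's land
    cells (shared edges + landscape-exterior edges).
    """

    units: pd.DataFrame
    boundaries: pd.DataFrame
    perimeter_km: dict[int, float]
    unit_size_cells: int
    cell_size: float

    def to_csv(self, path: str | Path) -> None:
        self.units.to_csv(path, index=False)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def neighbours(self, unit_id: int) -> list[tuple[int, float]]:
        b = self.boundaries
        out = [
            (int(r.id2), float(r.length_km)) for r in b[b.id1 == unit_id].itertuples()
        ] + [(int(r.id1), float(r.length_km)) for r in b[b.id2 == unit_id].itertuples()]
        return sorted(out)


def build_planning_units(
    rasters: dict[str, GridRaster], unit_size_cells: int
) -> PlanningUnitTable:
    """Aggregate cell layers onto a coarse grid of square planning units.

    ``rasters`` must contain ``landcover``; optional layers ``pa_mask``,
    ``kernel``, ``carbon``, ``risk`` feed the corresponding aggregates (absent
    layers yield zero columns). Edge units may be truncated (partial "coastal"
    units with area below the full unit area). Aggregation is an exact
    partition: unit sums reproduce raster totals.
    """
    if "landcover" not in rasters:
        raise ValueError("rasters must include a 'landcover' layer")
    base = rasters["landcover"]
    base.require_aligned(*[r for k, r in rasters.items() if k != "landcover"])
    if unit_size_cells < 1:
        raise ValueError("unit_size_cells must be >= 1")

    nrows, ncols = base.shape
    cell_area = base.cell_area_km2
    cell_km = base.cell_size / 1000.0
    u = unit_size_cells
    unit_rows = int(np.ceil(nrows / u))
    unit_cols = int(np.ceil(ncols / u))

    # Row-major unit id per cell.
    rr, cc = np.meshgrid(np.arange(nrows) // u, np.arange(ncols) // u, indexing="ij")
    unit_id = rr * unit_cols + cc

    valid = base.valid_mask()
    forest = np.isin(base.values, [int(c) for c in FOREST_CLASSES])

    def zonal_sum(values: np.ndarray, where: np.ndarray) -> np.ndarray:
        w = np.where(where, values, 0.0)
        return np.bincount(unit_id.ravel(), weights=w.ravel(), minlength=unit_rows * unit_cols)

    n_cells = zonal_sum(np.ones(base.shape), valid)
    forest_cells = zonal_sum(np.ones(base.shape), valid & forest)
    records: dict[str, np.ndarray] = {
        "area_km2": n_cells * cell_area,
        "forest_area_km2": forest_cells * cell_area,
    }
    if "pa_mask" in rasters:
        records["pa_area_km2"] = zonal_sum(rasters["pa_mask"].values > 0, valid) * cell_area
    else:
        records["pa_area_km2"] = np.zeros_like(n_cells)
    for key, col in (("kernel", "kernel_sum"), ("carbon", "carbon_sum"), ("risk", "risk_sum")):
        if key in rasters:
            records[col] = zonal_sum(rasters[key].values, valid)
        else:
            records[col] = np.zeros_like(n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_risk = np.where(n_cells > 0, records["risk_sum"] / np.maximum(n_cells, 1), 0.0)
    records["mean_risk"] = mean_risk

    keep = n_cells > 0  # units intersecting land
    ids = np.arange(unit_rows * unit_cols)
    units = pd.DataFrame(
        {
            "id": ids[keep],
            "row": ids[keep] // unit_cols,
            "col": ids[keep] % unit_cols,
            **{k: v[keep] for k, v in records.items()},
        }
    )
    units["available"] = False
    units["locked"] = False

    # Shared boundaries between horizontally/vertically adjacent land cells in
    # different units; exterior edges (grid border, nodata side) count toward
    # the unit's perimeter only.
    n_units_total = unit_rows * unit_cols
    shared: dict[tuple[int, int], float] = {}
    exposed = np.zeros(n_units_total)

    for axis in (0, 1):
        a = slice(None, -1), slice(None)
        b = slice(1, None), slice(None)
        if axis == 1:
            a = a[::-1]
            b = b[::-1]
        va, vb = valid[a], valid[b]
        ua, ub = unit_id[a], unit_id[b]
        both = va & vb
        diff = both & (ua != ub)
        for i, j in zip(ua[diff].ravel(), ub[diff].ravel()):
            key = (min(int(i), int(j)), max(int(i), int(j)))
            shared[key] = shared.get(key, 0.0) + cell_km
        # shared edges also belong to both unit perimeters
        np.add.at(exposed, ua[diff].ravel(), cell_km)
        np.add.at(exposed, ub[diff].ravel(), cell_km)
        # edges against nodata
        only_a = va & ~vb
        only_b = vb & ~va
        np.add.at(exposed, ua[only_a].ravel(), cell_km)
        np.add.at(exposed, ub[only_b].ravel(), cell_km)

    # grid-exterior edges
    for edge_cells, uid_edge in (
        (valid[0, :], unit_id[0, :]),
        (valid[-1, :], unit_id[-1, :]),
        (valid[:, 0], unit_id[:, 0]),
        (valid[:, -1], unit_id[:, -1]),
    ):
        np.add.at(exposed, uid_edge[edge_cells].ravel(), cell_km)

    boundaries = pd.DataFrame(
        [(i, j, L) for (i, j), L in sorted(shared.items())],
        columns=["id1", "id2", "length_km"],
    ).astype({"id1": int, "id2": int})
    perimeter = {int(i): float(exposed[i]) for i in ids[keep]}
    return PlanningUnitTable(
        units=units,
        boundaries=boundaries,
        perimeter_km=perimeter,
        unit_size_cells=u,
        cell_size=base.cell_size,
    )


def apply_eligibility(
    table: PlanningUnitTable, min_forest_km2: float = 16.0, min_pa_km2: float = 16.0
) -> PlanningUnitTable:
    """Set availability and locked flags from forest and protected-area content.

    available <=> forest_area_km2 >= min_forest_km2 (inclusive);
    locked    <=> pa_area_km2   >  min_pa_km2     (strict);
    locked units are forced available regardless of forest content, since
    scenarios that retain the existing network lock them unconditionally.
    Idempotent and order-independent.
    """
    units = table.units.copy()
    if (units["forest_area_km2"] < 0).any() or (units["pa_area_km2"] < 0).any():
        raise ValueError("negative areas in planning-unit table")
    units["available"] = units["forest_area_km2"] >= min_forest_km2
    units["locked"] = units["pa_area_km2"] > min_pa_km2
    units.loc[units["locked"], "available"] = True
    return PlanningUnitTable(
        units=units,
        boundaries=table.boundaries,
        perimeter_km=table.perimeter_km,
        unit_size_cells=table.unit_size_cells,
        cell_size=table.cell_size,
    )


def write_marxan_files(
    table: PlanningUnitTable,
    outdir: str | Path,
    feature_columns: tuple[str, ...] = ("kernel_sum", "carbon_sum"),
    target_fraction: float = 0.30,
    spf: float = 2.0,
) -> None:
    """Write the classic MARXAN input dialect for interoperability.

    pu.dat (id,cost,status), spec.dat (id,prop,spf,name),
    puvspr.dat (species,pu,amount) and bound.dat (id1,id2,boundary).
    Status: 2 for locked-in units, 0 otherwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    units = table.units
    avail = units[units["available"]]

    pu = pd.DataFrame(
        {
            "id": avail["id"],
            "cost": avail["area_km2"],
            "status": np.where(avail["locked"], 2, 0),
        }
    )
    pu.to_csv(outdir / "pu.dat", index=False)

    spec_rows = [
        {"id": k + 1, "prop": target_fraction, "spf": spf, "name": col}
        for k, col in enumerate(feature_columns)
    ]
    pd.DataFrame(spec_rows).to_csv(outdir / "spec.dat", index=False)

    puvspr = []
    for k, col in enumerate(feature_columns):
        sub = avail[avail[col] > 0]
        puvspr.append(
            pd.DataFrame({"species": k + 1, "pu": sub["id"], "amount": sub[col]})
        )
    pd.concat(puvspr, ignore_index=True).sort_values(["pu", "species"]).to_csv(
        outdir / "puvspr.dat", index=False
    )

    bound = table.boundaries.rename(columns={"length_km": "boundary"})
    bound.to_csv(outdir / "bound.dat", index=False)
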