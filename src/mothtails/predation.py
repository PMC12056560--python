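"""Bat predation-pressure surfaces and covariate extraction.

Builds spatial predation metrics from species distribution model (SDM)
outputs: a richness surface (cellwise sum of clog-log suitability values), a
per-species density surface (the species' population total allocated over
cells proportionally to suitability), and the total abundance surface (sum of
densities).  Also implements the taxonomic filter selecting large aerial
insectivorous bats, and point extraction of raster values at moth occurrence
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "PressureSurfaces",
    "ExtractionError",
    "filter_bat_taxa",
    "richness_surface",
    "abundance_surface",
    "total_pressure_surface",
    "extract_at_points",
]


@dataclass
class RasterGrid:
    """A regular lon/lat grid; row 0 is the northernmost row.

    ``values`` is a 2-D float array with ``numpy.nan`` marking nodata cells
    in memory; ``nodata`` is the sentinel used on disk.  Cells are square
    (one ``cell_size``, in decimal degrees) as in the ESRI ASCII grid model,
    and are half-open: a point on a shared edge belongs to the cell to the
    east/south.
    """

    values: np.ndarray
    x_ll: float
    y_ll: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def y_top(self) -> float:
        return self.y_ll + self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple:
        """(lon_min, lon_max, lat_min, lat_max)."""
        return (
            self.x_ll,
            self.x_ll + self.n_cols * self.cell_size,
            self.y_ll,
            self.y_top,
        )

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x_ll - other.x_ll) <= tol
            and abs(self.y_ll - other.y_ll) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(
            values=values,
            x_ll=self.x_ll,
            y_ll=self.y_ll,
            cell_size=self.cell_size,
            nodata=self.nodata,
        )


@dataclass
class PressureSurfaces:
    """Richness, total abundance, and the per-species density surfaces."""

    richness: RasterGrid
    abundance: RasterGrid
    per_species_density: dict = field(default_factory=dict)


class ExtractionError(ValueError):
    """One or more points fell outside the raster extent."""

    def __init__(self, records: list):
        self.records = records
        preview = "; ".join(
            f"point {r['index']} ({r['lon']}, {r['lat']}): {r['reason']}"
            for r in records[:5]
        )
        more = f" (+{len(records) - 5} more)" if len(records) > 5 else ""
        super().__init__(f"{len(records)} point(s) outside raster extent: {preview}{more}")


# ---------------------------------------------------------------- bat filter
def filter_bat_taxa(
    table: pd.DataFrame, mass_threshold: float = 10.0, fraction: float = 0.5
) -> tuple:
    """Select likely saturniid-predator bats by three nested passes.

    1. Keep families in which at least ``fraction`` of genera are
       aerial-insectivore genera (a genus qualifies here when at least
       ``fraction`` of its species are aerial insectivores).
    2. Within kept families, keep genera in which at least ``fraction`` of
       species are aerial insectivores of mean mass >= ``mass_threshold``
       grams whose ranges overlap the moths.
    3. Keep the individual species satisfying that same conjunction.

    Returns ``(species_list, audit)`` where ``audit`` counts taxa retained at
    each level.
    """
    required = {
        "family",
        "genus",
        "species",
        "aerial_insectivore",
        "mean_mass_g",
        "overlaps_moths",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"bat taxon table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("bat taxon table is empty")
    t = table.copy()
    t["qualifies"] = (
        t["aerial_insectivore"].astype(bool)
        & (t["mean_mass_g"] >= mass_threshold)
        & t["overlaps_moths"].astype(bool)
    )

    genus_ai = t.groupby(["family", "genus"])["aerial_insectivore"].mean() >= fraction
    family_frac = genus_ai.groupby("family").mean()
    kept_families = set(family_frac[family_frac >= fraction].index)

    in_fam = t[t["family"].isin(kept_families)]
    genus_q = in_fam.groupby(["family", "genus"])["qualifies"].mean() >= fraction
    kept_genera = set(genus_q[genus_q].index)

    sel = in_fam[
        in_fam.apply(lambda r: (r["family"], r["genus"]) in kept_genera, axis=1)
        & in_fam["qualifies"]
    ]
    species = sorted(sel["species"].tolist())
    audit = {
        "n_families_total": int(t["family"].nunique()),
        "n_families_kept": len(kept_families),
        "n_genera_total": int(t.groupby(["family", "genus"]).ngroups),
        "n_genera_kept": len(kept_genera),
        "n_species_total": int(len(t)),
        "n_species_kept": len(species),
    }
    return species, audit


# ------------------------------------------------------------------ surfaces
def _check_shared_grid(surfaces: dict) -> RasterGrid:
    grids = list(surfaces.values())
    if not grids:
        raise ValueError("no surfaces provided")
    ref = grids[0]
    for name, g in surfaces.items():
        if not ref.same_grid(g):
            raise ValueError(f"surface {name!r} has a mismatched geotransform")
    return ref


def richness_surface(surfaces: dict) -> RasterGrid:
    """Cellwise sum of clog-log suitability surfaces (species richness).

    Nodata propagates only where *all* inputs are nodata.
    """
    ref = _check_shared_grid(surfaces)
    stack = np.stack([g.values for g in surfaces.values()])
    with np.errstate(invalid="ignore"):
        if np.nanmin(stack) < 0 or np.nanmax(stack) > 1:
            raise ValueError("suitability values must lie in [0, 1]")
    total = np.nansum(stack, axis=0)
    total[np.all(np.isnan(stack), axis=0)] = np.nan
    return ref.with_values(total)


def abundance_surface(suitability: RasterGrid, population: float) -> RasterGrid:
    """Allocate a population total over cells proportionally to suitability.

    ``density(cell) = suitability(cell) * population / sum(suitability)``;
    densities sum back to the population total.
    """
    if population < 0:
        raise ValueError("population must be >= 0")
    total = np.nansum(suitability.values)
    if population == 0:
        return suitability.with_values(np.where(np.isnan(suitability.values), np.nan, 0.0))
    if not np.isfinite(total) or total <= 0:
        raise ValueError(
            "all-zero (or all-nodata) suitability: population allocation undefined"
        )
    return suitability.with_values(suitability.values * (population / total))


def total_pressure_surface(surfaces: dict, populations: dict) -> PressureSurfaces:
    """Richness plus total and per-species bat density surfaces."""
    missing = set(surfaces) - set(populations)
    if missing:
        raise KeyError(f"missing population totals for: {sorted(missing)}")
    ref = _check_shared_grid(surfaces)
    densities = {
        name: abundance_surface(grid, populations[name])
        for name, grid in surfaces.items()
    }
    stack = np.stack([d.values for d in densities.values()])
    total = np.nansum(stack, axis=0)
    total[np.all(np.isnan(stack), axis=0)] = np.nan
    return PressureSurfaces(
        richness=richness_surface(surfaces),
        abundance=ref.with_values(total),
        per_species_density=densities,
    )


# ---------------------------------------------------------------- extraction
def extract_at_points(
    grid: RasterGrid, points: list, errors: str = "raise"
) -> np.ndarray:
    """Containing-cell lookup of raster values at (lon, lat) points.

    Cells are half-open in both axes: a point on a shared edge is assigned to
    the cell to the east/south.  Nodata cells yield ``numpy.nan``.  Points
    outside the extent raise :class:`ExtractionError` carrying one record per
    offending point, or — with ``errors="return"`` — yield ``nan`` and the
    records are returned alongside the values as ``(values, records)``.
    """
    if errors not in ("raise", "return"):
        raise ValueError("errors must be 'raise' or 'return'")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        out = np.empty(0)
        return (out, []) if errors == "return" else out
    lon, lat = pts[:, 0], pts[:, 1]
    col = np.floor((lon - grid.x_ll) / grid.cell_size).astype(int)
    row = np.floor((grid.y_top - lat) / grid.cell_size).astype(int)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    values = np.full(len(pts), np.nan)
    values[inside] = grid.values[row[inside], col[inside]]
    records = [
        {
            "index": int(i),
            "lon": float(lon[i]),
            "lat": float(lat[i]),
            "reason": "outside raster extent",
        }
        for i in np.flatnonzero(~inside)
    ]
    if records and errors == "raise":
        raise ExtractionError(records)
    if errors == "return":
        return values, records
    return values
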