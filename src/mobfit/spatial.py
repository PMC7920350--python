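"""Gridded representations of a population raster.

A :class:`SpatialSystem` is the geography every mobility model is evaluated
on: a set of cells with population-weighted centroids (planar metre
coordinates), a population count per cell, and an assignment of each cell to
an administrative unit.  At the special scale ``"admin"`` the cells *are* the
administrative units.

Coordinates are planar metres throughout; projecting geographic rasters is
the caller's responsibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

RASTER_COLUMNS = ("x", "y", "population", "admin_id")

ADMIN_SCALE = "admin"


def _validate_raster(raster: pd.DataFrame, require_admin: bool = False) -> None:
    if len(raster) == 0:
        raise ValueError("raster is empty")
    for col in ("x", "y", "population"):
        if col not in raster.columns:
            raise ValueError(f"raster is missing required column {col!r}")
    if require_admin and "admin_id" not in raster.columns:
        raise ValueError("raster is missing required column 'admin_id'")
    pop = np.asarray(raster["population"], dtype=float)
    if np.any(pop < 0) or not np.all(np.isfinite(pop)):
        raise ValueError("raster populations must be finite and >= 0")
    if pop.sum() <= 0:
        raise ValueError("raster population is all zero")


@dataclass(frozen=True)
class SpatialSystem:
    """Cells with centroids, populations and admin-unit membership.

    Parameters
    ----------
    scale
        Label of the spatial scale, e.g. ``"admin"``, ``"20km"``.  At scale
        ``"admin"`` cells and administrative units coincide one-to-one.
    x, y
        Cell centroid coordinates in metres (population-weighted means of
        the member raster pixels).
    population
        Ambient population per cell (persons, >= 0).
    admin_id
        Administrative unit owning each cell.
    """

    scale: str
    x: np.ndarray
    y: np.ndarray
    population: np.ndarray
    admin_id: np.ndarray
    spacing: float | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        for name in ("x", "y", "population", "admin_id"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.x)
        if not (len(self.y) == len(self.population) == len(self.admin_id) == n):
            raise ValueError("cell arrays must have equal length")
        if n == 0:
            raise ValueError("system has no cells")
        if np.any(self.population < 0):
            raise ValueError("cell populations must be >= 0")
        if self.scale == ADMIN_SCALE:
            if len(np.unique(self.admin_id)) != n:
                raise ValueError("at admin scale cells and units must coincide one-to-one")

    # -- basic views ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.x)

    @property
    def unit_ids(self) -> np.ndarray:
        """Sorted unique administrative-unit identifiers."""
        if "unit_ids" not in self._cache:
            self._cache["unit_ids"] = np.unique(self.admin_id)
        return self._cache["unit_ids"]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def unit_codes(self) -> np.ndarray:
        """Per-cell integer code 0..n_units-1 into :attr:`unit_ids`."""
        if "unit_codes" not in self._cache:
            self._cache["unit_codes"] = np.searchsorted(self.unit_ids, self.admin_id)
        return self._cache["unit_codes"]

    @property
    def unit_populations(self) -> np.ndarray:
        if "unit_pop" not in self._cache:
            self._cache["unit_pop"] = np.bincount(
                self.unit_codes, weights=self.population, minlength=self.n_units
            )
        return self._cache["unit_pop"]

    @property
    def unit_centroids(self) -> np.ndarray:
        """Population-weighted unit centroids, shape (n_units, 2)."""
        if "unit_cen" not in self._cache:
            w = self.population
            sx = np.bincount(self.unit_codes, weights=w * self.x, minlength=self.n_units)
            sy = np.bincount(self.unit_codes, weights=w * self.y, minlength=self.n_units)
            tot = self.unit_populations
            self._cache["unit_cen"] = np.column_stack([sx / tot, sy / tot])
        return self._cache["unit_cen"]

    @property
    def distances(self) -> np.ndarray:
        """Dense pairwise centroid-distance matrix in metres (cached)."""
        if "D" not in self._cache:
            self._cache["D"] = distance_matrix(self)
        return self._cache["D"]

    def to_admin_scale(self) -> "SpatialSystem":
        """Collapse the system to one cell per administrative unit."""
        cen = self.unit_centroids
        return SpatialSystem(
            scale=ADMIN_SCALE,
            x=cen[:, 0],
            y=cen[:, 1],
            population=self.unit_populations.copy(),
            admin_id=self.unit_ids.copy(),
        )

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x": self.x,
                "y": self.y,
                "population": self.population,
                "admin_id": self.admin_id,
            }
        )

    def units_frame(self) -> pd.DataFrame:
        cen = self.unit_centroids
        return pd.DataFrame(
            {
                "admin_id": self.unit_ids,
                "population": self.unit_populations,
                "centroid_x": cen[:, 0],
                "centroid_y": cen[:, 1],
            }
        )

    def relabel_units(self, mapping: Mapping) -> "SpatialSystem":
        """Apply a unit-id relabelling (e.g. a merge map old->new).

        At grid scales only ``admin_id`` changes; at admin scale the merged
        cells are combined (populations summed, centroids population-weighted).
        """
        new_admin = np.array([mapping.get(a, a) for a in self.admin_id])
        if self.scale != ADMIN_SCALE:
            return dataclasses.replace(self, admin_id=new_admin, _cache={})
        tmp = SpatialSystem(
            scale="merged",
            x=self.x,
            y=self.y,
            population=self.population,
            admin_id=new_admin,
        )
        return tmp.to_admin_scale()


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def _grid_bins(raster: pd.DataFrame, spacing: float, origin_offset=(0.0, 0.0)):
    """Integer (gx, gy) square-bin indices of each raster pixel centre.

    The grid origin defaults to the raster's minimum corner, shifted by
    ``origin_offset`` (grid positioning can matter, so it is exposed).
    """
    x = np.asarray(raster["x"], dtype=float)
    y = np.asarray(raster["y"], dtype=float)
    ox, oy = origin_offset
    x0 = x.min() + ox
    y0 = y.min() + oy
    gx = np.floor((x - x0) / spacing).astype(np.int64)
    gy = np.floor((y - y0) / spacing).astype(np.int64)
    return gx, gy


def build_grid(
    raster: pd.DataFrame,
    spacing: float,
    origin_offset: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Bin fine raster pixels into square grid cells of side ``spacing``.

    Each output cell's population is the sum of its member pixels and its
    centroid is the population-weighted mean of the member pixel
    coordinates.  Cells with zero population are dropped.

    Returns a DataFrame with columns ``cell_id, gx, gy, x, y, population``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    _validate_raster(raster)
    gx, gy = _grid_bins(raster, spacing, origin_offset)
    pop = np.asarray(raster["population"], dtype=float)
    x = np.asarray(raster["x"], dtype=float)
    y = np.asarray(raster["y"], dtype=float)

    key = pd.MultiIndex.from_arrays([gx, gy])
    grouped = pd.DataFrame(
        {"population": pop, "wx": pop * x, "wy": pop * y}, index=key
    ).groupby(level=[0, 1]).sum()
    grouped = grouped[grouped["population"] > 0]
    cells = pd.DataFrame(
        {
            "gx": grouped.index.get_level_values(0),
            "gy": grouped.index.get_level_values(1),
            "x": grouped["wx"].to_numpy() / grouped["population"].to_numpy(),
            "y": grouped["wy"].to_numpy() / grouped["population"].to_numpy(),
            "population": grouped["population"].to_numpy(),
        }
    ).reset_index(drop=True)
    cells.insert(0, "cell_id", np.arange(len(cells)))
    return cells


def assign_cells_to_admin(
    cells: pd.DataFrame,
    raster: pd.DataFrame,
    spacing: float,
    origin_offset: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Assign each grid cell the admin unit of most of its pixels.

    The pixel count is the area proxy: the winning unit is the one
    contributing the most member pixels; ties break to the smallest unit id.
    """
    _validate_raster(raster, require_admin=True)
    if raster["admin_id"].isna().any():
        raise ValueError("every raster pixel must carry an admin label")
    gx, gy = _grid_bins(raster, spacing, origin_offset)
    counts = (
        pd.DataFrame({"gx": gx, "gy": gy, "admin_id": raster["admin_id"].to_numpy()})
        .groupby(["gx", "gy", "admin_id"])
        .size()
        .reset_index(name="n_pixels")
        # sort: most pixels first, then smallest admin id (deterministic tie rule)
        .sort_values(["gx", "gy", "n_pixels", "admin_id"], ascending=[True, True, False, True])
        .drop_duplicates(["gx", "gy"], keep="first")
    )
    out = cells.merge(counts[["gx", "gy", "admin_id"]], on=["gx", "gy"], how="left")
    if out["admin_id"].isna().any():
        missing = out.loc[out["admin_id"].isna(), "cell_id"].tolist()
        raise ValueError(f"cells with no labelled pixels: {missing}")
    return out


def system_from_raster(
    raster: pd.DataFrame,
    spacing: float | None = None,
    origin_offset: tuple[float, float] = (0.0, 0.0),
    scale: str | None = None,
) -> SpatialSystem:
    """Build a SpatialSystem from a fine raster table.

    With ``spacing=None`` the admin-scale system is returned (one location
    per administrative unit, ambient population and population-weighted
    centroid computed directly from the pixels).  Otherwise pixels are binned
    at ``spacing`` metres and each cell assigned to an admin unit by pixel
    majority.
    """
    _validate_raster(raster, require_admin=True)
    if spacing is None:
        pixel_system = SpatialSystem(
            scale="raster",
            x=np.asarray(raster["x"], dtype=float),
            y=np.asarray(raster["y"], dtype=float),
            population=np.asarray(raster["population"], dtype=float),
            admin_id=np.asarray(raster["admin_id"]),
        )
        return pixel_system.to_admin_scale()
    cells = build_grid(raster, spacing, origin_offset)
    cells = assign_cells_to_admin(cells, raster, spacing, origin_offset)
    return SpatialSystem(
        scale=scale if scale is not None else f"{spacing / 1000:g}km",
        x=cells["x"].to_numpy(),
        y=cells["y"].to_numpy(),
        population=cells["population"].to_numpy(),
        admin_id=cells["admin_id"].to_numpy(),
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# unit merging and cell filtering
# ---------------------------------------------------------------------------

def merge_small_units(
    systems: Mapping[str, SpatialSystem],
) -> tuple[dict[str, SpatialSystem], dict]:
    """Merge units owning zero cells at any gridded scale into their nearest
    neighbour, consistently across all scales.

    A unit may end up with no cells at a coarse grid scale when all its
    pixels fall in cells dominated by neighbouring units.  Each such unit is
    merged (population and membership) into the unit with the nearest
    population-weighted centroid, at every scale, repeating until every unit
    owns at least one cell at every scale.  Returns the merged systems and
    the merge map ``{merged_unit: absorbing_unit}``.
    """
    systems = dict(systems)
    if not systems:
        raise ValueError("no systems given")
    merge_map: dict = {}

    def _canonical(sys_map):
        # admin-scale entry if present, else the finest (most cells) system
        for s in sys_map.values():
            if s.scale == ADMIN_SCALE:
                return s
        return max(sys_map.values(), key=lambda s: s.n_cells)

    while True:
        universe = np.unique(np.concatenate([s.unit_ids for s in systems.values()]))
        missing = set()
        for s in systems.values():
            missing.update(set(universe) - set(s.unit_ids))
        if not missing:
            if len(universe) < 2:
                raise ValueError("merging left a single administrative unit")
            break
        if len(universe) <= 1:
            raise ValueError("cannot merge: a single administrative unit remains")
        ref = _canonical(systems)
        ref_ids = list(ref.unit_ids)
        cen = ref.unit_centroids
        u = min(missing)
        if u not in ref_ids:
            # unit invisible even in the reference system; fold into nearest
            # by the coarsest information available: drop via first other id
            target = min(i for i in universe if i != u)
        else:
            k = ref_ids.index(u)
            d = np.hypot(cen[:, 0] - cen[k, 0], cen[:, 1] - cen[k, 1])
            d[k] = np.inf
            target = ref_ids[int(np.argmin(d))]
        step = {u: target}
        # keep previously recorded merges pointing at surviving units
        merge_map = {old: (target if new == u else new) for old, new in merge_map.items()}
        merge_map[u] = target
        systems = {lbl: s.relabel_units(step) for lbl, s in systems.items()}
    return systems, merge_map


@dataclass(frozen=True)
class FilterReport:
    n_removed: int
    removed_population: float
    removed_population_fraction: float
    removed_cell_fraction: float


def filter_low_pop_cells(
    system: SpatialSystem, threshold: float
) -> tuple[SpatialSystem, FilterReport]:
    """Drop cells with population <= ``threshold`` (inclusive).

    Unit populations for modelling are recomputed from the surviving cells.
    Raises if the filter would empty an administrative unit.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = system.population > threshold
    if keep.all():
        report = FilterReport(0, 0.0, 0.0, 0.0)
        return system, report
    kept_units = set(np.unique(system.admin_id[keep])) if keep.any() else set()
    emptied = sorted(set(system.unit_ids) - kept_units)
    if emptied:
        raise ValueError(
            f"filtering at threshold {threshold} empties administrative unit(s): {emptied}"
        )
    removed_pop = float(system.population[~keep].sum())
    total = float(system.population.sum())
    report = FilterReport(
        n_removed=int((~keep).sum()),
        removed_population=removed_pop,
        removed_population_fraction=removed_pop / total,
        removed_cell_fraction=float((~keep).sum()) / system.n_cells,
    )
    filtered = SpatialSystem(
        scale=system.scale,
        x=system.x[keep],
        y=system.y[keep],
        population=system.population[keep],
        admin_id=system.admin_id[keep],
        spacing=system.spacing,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# distances and ring populations
# ---------------------------------------------------------------------------

def distance_matrix(system: SpatialSystem) -> np.ndarray:
    """Euclidean centroid-to-centroid distances in metres."""
    xy = np.column_stack([system.x, system.y])
    if not np.all(np.isfinite(xy)):
        raise ValueError("centroid coordinates must be finite")
    D = cdist(xy, xy)
    np.fill_diagonal(D, 0.0)
    return D


def ring_population(system: SpatialSystem) -> np.ndarray:
    """Population r[i, j] inside the circle around i of radius d(i, j).

    r[i, j] sums the populations of all cells k (k != i, k != j) with
    d(i, k) <= d(i, j); cells at exactly the radius are included (the ring is
    closed, making r right-continuous in distance).  The origin and
    destination populations are excluded by definition.
    """
    D = system.distances
    pop = system.population.astype(float)
    n = system.n_cells
    r = np.empty((n, n))
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        d_sorted = D[i, order]
        csum = np.cumsum(pop[order])
        pos = np.searchsorted(d_sorted, D[i], side="right")
        r[i] = csum[pos - 1] - pop[i] - pop
        r[i, i] = 0.0
    return r
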