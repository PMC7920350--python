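"""Synthetic population rasters, admin partitions and NB-noised flows.

Real inputs for this kind of analysis (gridded population rasters,
administrative boundaries, CDR-derived OD matrices) are licence-restricted
downloads, so the package ships a generator that emulates their statistical
structure: a population laid out as a mixture of isotropic Gaussian
clusters over a thin uniform background, a Voronoi partition into
administrative units around population-weighted seed pixels, and OD counts
drawn from a known mobility model with negative binomial noise.

Two preset scenarios bracket the settings of interest:

* ``clustered`` - a strongly urbanised population with most people in a
  handful of dense centres;
* ``dispersed`` - a sparse, spread-out population where most populated grid
  cells hold only a handful of people.

The generator is deterministic given its seed and emits the same raster /
flow table formats the ingestion layer reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .flows import FlowMatrix, ModelParams, expected_flows
from .likelihood import FlowDataset
from .spatial import SpatialSystem, system_from_raster


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic study setting.

    Distances in metres, populations in persons.  ``cluster_weights`` are
    relative masses of the Gaussian clusters (normalised internally);
    ``background_fraction`` is the share of the population allocated
    uniformly over the whole extent.
    """

    extent: tuple[float, float] = (260_000.0, 260_000.0)
    pixel_size: float = 2_000.0
    n_clusters: int = 8
    cluster_spread: float = 15_000.0
    cluster_weights: tuple[float, ...] | None = None
    background_fraction: float = 0.05
    total_population: int = 400_000_000
    n_admin_units: int = 10
    model: str = "GM"
    true_params: ModelParams = field(
        default_factory=lambda: ModelParams(
            kappa=-4.0, alpha=1.8, beta=0.6, gamma=3.5, epsilon=2.3, disp=1.5)
    )
    directional: bool = False
    has_diagonal: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.total_population <= 0:
            raise ValueError("total_population must be > 0")
        if self.n_admin_units < 2:
            raise ValueError("need >= 2 administrative units")


#: strongly urbanised setting: population concentrated in 8 centres over a
#: 260 km square; at 20 km grid spacing this yields ~150 populated cells in
#: 10 units with a heavy-tailed cell-population distribution.  The total is
#: sized so that with the true gravity parameters the simulated admin-level
#: counts span ~10^0-10^4 trips, the magnitude regime of year-long
#: CDR-derived flow matrices (where over-dispersion matters).
CLUSTERED = ScenarioConfig()

#: sparse setting: 2.4M people over a 400 km square, weak clusters plus a
#: thin background, so that at 5 km scale the majority of populated cells
#: hold only a few people while carrying a tiny share of the population.
DISPERSED = ScenarioConfig(
    extent=(400_000.0, 400_000.0),
    pixel_size=5_000.0,
    n_clusters=6,
    cluster_spread=10_000.0,
    background_fraction=0.02,
    total_population=2_400_000,
    n_admin_units=12,
    model="RM4",
    true_params=ModelParams(kappa=-3.5, alpha=1.3, theta=250_000.0, disp=1.8),
    directional=True,
    has_diagonal=False,
    seed=0,
)

PRESETS = {"clustered": CLUSTERED, "dispersed": DISPERSED}


def preset(name: str, **overrides) -> ScenarioConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


# ---------------------------------------------------------------------------
# population raster
# ---------------------------------------------------------------------------

def synth_population(config: ScenarioConfig, seed=None) -> pd.DataFrame:
    """Multinomial allocation of the population over a Gaussian-mixture
    density, returned as a fine raster table (x, y, population).

    Pixel centres sit on a regular grid of ``pixel_size``; the density is a
    weighted sum of isotropic Gaussian cluster kernels plus a uniform
    background.  The allocation conserves ``total_population`` exactly and
    is deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w, h = config.extent
    px = config.pixel_size
    nx, ny = int(round(w / px)), int(round(h / px))
    xc = (np.arange(nx) + 0.5) * px
    yc = (np.arange(ny) + 0.5) * px
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    X, Y = X.ravel(), Y.ravel()

    density = np.full(X.shape, config.background_fraction / len(X))
    if config.n_clusters > 0:
        centres = rng.uniform([0, 0], [w, h], size=(config.n_clusters, 2))
        weights = (
            np.asarray(config.cluster_weights, dtype=float)
            if config.cluster_weights is not None
            else rng.dirichlet(np.full(config.n_clusters, 1.5))
        )
        weights = weights / weights.sum() * (1.0 - config.background_fraction)
        s2 = config.cluster_spread ** 2
        for (cx, cy), wt in zip(centres, weights):
            k = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * s2))
            total = k.sum()
            if total > 0:
                density += wt * k / total
    density = density / density.sum()
    pop = rng.multinomial(config.total_population, density)
    return pd.DataFrame({"x": X, "y": Y, "population": pop})


def synth_admin(raster: pd.DataFrame, n_units: int, seed=None) -> pd.DataFrame:
    """Voronoi partition of the raster into admin units.

    ``n_units`` seed pixels are sampled with probability proportional to
    population (distinct pixels); every pixel joins the nearest seed.
    Returns the raster with an ``admin_id`` column (1..n_units).
    """
    rng = np.random.default_rng(seed)
    pop = raster["population"].to_numpy(dtype=float)
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    p = pop / pop.sum()
    n_candidates = int((p > 0).sum())
    if n_candidates < n_units:
        raise ValueError("fewer populated pixels than requested units")
    seeds = rng.choice(len(raster), size=n_units, replace=False, p=p)
    xy = raster[["x", "y"]].to_numpy(dtype=float)
    _, owner = cKDTree(xy[seeds]).query(xy, k=1)
    out = raster.copy()
    out["admin_id"] = owner + 1
    return out


def scenario_raster(config: ScenarioConfig) -> pd.DataFrame:
    """Population raster with admin labels for a scenario (one seed drives
    both the population and the partition)."""
    root = np.random.SeedSequence(config.seed)
    pop_seed, admin_seed = root.spawn(2)
    raster = synth_population(config, seed=np.random.default_rng(pop_seed))
    return synth_admin(raster, config.n_admin_units,
                       seed=np.random.default_rng(admin_seed))


def scenario_system(config: ScenarioConfig, spacing: float | None = None) -> SpatialSystem:
    """SpatialSystem of a scenario at a grid spacing (or admin scale)."""
    return system_from_raster(scenario_raster(config), spacing=spacing)


# ---------------------------------------------------------------------------
# flows
# ---------------------------------------------------------------------------

def sample_nb_counts(rng, mean, disp: float):
    """NB counts with var = mean + disp*mean^2 via Gamma-Poisson mixing;
    disp = 0 draws Poisson."""
    mean = np.asarray(mean, dtype=float)
    if disp < 0:
        raise ValueError("disp must be >= 0")
    if disp == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / disp, scale=mean * disp)
    return rng.poisson(lam)


def synth_flows(
    system: SpatialSystem,
    model: str,
    true_params: ModelParams,
    directional: bool = True,
    diagonal: bool = False,
    seed=None,
) -> FlowDataset:
    """Draw an admin-level OD count dataset from a known model.

    Expected flows are evaluated on ``system`` (and aggregated to admin
    units when the system is gridded); each masked pair's count is NB with
    that mean and the true dispersion.  Symmetrised datasets are generated
    once per unordered pair from the symmetrised model flows.
    """
    rng = np.random.default_rng(seed)
    if diagonal and model != "GM":
        raise ValueError("radiation models do not define within-unit flows")
    F: FlowMatrix = expected_flows(
        system, model, true_params, symmetrised=not directional)
    labels = F.labels
    U = len(labels)
    rows = []
    for a in range(U):
        for b in range(U):
            if a == b and not diagonal:
                continue
            if not directional and a > b:
                continue
            mean = F.values[a, b]
            count = int(sample_nb_counts(rng, mean, true_params.disp))
            rows.append((labels[a], labels[b], count))
    df = pd.DataFrame(rows, columns=["origin", "destination", "count"])
    return FlowDataset(df, directional=directional, has_diagonal=diagonal)


def scenario_dataset(config: ScenarioConfig, spacing: float | None = None,
                     seed=None) -> tuple[SpatialSystem, FlowDataset]:
    """System + simulated dataset for a scenario at one spacing.

    ``seed`` (default: the scenario seed) controls the flow noise only; the
    geography is fixed by the scenario seed so that repeated draws share
    the same population landscape.
    """
    system = scenario_system(config, spacing)
    flow_seed = config.seed if seed is None else seed
    data = synth_flows(
        system, config.model, config.true_params,
        directional=config.directional, diagonal=config.has_diagonal,
        seed=flow_seed)
    return system, data
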