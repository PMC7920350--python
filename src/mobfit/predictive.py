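"""Posterior-predictive flows, credible-interval coverage, trip-distance
profiles with power-law fits, and the OD symmetry diagnostic.

"Simulated flows" are by default the *expected* flows per posterior draw
(the average estimated flow across parameter samples); ``nb_noise=True``
additionally draws negative binomial counts around each expected flow using
the draw's dispersion, which is what calibration checks of the 95% CrI
coverage require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .likelihood import FlowDataset
from .spatial import SpatialSystem

DEFAULT_BIN_WIDTH = 10_000.0  # metres


@dataclass
class FlowSummary:
    """Per-OD-pair posterior-predictive mean and equal-tailed 95% CrI."""

    table: pd.DataFrame  # origin, destination, mean, lo95, hi95
    n_draws: int

    def __post_init__(self):
        if np.any(self.table["lo95"] > self.table["hi95"]):
            raise ValueError("lower CrI bound above upper")


@dataclass
class DistanceProfile:
    """Trip frequency by centroid distance."""

    bin_edges: np.ndarray      # metres, len = n_bins + 1
    frequency: np.ndarray      # trips per bin
    cumulative: np.ndarray     # proportion of all trips, non-decreasing to 1

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PowerLawFit:
    exponent: float     # positive decay power of frequency ~ d^-exponent
    intercept: float    # log10 frequency at log10 d = 0
    stderr: float       # standard error of the exponent

    def conf_int(self, z: float = 1.96) -> tuple[float, float]:
        return self.exponent - z * self.stderr, self.exponent + z * self.stderr


def _sample_nb(rng, mean, disp):
    """NB(mean, disp) counts via the Gamma-Poisson mixture (size = 1/disp)."""
    mean = np.asarray(mean, dtype=float)
    if disp < 1e-8:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / disp, scale=mean * disp)
    return rng.poisson(lam)


def posterior_predictive_flows(results, n_draws: int = 100, seed=None,
                               nb_noise: bool = False) -> FlowSummary:
    """Flow summary over parameter samples from a fitted posterior.

    Samples ``n_draws`` parameter vectors without replacement from the
    retained posterior draws, computes the admin-level expected flows for
    each, and reports per-pair mean and equal-tailed 95% CrI for the
    dataset's masked OD pairs.
    """
    model = results.model
    draws = results.retained_draws()
    if len(draws) == 0:
        raise ValueError("empty posterior")
    if n_draws > len(draws):
        raise ValueError(f"n_draws={n_draws} exceeds the {len(draws)} retained draws")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(draws), size=n_draws, replace=False)
    obj = model._objective
    sims = np.empty((n_draws, obj.n_terms))
    for k, i in enumerate(idx):
        theta = draws[i]
        means = obj.admin_means(theta)
        if nb_noise:
            means = _sample_nb(rng, means, theta[-1])
        sims[k] = means
    return _summarise_draws(model, obj, sims, n_draws)


def predictive_flows_at(model, theta, n_draws: int = 100, seed=None,
                        nb_noise: bool = True) -> FlowSummary:
    """Predictive summary at a single parameter vector (degenerate
    posterior); with ``nb_noise`` the draws are NB replicates, which is the
    calibration reference for CrI coverage."""
    rng = np.random.default_rng(seed)
    obj = model._objective
    means = obj.admin_means(np.asarray(theta, dtype=float))
    if nb_noise:
        sims = np.stack([_sample_nb(rng, means, theta[-1]) for _ in range(n_draws)])
    else:
        sims = np.tile(means, (n_draws, 1))
    return _summarise_draws(model, obj, sims, n_draws)


def _summarise_draws(model, obj, sims, n_draws) -> FlowSummary:
    mask_rows = model.data.flows
    # radiation models drop diagonal pairs from the mask; align the table
    if obj.n_terms != len(mask_rows):
        keep = mask_rows["origin"] != mask_rows["destination"]
        mask_rows = mask_rows[keep]
    table = pd.DataFrame(
        {
            "origin": mask_rows["origin"].to_numpy(),
            "destination": mask_rows["destination"].to_numpy(),
            "mean": sims.mean(axis=0),
            "lo95": np.quantile(sims, 0.025, axis=0),
            "hi95": np.quantile(sims, 0.975, axis=0),
        }
    )
    return FlowSummary(table=table, n_draws=n_draws)


def cri_coverage(data: FlowDataset, summary: FlowSummary) -> float:
    """Fraction of observed masked counts inside the 95% CrI bounds.

    The summary may legitimately omit the data's diagonal pairs (radiation
    models do not predict within-unit trips); any other mask mismatch is an
    error.
    """
    obs = data.flows.set_index(["origin", "destination"])["count"]
    key = pd.MultiIndex.from_frame(summary.table[["origin", "destination"]])
    if not key.isin(obs.index).all():
        raise ValueError("mask mismatch: summary contains pairs absent from the data")
    non_diag = (obs.index.get_level_values(0) != obs.index.get_level_values(1)).sum()
    if len(key) not in (len(obs), non_diag):
        raise ValueError("mask mismatch between data and summary")
    counts = obs.loc[key].to_numpy()
    lo = summary.table["lo95"].to_numpy()
    hi = summary.table["hi95"].to_numpy()
    return float(np.mean((counts >= lo) & (counts <= hi)))


# ---------------------------------------------------------------------------
# trip-distance profiles
# ---------------------------------------------------------------------------

def distance_profile(flows, system: SpatialSystem,
                     bin_width: float = DEFAULT_BIN_WIDTH) -> DistanceProfile:
    """Accumulate trips into distance bins of the OD pair's centroid distance.

    ``flows`` is a FlowDataset (observed counts) or FlowMatrix over the
    system's admin units (model flows; diagonal skipped when excluded, and
    zero-distance within-unit pairs never enter the profile).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    admin = system.to_admin_scale() if system.scale != "admin" else system
    D = admin.distances
    lut = {lab: k for k, lab in enumerate(admin.admin_id)}

    if isinstance(flows, FlowDataset):
        o = np.array([lut[v] for v in flows.flows["origin"]])
        d = np.array([lut[v] for v in flows.flows["destination"]])
        w = flows.flows["count"].to_numpy(dtype=float)
        off = o != d
        dist, w = D[o[off], d[off]], w[off]
    else:
        vals = flows.values
        if vals.shape != D.shape:
            raise ValueError("flow matrix does not match the system's admin units")
        # align matrix order (sorted unit ids) with the admin system
        order = np.array([lut[v] for v in flows.labels])
        iu, ju = np.meshgrid(order, order, indexing="ij")
        off = ~np.eye(len(vals), dtype=bool)
        dist, w = D[iu[off], ju[off]], vals[off]

    # right-open bins [k*w, (k+1)*w); a distance on the top edge gets its
    # own bin rather than being clamped into the previous one
    n_bins = int(np.floor(dist.max() / bin_width)) + 1 if len(dist) else 1
    edges = np.arange(n_bins + 1) * bin_width
    which = (dist / bin_width).astype(int)
    freq = np.bincount(which, weights=w, minlength=n_bins)
    total = freq.sum()
    if total <= 0:
        raise ValueError("no trips to profile")
    return DistanceProfile(bin_edges=edges, frequency=freq,
                           cumulative=np.cumsum(freq) / total)


def powerlaw_fit(profile: DistanceProfile) -> PowerLawFit:
    """Least-squares power law through the non-empty profile bins.

    Fits log10 frequency against log10 bin-centre distance and returns the
    positive decay exponent (the negated slope).
    """
    keep = profile.frequency > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 non-empty bins for a power-law fit")
    x = np.log10(profile.bin_centres[keep])
    y = np.log10(profile.frequency[keep])
    res = linregress(x, y)
    return PowerLawFit(exponent=-res.slope, intercept=res.intercept,
                       stderr=res.stderr if np.isfinite(res.stderr) else 0.0)


# ---------------------------------------------------------------------------
# OD symmetry diagnostic
# ---------------------------------------------------------------------------

@dataclass
class SymmetryStatistic:
    """Pairwise flow asymmetry F_ij = 100 (f_ij - f_ji) / max(f_ij, f_ji)."""

    pairs: pd.DataFrame         # origin, destination, F (antisymmetric, in [-100, 100])
    mean_abs: float
    lo95: float                 # 2.5% quantile of |F| over unordered pairs
    hi95: float
    n_skipped: int              # unordered pairs with both flows zero


def plot_distance_profile(profiles, path=None, labels=None):
    """Log-log trip-frequency-by-distance plot for one or more profiles.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(profiles, DistanceProfile):
        profiles = [profiles]
    labels = labels or [f"profile {k}" for k in range(len(profiles))]
    fig, ax = plt.subplots(figsize=(5, 4))
    for prof, lab in zip(profiles, labels):
        keep = prof.frequency > 0
        ax.loglog(prof.bin_centres[keep] / 1000.0, prof.frequency[keep],
                  marker="o", ls="-", ms=3, label=lab)
    ax.set_xlabel("distance (km)")
    ax.set_ylabel("trips")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_flow_heatmap(summary_or_matrix, path=None, log: bool = True):
    """Origin x destination heatmap of flows, diagonal pixels removed.

    Accepts a FlowSummary (mean column) or a dense matrix.  Returns the
    figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(summary_or_matrix, FlowSummary):
        t = summary_or_matrix.table
        units = np.unique(np.concatenate([t["origin"], t["destination"]]))
        lut = {u: k for k, u in enumerate(units)}
        M = np.full((len(units), len(units)), np.nan)
        for o, d, v in zip(t["origin"], t["destination"], t["mean"]):
            M[lut[o], lut[d]] = v
    else:
        M = np.asarray(summary_or_matrix, dtype=float).copy()
    np.fill_diagonal(M, np.nan)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        img = np.log10(M) if log else M
    im = ax.imshow(img, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax, label="log10 trips" if log else "trips")
    ax.set_xlabel("destination")
    ax.set_ylabel("origin")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def symmetry_statistic(data: FlowDataset) -> SymmetryStatistic:
    """Directional-flow symmetry diagnostic on the 0-100 scale.

    For every unordered pair with max(f_ij, f_ji) > 0, F_ij is the signed
    percentage imbalance; the summary reports the mean and equal-tailed 95%
    range of |F|.  Pairs where both directions are zero are skipped and
    counted.
    """
    if not data.directional:
        raise ValueError("symmetry statistic requires directional data")
    mat = data.flows.set_index(["origin", "destination"])["count"].to_dict()
    units = data.units
    rows = []
    n_skipped = 0
    for a in range(len(units)):
        for b in range(a + 1, len(units)):
            i, j = units[a], units[b]
            fij = mat.get((i, j))
            fji = mat.get((j, i))
            if fij is None and fji is None:
                continue  # unobserved pair, not part of the mask
            fij = 0 if fij is None else fij
            fji = 0 if fji is None else fji
            mx = max(fij, fji)
            if mx == 0:
                n_skipped += 1
                continue
            F = 100.0 * (fij - fji) / mx
            rows.append((i, j, F))
            rows.append((j, i, -F))
    if not rows:
        raise ValueError("no pairs with non-zero flow")
    pairs = pd.DataFrame(rows, columns=["origin", "destination", "F"])
    upper = pairs[pairs["origin"] < pairs["destination"]]["F"].abs().to_numpy()
    return SymmetryStatistic(
        pairs=pairs,
        mean_abs=float(upper.mean()),
        lo95=float(np.quantile(upper, 0.025)),
        hi95=float(np.quantile(upper, 0.975)),
        n_skipped=n_skipped,
    )
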