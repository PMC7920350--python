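"""Model/Results front end for fitting mobility models to OD flow data.

Usage follows the fit-and-summarise idiom of statistical modelling
libraries::

    model = MobilityModel(data, system, model="GM", symmetrised=True)
    res = model.fit(n_iter=20_000, n_chains=4, seed=1)
    print(res.summary())
    flows = res.posterior_predictive(n_draws=100, seed=2)

``MobilityModel`` binds a :class:`~mobfit.likelihood.FlowDataset` to a
:class:`~mobfit.spatial.SpatialSystem` and a named flow kernel (GM or
RM1-RM4).  When the system is at a finer scale than the data, every
likelihood evaluation computes the cell-pair flow matrix and sums it into
admin-level OD pairs before the negative binomial terms are taken; static
quantities (log-populations, log-distances, ring populations, the
cell-pair -> admin-pair index) are precomputed once so MCMC iterations stay
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .flows import (
    LN10,
    MODEL_PARAM_NAMES,
    MODEL_NAMES,
    RADIATION_MODELS,
    FlowMatrix,
    ModelParams,
    expected_flows,
)
from .inference import (
    Chain,
    PosteriorChains,
    PriorBox,
    assess_convergence,
    default_prior,
    lhs_candidates,
    run_chain,
    run_chains_pooled,
    summarise_posterior,
)
from .likelihood import _nb_loglik_fast
from .spatial import SpatialSystem, ring_population


class _Objective:
    """Precomputed log-likelihood of a dataset under one model family.

    Callable on the packed parameter vector (model parameters in canonical
    order, dispersion last).  Designed for speed: per call it does a few
    dense vector operations on the cell-pair arrays plus a bincount
    aggregation, and returns -inf (rather than raising) for numerically
    degenerate proposals.
    """

    def __init__(self, system: SpatialSystem, data, model: str, symmetrised: bool,
                 scale_factor: str = "kappa-gamma-eps"):
        self.model = model
        self.symmetrised = symmetrised
        self.scale_factor = scale_factor
        m = system.population.astype(float)
        if np.any(m <= 0):
            raise ValueError("populations must be > 0 to fit (drop empty cells first)")
        self.m = m
        self.log_m = np.log(m)
        if model == "GM":
            D = system.distances
            with np.errstate(divide="ignore"):
                self.log_d = np.log(D, out=np.full_like(D, -np.inf), where=D > 0)
        else:
            self.rings = ring_population(system)

        # cell-pair -> admin-pair aggregation index
        codes = system.unit_codes
        U = system.n_units
        self.n_units = U
        self.pair_id = (codes[:, None] * U + codes[None, :]).ravel()
        self.cell_diag_flat = np.arange(system.n_cells) * system.n_cells + np.arange(system.n_cells)
        unit_ids = list(system.unit_ids)

        # masked pairs of the dataset, as flat indices into the U*U aggregate
        lut = {lab: k for k, lab in enumerate(unit_ids)}
        try:
            oi = np.array([lut[v] for v in data.flows["origin"]])
            di = np.array([lut[v] for v in data.flows["destination"]])
        except KeyError as exc:
            raise ValueError(f"dataset unit {exc.args[0]!r} not in the spatial system") from exc
        diag = oi == di
        if diag.any() and model in RADIATION_MODELS:
            # radiation models do not predict within-unit trips
            keep = ~diag
            oi, di = oi[keep], di[keep]
            counts = data.flows["count"].to_numpy()[keep]
        else:
            counts = data.flows["count"].to_numpy()
        self.mask_flat = oi * U + di
        self.counts = counts.astype(np.int64)
        self.lgamma_D1 = gammaln(self.counts + 1.0)
        self.n_terms = len(self.counts)

    # -- kernels on packed vectors --------------------------------------
    def _cell_flows(self, theta: np.ndarray) -> np.ndarray:
        model = self.model
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if model == "GM":
                kappa, alpha, beta, gamma, epsilon = theta[:5]
                a = np.exp(alpha * self.log_m)
                b = np.exp(beta * self.log_m)
                kern = 1.0 + np.exp(epsilon * (self.log_d - gamma * LN10))
                if self.symmetrised:
                    num = np.outer(a, b)
                    num = num + num.T
                    if self.scale_factor == "kappa-gamma-eps":
                        pref = 10.0 ** (kappa - gamma * epsilon)
                    else:
                        pref = 10.0 ** kappa
                    F = pref * num / kern
                else:
                    F = 10.0 ** kappa * np.outer(a, b) / kern
                return F
            # radiation family
            m = self.m
            if model == "RM1":
                T = theta[0] * m
                th = 0.0
            elif model == "RM2":
                T = 10.0 ** theta[0] * np.exp(theta[1] * self.log_m)
                th = 0.0
            elif model == "RM3":
                T = 10.0 ** theta[0] * m
                th = theta[1]
            else:  # RM4
                T = 10.0 ** theta[0] * np.exp(theta[1] * self.log_m)
                th = theta[2]
            mi = (m + th)[:, None]
            mj = m[None, :]
            denom = (mi + self.rings + mj) * (mi + self.rings)
            F = T[:, None] * mi * mj / denom
            if self.symmetrised:
                F = F + F.T
            F.ravel()[self.cell_diag_flat] = 0.0
            return F

    def admin_means(self, theta: np.ndarray) -> np.ndarray:
        F = self._cell_flows(theta)
        agg = np.bincount(self.pair_id, weights=F.ravel(),
                          minlength=self.n_units * self.n_units)
        return agg[self.mask_flat]

    def __call__(self, theta: np.ndarray) -> float:
        disp = theta[-1]
        if disp < 0:
            return -np.inf
        means = self.admin_means(theta)
        return _nb_loglik_fast(self.counts, self.lgamma_D1, means, disp)


class MobilityModel:
    """A mobility flow model bound to data and a geography.

    Parameters
    ----------
    data : FlowDataset
        Observed admin-level OD counts.
    system : SpatialSystem
        The geography the kernel is evaluated on; may be at a finer scale
        than the data, in which case cell-pair flows are aggregated to
        admin pairs inside the likelihood.
    model : str
        "GM" or one of "RM1".."RM4".
    symmetrised : bool, optional
        Defaults to ``not data.directional``: undirected data requires a
        symmetrised kernel.
    scale_factor : str
        Prefactor convention of the symmetrised gravity model:
        "kappa-gamma-eps" (default, 10^(kappa - gamma*epsilon)) or "kappa".
    prior : PriorBox, optional
        Uniform box prior; defaults to wide per-parameter bounds.
    """

    def __init__(self, data, system: SpatialSystem, model: str = "GM",
                 symmetrised: bool | None = None,
                 scale_factor: str = "kappa-gamma-eps",
                 prior: PriorBox | None = None):
        if model not in MODEL_NAMES:
            raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
        if symmetrised is None:
            symmetrised = not data.directional
        if not data.directional and not symmetrised:
            raise ValueError("undirected data requires a symmetrised model")
        self.data = data
        self.system = system
        self.model = model
        self.symmetrised = symmetrised
        self.scale_factor = scale_factor
        self.param_names: tuple[str, ...] = MODEL_PARAM_NAMES[model] + ("disp",)
        self.prior = prior if prior is not None else default_prior(
            model, self.param_names)
        if tuple(self.prior.names) != self.param_names:
            raise ValueError(
                f"prior names {self.prior.names} do not match model parameters {self.param_names}")
        self._objective = _Objective(system, data, model, symmetrised, scale_factor)
        # identifiability: alpha > beta only for the symmetrised gravity model
        if model == "GM" and symmetrised:
            names = self.param_names
            ia, ib = names.index("alpha"), names.index("beta")
            self.constraint = lambda th: th[ia] > th[ib]
        else:
            self.constraint = None

    # -- likelihood ------------------------------------------------------
    def loglik(self, theta) -> float:
        """Dataset log-likelihood at a packed parameter vector
        (model parameters in canonical order, then disp)."""
        return self._objective(np.asarray(theta, dtype=float))

    def expected(self, params: ModelParams) -> FlowMatrix:
        """Admin-level expected flows at given parameters."""
        return expected_flows(
            self.system, self.model, params, symmetrised=self.symmetrised,
            scale_factor=self.scale_factor,
            rings=getattr(self._objective, "rings", None),
        )

    def pack(self, params: ModelParams) -> np.ndarray:
        return np.array([getattr(params, n) for n in self.param_names], dtype=float)

    def unpack(self, theta) -> ModelParams:
        return ModelParams(**dict(zip(self.param_names, np.asarray(theta, dtype=float))))

    # -- fitting ---------------------------------------------------------
    def fit(self, n_iter: int = 20_000, n_chains: int = 4, n_lhs: int = 200,
            seed=0, burn_in: int | None = None, rhat_threshold: float = 1.05,
            proposal_scales=None) -> "MobilityResults":
        """LHS-seeded multi-chain Metropolis fit.

        ``seed`` drives every random element (LHS, per-chain streams).
        ``burn_in`` bounds proposal adaptation and the earliest retained
        draw (default ``n_iter // 2``).
        """
        root = np.random.SeedSequence(seed)
        lhs_seed, *chain_seeds = root.spawn(n_chains + 1)
        starts, start_objs = lhs_candidates(
            self.prior, n_lhs, self._objective, n_chains,
            seed=np.random.default_rng(lhs_seed), constraint=self.constraint)
        if burn_in is None:
            burn_in = n_iter // 2
        if proposal_scales is not None:
            chains: list[Chain] = [
                run_chain(starts[k], self.prior, self._objective, n_iter,
                          proposal_scales=proposal_scales,
                          seed=np.random.default_rng(chain_seeds[k]),
                          constraint=self.constraint, adapt_until=burn_in)
                for k in range(n_chains)]
        else:
            chains = run_chains_pooled(
                starts, self.prior, self._objective, n_iter,
                seeds=[np.random.default_rng(s) for s in chain_seeds],
                constraint=self.constraint, adapt_until=burn_in)
        conv = assess_convergence(chains, self.param_names,
                                  threshold=rhat_threshold, min_start=burn_in)
        posterior = PosteriorChains(chains=chains, param_names=self.param_names,
                                    seed=seed if isinstance(seed, int) else None,
                                    convergence=conv)
        return MobilityResults(self, posterior)


class MobilityResults:
    """Posterior estimates, uncertainties and diagnostics of a fitted model."""

    def __init__(self, model: MobilityModel, posterior: PosteriorChains):
        self.model = model
        self.posterior = posterior
        self._summary = summarise_posterior(posterior)

    # -- estimate accessors ----------------------------------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.param_names

    @property
    def params(self) -> pd.Series:
        """Posterior means of the model parameters (and disp)."""
        return self._summary.table["mean"].drop("loglik")

    @property
    def rhat(self) -> pd.Series:
        return self._summary.table["rhat"].drop("loglik")

    @property
    def converged(self) -> bool:
        return bool(self.posterior.convergence.converged)

    @property
    def loglik_mean(self) -> float:
        return float(self._summary.table.loc["loglik", "mean"])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Equal-tailed credible intervals of the parameters."""
        draws, _ = self.posterior.retained()
        lo = np.quantile(draws, alpha / 2, axis=0)
        hi = np.quantile(draws, 1 - alpha / 2, axis=0)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(self.param_names))

    def draws_frame(self) -> pd.DataFrame:
        return self.posterior.to_frame()

    def retained_draws(self) -> np.ndarray:
        return self.posterior.retained()[0]

    def summary(self) -> str:
        head = (
            f"MobilityModel: {self.model.model}"
            f"{' (symmetrised)' if self.model.symmetrised else ''}"
            f" on scale {self.model.system.scale!r}\n"
            f"chains: {len(self.posterior.chains)}, iterations: {self.posterior.n_iter}, "
            f"retained from: {self.posterior.convergence.converged_from}, "
            f"converged: {self.converged}\n"
            f"OD pairs in likelihood: {self.model._objective.n_terms}\n"
        )
        return head + str(self._summary)

    # -- posterior predictive --------------------------------------------
    def posterior_predictive(self, n_draws: int = 100, seed=None, nb_noise: bool = False):
        from .predictive import posterior_predictive_flows

        return posterior_predictive_flows(self, n_draws=n_draws, seed=seed,
                                          nb_noise=nb_noise)

    def expected_at_mean(self) -> FlowMatrix:
        return self.model.expected(self.model.unpack(self.params.to_numpy()))
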