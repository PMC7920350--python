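"""LHS-seeded multi-chain Metropolis MCMC with uniform box priors.

The sampler is a random-walk Metropolis with independent Gaussian increments
per component.  During a burn-in window the per-component proposal scales
are adapted to the spread of the recent draws and a global scale factor is
tuned towards the 0.234 acceptance rate that is optimal for multivariate
random-walk proposals; after the window the proposal is frozen so the chain
is a proper Markov chain.  Chain starting points come from Latin Hypercube
Sampling of the prior box, keeping the highest-likelihood candidates.

Convergence is assessed with split-R-hat over a set of candidate
truncations; posterior summaries pool the retained (converged) portions of
all chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

TARGET_ACCEPT = 0.234


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform prior bounds per parameter."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r} must have lower < upper")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()], dtype=float)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def replace(self, **bounds) -> "PriorBox":
        new = dict(self.bounds)
        new.update(bounds)
        return PriorBox(new)


#: default prior bounds; deliberately wide, uniform boxes
DEFAULT_BOUNDS = {
    "kappa": (-15.0, 15.0),       # log10 proportionality constant
    "kappa_natural": (0.0, 50.0),  # RM1 trips-per-resident scale
    "alpha": (0.0, 6.0),
    "beta": (0.0, 6.0),
    "gamma": (0.0, 7.0),          # log10 metres
    "epsilon": (0.0, 6.0),
    "theta": (0.0, 1e7),          # persons
    "disp": (0.0, 10.0),
}


def default_prior(model: str, param_names: tuple[str, ...]) -> PriorBox:
    bounds = {}
    for name in param_names:
        key = "kappa_natural" if (name == "kappa" and model == "RM1") else name
        bounds[name] = DEFAULT_BOUNDS[key]
    return PriorBox(bounds)


# ---------------------------------------------------------------------------
# Latin Hypercube starting points
# ---------------------------------------------------------------------------

def lhs_candidates(
    prior: PriorBox,
    n_samples: int,
    objective,
    n_chains: int,
    seed,
    constraint=None,
) -> tuple[np.ndarray, np.ndarray]:
    """LHS points over the prior box ranked by objective.

    Returns the ``n_chains`` highest-objective points (and their objective
    values), sorted best first.  Points violating ``constraint`` score -inf.
    """
    if n_samples < n_chains:
        raise ValueError("n_samples must be >= n_chains")
    sampler = qmc.LatinHypercube(d=len(prior.names), seed=seed)
    unit = sampler.random(n_samples)
    points = qmc.scale(unit, prior.lower, prior.upper)
    objs = np.full(n_samples, -np.inf)
    for k, theta in enumerate(points):
        if constraint is not None and not constraint(theta):
            continue
        val = objective(theta)
        objs[k] = val if np.isfinite(val) else -np.inf
    if not np.any(np.isfinite(objs)):
        raise ValueError("objective is -inf at every LHS candidate")
    order = np.argsort(objs)[::-1][:n_chains]
    return points[order], objs[order]


# ---------------------------------------------------------------------------
# Metropolis random walk
# ---------------------------------------------------------------------------

@dataclass
class Chain:
    draws: np.ndarray       # (n_iter, d)
    loglik: np.ndarray      # (n_iter,)
    accept_rate: float
    proposal_scales: np.ndarray
    seed: int | None = None


def run_chain(
    start: np.ndarray,
    prior: PriorBox,
    objective,
    n_iter: int,
    proposal_scales: np.ndarray | None = None,
    seed=None,
    constraint=None,
    adapt_until: int | None = None,
    target_accept: float = TARGET_ACCEPT,
    adapt_interval: int = 100,
    proposal_chol: np.ndarray | None = None,
) -> Chain:
    """One Metropolis random-walk chain over the prior box.

    Proposals outside the box or violating ``constraint`` are rejected
    outright.  ``adapt_until`` bounds the adaptation window (default half
    the chain); retained inference should discard at least that prefix.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(start, dtype=float).copy()
    d = len(theta)
    if not prior.contains(theta):
        raise ValueError("start point outside the prior box")
    if constraint is not None and not constraint(theta):
        raise ValueError("start point violates the constraint")
    ll = float(objective(theta))
    if not np.isfinite(ll):
        raise ValueError("objective not finite at the start point")

    if adapt_until is None:
        adapt_until = n_iter // 2
    scales = (
        np.asarray(proposal_scales, dtype=float).copy()
        if proposal_scales is not None
        else prior.width / 20.0
    )
    frozen_scales = proposal_scales is not None
    log_sf = 0.0
    # proposal shape: Cholesky factor of the (scaled) covariance; starts
    # diagonal (or from `proposal_chol`, e.g. spanning the high-likelihood
    # LHS candidates), then adapted to the empirical covariance of the
    # recent draws so that correlated posterior ridges are proposed along,
    # not across
    L = np.diag(scales) if proposal_chol is None else np.asarray(proposal_chol)
    draws = np.empty((n_iter, d))
    logliks = np.empty(n_iter)
    accepted = 0
    window_accepted = 0

    for t in range(n_iter):
        prop = theta + np.exp(log_sf) * (L @ rng.standard_normal(d))
        ok = prior.contains(prop) and (constraint is None or constraint(prop))
        if ok:
            ll_prop = float(objective(prop))
            if np.isfinite(ll_prop) and np.log(rng.random()) < ll_prop - ll:
                theta, ll = prop, ll_prop
                accepted += 1
                window_accepted += 1
        draws[t] = theta
        logliks[t] = ll
        if t < adapt_until and (t + 1) % adapt_interval == 0:
            rate = window_accepted / adapt_interval
            log_sf += (rate - target_accept)  # Robbins-Monro-style nudge
            window_accepted = 0
            if not frozen_scales and t + 1 >= 5 * adapt_interval:
                recent = draws[max(0, t + 1 - 5000): t + 1]
                cov = np.cov(recent.T)
                # regularise: floor each variance at a sliver of the box
                jitter = np.diag((prior.width * 1e-6) ** 2)
                try:
                    L = np.linalg.cholesky(
                        (2.38 ** 2 / d) * (np.atleast_2d(cov) + jitter))
                except np.linalg.LinAlgError:
                    L = np.diag(np.maximum(recent.std(axis=0), prior.width * 1e-6)
                                * 2.38 / np.sqrt(d))

    return Chain(
        draws=draws,
        loglik=logliks,
        accept_rate=accepted / n_iter,
        proposal_scales=np.exp(log_sf) * np.sqrt(np.diag(L @ L.T)),
        seed=seed if isinstance(seed, int) else None,
    )


class _ProposalMixture:
    """Frozen Gaussian-mixture independence proposal.

    Sampling and scoring are done directly from the component parameters so
    that draws come from the caller's RNG stream.
    """

    def __init__(self, weights, means, covariances):
        self.weights = np.asarray(weights)
        self.means = np.asarray(means)
        self.chols = np.stack([np.linalg.cholesky(c) for c in covariances])
        self._log_norm = np.array([
            -0.5 * (len(m) * np.log(2 * np.pi)) - np.log(np.diag(ch)).sum()
            for m, ch in zip(self.means, self.chols)])

    def sample_one(self, rng) -> np.ndarray:
        k = rng.choice(len(self.weights), p=self.weights)
        return self.means[k] + self.chols[k] @ rng.standard_normal(self.means.shape[1])

    def log_density(self, x: np.ndarray) -> float:
        from scipy.linalg import solve_triangular
        from scipy.special import logsumexp

        comps = []
        for k in range(len(self.weights)):
            u = solve_triangular(self.chols[k], x - self.means[k], lower=True)
            comps.append(np.log(self.weights[k]) + self._log_norm[k] - 0.5 * u @ u)
        return float(logsumexp(comps))


def _fit_proposal_mixture(samples: np.ndarray, max_points: int = 20_000):
    """Fit a full-covariance Gaussian mixture to pooled burn-in draws."""
    if len(samples) < 500:
        return None
    if len(samples) > max_points:
        samples = samples[:: len(samples) // max_points + 1]
    try:
        from sklearn.mixture import GaussianMixture

        k = min(16, len(samples) // 200)
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             random_state=0, reg_covar=1e-10, max_iter=200)
        gm.fit(samples)
        return _ProposalMixture(gm.weights_, gm.means_, gm.covariances_)
    except Exception:
        return None


def run_chains_pooled(
    starts: np.ndarray,
    prior: PriorBox,
    objective,
    n_iter: int,
    seeds,
    constraint=None,
    adapt_until: int | None = None,
    target_accept: float = TARGET_ACCEPT,
    adapt_interval: int = 100,
    jump_prob: float = 0.1,
    indep_prob: float = 0.2,
) -> list[Chain]:
    """Multiple Metropolis chains run in lockstep with shared adaptation.

    During the adaptation window all chains use one common proposal
    covariance estimated from their pooled recent draws.  Because the pooled
    covariance includes the between-chain spread, the proposal is inflated
    exactly along the directions where chains still disagree (e.g. weakly
    identified parameter ridges), which is what lets them merge.  In the
    same window a small fraction ``jump_prob`` of proposals are
    independence moves onto a (jittered) pooled draw, so a chain trailing
    on a minor branch of a ridge can hop straight onto the branch the
    others occupy; these moves use the plain likelihood-ratio acceptance,
    whose bias is confined to the discarded window.

    When the window closes, a Gaussian mixture is fitted to the pooled
    burn-in draws and frozen.  The retained phase then uses a fixed
    mixture kernel, identical across chains: random-walk proposals with
    probability ``1 - indep_prob`` and independence proposals from the
    mixture (with the exact Metropolis-Hastings density correction)
    otherwise.  The independence component supplies posterior-scale global
    moves, so long flat ridges and minor branches are traversed at a rate
    their mass deserves rather than by diffusion.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    m, d = starts.shape
    if len(seeds) != m:
        raise ValueError("need one seed per chain")
    rngs = [np.random.default_rng(s) for s in seeds]
    thetas = [s.copy() for s in starts]
    lls = []
    for th in thetas:
        if not prior.contains(th) or (constraint is not None and not constraint(th)):
            raise ValueError("start point outside the prior box or constraint")
        ll = float(objective(th))
        if not np.isfinite(ll):
            raise ValueError("objective not finite at a start point")
        lls.append(ll)

    if adapt_until is None:
        adapt_until = n_iter // 2
    L = np.diag(prior.width / 20.0)
    log_sf = 0.0
    draws = np.empty((m, n_iter, d))
    logliks = np.empty((m, n_iter))
    accepted = np.zeros(m, dtype=int)
    window_accepted = 0

    window_rw = 0
    gmm = None
    for t in range(n_iter):
        adapting = t < adapt_until
        if not adapting and gmm is None and indep_prob > 0 and t > 0:
            gmm = _fit_proposal_mixture(
                draws[:, max(2 * adapt_interval, adapt_until // 2): t].reshape(-1, d))
        for c in range(m):
            is_indep = False
            if adapting and t >= 5 * adapt_interval and rngs[c].random() < jump_prob:
                # independence move onto another chain's recent region
                src = rngs[c].integers(m)
                back = 1 + rngs[c].integers(min(t, 5000))
                prop = (draws[src, t - back]
                        + 0.1 * np.exp(log_sf) * (L @ rngs[c].standard_normal(d)))
                is_jump = True
            elif not adapting and gmm is not None and rngs[c].random() < indep_prob:
                prop = gmm.sample_one(rngs[c])
                is_jump = False
                is_indep = True
            else:
                # symmetric scale mixture: occasional 5x jumps keep
                # ridge-length moves alive at the tuned local scale
                mult = 5.0 if rngs[c].random() < 0.1 else 1.0
                prop = thetas[c] + mult * np.exp(log_sf) * (L @ rngs[c].standard_normal(d))
                is_jump = False
                if adapting:
                    window_rw += 1
            ok = prior.contains(prop) and (constraint is None or constraint(prop))
            if ok:
                ll_prop = float(objective(prop))
                if is_indep:
                    # exact MH correction for the independence component
                    log_alpha = (ll_prop - lls[c]
                                 + gmm.log_density(thetas[c]) - gmm.log_density(prop))
                else:
                    log_alpha = ll_prop - lls[c]
                if np.isfinite(ll_prop) and np.log(rngs[c].random()) < log_alpha:
                    thetas[c], lls[c] = prop, ll_prop
                    accepted[c] += 1
                    if adapting and not is_jump:
                        window_accepted += 1
            draws[c, t] = thetas[c]
            logliks[c, t] = lls[c]
        if t < adapt_until and (t + 1) % adapt_interval == 0:
            rate = window_accepted / max(window_rw, 1)
            log_sf += (rate - target_accept)
            window_accepted = 0
            window_rw = 0
            if t + 1 >= 5 * adapt_interval:
                # pool the post-warm-up history (minus the first quarter,
                # the approach from the LHS starts) so the covariance spans
                # the full extent of any posterior ridge
                lo = max(2 * adapt_interval, (t + 1) // 4)
                recent = draws[:, lo: t + 1].reshape(-1, d)
                cov = np.cov(recent.T)
                jitter = np.diag((prior.width * 1e-6) ** 2)
                try:
                    L = np.linalg.cholesky(
                        (2.38 ** 2 / d) * (np.atleast_2d(cov) + jitter))
                except np.linalg.LinAlgError:
                    L = np.diag(np.maximum(recent.std(axis=0), prior.width * 1e-6)
                                * 2.38 / np.sqrt(d))

    scales = np.exp(log_sf) * np.sqrt(np.diag(L @ L.T))
    return [
        Chain(draws=draws[c], loglik=logliks[c],
              accept_rate=accepted[c] / n_iter, proposal_scales=scales)
        for c in range(m)
    ]


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one parameter across chains; x has shape (m, n).

    Each chain is split in half, then the classic between/within variance
    ratio is computed over the 2m half-chains.  The value is clamped below
    at 1.0; identical constant chains give exactly 1.0 and diverging chains
    give large values (inf when within-variance is zero).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    m, n = x.shape
    if n >= 4:
        half = n // 2
        x = np.concatenate([x[:, :half], x[:, n - half:]], axis=0)
        m, n = x.shape
    chain_means = x.mean(axis=1)
    B = n * chain_means.var(ddof=1)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return max(1.0, float(np.sqrt(var_plus / W)))


@dataclass(frozen=True)
class ConvergenceResult:
    rhat: dict[str, float]
    converged_from: int
    converged: bool


def assess_convergence(
    chains: list[Chain],
    param_names: tuple[str, ...],
    threshold: float = 1.05,
    min_start: int = 0,
    n_candidates: int = 6,
) -> ConvergenceResult:
    """Pick the earliest truncation from which all split-R-hat < threshold.

    Candidate truncation points run from ``min_start`` (at least the
    adaptation window) to 3/4 of the chain length.  If none passes, the last
    candidate is reported with ``converged=False``.
    """
    if len(chains) < 2:
        raise ValueError("need >= 2 chains to assess convergence")
    n = min(len(c.draws) for c in chains)
    stack = np.stack([c.draws[:n] for c in chains])  # (m, n, d)
    starts = np.unique(
        np.linspace(min_start, int(n * 0.75), n_candidates).astype(int)
    )
    last_rhat: dict[str, float] = {}
    for s in starts:
        rh = {
            name: split_rhat(stack[:, s:, k])
            for k, name in enumerate(param_names)
        }
        last_rhat = rh
        if max(rh.values()) < threshold:
            return ConvergenceResult(rhat=rh, converged_from=int(s), converged=True)
    return ConvergenceResult(rhat=last_rhat, converged_from=int(starts[-1]), converged=False)


@dataclass(frozen=True)
class PosteriorChains:
    """Draws and log-likelihood traces of a multi-chain run."""

    chains: list[Chain]
    param_names: tuple[str, ...]
    seed: int | None = None
    convergence: ConvergenceResult | None = None

    @property
    def n_iter(self) -> int:
        return min(len(c.draws) for c in self.chains)

    def retained(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled post-convergence draws (n, d) and logliks (n,)."""
        start = self.convergence.converged_from if self.convergence else 0
        draws = np.concatenate([c.draws[start:] for c in self.chains])
        lls = np.concatenate([c.loglik[start:] for c in self.chains])
        if len(draws) == 0:
            raise ValueError("no retained draws")
        return draws, lls

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, c in enumerate(self.chains):
            df = pd.DataFrame(c.draws, columns=list(self.param_names))
            df.insert(0, "iteration", np.arange(len(c.draws)))
            df.insert(0, "chain", ci)
            df["loglik"] = c.loglik
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means and equal-tailed 95% credible intervals."""

    table: pd.DataFrame  # rows: parameters + loglik; cols: mean, lo95, hi95, rhat

    def __str__(self):
        return self.table.to_string(float_format=lambda v: f"{v:.6g}")


def summarise_posterior(posterior: PosteriorChains) -> PosteriorSummary:
    draws, lls = posterior.retained()
    rhat = posterior.convergence.rhat if posterior.convergence else {}
    rows = {}
    for k, name in enumerate(posterior.param_names):
        col = draws[:, k]
        rows[name] = {
            "mean": col.mean(),
            "lo95": np.quantile(col, 0.025),
            "hi95": np.quantile(col, 0.975),
            "rhat": rhat.get(name, np.nan),
        }
    rows["loglik"] = {
        "mean": lls.mean(),
        "lo95": np.quantile(lls, 0.025),
        "hi95": np.quantile(lls, 0.975),
        "rhat": np.nan,
    }
    return PosteriorSummary(pd.DataFrame(rows).T[["mean", "lo95", "hi95", "rhat"]])
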