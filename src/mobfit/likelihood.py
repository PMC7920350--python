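"""Negative binomial likelihood of observed OD counts given model flows.

The count Data_ij for each origin-destination pair of administrative units
is modelled as negative binomial with mean Model_ij and dispersion ``disp``
(size = 1/disp), so that var = mean + disp * mean^2.  ``disp`` below 1e-8 is
evaluated on the Poisson branch for numerical stability; disp = 0 *is* the
Poisson likelihood.

A :class:`FlowDataset` also records the bookkeeping the masking rules need:
whether flows are directional or symmetrised sums f_ij+f_ji stored once
per unordered pair (when outbound and return trips are indistinguishable),
and whether within-unit
(diagonal) counts exist.  OD pairs absent from the table are unobserved and
excluded from the likelihood, not treated as zeros; observed zeros are
ordinary likelihood terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .flows import FlowMatrix

POISSON_DISP_TOL = 1e-8


@dataclass(frozen=True)
class LikelihoodValue:
    loglik: float
    n_terms: int


@dataclass
class FlowDataset:
    """Observed admin-level OD trip counts.

    ``flows`` has columns origin, destination, count (non-negative
    integers).  If ``directional`` is False the stored count for a pair is
    the symmetrised sum f_ij + f_ji, kept once per unordered pair with
    origin <= destination.  ``has_diagonal`` says whether within-unit
    counts are present; diagonal pairs enter the likelihood only if so.
    """

    flows: pd.DataFrame
    directional: bool
    has_diagonal: bool

    def __post_init__(self):
        df = self.flows
        for col in ("origin", "destination", "count"):
            if col not in df.columns:
                raise ValueError(f"flow table is missing column {col!r}")
        counts = np.asarray(df["count"])
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        df = df.copy()
        df["count"] = np.round(counts).astype(np.int64)
        diag = df["origin"] == df["destination"]
        if diag.any() and not self.has_diagonal:
            raise ValueError("diagonal rows present but has_diagonal is False")
        if not self.directional:
            o = df["origin"].to_numpy()
            d = df["destination"].to_numpy()
            if np.any(o > d):
                raise ValueError(
                    "symmetrised datasets must store unordered pairs with origin <= destination"
                )
        if df.duplicated(["origin", "destination"]).any():
            raise ValueError("duplicate OD pairs in flow table")
        self.flows = df.reset_index(drop=True)

    @property
    def units(self) -> np.ndarray:
        return np.unique(
            np.concatenate([self.flows["origin"].to_numpy(), self.flows["destination"].to_numpy()])
        )

    @property
    def n_pairs(self) -> int:
        return len(self.flows)

    def total_trips(self) -> int:
        return int(self.flows["count"].sum())

    @classmethod
    def from_matrix(cls, counts: np.ndarray, labels, directional: bool,
                    has_diagonal: bool) -> "FlowDataset":
        """Build from a dense count matrix; symmetrised input is folded to
        the upper triangle (counts summed across the two directions)."""
        counts = np.asarray(counts)
        labels = np.asarray(labels)
        rows = []
        n = counts.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j and not has_diagonal:
                    continue
                if not directional:
                    if i > j:
                        continue
                    c = counts[i, j] + (counts[j, i] if i != j else 0)
                else:
                    c = counts[i, j]
                rows.append((labels[i], labels[j], int(c)))
        df = pd.DataFrame(rows, columns=["origin", "destination", "count"])
        return cls(df, directional=directional, has_diagonal=has_diagonal)


# ---------------------------------------------------------------------------
# negative binomial log-pmf
# ---------------------------------------------------------------------------

def nb_loglik_term(count, mean, disp: float):
    """Log-pmf of the negative binomial at ``count`` with the given mean and
    over-dispersion; the Poisson limit is used below ``disp`` = 1e-8.

    Vectorised over ``count`` and ``mean`` (broadcast together).
    """
    count = np.asarray(count)
    mean = np.asarray(mean, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be >= 0")
    if not np.allclose(count, np.round(count)):
        raise ValueError("counts must be integers")
    if np.any(mean <= 0) or not np.all(np.isfinite(mean)):
        raise ValueError("means must be finite and > 0")
    if disp < 0:
        raise ValueError("disp must be >= 0")
    D = np.round(count).astype(np.int64)
    if disp < POISSON_DISP_TOL:
        out = D * np.log(mean) - mean - gammaln(D + 1.0)
    else:
        s = 1.0 / disp  # NB size parameter
        out = (
            gammaln(D + s)
            - gammaln(D + 1.0)
            - gammaln(s)
            + D * np.log(mean / (mean + s))
            + s * np.log(s / (mean + s))
        )
    if out.ndim == 0:
        return float(out)
    return out


def _nb_loglik_fast(D, lgamma_D1, mean, disp):
    """Masked-term sum without validation: the hot path of MCMC objectives.

    Returns -inf for any non-finite or non-positive mean (an out-of-range
    parameter proposal) instead of raising.
    """
    if not np.all(np.isfinite(mean)) or np.any(mean <= 0):
        return -np.inf
    if disp < POISSON_DISP_TOL:
        terms = D * np.log(mean) - mean - lgamma_D1
    else:
        s = 1.0 / disp
        terms = (
            gammaln(D + s) - lgamma_D1 - gammaln(s)
            + D * np.log(mean / (mean + s))
            + s * np.log(s / (mean + s))
        )
    total = terms.sum()
    return float(total) if np.isfinite(total) else -np.inf


def match_means(data: FlowDataset, model_flows: FlowMatrix) -> np.ndarray:
    """Model means aligned with the dataset's masked pairs.

    For symmetrised data the model matrix must be symmetric and the mean for
    an unordered pair is the (upper-triangle) matrix entry.  Raises when a
    masked pair has an undefined (excluded diagonal) or non-positive flow.
    """
    if model_flows.labels is None:
        raise ValueError("model flows carry no unit labels")
    labels = np.asarray(model_flows.labels)
    lut = {lab: k for k, lab in enumerate(labels)}
    o = data.flows["origin"].to_numpy()
    d = data.flows["destination"].to_numpy()
    try:
        oi = np.array([lut[v] for v in o])
        di = np.array([lut[v] for v in d])
    except KeyError as exc:
        raise ValueError(f"dataset unit {exc.args[0]!r} not in model flows") from exc
    diag = oi == di
    if diag.any() and model_flows.diagonal == "excluded":
        bad = o[diag][0]
        raise ValueError(f"model does not define within-unit flow for unit {bad!r}")
    means = model_flows.values[oi, di]
    if np.any(means <= 0) or not np.all(np.isfinite(means)):
        k = int(np.argmin(means))
        raise ValueError(f"masked pair ({o[k]!r}, {d[k]!r}) has non-positive model flow")
    return means


def dataset_loglik(data: FlowDataset, model_flows: FlowMatrix, disp: float) -> LikelihoodValue:
    """Sum of NB log-pmf terms over the dataset's masked OD pairs."""
    means = match_means(data, model_flows)
    terms = nb_loglik_term(data.flows["count"].to_numpy(), means, disp)
    return LikelihoodValue(loglik=float(np.sum(terms)), n_terms=len(means))


# ---------------------------------------------------------------------------
# ingestion of proportion-of-nights data
# ---------------------------------------------------------------------------

def ingest_proportions(
    nights_shares: pd.DataFrame,
    residents: pd.Series,
    tolerance: float = 1e-6,
) -> FlowDataset:
    """Convert proportion-of-nights shares into integer trip counts.

    ``nights_shares`` has columns origin (resident unit), destination
    (visited unit) and proportion; counts are proportion x residents of the
    origin unit, rounded half-up.  Units absent from ``residents`` or with
    zero population are dropped.  The result is directional with diagonal.
    """
    for col in ("origin", "destination", "proportion"):
        if col not in nights_shares.columns:
            raise ValueError(f"nights table is missing column {col!r}")
    props = np.asarray(nights_shares["proportion"], dtype=float)
    if np.any(props < 0):
        raise ValueError("proportions must be >= 0")
    sums = nights_shares.groupby("origin")["proportion"].sum()
    if (sums > 1 + tolerance).any():
        bad = sums[sums > 1 + tolerance].index.tolist()
        raise ValueError(f"proportions for origin unit(s) {bad} sum above 1")

    residents = residents[residents > 0]
    keep_units = set(residents.index)
    df = nights_shares[
        nights_shares["origin"].isin(keep_units)
        & nights_shares["destination"].isin(keep_units)
    ].copy()
    res = residents.loc[df["origin"]].to_numpy(dtype=float)
    # round half-up to the nearest integer trip count
    df["count"] = np.floor(df["proportion"].to_numpy() * res + 0.5).astype(np.int64)
    out = df[["origin", "destination", "count"]].reset_index(drop=True)
    return FlowDataset(out, directional=True, has_diagonal=True)
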