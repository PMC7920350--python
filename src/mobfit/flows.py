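"""Expected-flow kernels: gravity model and radiation variants RM1-RM4.

All kernels return a dense :class:`FlowMatrix` of expected trips over the
locations of a :class:`~mobfit.spatial.SpatialSystem` (cells or admin
units).  ``aggregate_to_admin`` sums cell-pair flows into admin-level OD
pairs, which is how a fine-scale model is compared against flow data
observed only between administrative units.

Gravity model (directional):

    F_ij = 10^kappa * m_i^alpha * m_j^beta / (1 + (d_ij / 10^gamma)^epsilon)

The symmetrised variant, for undirected data where outbound and return
journeys cannot be distinguished, sums the two ordered numerators and by
default carries the prefactor 10^(kappa - gamma*epsilon), which keeps kappa
well identified when no within-unit counts are available.

Radiation models replace the distance kernel with the ring population
r_ij (population strictly between i and the circle through j, excluding
m_i and m_j):

    F_ij = T_i * (m_i + theta) * m_j
           / [(m_i + theta + r_ij + m_j) * (m_i + theta + r_ij)]

with theta = 0 for RM1/RM2 and the traveller number T_i estimated as
kappa*m_i (RM1, natural-scale kappa), 10^kappa*m_i^alpha (RM2),
10^kappa*m_i (RM3) or 10^kappa*m_i^alpha (RM4).  Radiation models do not
define within-location trips; their diagonal is zero and flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .spatial import SpatialSystem

LN10 = np.log(10.0)

GRAVITY_MODELS = ("GM",)
RADIATION_MODELS = ("RM1", "RM2", "RM3", "RM4")
MODEL_NAMES = GRAVITY_MODELS + RADIATION_MODELS

#: free parameters per model, in canonical order (dispersion excluded)
MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "GM": ("kappa", "alpha", "beta", "gamma", "epsilon"),
    "RM1": ("kappa",),
    "RM2": ("kappa", "alpha"),
    "RM3": ("kappa", "theta"),
    "RM4": ("kappa", "alpha", "theta"),
}

ScaleFactor = Literal["kappa-gamma-eps", "kappa"]


@dataclass
class ModelParams:
    """Parameter vector for the mobility models.

    kappa is the log10 proportionality constant, except for RM1 where it is
    natural-scale (>= 0).  gamma is log10 of the distance scale in metres
    (the kernel scale is 10^gamma m).  theta is the origin-population
    increment in persons.  disp is the negative binomial over-dispersion
    (variance = mean + disp * mean^2; disp = 0 is Poisson).
    """

    kappa: float = 0.0
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    epsilon: float | None = None
    theta: float | None = None
    disp: float = 0.0

    def __post_init__(self):
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.disp < 0:
            raise ValueError("disp must be >= 0")

    def require(self, model: str) -> None:
        for name in MODEL_PARAM_NAMES[model]:
            if getattr(self, name) is None:
                raise ValueError(f"model {model} requires parameter {name!r}")

    @classmethod
    def from_vector(cls, model: str, values, disp: float = 0.0) -> "ModelParams":
        names = MODEL_PARAM_NAMES[model]
        if len(values) not in (len(names), len(names) + 1):
            raise ValueError(f"expected {len(names)}(+1) values for {model}")
        kw = dict(zip(names, values))
        if len(values) == len(names) + 1:
            disp = values[-1]
        return cls(disp=disp, **kw)


@dataclass
class FlowMatrix:
    """Dense matrix of expected trips between the locations of a system.

    ``diagonal`` records whether within-location (i = i) flows are part of
    the model ("included") or undefined ("excluded", entries zeroed).
    ``labels`` carries location identifiers (admin-unit ids after
    aggregation; cell indices otherwise).
    """

    values: np.ndarray
    diagonal: Literal["included", "excluded"]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("flow matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("flows must be finite")
        if np.any(self.values < 0):
            raise ValueError("flows must be >= 0")

    @property
    def total(self) -> float:
        """Sum over the entries the model defines."""
        t = float(self.values.sum())
        if self.diagonal == "excluded":
            t -= float(np.trace(self.values))
        return t


def _positive_populations(system: SpatialSystem) -> np.ndarray:
    m = system.population.astype(float)
    if np.any(m <= 0):
        raise ValueError(
            "all populations must be > 0 to evaluate a mobility model "
            "(drop empty cells first)"
        )
    return m


# ---------------------------------------------------------------------------
# gravity
# ---------------------------------------------------------------------------

def _gravity_kernel(D: np.ndarray, gamma: float, epsilon: float) -> np.ndarray:
    # 1 + (d / 10^gamma)^epsilon, exact 1 on the diagonal (d = 0)
    with np.errstate(divide="ignore"):
        ld = np.log(D, out=np.full_like(D, -np.inf), where=D > 0)
    return 1.0 + np.exp(epsilon * (ld - gamma * LN10))


def gravity_flow_directional(system: SpatialSystem, params: ModelParams) -> FlowMatrix:
    """Directional gravity flows, including within-location (d = 0) entries."""
    params.require("GM")
    m = _positive_populations(system)
    kern = _gravity_kernel(system.distances, params.gamma, params.epsilon)
    F = 10.0 ** params.kappa * np.outer(m ** params.alpha, m ** params.beta) / kern
    return FlowMatrix(F, diagonal="included")


def gravity_flow_symmetrised(
    system: SpatialSystem,
    params: ModelParams,
    scale_factor: ScaleFactor = "kappa-gamma-eps",
) -> FlowMatrix:
    """Symmetrised gravity flows for undirected OD data.

    With the default ``scale_factor`` the prefactor is
    10^(kappa - gamma*epsilon); with ``scale_factor="kappa"`` it is plain
    10^kappa, in which case (absent within-unit data and with
    10^(gamma*epsilon) << d^epsilon) only kappa + gamma*epsilon is
    identified and the posterior shows a kappa-gamma ridge.
    """
    params.require("GM")
    m = _positive_populations(system)
    kern = _gravity_kernel(system.distances, params.gamma, params.epsilon)
    a = m ** params.alpha
    b = m ** params.beta
    num = np.outer(a, b)
    num = num + num.T
    if scale_factor == "kappa-gamma-eps":
        pref = 10.0 ** (params.kappa - params.gamma * params.epsilon)
    elif scale_factor == "kappa":
        pref = 10.0 ** params.kappa
    else:
        raise ValueError(f"unknown scale_factor {scale_factor!r}")
    return FlowMatrix(pref * num / kern, diagonal="included")


# ---------------------------------------------------------------------------
# radiation
# ---------------------------------------------------------------------------

def radiation_flow(
    system: SpatialSystem,
    rings: np.ndarray,
    params: ModelParams,
    variant: str,
) -> FlowMatrix:
    """Directional radiation flows for one of the variants RM1-RM4."""
    if variant not in RADIATION_MODELS:
        raise ValueError(f"unknown radiation variant {variant!r}")
    params.require(variant)
    m = _positive_populations(system)
    if rings.shape != (len(m), len(m)):
        raise ValueError("ring matrix does not match the system")

    if variant == "RM1":
        if params.kappa < 0:
            raise ValueError("RM1 kappa is natural-scale and must be >= 0")
        T = params.kappa * m
    elif variant == "RM2":
        T = 10.0 ** params.kappa * m ** params.alpha
    elif variant == "RM3":
        T = 10.0 ** params.kappa * m
    else:  # RM4
        T = 10.0 ** params.kappa * m ** params.alpha

    theta = 0.0 if variant in ("RM1", "RM2") else params.theta
    if theta is None or theta < 0:
        raise ValueError("theta must be >= 0")

    mi = (m + theta)[:, None]
    mj = m[None, :]
    denom = (mi + rings + mj) * (mi + rings)
    F = T[:, None] * mi * mj / denom
    np.fill_diagonal(F, 0.0)
    return FlowMatrix(F, diagonal="excluded")


def radiation_flow_symmetrised(
    system: SpatialSystem,
    rings: np.ndarray,
    params: ModelParams,
    variant: str,
) -> FlowMatrix:
    """Transpose-sum symmetrisation F_ij + F_ji of a radiation variant."""
    directional = radiation_flow(system, rings, params, variant)
    return FlowMatrix(directional.values + directional.values.T, diagonal="excluded")


# ---------------------------------------------------------------------------
# aggregation of cell flows to admin OD pairs
# ---------------------------------------------------------------------------

def aggregate_to_admin(cell_flow: FlowMatrix, system: SpatialSystem) -> FlowMatrix:
    """Sum cell-pair flows into admin-unit OD pairs.

    AdminF[I, J] = sum of cell_flow over cells of I x cells of J.  The
    within-unit (I = J) aggregate is defined only when the cell model
    defines self/within flows (gravity); for diagonal-excluded cell models
    the admin diagonal is zeroed and flagged excluded.
    """
    n = system.n_cells
    if cell_flow.values.shape != (n, n):
        raise ValueError("flow matrix does not match the system")
    codes = system.unit_codes
    U = system.n_units
    pair_id = (codes[:, None] * U + codes[None, :]).ravel()
    agg = np.bincount(pair_id, weights=cell_flow.values.ravel(), minlength=U * U)
    A = agg.reshape(U, U)
    if cell_flow.diagonal == "excluded":
        np.fill_diagonal(A, 0.0)
    return FlowMatrix(A, diagonal=cell_flow.diagonal, labels=system.unit_ids)


def expected_flows(
    system: SpatialSystem,
    model: str,
    params: ModelParams,
    symmetrised: bool = False,
    scale_factor: ScaleFactor = "kappa-gamma-eps",
    rings: np.ndarray | None = None,
    aggregate: bool = True,
) -> FlowMatrix:
    """Evaluate a named model on a system; optionally aggregate to admin.

    Convenience front door used by the fitting and predictive layers.
    """
    if model == "GM":
        if symmetrised:
            F = gravity_flow_symmetrised(system, params, scale_factor)
        else:
            F = gravity_flow_directional(system, params)
    elif model in RADIATION_MODELS:
        if rings is None:
            from .spatial import ring_population

            rings = ring_population(system)
        if symmetrised:
            F = radiation_flow_symmetrised(system, rings, params, model)
        else:
            F = radiation_flow(system, rings, params, model)
    else:
        raise ValueError(f"unknown model {model!r}")
    if aggregate:
        # at admin scale this is the identity up to unit-id ordering
        F = aggregate_to_admin(F, system)
    return F
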