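"""Data model, likelihood and prior log-densities for both mixture models.

Counts Y_it in area i at time t are Poisson with mean mu_it * E_it, where
E_it is an exposure offset (expected cases, or traffic volume).  The log
relative risk log(mu_it) is a two-component mixture:

* Common model:        alpha0 + eta_i + gamma_t  — one national time trend
  gamma (RW1) plus a BYM spatial surface (eta_i ~ N(v_i, sigma2_eta), v
  spatially structured ICAR).
* Area-Specific model: nu_i + kappa_it           — a free intercept and
  RW1 trend per area.

A binary allocation z selects the component: per area (baseline model,
z_i ~ Bern(0.95)) or per area-time cell (proposed model, z_it Bernoulli
with a hierarchical logit field pi_i + delta_t + logit(tau),
tau ~ U(0.9, 1)).  z = 1 means the unit follows the common trend; low
posterior allocation probability marks it unusual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit
from scipy.stats import halfnorm, norm

from .graphs import AdjacencyStructure, icar_logpdf

# Prior constants fixed by the model specification.
BASELINE_COMMON_PRIOR = 0.95     # z_i ~ Bern(0.95): ~5% of areas unusual a priori
NU_PRIOR_VAR = 1000.0            # nu_i ~ N(0, 1000)
A_PRIOR_VAR = 1000.0             # a ~ N(0, 1000)
B_HALFNORMAL_SCALE = 2.5         # b ~ N(0, 2.5^2) truncated to b >= 0
VAR_HALFNORMAL_SCALE = 1.0       # half-Normal N(0,1) on variance hyperparameters
TAU_BOUNDS = (0.9, 1.0)          # tau ~ U(0.9, 1)


@dataclass
class CountData:
    """Observed counts Y and positive exposures E on an N x T grid."""

    Y: np.ndarray
    E: np.ndarray
    area_labels: list = None
    time_labels: list = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        self.E = np.asarray(self.E, dtype=float)
        if self.Y.shape != self.E.shape or self.Y.ndim != 2:
            raise ValueError("Y and E must be matching N x T matrices")
        if np.any(self.E <= 0):
            raise ValueError("exposures E must be strictly positive")
        if np.any(self.Y < 0) or not np.allclose(self.Y, np.round(self.Y)):
            raise ValueError("counts Y must be nonnegative integers")
        self.Y = np.round(self.Y).astype(np.int64)

    @property
    def n_areas(self) -> int:
        return self.Y.shape[0]

    @property
    def n_times(self) -> int:
        return self.Y.shape[1]


@dataclass
class CommonParams:
    """Common-model parameters: one spatial surface, one national trend."""

    alpha0: float
    eta: np.ndarray          # convolved (BYM) spatial effect, length N
    v: np.ndarray            # structured ICAR component, length N
    gamma: np.ndarray        # RW1 national trend, length T
    sigma2_eta: float
    sigma2_v: float
    sigma2_gamma: float


@dataclass
class AreaSpecificParams:
    """Area-specific component: free intercept and RW1 trend per area."""

    nu: np.ndarray           # length N
    kappa: np.ndarray        # N x T
    sigma2_kappa: np.ndarray  # length N
    a_hyper: float = 0.0     # lognormal hyperprior location (baseline only)
    b_hyper: float = 1.0     # lognormal hyperprior scale (baseline only)


@dataclass
class MixingFieldBaseline:
    """Per-area binary allocation; 1 = follows the common trend."""

    z: np.ndarray            # length N, entries in {0,1}


@dataclass
class MixingFieldProposed:
    """Per-cell allocation with a spatio-temporal hierarchical prior.

    logit(phi_it) = pi_i + delta_t + logit(tau); pi spatial ICAR, delta
    temporal ICAR, tau ~ U(0.9, 1) sets the prior expected proportion of
    common cells between 90% and 100%.
    """

    z: np.ndarray            # N x T binary
    pi: np.ndarray           # length N
    delta: np.ndarray        # length T
    tau: float
    sigma2_pi: float
    sigma2_delta: float


def common_linpred(p: CommonParams) -> np.ndarray:
    """Log relative risk under the common model: alpha0 + eta_i + gamma_t."""
    return p.alpha0 + np.asarray(p.eta)[:, None] + np.asarray(p.gamma)[None, :]


def area_specific_linpred(p: AreaSpecificParams) -> np.ndarray:
    """Log relative risk under the area-specific model: nu_i + kappa_it."""
    nu = np.asarray(p.nu)
    kappa = np.asarray(p.kappa)
    if kappa.shape[0] != nu.shape[0]:
        raise ValueError("kappa rows must match length of nu")
    return nu[:, None] + kappa


def mixture_linpred(z, muC, muAS) -> np.ndarray:
    """Mixture log risk: z * mu^(C) + (1 - z) * mu^(AS), entrywise.

    z may be a length-N vector (baseline: one allocation per area,
    broadcast over time) or an N x T matrix (proposed model).
    """
    z = np.asarray(z, dtype=float)
    muC = np.asarray(muC, dtype=float)
    muAS = np.asarray(muAS, dtype=float)
    if muC.shape != muAS.shape:
        raise ValueError("component predictors must share a shape")
    if not np.all((z == 0) | (z == 1)):
        raise ValueError("allocation z must be binary")
    if z.ndim == 1:
        z = z[:, None]
    return z * muC + (1.0 - z) * muAS


def poisson_loglik(data: CountData, log_mu) -> float:
    """Full Poisson log likelihood of the counts given log relative risks.

    sum_it [ Y_it (log E_it + log mu_it) - E_it exp(log mu_it) - log(Y_it!) ]
    """
    log_mu = np.asarray(log_mu, dtype=float)
    if log_mu.shape != data.Y.shape:
        raise ValueError("log_mu must match the data shape")
    Y, E = data.Y, data.E
    return float(np.sum(Y * (np.log(E) + log_mu) - E * np.exp(log_mu)
                        - gammaln(Y + 1.0)))


def poisson_loglik_cells(Y, E, log_mu) -> np.ndarray:
    """Per-cell Poisson log likelihood kernel Y*log_mu - E*exp(log_mu).

    Terms free of log_mu (Y log E and log Y!) are omitted; they cancel in
    every likelihood ratio the samplers and allocation updates need.
    """
    return Y * log_mu - E * np.exp(log_mu)


def phi_field(m: MixingFieldProposed) -> np.ndarray:
    """Prior common-allocation probabilities phi_it on the N x T grid."""
    if not (0.0 < m.tau < 1.0):
        raise ValueError("tau must lie strictly inside (0, 1)")
    lp = (np.asarray(m.pi)[:, None] + np.asarray(m.delta)[None, :]
          + logit(m.tau))
    return expit(lp)


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(halfnorm.logpdf(x, scale=scale))


def _check_variances(*vals):
    for s2 in vals:
        if not np.isfinite(s2) or s2 <= 0:
            raise ValueError("variance parameters must be positive and finite")


def _shared_log_prior(common: CommonParams, areasp: AreaSpecificParams,
                      W: AdjacencyStructure, Q: AdjacencyStructure) -> float:
    """Prior terms common to both models (alpha0 flat contributes 0)."""
    lp = icar_logpdf(common.v, W, common.sigma2_v)
    lp += float(np.sum(norm.logpdf(common.eta, loc=common.v,
                                   scale=np.sqrt(common.sigma2_eta))))
    lp += icar_logpdf(common.gamma, Q, common.sigma2_gamma)
    lp += float(np.sum(norm.logpdf(areasp.nu, scale=np.sqrt(NU_PRIOR_VAR))))
    for i in range(areasp.kappa.shape[0]):
        lp += icar_logpdf(areasp.kappa[i], Q, float(areasp.sigma2_kappa[i]))
    for s2 in (common.sigma2_eta, common.sigma2_v, common.sigma2_gamma):
        lp += _halfnormal_logpdf(s2, VAR_HALFNORMAL_SCALE)
    return lp


def log_prior_baseline(common: CommonParams, areasp: AreaSpecificParams,
                       mixing: MixingFieldBaseline,
                       W: AdjacencyStructure, Q: AdjacencyStructure) -> float:
    """Joint log prior of the baseline model.

    Area-specific trend variances get the lognormal hierarchy
    log(sigma2_kappa_i) ~ N(a, b^2) with a ~ N(0, 1000) and half-normal b;
    allocations are independent Bern(0.95) per area.
    """
    _check_variances(common.sigma2_eta, common.sigma2_v, common.sigma2_gamma,
                     *np.atleast_1d(areasp.sigma2_kappa))
    if areasp.b_hyper <= 0:
        return -np.inf
    lp = _shared_log_prior(common, areasp, W, Q)
    ls2 = np.log(np.asarray(areasp.sigma2_kappa, dtype=float))
    # density of sigma2 when log(sigma2) ~ N(a, b^2): subtract the Jacobian
    lp += float(np.sum(norm.logpdf(ls2, loc=areasp.a_hyper,
                                   scale=areasp.b_hyper) - ls2))
    lp += float(norm.logpdf(areasp.a_hyper, scale=np.sqrt(A_PRIOR_VAR)))
    lp += _halfnormal_logpdf(areasp.b_hyper, B_HALFNORMAL_SCALE)
    z = np.asarray(mixing.z, dtype=float)
    if not np.all((z == 0) | (z == 1)):
        raise ValueError("z must be binary")
    p = BASELINE_COMMON_PRIOR
    lp += float(np.sum(z * np.log(p) + (1 - z) * np.log(1 - p)))
    return lp


def log_prior_proposed(common: CommonParams, areasp: AreaSpecificParams,
                       mixing: MixingFieldProposed,
                       W: AdjacencyStructure, Q: AdjacencyStructure) -> float:
    """Joint log prior of the proposed model.

    Differences from the baseline: half-normal N(0,1) directly on each
    sigma2_kappa_i; per-cell allocations z_it ~ Bern(phi_it) with the
    hierarchical logit field; ICAR priors on pi (spatial) and delta
    (temporal); tau ~ U(0.9, 1) (outside the support the density is -inf).
    """
    _check_variances(common.sigma2_eta, common.sigma2_v, common.sigma2_gamma,
                     mixing.sigma2_pi, mixing.sigma2_delta,
                     *np.atleast_1d(areasp.sigma2_kappa))
    lo, hi = TAU_BOUNDS
    if not (lo < mixing.tau < hi):
        return -np.inf
    lp = _shared_log_prior(common, areasp, W, Q)
    for s2 in np.atleast_1d(areasp.sigma2_kappa):
        lp += _halfnormal_logpdf(float(s2), VAR_HALFNORMAL_SCALE)
    lp += icar_logpdf(mixing.pi, W, mixing.sigma2_pi)
    lp += icar_logpdf(mixing.delta, Q, mixing.sigma2_delta)
    lp += _halfnormal_logpdf(mixing.sigma2_pi, VAR_HALFNORMAL_SCALE)
    lp += _halfnormal_logpdf(mixing.sigma2_delta, VAR_HALFNORMAL_SCALE)
    lp += -np.log(hi - lo)  # uniform tau density
    z = np.asarray(mixing.z, dtype=float)
    if not np.all((z == 0) | (z == 1)):
        raise ValueError("z must be binary")
    phi = phi_field(mixing)
    lp += float(np.sum(z * np.log(phi) + (1 - z) * np.log1p(-phi)))
    return lp
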