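"""Metropolis-within-Gibbs MCMC for the baseline and proposed mixture models.

The sampler follows the standard re-implementation recipe for BUGS-era
spatio-temporal mixtures: random-walk Metropolis for the log-linear
effects (single-site moves batched over conditionally independent blocks
via graph colouring), a constrained Gaussian full-conditional draw for the
structured spatial effect v, log-scale random-walk moves for variance
hyperparameters, and exact Gibbs draws for the binary allocations z from
their full conditionals.  ICAR-distributed vectors are recentred each
sweep to keep the models identifiable, with the removed level absorbed by
the relevant intercept where one exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import linalg
from scipy.special import expit, logit

from .graphs import AdjacencyStructure, icar_quadform, temporal_path_adjacency
from .model_core import (
    A_PRIOR_VAR,
    B_HALFNORMAL_SCALE,
    BASELINE_COMMON_PRIOR,
    NU_PRIOR_VAR,
    TAU_BOUNDS,
    CountData,
)

_ADAPT_TARGET = 0.44     # optimal-ish acceptance for single-site RW moves
_ADAPT_WINDOW = 50


@dataclass
class MCMCConfig:
    """Sampler run settings.

    Defaults mirror a production surveillance run: two chains of 80 000
    iterations, every 2nd stored, the first 20 000 discarded.  Tests and
    the scaled simulation studies use far shorter chains.
    """

    n_iter: int = 80_000
    burn_in: int = 20_000
    thin: int = 2
    n_chains: int = 2
    seed: int = 0
    step_sizes: dict = field(default_factory=dict)
    adapt: bool = True

    def __post_init__(self):
        if self.n_iter <= 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("invalid MCMC configuration")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")

    @classmethod
    def from_file(cls, path) -> "MCMCConfig":
        """Load settings from a YAML or JSON mapping."""
        text = open(path).read()
        try:
            import yaml
            raw = yaml.safe_load(text)
        except ImportError:  # pragma: no cover
            raw = json.loads(text)
        valid = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in valid})


@dataclass
class PosteriorSamples:
    """MCMC output: monitored traces, allocation probabilities, diagnostics.

    ``f`` is the posterior mean of the allocation z — per area (length N)
    for the baseline model, per cell (N x T) for the proposed model — and
    is the quantity detection rules consume.  ``draws`` maps monitored
    parameter names to arrays indexed (chain, stored iteration, ...).
    """

    draws: dict
    f: np.ndarray
    acceptance_rates: dict
    model: str
    n_stored: int
    config: MCMCConfig = None


def z_full_conditional(loglik_common, loglik_area_specific, prior_prob):
    """Posterior probability that a unit follows the common component.

    p = prior * exp(LC) / (prior * exp(LC) + (1 - prior) * exp(LAS)),
    evaluated stably on the logit scale.  Works elementwise on arrays.
    """
    lc = np.asarray(loglik_common, dtype=float)
    las = np.asarray(loglik_area_specific, dtype=float)
    p = np.asarray(prior_prob, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("prior_prob must lie strictly inside (0, 1)")
    with np.errstate(invalid="ignore"):
        log_odds = logit(p) + (lc - las)
    out = expit(log_odds)
    # resolve the indeterminate -inf - (-inf) case to the prior
    both_off = np.isneginf(lc) & np.isneginf(las)
    out = np.where(both_off, p, out)
    return float(out) if out.ndim == 0 else out


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from two or more chains.

    R = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the variance of the chain means.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = x.shape[1]
    within = np.mean(np.var(x, axis=1, ddof=1))
    b_over_n = np.var(np.mean(x, axis=1), ddof=1)
    if within == 0:
        return 1.0
    var_hat = (n - 1) / n * within + b_over_n
    return float(np.sqrt(var_hat / within))


def mc_error(draws, batches: int = 20) -> float:
    """Batch-means Monte Carlo standard error of a posterior mean."""
    x = np.asarray(draws, dtype=float).ravel()
    if batches < 2 or x.size < 2 * batches:
        raise ValueError("need at least two batches of two draws each")
    usable = (x.size // batches) * batches
    means = x[:usable].reshape(batches, -1).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(batches))


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

_DEFAULT_STEPS = {
    "alpha0": 0.05, "eta": 0.2, "gamma": 0.05, "nu": 0.2, "kappa": 0.3,
    "sigma2_eta": 0.6, "sigma2_v": 0.6, "sigma2_gamma": 0.6,
    "sigma2_kappa": 0.8, "b_hyper": 0.4,
    "pi": 0.6, "delta": 0.4, "tau": 0.5,
    "sigma2_pi": 0.8, "sigma2_delta": 0.8,
}


def _halfnorm_lp(x, scale):
    """Half-normal log density up to a constant; -inf for x <= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, -x * x / (2.0 * scale * scale), -np.inf)
    return out if out.ndim else float(out)


def _softplus(x):
    return np.logaddexp(0.0, x)


class _ChainState:
    """One chain of either model; everything vectorised over areas/times."""

    def __init__(self, model: str, data: CountData, W: AdjacencyStructure,
                 Q: AdjacencyStructure, cfg: MCMCConfig, seed: int):
        self.model = model
        self.data = data
        self.W = W
        self.Q = Q
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.N, self.T = data.Y.shape
        self.Y = data.Y.astype(float)
        self.E = data.E

        self.W_csr = W.neighbor_matrix()
        self.Wn = W.neighbor_counts.astype(float)
        self.w_colors = W.coloring()
        self.t_colors = [np.arange(0, self.T, 2), np.arange(1, self.T, 2)]
        self.Qn = Q.neighbor_counts.astype(float)

        # --- initial state: start in the all-common regime ---------------
        self.alpha0 = float(np.log(self.Y.sum() / self.E.sum()))
        if not np.isfinite(self.alpha0):
            raise RuntimeError("non-finite initial intercept: check Y and E")
        self.eta = np.zeros(self.N)
        self.v = np.zeros(self.N)
        self.gamma = np.zeros(self.T)
        self.nu = np.full(self.N, self.alpha0)  # AS level matches data scale
        self.kappa = np.zeros((self.N, self.T))
        self.sigma2_eta = 0.1
        self.sigma2_v = 0.1
        self.sigma2_gamma = 0.1
        self.sigma2_kappa = np.full(self.N, 0.1)
        self.a_hyper = float(np.log(0.1))
        self.b_hyper = 1.0
        if model == "baseline":
            self.z = np.ones(self.N, dtype=np.int64)
        else:
            self.z = np.ones((self.N, self.T), dtype=np.int64)
            self.pi = np.zeros(self.N)
            self.delta = np.zeros(self.T)
            self.tau = 0.95
            self.sigma2_pi = 0.1
            self.sigma2_delta = 0.1

        self.steps = dict(_DEFAULT_STEPS)
        self.steps.update(cfg.step_sizes)
        self.acc: dict[str, list] = {k: [0, 0] for k in self.steps}
        self.win_acc: dict[str, list] = {k: [0, 0] for k in self.steps}
        self.counting = False  # flip on after burn-in

    # -- bookkeeping -------------------------------------------------------

    def _tally(self, name, n_acc, n_prop):
        if self.counting:
            self.acc[name][0] += n_acc
            self.acc[name][1] += n_prop
        else:
            self.win_acc[name][0] += n_acc
            self.win_acc[name][1] += n_prop

    def adapt_steps(self):
        for name, (na, np_) in self.win_acc.items():
            if np_ == 0:
                continue
            rate = na / np_
            self.steps[name] *= float(np.exp(0.8 * (rate - _ADAPT_TARGET)))
            self.steps[name] = float(np.clip(self.steps[name], 1e-4, 10.0))
        self.win_acc = {k: [0, 0] for k in self.win_acc}

    # -- cached predictors ---------------------------------------------------

    def muC(self):
        return self.alpha0 + self.eta[:, None] + self.gamma[None, :]

    def muAS(self):
        return self.nu[:, None] + self.kappa

    # Both components are fit to the full data grid, with no feedback from
    # the allocation z into the component updates (the cut construction the
    # original surveillance mixture relies on); z is then drawn from the
    # exact likelihood comparison of the two fitted components.  A genuine
    # feedback mixture traps the area-specific block in a prior-only random
    # walk for every unit currently allocated common, and the allocation
    # can then never discover unusual units.

    # -- common-block updates ------------------------------------------------

    def update_alpha0(self):
        lamC = self.E * np.exp(self.muC())
        d = self.steps["alpha0"] * self.rng.standard_normal()
        dll = d * self.Y.sum() - (np.expm1(d)) * lamC.sum()
        ok = np.log(self.rng.random()) < dll
        if ok:
            self.alpha0 += d
        self._tally("alpha0", int(ok), 1)

    def update_eta(self):
        muC = self.muC()
        rowY = np.sum(self.Y, axis=1)
        rowLam = np.sum(self.E * np.exp(muC), axis=1)
        d = self.steps["eta"] * self.rng.standard_normal(self.N)
        dll = d * rowY - np.expm1(d) * rowLam
        e_new = self.eta + d
        dpr = ((self.eta - self.v) ** 2 - (e_new - self.v) ** 2) / (
            2.0 * self.sigma2_eta)
        acc = np.log(self.rng.random(self.N)) < dll + dpr
        self.eta[acc] = e_new[acc]
        self._tally("eta", int(acc.sum()), self.N)

    def update_v(self):
        """Gaussian full conditional constrained to per-component sum zero."""
        P = self.W.laplacian() / self.sigma2_v
        P[np.diag_indices(self.N)] += 1.0 / self.sigma2_eta
        cf = linalg.cho_factor(P, lower=True)
        mean = linalg.cho_solve(cf, self.eta / self.sigma2_eta)
        noise = linalg.solve_triangular(cf[0], self.rng.standard_normal(self.N),
                                        trans="T", lower=True)
        x = mean + noise
        # conditioning by kriging onto {sum_component v = 0}
        labels = self.W.component_labels
        ncomp = int(labels.max()) + 1
        A = np.zeros((ncomp, self.N))
        A[labels, np.arange(self.N)] = 1.0
        PiAT = linalg.cho_solve(cf, A.T)
        corr = PiAT @ np.linalg.solve(A @ PiAT, A @ x)
        self.v = x - corr

    def update_gamma(self):
        muC = self.muC()
        colY = np.sum(self.Y, axis=0)
        colLam = np.sum(self.E * np.exp(muC), axis=0)
        for ts in self.t_colors:
            d = self.steps["gamma"] * self.rng.standard_normal(ts.size)
            g = self.gamma
            S = np.zeros(ts.size)
            left = ts - 1 >= 0
            S[left] += g[ts[left] - 1]
            right = ts + 1 < self.T
            S[right] += g[ts[right] + 1]
            g_new = g[ts] + d
            dpr = -(self.Qn[ts] * (g_new ** 2 - g[ts] ** 2) - 2.0 * S * d) / (
                2.0 * self.sigma2_gamma)
            dll = d * colY[ts] - np.expm1(d) * colLam[ts]
            acc = np.log(self.rng.random(ts.size)) < dll + dpr
            self.gamma[ts[acc]] = g_new[acc]
            self._tally("gamma", int(acc.sum()), ts.size)
        # recentre; the flat-prior intercept absorbs the level exactly
        m = self.gamma.mean()
        self.gamma -= m
        self.alpha0 += m

    # -- area-specific block ---------------------------------------------------

    def update_nu(self):
        muAS = self.muAS()
        rowY = np.sum(self.Y, axis=1)
        rowLam = np.sum(self.E * np.exp(muAS), axis=1)
        d = self.steps["nu"] * self.rng.standard_normal(self.N)
        n_new = self.nu + d
        dll = d * rowY - np.expm1(d) * rowLam
        dpr = (self.nu ** 2 - n_new ** 2) / (2.0 * NU_PRIOR_VAR)
        acc = np.log(self.rng.random(self.N)) < dll + dpr
        self.nu[acc] = n_new[acc]
        self._tally("nu", int(acc.sum()), self.N)

    def update_kappa(self):
        muAS = self.muAS()
        lamAS = self.E * np.exp(muAS)
        YAS = self.Y
        s2 = self.sigma2_kappa[:, None]
        for ts in self.t_colors:
            k = self.kappa
            d = self.steps["kappa"] * self.rng.standard_normal((self.N, ts.size))
            S = np.zeros((self.N, ts.size))
            left = ts - 1 >= 0
            S[:, left] += k[:, ts[left] - 1]
            right = ts + 1 < self.T
            S[:, right] += k[:, ts[right] + 1]
            k_new = k[:, ts] + d
            dpr = -(self.Qn[ts][None, :] * (k_new ** 2 - k[:, ts] ** 2)
                    - 2.0 * S * d) / (2.0 * s2)
            dll = d * YAS[:, ts] - np.expm1(d) * lamAS[:, ts]
            acc = np.log(self.rng.random((self.N, ts.size))) < dll + dpr
            cols = k[:, ts]
            cols[acc] = k_new[acc]
            self.kappa[:, ts] = cols
            self._tally("kappa", int(acc.sum()), acc.size)
        # recentre each row; the diffuse area intercept absorbs the level
        m = self.kappa.mean(axis=1)
        self.kappa -= m[:, None]
        self.nu += m

    # -- variance hyperparameters ---------------------------------------------

    def _logvar_rw(self, name, cur, loglik_fn, prior_fn):
        d = self.steps[name] * self.rng.standard_normal()
        new = cur * np.exp(d)
        ratio = (loglik_fn(new) + prior_fn(new) + np.log(new)
                 - loglik_fn(cur) - prior_fn(cur) - np.log(cur))
        ok = np.log(self.rng.random()) < ratio
        self._tally(name, int(ok), 1)
        return new if ok else cur

    def update_variances(self):
        sse = float(np.sum((self.eta - self.v) ** 2))
        self.sigma2_eta = self._logvar_rw(
            "sigma2_eta", self.sigma2_eta,
            lambda s2: -0.5 * self.N * np.log(s2) - sse / (2 * s2),
            lambda s2: _halfnorm_lp(s2, 1.0))
        qv = icar_quadform(self.v, self.W)
        rv = self.N - self.W.n_components
        self.sigma2_v = self._logvar_rw(
            "sigma2_v", self.sigma2_v,
            lambda s2: -0.5 * rv * np.log(s2) - qv / (2 * s2),
            lambda s2: _halfnorm_lp(s2, 1.0))
        qg = icar_quadform(self.gamma, self.Q)
        rg = self.T - self.Q.n_components
        self.sigma2_gamma = self._logvar_rw(
            "sigma2_gamma", self.sigma2_gamma,
            lambda s2: -0.5 * rg * np.log(s2) - qg / (2 * s2),
            lambda s2: _halfnorm_lp(s2, 1.0))

    def update_sigma2_kappa(self):
        qrow = np.sum(np.diff(self.kappa, axis=1) ** 2, axis=1)
        rk = self.T - 1
        cur = self.sigma2_kappa
        d = self.steps["sigma2_kappa"] * self.rng.standard_normal(self.N)
        new = cur * np.exp(d)

        def target(s2):
            icar = -0.5 * rk * np.log(s2) - qrow / (2 * s2)
            if self.model == "baseline":
                ls2 = np.log(s2)
                pr = (-ls2
                      - (ls2 - self.a_hyper) ** 2 / (2 * self.b_hyper ** 2))
            else:
                pr = _halfnorm_lp(s2, 1.0)
            return icar + pr + np.log(s2)  # includes the log-scale Jacobian

        acc = np.log(self.rng.random(self.N)) < target(new) - target(cur)
        self.sigma2_kappa = np.where(acc, new, cur)
        self._tally("sigma2_kappa", int(acc.sum()), self.N)

    def update_ab_hyper(self):
        ls2 = np.log(self.sigma2_kappa)
        prec = self.N / self.b_hyper ** 2 + 1.0 / A_PRIOR_VAR
        mean = (ls2.sum() / self.b_hyper ** 2) / prec
        self.a_hyper = mean + self.rng.standard_normal() / np.sqrt(prec)
        sse = float(np.sum((ls2 - self.a_hyper) ** 2))
        self.b_hyper = self._logvar_rw(
            "b_hyper", self.b_hyper,
            lambda b: -self.N * np.log(b) - sse / (2 * b * b),
            lambda b: _halfnorm_lp(b, B_HALFNORMAL_SCALE))

    # -- allocation -------------------------------------------------------------

    def _cell_ll(self, mu):
        return self.Y * mu - self.E * np.exp(mu)

    def update_z(self):
        llC = self._cell_ll(self.muC())
        llAS = self._cell_ll(self.muAS())
        if self.model == "baseline":
            p = z_full_conditional(llC.sum(axis=1), llAS.sum(axis=1),
                                   BASELINE_COMMON_PRIOR)
            self.z = (self.rng.random(self.N) < p).astype(np.int64)
        else:
            theta = (self.pi[:, None] + self.delta[None, :]
                     + logit(self.tau))
            log_odds = theta + (llC - llAS)
            p = expit(log_odds)
            self.z = (self.rng.random((self.N, self.T)) < p).astype(np.int64)

    # -- proposed-model allocation field ----------------------------------------

    def _bern_theta(self):
        return self.pi[:, None] + self.delta[None, :] + logit(self.tau)

    def update_pi(self):
        zf = self.z.astype(float)
        rowz = zf.sum(axis=1)
        for nodes in self.w_colors:
            theta = self._bern_theta()
            d = self.steps["pi"] * self.rng.standard_normal(nodes.size)
            th = theta[nodes, :]
            dll = (d * rowz[nodes]
                   - np.sum(_softplus(th + d[:, None]) - _softplus(th), axis=1))
            S = np.asarray(self.W_csr[nodes] @ self.pi).ravel()
            p_new = self.pi[nodes] + d
            dpr = -(self.Wn[nodes] * (p_new ** 2 - self.pi[nodes] ** 2)
                    - 2.0 * S * d) / (2.0 * self.sigma2_pi)
            acc = np.log(self.rng.random(nodes.size)) < dll + dpr
            self.pi[nodes[acc]] = p_new[acc]
            self._tally("pi", int(acc.sum()), nodes.size)
        # plain per-component recentring (BUGS car.normal convention)
        labels = self.W.component_labels
        for c in range(int(labels.max()) + 1):
            mask = labels == c
            self.pi[mask] -= self.pi[mask].mean()

    def update_delta(self):
        zf = self.z.astype(float)
        colz = zf.sum(axis=0)
        for ts in self.t_colors:
            theta = self._bern_theta()
            d = self.steps["delta"] * self.rng.standard_normal(ts.size)
            th = theta[:, ts]
            dll = (d * colz[ts]
                   - np.sum(_softplus(th + d[None, :]) - _softplus(th), axis=0))
            g = self.delta
            S = np.zeros(ts.size)
            left = ts - 1 >= 0
            S[left] += g[ts[left] - 1]
            right = ts + 1 < self.T
            S[right] += g[ts[right] + 1]
            d_new = g[ts] + d
            dpr = -(self.Qn[ts] * (d_new ** 2 - g[ts] ** 2) - 2.0 * S * d) / (
                2.0 * self.sigma2_delta)
            acc = np.log(self.rng.random(ts.size)) < dll + dpr
            self.delta[ts[acc]] = d_new[acc]
            self._tally("delta", int(acc.sum()), ts.size)
        self.delta -= self.delta.mean()

    def update_tau(self):
        lo, hi = TAU_BOUNDS
        ell = logit(self.tau)
        ell_new = ell + self.steps["tau"] * self.rng.standard_normal()
        tau_new = float(expit(ell_new))
        ok = False
        if lo < tau_new < hi:
            d = ell_new - ell
            theta = self._bern_theta()
            zf = self.z.astype(float)
            dll = (d * zf.sum()
                   - np.sum(_softplus(theta + d) - _softplus(theta)))
            # uniform prior on tau, sampled on the logit scale: Jacobian
            jac = (np.log(tau_new * (1 - tau_new))
                   - np.log(self.tau * (1 - self.tau)))
            ok = np.log(self.rng.random()) < dll + jac
            if ok:
                self.tau = tau_new
        self._tally("tau", int(ok), 1)

    def update_sigma2_mixing(self):
        qp = icar_quadform(self.pi, self.W)
        rp = self.N - self.W.n_components
        self.sigma2_pi = self._logvar_rw(
            "sigma2_pi", self.sigma2_pi,
            lambda s2: -0.5 * rp * np.log(s2) - qp / (2 * s2),
            lambda s2: _halfnorm_lp(s2, 1.0))
        qd = icar_quadform(self.delta, self.Q)
        rd = self.T - self.Q.n_components
        self.sigma2_delta = self._logvar_rw(
            "sigma2_delta", self.sigma2_delta,
            lambda s2: -0.5 * rd * np.log(s2) - qd / (2 * s2),
            lambda s2: _halfnorm_lp(s2, 1.0))

    # -- one full sweep -----------------------------------------------------------

    def sweep(self):
        self.update_alpha0()
        self.update_eta()
        self.update_v()
        self.update_gamma()
        self.update_nu()
        self.update_kappa()
        self.update_variances()
        self.update_sigma2_kappa()
        if self.model == "baseline":
            self.update_ab_hyper()
        else:
            self.update_pi()
            self.update_delta()
            self.update_tau()
            self.update_sigma2_mixing()
        self.update_z()


def run_mcmc(model: str, data: CountData, W: AdjacencyStructure,
             cfg: MCMCConfig, Q: AdjacencyStructure = None) -> PosteriorSamples:
    """Run the sampler for one model and return posterior summaries.

    ``model`` is "baseline" (per-area allocation, Bern(0.95) prior) or
    "proposed" (per-cell allocation with the hierarchical logit field).
    Each chain c is seeded with cfg.seed + c; identical seeds reproduce
    draws exactly.
    """
    if model not in ("baseline", "proposed"):
        raise ValueError(f"unknown model {model!r}")
    if data.n_times < 2:
        raise ValueError("need at least two time points")
    if W.n != data.n_areas:
        raise ValueError("spatial structure does not match the data")
    if Q is None:
        Q = temporal_path_adjacency(data.n_times)

    n_stored = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    monitored = ["alpha0", "sigma2_eta", "sigma2_v", "sigma2_gamma"]
    if model == "proposed":
        monitored.append("tau")

    draws = {k: np.empty((cfg.n_chains, n_stored)) for k in monitored}
    draws["gamma"] = np.empty((cfg.n_chains, n_stored, data.n_times))
    f_chains = []
    acc_all: dict[str, list] = {}

    for c in range(cfg.n_chains):
        chain = _ChainState(model, data, W, Q, cfg, seed=cfg.seed + c)
        f_sum = np.zeros_like(chain.z, dtype=float)
        stored = 0
        for it in range(cfg.n_iter):
            if it == cfg.burn_in:
                chain.counting = True
            chain.sweep()
            if (cfg.adapt and it < cfg.burn_in
                    and (it + 1) % _ADAPT_WINDOW == 0):
                chain.adapt_steps()
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                for k in monitored:
                    draws[k][c, stored] = getattr(chain, k)
                draws["gamma"][c, stored] = chain.gamma
                f_sum += chain.z
                stored += 1
        assert stored == n_stored
        f_chains.append(f_sum / n_stored)
        for k, (na, np_) in chain.acc.items():
            if np_ > 0:
                acc_all.setdefault(k, []).append(na / np_)

    f = np.mean(f_chains, axis=0)
    acc = {k: float(np.mean(v)) for k, v in acc_all.items()}
    return PosteriorSamples(draws=draws, f=f, acceptance_rates=acc,
                            model=model, n_stored=n_stored, config=cfg)
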