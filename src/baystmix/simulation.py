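"""Synthetic surveillance data with injected unusual area/time behaviour.

Datasets are generated from the common model (a BYM spatial surface plus
one RW1 national trend), representing a disease under normal conditions;
a chosen set of unusual areas then receives log-risk departures from the
national trend at known time points, giving ground truth for evaluating
detection.  Ten study scenarios cross the spatial configuration of the
unusual areas (isolated vs clustered), the temporal shape of the departure
(isolated spikes, consecutive-variable, consecutive-stable), series length,
the magnitude of the expected counts, and a no-aberration null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graphs import AdjacencyStructure, sum_to_zero
from .model_core import CommonParams, CountData, common_linpred

# Default common-surface hyperparameters.  The study that motivated these
# scenarios seeded its generator with posterior estimates from a real
# hospital-admissions analysis; these synthetic stand-ins give a smooth
# spatial surface and a visible but moderate national trend, and every one
# of them can be overridden through ScenarioSpec / function arguments.
DEFAULT_HYPER = {
    "alpha0": 0.0,
    "sigma2_v": 0.1,      # structured spatial variability
    "sigma2_eta": 0.01,   # unstructured spatial noise
    "sigma2_gamma": 0.05, # RW1 increment variance of the national trend
}

#: scenario id -> (spatial pattern, temporal pattern, T, expected-count scale)
SCENARIO_TABLE = {
    "S1": ("isolated", "isolated", 15, 1.0),
    "S2": ("isolated", "consecutive_variable", 15, 1.0),
    "S3": ("isolated", "consecutive_stable", 15, 1.0),
    "S4": ("clustered", "isolated", 15, 1.0),
    "S5": ("clustered", "consecutive_variable", 15, 1.0),
    "S6": ("clustered", "consecutive_stable", 15, 1.0),
    "S7": ("isolated", "consecutive_variable", 30, 1.0),   # long time series
    "S8": ("isolated", "consecutive_variable", 15, 2.0),   # increased E
    "S9": ("isolated", "consecutive_variable", 15, 0.5),   # reduced E
    "S10": ("none", "none", 15, 1.0),                      # no aberrations
}


@dataclass
class ScenarioSpec:
    """Full description of one simulation scenario."""

    id: str
    spatial_pattern: str
    temporal_pattern: str
    T: int = 15
    n_unusual_areas: int = 15
    expected_scale: float = 1.0
    n_sims: int = 50
    seed: int = 0
    departure_magnitude: float = 0.4
    cluster_size: int = 5
    hyper: dict = field(default_factory=lambda: dict(DEFAULT_HYPER))

    def __post_init__(self):
        if self.expected_scale <= 0:
            raise ValueError("expected_scale must be positive")
        if self.id == "S10" and self.n_unusual_areas != 0:
            raise ValueError("the no-aberration scenario injects nothing")


def scenario_spec(scenario_id: str, *, n_unusual_areas: int = None,
                  n_sims: int = 50, seed: int = 0,
                  departure_magnitude: float = 0.4, T: int = None,
                  cluster_size: int = 5, hyper: dict = None) -> ScenarioSpec:
    """Build the spec for one of the named scenarios S1..S10."""
    if scenario_id not in SCENARIO_TABLE:
        raise ValueError(f"unknown scenario {scenario_id!r}")
    spat, temp, T_default, scale = SCENARIO_TABLE[scenario_id]
    if n_unusual_areas is None:
        n_unusual_areas = 0 if scenario_id == "S10" else 15
    return ScenarioSpec(
        id=scenario_id, spatial_pattern=spat, temporal_pattern=temp,
        T=T if T is not None else T_default,
        n_unusual_areas=n_unusual_areas, expected_scale=scale,
        n_sims=n_sims, seed=seed, departure_magnitude=departure_magnitude,
        cluster_size=cluster_size,
        hyper=dict(hyper) if hyper is not None else dict(DEFAULT_HYPER),
    )


@dataclass
class SimulatedDataset:
    """Generated counts plus the injected ground truth."""

    data: CountData
    z_true: np.ndarray           # N x T, 0 exactly at injected cells
    unusual_areas: np.ndarray
    unusual_times: dict          # area index -> affected time indices
    generator_params: CommonParams
    log_risk: np.ndarray = None  # injected log relative-risk surface
    spec: ScenarioSpec = None

    @property
    def truth_unusual(self) -> np.ndarray:
        """Boolean N x T matrix marking injected (unusual) cells."""
        return self.z_true == 0


def default_expected_counts(n_areas: int, T: int, rng,
                            median: float = 100.0,
                            log_sd: float = 0.5) -> np.ndarray:
    """Area-level exposures, constant over time, lognormal across areas."""
    rng = np.random.default_rng(rng)
    e_area = np.exp(np.log(median) + log_sd * rng.standard_normal(n_areas))
    return np.tile(e_area[:, None], (1, T))


def _icar_draw(A: AdjacencyStructure, sigma2: float, rng) -> np.ndarray:
    """Exact ICAR draw on the per-component sum-to-zero subspace.

    Sampled in the eigenbasis of the graph Laplacian: mode k with
    eigenvalue lam_k > 0 gets variance sigma2 / lam_k; null modes
    (component constants) are fixed at zero.
    """
    if sigma2 == 0:
        return np.zeros(A.n)
    lam, vec = np.linalg.eigh(A.laplacian())
    pos = lam > 1e-9 * max(1.0, lam.max())
    coefs = rng.standard_normal(pos.sum()) * np.sqrt(sigma2 / lam[pos])
    return sum_to_zero(vec[:, pos] @ coefs, A)


def generate_common_surface(W: AdjacencyStructure, T: int, hyper: dict = None,
                            rng=None) -> CommonParams:
    """Draw the common-model parameters: v ~ ICAR, eta ~ N(v, s2), gamma ~ RW1."""
    if T < 2:
        raise ValueError("need at least two time points")
    rng = np.random.default_rng(rng)
    h = dict(DEFAULT_HYPER)
    if hyper:
        h.update(hyper)
    v = _icar_draw(W, h["sigma2_v"], rng)
    eta = v + np.sqrt(h["sigma2_eta"]) * rng.standard_normal(W.n)
    incr = np.sqrt(h["sigma2_gamma"]) * rng.standard_normal(T - 1)
    gamma = np.concatenate([[0.0], np.cumsum(incr)])
    gamma -= gamma.mean()
    return CommonParams(alpha0=h["alpha0"], eta=eta, v=v, gamma=gamma,
                        sigma2_eta=h["sigma2_eta"], sigma2_v=h["sigma2_v"],
                        sigma2_gamma=h["sigma2_gamma"])


def select_unusual_areas(W: AdjacencyStructure, n: int, pattern: str, rng,
                         cluster_size: int = 5, strata=None,
                         max_tries: int = 500) -> np.ndarray:
    """Choose which areas carry the injected unusual trend.

    ``isolated`` returns n pairwise non-adjacent areas; ``clustered``
    returns disjoint connected clusters (default target size 5) totalling
    n areas, mutually non-adjacent so each cluster is a separate pocket.
    Optional ``strata`` (per-area labels, e.g. exposure tertiles) makes the
    isolated selection cycle through strata so detectability is not
    confounded with expected-count magnitude.
    """
    rng = np.random.default_rng(rng)
    if n > W.n:
        raise ValueError("cannot select more areas than exist")
    nbrs = {i: set() for i in range(W.n)}
    for i, j in W.edges:
        nbrs[i].add(j)
        nbrs[j].add(i)

    if pattern == "isolated":
        for _ in range(max_tries):
            chosen: list[int] = []
            blocked: set[int] = set()
            if strata is not None:
                labels = np.asarray(strata)
                groups = [list(rng.permutation(np.flatnonzero(labels == g)))
                          for g in np.unique(labels)]
                order = []
                while any(groups):
                    for g in groups:
                        if g:
                            order.append(int(g.pop()))
            else:
                order = list(rng.permutation(W.n))
            for cand in order:
                if cand in blocked:
                    continue
                chosen.append(int(cand))
                blocked.add(cand)
                blocked |= nbrs[cand]
                if len(chosen) == n:
                    return np.array(sorted(chosen), dtype=np.int64)
        raise ValueError(f"no independent set of size {n} found "
                         f"in {max_tries} attempts")

    if pattern == "clustered":
        n_clusters = max(1, round(n / cluster_size))
        sizes = [n // n_clusters + (1 if r < n % n_clusters else 0)
                 for r in range(n_clusters)]
        for _ in range(max_tries):
            used: set[int] = set()
            forbidden: set[int] = set()
            clusters: list[list[int]] = []
            ok = True
            for size in sizes:
                seeds = [s for s in rng.permutation(W.n)
                         if s not in used and s not in forbidden]
                grown = None
                for seed_node in seeds[:25]:
                    # breadth-first growth inside allowed nodes
                    cluster = [int(seed_node)]
                    frontier = [int(seed_node)]
                    avoid = used | forbidden
                    while len(cluster) < size and frontier:
                        nxt = sorted({j for u in frontier for j in nbrs[u]}
                                     - set(cluster) - avoid)
                        if not nxt:
                            break
                        take = list(rng.permutation(nxt))[:size - len(cluster)]
                        cluster.extend(int(t) for t in take)
                        frontier = take
                    if len(cluster) == size:
                        grown = cluster
                        break
                if grown is None:
                    ok = False
                    break
                clusters.append(grown)
                used |= set(grown)
                forbidden |= {j for u in grown for j in nbrs[u]}
            if ok:
                flat = sorted(i for cl in clusters for i in cl)
                return np.array(flat, dtype=np.int64)
        raise ValueError(f"could not place {n_clusters} disjoint clusters "
                         f"totalling {n} areas in {max_tries} attempts")

    raise ValueError(f"unknown spatial pattern {pattern!r}")


def make_unusual_trend(pattern: str, T: int, magnitude: float,
                       rng) -> tuple[np.ndarray, np.ndarray]:
    """Log-risk departure profile for one unusual area.

    Returns (departures, affected_times).  ``isolated``: two +-magnitude
    spikes at non-adjacent time points; ``consecutive_variable``: a
    contiguous window of length ceil(T/3) with alternating-sign departures
    of size ~magnitude; ``consecutive_stable``: the same window with a
    constant +magnitude shift.  The affected set is returned even when
    magnitude is 0 (used for power-vs-magnitude curves).
    """
    if T < 4:
        raise ValueError("temporal departure patterns need T >= 4")
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    rng = np.random.default_rng(rng)
    dep = np.zeros(T)

    if pattern == "isolated":
        while True:
            times = np.sort(rng.choice(T, size=2, replace=False))
            if times[1] - times[0] > 1:
                break
        signs = rng.choice([-1.0, 1.0], size=2)
        dep[times] = signs * magnitude
        return dep, times

    window = int(np.ceil(T / 3))
    start = int(rng.integers(0, T - window + 1))
    times = np.arange(start, start + window)
    if pattern == "consecutive_variable":
        alt = np.where(np.arange(window) % 2 == 0, 1.0, -1.0)
        if rng.random() < 0.5:
            alt = -alt
        dep[times] = alt * magnitude * rng.uniform(0.75, 1.25, size=window)
    elif pattern == "consecutive_stable":
        dep[times] = magnitude
    else:
        raise ValueError(f"unknown temporal pattern {pattern!r}")
    return dep, times


def simulate_scenario(spec: ScenarioSpec, W: AdjacencyStructure,
                      E_base: np.ndarray, strata=None) -> SimulatedDataset:
    """Generate one dataset under a scenario with known ground truth."""
    E_base = np.asarray(E_base, dtype=float)
    if E_base.shape != (W.n, spec.T):
        raise ValueError(f"E_base must be {W.n} x {spec.T}")
    rng = np.random.default_rng(spec.seed)
    surface = generate_common_surface(W, spec.T, spec.hyper, rng)
    log_mu = common_linpred(surface)
    z_true = np.ones((W.n, spec.T), dtype=np.int64)
    unusual_times: dict[int, np.ndarray] = {}
    if spec.n_unusual_areas > 0:
        areas = select_unusual_areas(W, spec.n_unusual_areas,
                                     spec.spatial_pattern, rng,
                                     cluster_size=spec.cluster_size,
                                     strata=strata)
        for i in areas:
            dep, times = make_unusual_trend(spec.temporal_pattern, spec.T,
                                            spec.departure_magnitude, rng)
            log_mu[i] = log_mu[i] + dep
            z_true[i, times] = 0
            unusual_times[int(i)] = times
    else:
        areas = np.array([], dtype=np.int64)
    E = spec.expected_scale * E_base
    Y = rng.poisson(np.exp(log_mu) * E)
    return SimulatedDataset(data=CountData(Y=Y, E=E), z_true=z_true,
                            unusual_areas=areas, unusual_times=unusual_times,
                            generator_params=surface, log_risk=log_mu,
                            spec=spec)


def batch_simulate(spec: ScenarioSpec, W: AdjacencyStructure,
                   E_base: np.ndarray, strata=None) -> list[SimulatedDataset]:
    """Independent replicates; replicate r uses seed spec.seed + r."""
    if spec.n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    return [simulate_scenario(replace(spec, seed=spec.seed + r), W, E_base,
                              strata=strata)
            for r in range(spec.n_sims)]
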