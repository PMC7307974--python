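"""Reproducible scaled-down replications of the simulation study.

The full study design (211 areas, 50 replicates, 80 000-iteration chains)
is a multi-day batch job; these helpers run the same pipeline — generate a
scenario, fit both models, classify, score — at study sizes chosen to
finish in minutes: a 10 x 10 lattice with 9 unusual areas (three clusters
of three in the clustered scenarios, preserving the under-10% unusual
fraction the proposed model's allocation prior assumes), a handful of
replicates, and chains of a few thousand sweeps.  docs/methods.md
discusses what these scaled runs can and cannot show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import bayesian_fdr_classify, fixed_threshold_classify
from .evaluation import (MetricsReport, confusion, metrics,
                         no_aberration_summary, summarize_replicates)
from .graphs import lattice_adjacency
from .inference import MCMCConfig, run_mcmc
from .simulation import default_expected_counts, scenario_spec, simulate_scenario


@dataclass
class StudyConfig:
    """Problem sizes for a scaled scenario study."""

    rows: int = 10
    cols: int = 10
    n_unusual: int = 9
    cluster_size: int = 3
    n_replicates: int = 4
    n_iter: int = 2500
    burn_in: int = 1250
    n_chains: int = 1
    seed: int = 0
    e_median: float = 100.0
    departure_magnitude: float = 0.4
    scenario_overrides: dict = field(default_factory=dict)


@dataclass
class ScenarioStudyResult:
    """Per-model summaries for one scenario."""

    scenario: str
    summary: dict                 # model -> MetricsReport (replicate summary)
    replicates: dict              # model -> list[MetricsReport]
    n_replicates: int


@dataclass
class NullStudyResult:
    """No-aberration (null) scenario summaries."""

    proportion_with_any: dict     # model -> fraction of replicates flagging
    mean_count_among_positive: dict
    n_replicates: int


def _fit_and_classify(model: str, sim, W, cfg: MCMCConfig):
    post = run_mcmc(model, sim.data, W, cfg)
    if model == "baseline":
        det = bayesian_fdr_classify(post.f, alpha=0.05)
    else:
        det = fixed_threshold_classify(post.f, level=0.05)
    return det


def run_scenario_study(scenario_id: str, study: StudyConfig,
                       models=("baseline", "proposed")) -> ScenarioStudyResult:
    """Replicate one non-null scenario and summarise both models' metrics."""
    W = lattice_adjacency(study.rows, study.cols)
    spec0 = scenario_spec(scenario_id, n_unusual_areas=study.n_unusual,
                          seed=study.seed,
                          departure_magnitude=study.departure_magnitude,
                          cluster_size=study.cluster_size,
                          **study.scenario_overrides)
    E_base = default_expected_counts(W.n, spec0.T,
                                     np.random.default_rng(study.seed),
                                     median=study.e_median)
    reps: dict[str, list[MetricsReport]] = {m: [] for m in models}
    for r in range(study.n_replicates):
        spec = scenario_spec(scenario_id, n_unusual_areas=study.n_unusual,
                             seed=study.seed + 1 + r,
                             departure_magnitude=study.departure_magnitude,
                             cluster_size=study.cluster_size,
                             **study.scenario_overrides)
        sim = simulate_scenario(spec, W, E_base)
        cfg = MCMCConfig(n_iter=study.n_iter, burn_in=study.burn_in, thin=1,
                         n_chains=study.n_chains,
                         seed=study.seed + 101 * (r + 1))
        for model in models:
            det = _fit_and_classify(model, sim, W, cfg)
            unit = "area" if model == "baseline" else "area_time"
            reps[model].append(metrics(confusion(det.flags, sim.truth_unusual,
                                                 unit=unit)))
    summary = {m: summarize_replicates(v) for m, v in reps.items()}
    return ScenarioStudyResult(scenario=scenario_id, summary=summary,
                               replicates=reps,
                               n_replicates=study.n_replicates)


def run_null_study(study: StudyConfig,
                   models=("baseline", "proposed")) -> NullStudyResult:
    """Replicate the no-aberration scenario and summarise false alarms."""
    W = lattice_adjacency(study.rows, study.cols)
    spec0 = scenario_spec("S10", seed=study.seed)
    E_base = default_expected_counts(W.n, spec0.T,
                                     np.random.default_rng(study.seed),
                                     median=study.e_median)
    dets: dict[str, list] = {m: [] for m in models}
    for r in range(study.n_replicates):
        spec = scenario_spec("S10", seed=study.seed + 1 + r)
        sim = simulate_scenario(spec, W, E_base)
        cfg = MCMCConfig(n_iter=study.n_iter, burn_in=study.burn_in, thin=1,
                         n_chains=study.n_chains,
                         seed=study.seed + 101 * (r + 1))
        for model in models:
            dets[model].append(_fit_and_classify(model, sim, W, cfg))
    props, means = {}, {}
    for model in models:
        props[model], means[model] = no_aberration_summary(dets[model])
    return NullStudyResult(proportion_with_any=props,
                           mean_count_among_positive=means,
                           n_replicates=study.n_replicates)


def prior_unusual_proportion(n_draws: int = 100_000, seed: int = 0,
                             prior_common: float = 0.95) -> float:
    """Monte-Carlo prior expected proportion of unusual areas.

    Under the baseline allocation prior z_i ~ Bern(0.95) the expected
    unusual proportion is 5%; this simulates it directly.
    """
    rng = np.random.default_rng(seed)
    z = rng.random(n_draws) < prior_common
    return float(np.mean(~z))
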