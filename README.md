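# baystmix

Bayesian spatio-temporal mixture models for detecting unusual small-area
disease trends.

## The problem

Routine public-health surveillance watches counts of an outcome (deaths,
hospitalisations, accidents) across many small areas over time. Most
areas follow the national trend; a few depart from it — because of a
local exposure, a data problem, or a change in service provision — and
those are the ones an analyst needs to see. The difficulty is
separating a genuinely *unusual trend* from an area that is simply at a
high but stable level, and doing it with the small, noisy counts typical
of small-area data.

`baystmix` implements two Bayesian mixture models for this task. Both
model counts as

```
Y_it ~ Poisson(mu_it * E_it)
```

with known expected counts `E_it`, and let each unit switch between a
**common component** (shared spatial field + national temporal trend;
BYM spatial model, random-walk trend) and an **area-specific component**
(free intercept and random-walk trend per area). The posterior
probability `f` of belonging to the common component is the detection
statistic.

- **baseline model** — one allocation per area (`z_i ~ Bernoulli(0.95)`),
  areas flagged by a Bayesian false-discovery-rate rule on `f_i`.
- **proposed model** — one allocation per area-time cell, with a
  structured space–time prior on the mixing probability and a
  `tau ~ Uniform(0.9, 1)` global level encoding that unusual cells are
  rare; cells flagged when `f_it < 0.05`. This variant localises *when*
  an area departed and false-alarms far less often.

Both components are always fit to the full data and the allocation is
drawn from an exact likelihood comparison (a "cut" that prevents
feedback from the classifier into the fitted components); see
[docs/methods.md](docs/methods.md) for the model, sampler and rationale.

## Worked example

Simulate a 6 × 6 lattice with 4 unusual areas whose trend departs for a
window of consecutive periods (scenario S2), fit both models, and flag:

```python
import numpy as np
from baystmix import (lattice_adjacency, scenario_spec, simulate_scenario,
                      default_expected_counts, MCMCConfig, run_mcmc,
                      bayesian_fdr_classify, fixed_threshold_classify,
                      confusion, metrics)

W = lattice_adjacency(6, 6)
spec = scenario_spec("S2", seed=3, n_unusual_areas=4)
E = default_expected_counts(W.n, spec.T, 3)
sim = simulate_scenario(spec, W, E)
print("unusual areas:", sorted(int(i) for i in sim.unusual_areas))

cfg = MCMCConfig(n_iter=4000, burn_in=2000, thin=1, n_chains=2, seed=10)

post = run_mcmc("proposed", sim.data, W, cfg)      # f is N x T
det = fixed_threshold_classify(post.f, level=0.05)
rep = metrics(confusion(det.flags, sim.truth_unusual, unit="area_time"))
print(f"proposed: {det.n_flagged} cells flagged | "
      f"sensitivity {rep.sensitivity:.2f} | fp proportion {rep.fp_proportion:.2f}")
print("areas containing flagged cells:",
      sorted(set(np.where(det.flags)[0].tolist())))

postb = run_mcmc("baseline", sim.data, W, cfg)     # f is length N
detb = bayesian_fdr_classify(postb.f, alpha=0.05)
repb = metrics(confusion(detb.flags, sim.truth_unusual, unit="area"))
print(f"baseline: {detb.n_flagged} areas flagged | "
      f"sensitivity {repb.sensitivity:.2f} | fp proportion {repb.fp_proportion:.2f}")
print("flagged areas:", sorted(np.where(detb.flags)[0].tolist()))
```

Output (about 30 seconds on one CPU):

```
unusual areas: [2, 6, 19, 27]
proposed: 10 cells flagged | sensitivity 0.50 | fp proportion 0.00
areas containing flagged cells: [2, 6, 19, 27]
baseline: 4 areas flagged | sensitivity 1.00 | fp proportion 0.00
flagged areas: [2, 6, 19, 27]
```

Both models recover exactly the four injected areas with no false
positives; the proposed model additionally localises the affected cells
(its cell-level sensitivity of 0.50 reflects that it flags the clearest
periods inside each departure window).

## Command-line interface

The same pipeline is available as a CLI (`baystmix` or
`python -m baystmix.cli`):

```bash
baystmix simulate --scenario S2 --areas 10x10 --unusual 9 --seed 1 --out run/sim
baystmix fit      --counts run/sim/counts.csv --model proposed \
                  --iters 10000 --burnin 5000 --seed 1 --out run/fit
baystmix detect   --allocation run/fit/allocation.csv --rule fixed --out run/det
baystmix evaluate --detections run/det/detections.csv \
                  --truth run/sim/truth.csv --out run/eval
```

Every subcommand writes a JSON metadata file recording the seed and
settings, and re-running with identical inputs reproduces outputs
bit-for-bit. Real study regions can be supplied as a GAL neighbour list
(`--gal`), and counts as tidy CSV with columns
`area,time,count,expected`. For road-accident applications,
`aggregate_exposure` turns road-segment records (length × annual average
daily flow) into district-level traffic-volume offsets.

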