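# polyspread

Discrete-time stochastic and deterministic modelling of an arbitrary number
of contagions — pathogens, rumors, innovations — spreading *concurrently*
on networks, including multiplex (multi-layer) networks.

## The model

Every node of a simple undirected graph holds one of *m* states. Each
synchronous time step a node in state *k* can change state through two
mechanisms:

1. **Spontaneous transition** — a loaded dice: move to state *l* with
   probability δ_kl (the diagonal δ_kk = 1 − Σ_{l≠k} δ_kl is "stay put").
2. **Contact-induced transition** (a *reactive process*) — if the dice did
   not move the node, every neighbor attempts one transmission over its
   link: a neighbor in state *l* succeeds with probability γ_kl. If several
   links are infectious in the same step, the node picks **one uniformly at
   random**; the stimulation tensor θ^k_rl (0/1, one target per exposure)
   maps the transmitted state *r* to the adopted state *l* — identity for
   plain infection, non-identity for social mechanisms such as a rumor
   spreader who turns stifler upon meeting another spreader.

Keeping the time step finite means *several contagions can reach a node at
once* and must compete. The probability that state *l* wins the uniform
choice, given n_r neighbors per state, is

    q_l = E[ s_l / S ; S > 0 ],   s_r ~ Binomial(n_r, γ_kr),  S = Σ_r s_r,

with no-adoption probability h = Π_r (1 − γ_kr)^{n_r}. The package computes
q exactly (2^n event enumeration, and an independent exact polynomial-
integral backend that scales to any degree) and through the tractable
closed-form approximation

    q*_l = ( n_l γ_kl / Σ_r n_r γ_kr ) · ( 1 − Π_r (1 − γ_kr)^{n_r} ),

which is exact when only one state is transmissible, when all γ are equal,
and for degree ≤ 1, and stays within ~0.02 of the exact value for moderate
transmission probabilities.

On top of the per-node adoption probabilities the package provides

* a seeded synchronous **stochastic simulator** (single runs, ensembles,
  snapshots),
* the **deterministic discrete-time solver** (NLDS) evolving per-node
  probability vectors with exact or approximate adoption backends, plus
  fixed-point iteration,
* the **continuous-time ODE counterpart** (rate-form parameters, fixed-step
  RK4) and the homogeneous mean-field Maki–Thompson reduction,
* a **model zoo**: SIS, SIR, SIRS, Maki–Thompson with forgetting,
  two-contagion SIS-type competition (spontaneous or contact-only
  recovery), a three-innovation cycle model, and the two-layer multiplex
  competition variant — all expressed as (Γ, Δ, Θ) triples for the one
  generic engine,
* graph generators (complete, star, ring, periodic 2-D lattice),
  plain-text edge-list I/O and desk-scale replications of the
  approximation-accuracy experiments.

## Worked example

Competition of two contagions (β₁ = 0.5, β₂ = 0.35, both recovering with
probability 0.2/0.15) on a 6-node star, deterministic solver vs a
stochastic run:

```python
import numpy as np
from polyspread import make_graph, preset_SI1I2S, deterministic, stochastic

g = make_graph("star", 6)
spec = preset_SI1I2S(0.5, 0.35, 0.2, 0.15)

P0 = deterministic.field_from_assignment([0, 1, 2, 0, 1, 2], 3)
report = deterministic.iterate_to_fixed_point(P0, spec, g, backend="exact")
print(report.converged, report.iterations)
print(np.round(report.fractions, 6))
```

prints

```
True 1778
[0.305929 0.694071 0.      ]
```

— the weaker contagion is driven out entirely (winner-takes-all), the
stronger one settles at ≈ 69 % prevalence. The same model through the CLI:

```sh
polyspread solve --generator star:6 --preset SI1I2S --params 0.5,0.35,0.2,0.15 \
    --init random:1 --backend approx --fixed-point
polyspread simulate --generator star:6 --preset SI1I2S \
    --params 0.5,0.35,0.2,0.15 --steps 25 --runs 200 --seed 1
```

(`scan`, `compare`, `ode` and `fixtures` subcommands expose the remaining
experiments; every command writes CSV.)

## The acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch — the approx-vs-exact fixed-point errors of the competition scans
on the small benchmark graphs, the 200-run ensemble of the oscillatory
three-innovation model on a 32×32 periodic lattice against the
deterministic solver, the first-order discrete→continuous consistency fit,
and a seeded stochastic trajectory — printing each measured quantity and
writing the collected results as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model, the approximation and its measured
accuracy envelope, the numerical choices (backends, guards, tolerances,
RNG discipline), and the known limitations — in particular where and why
the deterministic solver's independence assumption biases it away from
ensemble averages on small or locally clustered graphs.
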