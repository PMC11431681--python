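# natind

Simulation toolkit for **adaptation by natural induction**: networks of
masses joined by viscoelastic (Maxwell) springs in which ordinary physical
relaxation performs optimisation and the slow creep of spring natural
lengths performs unsupervised learning.  When such a network is subjected to
occasional random disturbances of its state, the two processes feed back on
each other and the system spontaneously discovers configurations of
exceptionally low energy — including solutions to externally imposed
continuous problems and spin-glass/MaxCut instances.  The package is aimed
at researchers studying self-modelling dynamical systems, physical learning,
and energy-landscape views of adaptation.

## The model

Masses live in the 2D plane; a spring set S defines the potential

    V = Σ_(ij∈S) ½ k (r_ij − l_ij)²

where `r_ij` is the pair distance and `l_ij` the natural length.  Positions
follow the overdamped gradient flow `ẋ_i = −(1/γ) ∂V/∂x_i` (optimisation:
the state relaxes to the parameters).  Plastic springs are Maxwell elements
whose natural lengths creep as

    l̇_ij = (k/γ_m)(r_ij − l_ij)  ≡  −(1/γ_m) ∂V/∂l_ij

(learning: the parameters relax to the state).  With creep far slower than
settling (γ_m ≫ γ), the creep is applied once per visited equilibrium,
`l ← l + η (r_eq − l)`.  Periodic disturbances redraw the positions at
random, so the plastic springs average an associative model of the local
optima the system visits; the remodelled landscape then biases which optima
are visited next.  The headline measurement is the **STD score**: how many
baseline standard deviations (on log energies) the learned system's best
configuration lies below the mean of equilibria found without learning
under identical disturbances.

Three protocols are provided: a memory-formation experiment (creep at a
single held equilibrium enlarges its attractor basin), Scenario 1
(an all-plastic network that gets better at minimising its own original
energy function, read out through a resettle assay), and Scenario 2
(elastic "problem" P-springs plus a weak, dense, plastic "learning"
L-layer, with a final settling phase in which the L-springs melt away —
over continuous states, or over binary spins via a bistable mechanical
embedding of ±J couplings scored as MaxCut energies).  See
`docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Memory formation in a small all-plastic network (N=15, 90% connectivity,
l₀=10, k=10):

```python
import numpy as np
from natind import (SimulationConfig, cluster_attractors,
                    generate_random_network, run_memory_experiment)

net = generate_random_network(15, 0.9, natural_length=10.0, stiffness=10.0,
                              plastic=True, seed=7)
cfg = SimulationConfig(seed=7)
res = run_memory_experiment(net, cfg, n_samples=500)
baseline = cluster_attractors(res.baseline_records)
post = cluster_attractors(res.post_records)
print(f"baseline attractors visited: {baseline.n_clusters}")
print(f"post-creep attractors visited: {post.n_clusters}")
print(f"held-state energy after creep: {res.held_record.energy_current:.3f}")
print(f"fraction converging to the held state: {res.convergence_fraction:.3f}")
```

prints

```
baseline attractors visited: 498
post-creep attractors visited: 19
held-state energy after creep: 0.490
fraction converging to the held state: 0.812
```

Before creep, 500 random initial conditions settle into essentially 500
distinct equilibria.  After resting at one (arbitrary) equilibrium while the
springs deform, that configuration's energy has collapsed toward zero and
81% of the same initial conditions now fall into its basin — the network
has memorised a state of its own dynamics.

The same works from the shell.  A short self-adaptation run on a 40-mass
network:

```
$ natind s1 --seed 11 --resets 60 --eta 0.05 --config cfg.json --out demo
```

with `cfg.json` containing `{"network": {"n": 40, "connect_prob": 0.5}}`
writes a per-reset CSV trace, initial/final spring edge lists, and a JSON
summary including

```
"std_score": 2.93,
"min_energy_original": 16321.3,
"baseline_min": 16536.4
```

i.e. after 60 disturbances the learned springs steer the system to a
configuration whose energy *under the original springs* (16321.3) is below
the best of 60 baseline samples from identical disturbances, 2.9 baseline
log-STDs below the baseline mean.  Subcommands `memory`, `s1`, `s2a`, `s2b`
and `assay` cover all protocols; `--seed`, `--resets`, `--eta`, `--out` and
`--quiet` override the config file.

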