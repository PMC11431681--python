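# Methods

## The physical model

`natind` simulates networks of point masses confined to the 2D plane and
joined by Hookean springs.  A spring between masses *i* and *j* with
stiffness *k* and natural length *l·ᵢⱼ* stores elastic energy

    V = Σ_(ij∈S) ½ k (r_ij − l_ij)²,        r_ij = |x_i − x_j|.

Two processes act on this single potential:

* **State relaxation (optimisation).**  In the overdamped regime the
  positions follow the gradient flow ẋᵢ = Fᵢ/γ with Fᵢ = −∂V/∂xᵢ, where γ
  is a global damping (mobility) constant.  Relaxation terminates at a local
  minimum of V — a locally optimal resolution of the frustrated pairwise
  constraints.
* **Viscoelastic creep (learning).**  Springs flagged *plastic* are Maxwell
  elements: an ideal spring in series with a damper γ_m.  Their natural
  length deforms as l̇_ij = (k/γ_m)(r_ij − l_ij), which is exactly
  −∂V/∂l_ij up to the 1/γ_m mobility — the parameters descend the *same*
  energy that the state descends.  Under tension a spring lengthens, under
  compression it shortens, and a held configuration is slowly "memorised".

With γ_m ≫ γ the creep during settling transients is negligible, so the
package applies the creep in discrete per-equilibrium form: after each
settle, every plastic spring takes one step l ← l + η (r_eq − l).  The
learning rate η ∈ [0, 1] is the dimensionless surrogate for k·Δt/γ_m over
one inter-disturbance interval; η = 0 disables learning (control runs) and
η = 1 accommodates completely in one visit.

The third ingredient is the **disturbance**: at regular intervals all mobile
positions are redrawn i.i.d. uniform in a box (spring parameters untouched).
The system then samples many local optima, the creeping springs average the
visited equilibria into an associative model of them, the remodelled
landscape biases which optima are visited next, and this positive feedback
makes the network visit configurations of increasingly exceptional quality.

## Integration scheme

Settling uses an adaptive explicit Euler on the first-order flow:

* the step ceiling defaults to 4γ / maxᵢ Σ k(incident), a Gershgorin-style
  stability estimate that adapts automatically from stiff dense nets to soft
  two-layer nets (an explicit `step_size` overrides it);
* a **Lyapunov guard**: any trial step that would raise V beyond a 1e−12
  relative slack is retried at half the step; after an accepted step the
  step grows by 2% back toward the ceiling.  Energy is therefore
  non-increasing along every accepted trajectory, by construction;
* a **displacement cap** (0.05·l̄ per step by default) keeps the discrete
  path close to the continuous flow when forces are large immediately after
  a disturbance — basin identity depends on the path, not merely on
  descending;
* equilibrium is declared when the largest per-mass net force drops below
  `equilibrium_tolerance` (default 1e−6·k̄·l̄); exhausting the step budget is
  recorded on the result as `converged=False`, not raised;
* a vanishing pair distance (probability-zero geometry) is clamped to 1e−9
  with a fixed unit direction.

These choices trade a second energy evaluation per step for an enforced
descent property; the two-body closed form l + (r₀−l)·e^(−2kt/γ) is
reproduced to 1e−4 and is the engine's single-spring oracle.

## Scenarios

**Memory formation** (N=15, connectivity 0.9, l₀=10, k=10, all plastic).
Settle from M random initial conditions; hold the first equilibrium sampled
while creep runs to near-completion (alternating creep steps and
re-settling until the maximum plastic stress falls below 1% of its initial
value); re-settle the same M initial conditions.  Configurations are
compared by their vectors of pairwise distances (rigid-motion- and
reflection-invariant) at 1% relative tolerance.  Creep both lowers the
held state's energy (to ~0, since every spring accommodates) and enlarges
its attractor basin; under pure first-order gradient flow the enlarged
basin captures most but not all initial conditions — a minority of
trajectories still terminate in high-energy "folding defect" minima of the
distance-geometry landscape, a behaviour that is insensitive to the
integrator step and to the disturbance box, and that inertial (second-order)
transients would largely remove.  The oscillatory regime is out of scope
here, so the measured capture fraction is reported as the first-order
answer.

**Scenario 1 — self-adaptation** (N=100, connectivity 0.5, 200 resets,
η=0.02).  The loop disturb → settle → creep runs with all springs plastic.
Because the springs that define the problem are the springs that learn,
quality is read through the *resettle assay*: take the configuration found
by the learned system, settle a pristine copy of the original springs from
it, and report that system's energy V_o.  The no-learning baseline replays
the identical disturbance positions against the pristine springs.  The
headline statistic is the log-energy STD score

    score = (mean log E_baseline − log E_learned_min) / std log E_baseline,

with sample std (ddof=1), energies floored at 1e−12 before the log, and the
learned minimum taken over the last quarter of resets.  At this scale ten
independent realisations give a median score ≈ 3.4 with most runs above 3.

**Scenario 2a — external continuous problem** (N=100; elastic P-springs:
connectivity 0.5, k=1, lengths U[0,1]; plastic L-springs: connectivity
0.99, k=0.1, lengths U[0,1]; 200 resets, η=0.02).  The elastic layer is the
fixed problem; only the weak dense plastic layer learns.  After the
disturbance loop a final settling phase alternates creep and settling until
every L-spring stress is below 1e−3·k_L·l̄_L — the learning springs "melt
away" and the final configuration is scored by the P-spring energy alone
against P-only baselines from identical disturbances.  A caveat this
package's experiments make explicit: at N=100 the deepest states reachable
even by thousands of independent restarts lie only ~2.7–2.9 baseline
log-STDs below the baseline mean, so scores above 3 are not attainable at
this reduced scale; learned runs approach that ceiling (scores ~2) rather
than exceed 3.  The >3-STD regime requires larger systems, whose rare states
are deeper relative to their baseline spread.

**Scenario 2b — spin glass / MaxCut** (n≈30 binary variables, ±J couplings
on random pairs at p=0.5; 300 resets, η=0.1).  Each variable is one mobile
mass; an elastic anchor spring of natural length 1 to an immovable centre
pseudo-mass at the origin creates the double well ½K(|x|−1)² along the
x-axis (minima at ±1, cusp barrier at 0), and a weak transverse spring to a
distant pin confines y ≈ 0.  A coupling J between u and v is an elastic
spring of natural length 0 (J>0, favours the same well) or 2 (J<0, favours
opposite wells) and stiffness 0.8·|J|; the spin readout is sign(x), ties to
+1.  At any clean spin configuration the elastic coupling energy is an
affine decreasing function of −ΣJ s_u s_v, so the geometric and spin ground
states coincide — verified against exhaustive enumeration at n ≤ 14.

The encoding's force budget is a deliberate design point: anchors default to
2.5·(n−1)·p·|J|·k_c, a few times the expected aggregate coupling pull, so
plain relaxation *without* the learning layer commits each variable to a
near-random well — the baseline distribution of binarised local optima is
then wide (σ ≈ √M for M couplings) and only weakly biased, and the problem
is effectively invisible to a first-order hill-climber.  The plastic layer
(dense, per-spring stiffness anchor/(2·(n−1)·l_connect) ≈ 0.5, natural
lengths U[0,2]) aggregates to about half the anchor scale: strong enough
that the learned length pattern steers well choices during the descent
after each disturbance.  Making the anchors weak instead turns the baseline
into a competent local search whose mean sits within ~1.6σ of the ground
state, destroying the headroom that the learned-vs-unlearned comparison
measures; making them stiffer starves learning of any signal.  Binarised
energies are signed, so this scenario uses the plain (non-log) STD score.

## Synthetic data and what passing tests show

All networks and problems are generated programmatically (Bernoulli
connectivity with rejection of disconnected draws, uniform natural lengths,
uniform initial positions in a box of side √N·l̄ so density is roughly
N-independent).  The generator families are the experimental conditions
themselves — there is no external data.  Passing tests therefore demonstrate the
mechanism under these idealised conditions (global damping, uniform creep
rates, complete state resets, pairwise interactions only); they do not
speak to heterogeneous damping, partial disturbances, hidden state, 3D
embeddings, or plasticity in stiffness, all of which are out of scope.

## Numerical choices and degenerate inputs

* Tolerances: settle force tolerance 1e−6·k̄·l̄; memory-experiment match
  tolerance 1% relative on distance vectors; L-melt threshold
  1e−3·k_L·l̄_L; log floor 1e−12.
* Attractor clustering is single linkage at threshold 0.01·‖mean distance
  vector‖, deterministic with ties resolved by first occurrence.
* PCA embeddings are fitted on the baseline sample only and project learned
  records through the fitted transform.
* The neutrality assay reports both a two-sample KS statistic on the energy
  marginals and the paired start-by-start median |ΔE|; the paired statistic
  is the sharper instrument, because a strongly non-neutral layer changes
  *which* attractor each start reaches more than it changes the energy
  histogram.
* `learning_rate` accepts the closed interval [0,1]: 0 is the no-learning
  control, 1 is full accommodation in a single visit.
* Reproducibility: one seeded `numpy` Generator per run drives every random
  draw; checkpoints serialise springs plus the RNG state, and a restored run
  is bit-identical to an uninterrupted one.

## Problem sizes used by the shipped experiments

The experiment suites run N=15 (memory, 1000 initial conditions), N=100
(Scenarios 1 and 2a, 200 resets, 10 realisations each) and n=30 spins
(Scenario 2b, 300 resets, 10 realisations).  These sizes were chosen as the
package's standard benchmark scales; the generators and protocols accept
arbitrary sizes.

## Known limitations

* First-order overdamped dynamics only.  A real damped spring network
  settles with transient inertial oscillation, which funnels trajectories past shallow
  folding-defect minima; pure gradient flow retains those minima, which is
  why the memory experiment captures ~60–90% rather than ≳98% of initial
  conditions.  A second-order integrator is deliberately not part of this
  package's scope.
* Scenario 2a's >3-STD statistic is a large-N effect (see above); at the
  benchmark scale the honest report is the measured score near its ceiling.
* The spin-glass embedding is one concrete bistable mechanism; any encoding
  whose relaxed-binarised ground state matches enumeration is equally valid.
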