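"""The experimental protocols as end-to-end, seeded, resumable runs.

All three scenarios share one disturbance loop: randomise the mobile
positions, settle to a local energy minimum, then apply one per-equilibrium
creep step to the plastic springs.  They differ in which springs are plastic
and in how solution quality is read out:

* memory experiment — a small all-plastic net creeps at one held equilibrium
  and the basin of that configuration is measured before and after;
* scenario 1 — an all-plastic net adapts to its own energy function; quality
  is the resettled energy V_o under a pristine copy of the initial springs;
* scenario 2 — elastic P-springs define an external problem; a weak dense
  plastic L-layer learns, then a final settling phase lets the L-stress decay
  so only the problem springs score the final configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import binarised_energy, resettle_energy
from .dynamics import disturb, disturbance_box, potential_energy, settle
from .errors import ContractError, ParameterError
from .learning import equilibrium_update, max_plastic_stress
from .model import (
    EquilibriumRecord,
    ProblemInstance,
    SimulationConfig,
    SpringNetwork,
)

__all__ = [
    "DisturbanceRun",
    "RunResult",
    "MemoryResult",
    "run_memory_experiment",
    "run_scenario1",
    "run_scenario2",
    "replay_baseline",
]


@dataclass
class RunResult:
    """Everything a protocol run produced (records carry per-reset data)."""

    scenario: str
    seed: int | None
    config: SimulationConfig
    records: list[EquilibriumRecord]
    disturb_positions: np.ndarray  # (n_resets, n_mobile, 2)
    network_initial: SpringNetwork
    network_final: SpringNetwork
    baseline_energies: np.ndarray | None = None
    final_record: EquilibriumRecord | None = None
    final_phase_iters: int = 0
    final_phase_converged: bool = True
    extras: dict = field(default_factory=dict)

    @property
    def energies_current(self) -> np.ndarray:
        return np.array([r.energy_current for r in self.records])

    @property
    def energies_original(self) -> np.ndarray:
        return np.array(
            [np.nan if r.energy_original is None else r.energy_original
             for r in self.records]
        )


class DisturbanceRun:
    """Stepper for the disturb → settle → creep loop, with checkpointing.

    A checkpoint captures the spring state and the RNG state, so a run
    restored at reset t reproduces the uninterrupted run bit-for-bit.
    """

    def __init__(
        self,
        network: SpringNetwork,
        config: SimulationConfig,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.network = network.copy()
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.records: list[EquilibriumRecord] = []
        self.disturb_positions: list[np.ndarray] = []

    def step(self) -> EquilibriumRecord:
        disturb(self.network, self.config, self.rng)
        self.disturb_positions.append(
            self.network.positions[self.network.mobile].copy()
        )
        rec = settle(self.network, self.config, reset_index=len(self.records))
        equilibrium_update(self.network, rec, self.config.learning_rate)
        self.records.append(rec)
        return rec

    def run(self, n_resets: int) -> None:
        for _ in range(n_resets):
            self.step()

    # -- resumability --------------------------------------------------------

    def checkpoint(self) -> dict:
        return {
            "network": self.network.copy(),
            "rng_state": self.rng.bit_generator.state,
            "records": list(self.records),
            "disturb_positions": [p.copy() for p in self.disturb_positions],
            "config": self.config,
        }

    @classmethod
    def restore(cls, state: dict) -> "DisturbanceRun":
        run = cls.__new__(cls)
        run.network = state["network"].copy()
        run.config = state["config"]
        run.rng = np.random.default_rng()
        run.rng.bit_generator.state = state["rng_state"]
        run.records = list(state["records"])
        run.disturb_positions = [p.copy() for p in state["disturb_positions"]]
        return run


def replay_baseline(
    pristine: SpringNetwork,
    disturb_positions: np.ndarray,
    config: SimulationConfig,
    problem: ProblemInstance | None = None,
) -> dict:
    """Settle a pristine (non-learning) system from recorded disturbances.

    Returns per-reset energies; when ``problem`` carries couplings, also the
    binarised spin energies of the settled configurations.  The pristine
    springs are never updated, so this is the no-learning control under
    identical disturbances.
    """
    net = pristine.copy()
    energies = np.empty(len(disturb_positions))
    spin_energies = (
        np.empty(len(disturb_positions))
        if problem is not None and problem.couplings is not None
        else None
    )
    for t, start in enumerate(disturb_positions):
        net.positions[net.mobile] = start
        rec = settle(net, config)
        energies[t] = rec.energy_current
        if spin_energies is not None:
            _, spin_energies[t] = binarised_energy(problem, net.positions)
    out = {"energies": energies}
    if spin_energies is not None:
        out["spin_energies"] = spin_energies
    return out


def run_scenario1(
    network: SpringNetwork,
    config: SimulationConfig,
    *,
    assay: bool = True,
    baseline: bool = True,
) -> RunResult:
    """Generic self-adaptation: an all-plastic network under periodic
    disturbances, each equilibrium followed by one creep step.

    Every record is assayed for its original-system energy V_o (resettled
    under a pristine copy of the initial springs), and the same disturbance
    draws are replayed against the pristine system as the no-learning
    baseline."""
    if not np.all(network.plastic):
        raise ContractError("scenario 1 expects an all-plastic network")
    pristine = network.copy()
    loop = DisturbanceRun(network, config)
    loop.run(config.n_resets)

    disturb_positions = np.array(loop.disturb_positions)
    if assay:
        for rec in loop.records:
            rec.energy_original = resettle_energy(pristine, rec.positions, config)
    baseline_energies = None
    if baseline:
        baseline_energies = replay_baseline(pristine, disturb_positions, config)[
            "energies"
        ]
    return RunResult(
        scenario="s1",
        seed=config.seed,
        config=config,
        records=loop.records,
        disturb_positions=disturb_positions,
        network_initial=pristine,
        network_final=loop.network,
        baseline_energies=baseline_energies,
    )


def run_scenario2(
    problem: ProblemInstance,
    combined: SpringNetwork,
    config: SimulationConfig,
    *,
    baseline: bool = True,
    stress_threshold_frac: float = 1e-3,
    max_final_iters: int = 5000,
) -> RunResult:
    """External problems: elastic P-springs plus a plastic L-layer.

    After the disturbance loop, a final phase alternates creep and settling
    until every L-spring's stress magnitude falls below
    ``stress_threshold_frac · k̄_L · l̄_L`` — the learning springs "melt away"
    and only the problem springs carry energy.  The final record's energy is
    computed on the P-springs alone; for spin-glass problems the final
    configuration is also binarised and scored."""
    if not np.any(combined.plastic):
        raise ContractError("scenario 2 expects a plastic L-layer in the combined net")
    if np.any(problem.p_springs.plastic):
        raise ParameterError("problem springs must be elastic")
    if config.learning_rate == 0.0:
        raise ParameterError("scenario 2 final phase requires learning_rate > 0")

    l_mask = combined.plastic
    k_l = float(combined.stiffness[l_mask].mean())
    l_l = float(combined.natural_length[l_mask].mean())
    stress_threshold = stress_threshold_frac * k_l * max(l_l, 1e-12)

    loop = DisturbanceRun(combined, config)
    loop.run(config.n_resets)

    # final settling phase: let the L-stress decay at the settled state
    net = loop.network
    final_rec = settle(net, config)
    iters = 0
    while max_plastic_stress(net) > stress_threshold and iters < max_final_iters:
        equilibrium_update(net, final_rec, config.learning_rate)
        final_rec = settle(net, config)
        iters += 1
    converged = max_plastic_stress(net) <= stress_threshold

    p_energy = potential_energy(net, "elastic")
    l_energy = potential_energy(net, "plastic")
    final_rec.energy_original = p_energy

    extras = {"final_p_energy": p_energy, "final_l_energy": l_energy}
    disturb_positions = np.array(loop.disturb_positions)
    baseline_energies = None
    if baseline:
        rb = replay_baseline(
            problem.p_springs, disturb_positions, config, problem=problem
        )
        baseline_energies = rb["energies"]
        if "spin_energies" in rb:
            extras["baseline_spin_energies"] = rb["spin_energies"]
    if problem.couplings is not None:
        spins, e_spin = binarised_energy(problem, net.positions)
        extras["final_spins"] = spins
        extras["final_spin_energy"] = e_spin
    return RunResult(
        scenario="s2",
        seed=config.seed,
        config=config,
        records=loop.records,
        disturb_positions=disturb_positions,
        network_initial=combined.copy(),
        network_final=net,
        baseline_energies=baseline_energies,
        final_record=final_rec,
        final_phase_iters=iters,
        final_phase_converged=converged,
        extras=extras,
    )


@dataclass
class MemoryResult:
    baseline_records: list[EquilibriumRecord]
    held_record: EquilibriumRecord
    post_records: list[EquilibriumRecord]
    convergence_fraction: float
    creep_iters: int
    network_learned: SpringNetwork
    initial_positions: np.ndarray

    @staticmethod
    def _converged(rec: EquilibriumRecord, held: EquilibriumRecord, tol: float) -> bool:
        ref = np.linalg.norm(held.distance_vector)
        return bool(
            np.linalg.norm(rec.distance_vector - held.distance_vector) <= tol * ref
        )


def run_memory_experiment(
    network: SpringNetwork,
    config: SimulationConfig,
    n_samples: int = 1000,
    *,
    creep_stop_frac: float = 0.01,
    max_creep_iters: int = 5000,
    match_tol: float = 0.01,
) -> MemoryResult:
    """Memory formation in a small all-plastic network.

    1. Settle from ``n_samples`` random initial conditions with pristine
       springs (baseline equilibrium distribution).
    2. Hold the first equilibrium sampled while the springs creep to
       near-completion (alternating per-equilibrium creep and re-settling
       until the max plastic stress falls below ``creep_stop_frac`` of its
       initial value).
    3. Re-settle from the SAME initial conditions with the deformed springs.

    The convergence fraction counts re-settled runs whose distance vector
    lies within ``match_tol`` relative Euclidean distance of the held
    configuration's.  ``creep_stop_frac=None`` (or a learning rate of zero)
    leaves the springs untouched, reproducing the baseline exactly.
    """
    if not np.all(network.plastic):
        raise ContractError("memory experiment expects an all-plastic network")
    rng = np.random.default_rng(config.seed)
    lo, hi = disturbance_box(network, config)
    n = network.n_masses
    initial_positions = rng.uniform(lo, hi, size=(n_samples, n, 2))

    probe = network.copy()
    baseline: list[EquilibriumRecord] = []
    for t in range(n_samples):
        probe.positions[:] = initial_positions[t]
        baseline.append(settle(probe, config, reset_index=t))

    # creep at the first sampled equilibrium (chosen arbitrarily)
    learned = network.copy()
    learned.positions[:] = baseline[0].positions
    held_rec = settle(learned, config)
    creep_iters = 0
    if config.learning_rate > 0.0 and creep_stop_frac is not None:
        stress0 = max_plastic_stress(learned)
        target = creep_stop_frac * stress0
        while max_plastic_stress(learned) > target and creep_iters < max_creep_iters:
            equilibrium_update(learned, held_rec, config.learning_rate)
            held_rec = settle(learned, config)
            creep_iters += 1

    post: list[EquilibriumRecord] = []
    n_hit = 0
    for t in range(n_samples):
        learned.positions[:] = initial_positions[t]
        rec = settle(learned, config, reset_index=t)
        post.append(rec)
        if MemoryResult._converged(rec, held_rec, match_tol):
            n_hit += 1

    return MemoryResult(
        baseline_records=baseline,
        held_record=held_rec,
        post_records=post,
        convergence_fraction=n_hit / n_samples,
        creep_iters=creep_iters,
        network_learned=learned,
        initial_positions=initial_positions,
    )
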