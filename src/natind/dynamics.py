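"""Overdamped state relaxation: forces, potential energy, settling, disturbances.

The position dynamics are the first-order gradient flow ẋ_i = F_i/γ with
F_i = −∂V/∂x_i and V = Σ_springs ½ k (r_ij − l_ij)².  Natural lengths are
never modified here: settling is pure physical optimisation of the state
given the current spring parameters.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .errors import DegenerateGeometryError, IntegrationError, ParameterError
from .model import EquilibriumRecord, SimulationConfig, SpringNetwork

__all__ = [
    "potential_energy",
    "net_forces",
    "settle",
    "disturb",
    "resolve_tolerance",
    "disturbance_box",
]

_EMPTY_TRACE = np.empty(1)


def _layer_mask(network: SpringNetwork, springs: str) -> np.ndarray | None:
    if springs == "all":
        return None
    if springs == "plastic":
        return network.plastic
    if springs == "elastic":
        return ~network.plastic
    raise ParameterError(f"springs must be 'all', 'plastic' or 'elastic', got {springs!r}")


def potential_energy(network: SpringNetwork, springs: str = "all") -> float:
    """Elastic potential V = Σ ½ k (r − l)² over the selected spring layer."""
    if not np.all(np.isfinite(network.positions)):
        raise IntegrationError("non-finite positions")
    mask = _layer_mask(network, springs)
    if mask is None:
        return float(
            _kernels.potential(
                network.positions,
                network.edge_i,
                network.edge_j,
                network.stiffness,
                network.natural_length,
            )
        )
    return float(
        _kernels.potential(
            network.positions,
            network.edge_i[mask],
            network.edge_j[mask],
            network.stiffness[mask],
            network.natural_length[mask],
        )
    )


def net_forces(network: SpringNetwork) -> np.ndarray:
    """Net elastic force on every mass; Newton's third law holds pairwise.

    Damping does not appear here: in the overdamped reduction it enters as the
    mobility 1/γ in :func:`settle`.
    """
    r = network.spring_separations()
    if np.any(r < 1e-12):
        bad = int(np.argmin(r))
        raise DegenerateGeometryError(
            f"masses {int(network.edge_i[bad])} and {int(network.edge_j[bad])} "
            "are coincident; force direction undefined"
        )
    out = np.zeros_like(network.positions)
    _kernels.forces(
        network.positions,
        network.edge_i,
        network.edge_j,
        network.stiffness,
        network.natural_length,
        out,
    )
    return out


def resolve_tolerance(network: SpringNetwork, config: SimulationConfig) -> float:
    """Settle tolerance: explicit config value, else 1e−6 · k̄ · l̄."""
    if config.equilibrium_tolerance is not None:
        return config.equilibrium_tolerance
    k_bar = float(network.stiffness.mean()) if network.n_springs else 1.0
    l_bar = network.mean_natural_length()
    scale = k_bar * l_bar
    if scale <= 0:
        scale = k_bar
    return 1e-6 * scale


def resolve_step_size(network: SpringNetwork, config: SimulationConfig) -> float:
    """Euler step ceiling: explicit config value, else 4γ / max_i Σ k_incident.

    The per-mass stiffness sum bounds the largest curvature of V (Gershgorin
    estimate, pessimistic because spring directions decorrelate in 2D); the
    factor 4 deliberately over-shoots and lets the energy guard find the
    actual stable step just below the boundary."""
    if config.step_size is not None:
        return config.step_size
    n = network.n_masses
    ksum = np.zeros(n)
    np.add.at(ksum, network.edge_i, network.stiffness)
    np.add.at(ksum, network.edge_j, network.stiffness)
    kmax = float(ksum.max()) if network.n_springs else 1.0
    return 4.0 * config.damping / max(kmax, 1e-12)


def resolve_max_displacement(network: SpringNetwork, config: SimulationConfig) -> float:
    """Per-step displacement cap: explicit config value, else 0.05 · l̄."""
    if config.max_displacement is not None:
        return config.max_displacement
    l_bar = network.mean_natural_length()
    if l_bar <= 0:
        l_bar = 1.0
    return 0.05 * l_bar


def disturbance_box(network: SpringNetwork, config: SimulationConfig):
    """(lower, upper) corners of the disturbance box.

    A network may carry its own box (the spin-glass embedding does); otherwise
    a square of side ``config.box_size`` anchored at the origin is used, with
    side sqrt(N)·l̄ by default so the mass density is roughly N-independent.
    """
    if network.disturb_box is not None:
        return network.disturb_box
    side = config.box_size
    if side is None:
        l_bar = network.mean_natural_length()
        if l_bar <= 0:
            l_bar = 1.0
        side = float(np.sqrt(network.n_masses) * l_bar)
    return np.zeros(2), np.array([side, side], dtype=float)


def settle(
    network: SpringNetwork,
    config: SimulationConfig,
    *,
    reset_index: int = -1,
    record_trajectory: bool = False,
) -> EquilibriumRecord:
    """Relax the network (in place) to a local minimum of V.

    Integrates the overdamped gradient flow with an adaptive explicit Euler
    whose step never exceeds ``config.step_size`` and is halved whenever a
    trial step would increase V, so the energy is non-increasing along the
    whole trajectory.  Stops when the max per-mass force drops below the
    equilibrium tolerance, or after ``max_settle_steps`` (recorded as
    ``converged=False`` on the result, not fatal).
    """
    tol = resolve_tolerance(network, config)
    trace = (
        np.empty(config.max_settle_steps) if record_trajectory else _EMPTY_TRACE
    )
    steps, converged, v, n_trace = _kernels.settle(
        network.positions,
        network.edge_i,
        network.edge_j,
        network.stiffness,
        network.natural_length,
        network.mobile,
        config.damping,
        resolve_step_size(network, config),
        resolve_max_displacement(network, config),
        tol,
        config.max_settle_steps,
        trace,
    )
    if not np.all(np.isfinite(network.positions)):
        raise IntegrationError(
            "integration diverged to non-finite positions; reduce step_size"
        )
    return EquilibriumRecord(
        reset_index=reset_index,
        positions=network.positions.copy(),
        distance_vector=network.distance_vector(),
        energy_current=float(v),
        settle_steps=int(steps),
        converged=bool(converged),
        energy_trace=trace[:n_trace].copy() if record_trajectory else None,
    )


def disturb(
    network: SpringNetwork,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SpringNetwork:
    """Redraw all mobile positions i.i.d. uniform in the disturbance box.

    Spring parameters — including any learned natural lengths — are untouched;
    anchor pseudo-masses never move.  Mutates and returns ``network``.
    """
    lo, hi = disturbance_box(network, config)
    n_mobile = int(network.mobile.sum())
    draws = rng.uniform(lo, hi, size=(n_mobile, 2))
    network.positions[network.mobile] = draws
    return network
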