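"""Maxwell creep of plastic springs — the physical learning rule.

A viscoelastic (Maxwell) spring held at separation r deforms its natural
length as l̇ = (k/γ_m)(r − l): under tension it lengthens, under compression
it shortens.  This is gradient descent of the same potential V with respect
to l (l̇ = −∂V/∂l up to the 1/γ_m mobility), i.e. the spring parameters relax
to the state exactly as the state relaxes to the parameters.

Because γ_m ≫ γ, creep during transients is negligible and the continuous
law is applied in discrete per-equilibrium form: once per settled
configuration, l ← l + η (r_eq − l) with learning rate η ∈ [0, 1].
"""

from __future__ import annotations

import numpy as np

from .dynamics import potential_energy
from .errors import ContractError, ParameterError
from .model import EquilibriumRecord, Spring, SpringNetwork

__all__ = [
    "creep_rate",
    "creep_length",
    "gradient_check",
    "equilibrium_update",
    "max_plastic_stress",
]


def creep_rate(spring: Spring, r: float) -> float:
    """Instantaneous l̇ = (k/γ_m)(r − l) of a plastic spring at separation r."""
    if not spring.plastic:
        raise ContractError("creep_rate is only defined for plastic springs")
    return spring.creep_rate * (r - spring.natural_length)


def creep_length(spring: Spring, r: float, t: float) -> float:
    """Closed-form natural length after holding separation r for time t:
    l(t) = r + (l(0) − r)·exp(−(k/γ_m) t)."""
    if not spring.plastic:
        raise ContractError("creep only applies to plastic springs")
    return r + (spring.natural_length - r) * float(np.exp(-spring.creep_rate * t))


def gradient_check(network: SpringNetwork, rel_eps: float = 1e-6) -> float:
    """Max relative discrepancy between the creep law and −(1/γ_m)·∂V/∂l.

    The partial derivative is taken by central differences on each plastic
    spring's natural length; used as a consistency test of the implemented
    equations, not in production runs.
    """
    r_all = network.spring_separations()
    scale = max(1.0, float(np.abs(network.spring_stress()).max(initial=0.0)))
    worst = 0.0
    for s in np.flatnonzero(network.plastic):
        l0 = network.natural_length[s]
        eps = rel_eps * max(1.0, abs(l0))
        network.natural_length[s] = l0 + eps
        v_plus = potential_energy(network)
        network.natural_length[s] = l0 - eps
        v_minus = potential_energy(network)
        network.natural_length[s] = l0
        dv_dl = (v_plus - v_minus) / (2 * eps)
        # l̇ = creep_rate·(r − l) should equal −(creep_rate/k)·∂V/∂l
        analytic = network.creep_rate[s] * (r_all[s] - l0)
        numeric = -(network.creep_rate[s] / network.stiffness[s]) * dv_dl
        worst = max(worst, abs(analytic - numeric) / scale)
    return worst


def equilibrium_update(
    network: SpringNetwork,
    record: EquilibriumRecord | None = None,
    learning_rate: float = 0.02,
) -> SpringNetwork:
    """One per-equilibrium creep step: l ← l + η (r − l) on plastic springs.

    ``record``, when given, must hold the network's current settled positions
    (the update is defined at equilibrium).  Elastic springs are untouched.
    Each updated spring's energy term shrinks by the factor (1 − η)², so the
    update strictly reduces the energy of the current configuration unless
    the spring is already unstressed.  Mutates and returns ``network``.
    """
    if not (0.0 <= learning_rate <= 1.0):
        raise ParameterError("learning_rate must lie in [0, 1]")
    if record is not None and record.positions.shape != network.positions.shape:
        raise ContractError("record does not match the network")
    mask = network.plastic
    if mask.any():
        r = network.spring_separations()[mask]
        l = network.natural_length[mask]
        network.natural_length[mask] = l + learning_rate * (r - l)
    return network


def max_plastic_stress(network: SpringNetwork) -> float:
    """Largest |k (r − l)| over plastic springs (0 if there are none)."""
    stress = network.spring_stress()[network.plastic]
    return float(np.abs(stress).max()) if stress.size else 0.0
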