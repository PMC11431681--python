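"""Domain types for viscoelastic spring networks.

A network is a set of point masses confined to the 2D plane, joined by
Hookean springs.  Springs come in two kinds: perfectly elastic ones
(``plastic=False``, "P-springs") whose natural length never changes, and
viscoelastic Maxwell springs (``plastic=True``, "L-springs") whose natural
length slowly creeps toward the current separation of the masses it joins.
The creep is the physical learning rule; the overdamped relaxation of the
positions is the physical optimisation process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ContractError, ParameterError

__all__ = [
    "Spring",
    "SpringNetwork",
    "SimulationConfig",
    "EquilibriumRecord",
    "ProblemInstance",
]


@dataclass(frozen=True)
class Spring:
    """One pairwise connection between masses ``i`` and ``j``.

    ``stiffness`` is the Hookean constant k (force/length); ``natural_length``
    is the current rest length l_ij; ``creep_rate`` is k/γ_m, the inverse
    timescale of Maxwell creep (only meaningful when ``plastic``).
    """

    i: int
    j: int
    stiffness: float
    natural_length: float
    plastic: bool = False
    creep_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ParameterError(f"self-spring ({self.i}, {self.j}) is not allowed")
        if self.i < 0 or self.j < 0:
            raise ParameterError("mass indices must be non-negative")
        if not self.stiffness > 0:
            raise ParameterError(f"stiffness must be > 0, got {self.stiffness}")
        if self.natural_length < 0:
            raise ParameterError(
                f"natural_length must be >= 0, got {self.natural_length}"
            )
        if self.plastic and not self.creep_rate > 0:
            raise ParameterError("creep_rate must be > 0 for a plastic spring")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


class SpringNetwork:
    """Masses in the plane plus a spring set; the dynamical system itself.

    Internally the springs are held as parallel arrays (struct-of-arrays) so
    that the dynamics kernels can run over them directly; the ``springs``
    property materialises :class:`Spring` views on demand.

    Parameters
    ----------
    positions : (N, 2) array of mass coordinates.
    springs : iterable of :class:`Spring`.
    mobile : optional (N,) boolean mask.  Immobile masses are anchor
        pseudo-masses: they never move, are excluded from disturbances and
        from the pairwise ``distance_vector``.
    disturb_box : optional ((2,), (2,)) pair of lower/upper corners from which
        disturbed positions are drawn; defaults are resolved by the dynamics
        layer from the configuration.
    """

    __slots__ = (
        "positions",
        "edge_i",
        "edge_j",
        "stiffness",
        "natural_length",
        "plastic",
        "creep_rate",
        "mobile",
        "disturb_box",
    )

    def __init__(
        self,
        positions: np.ndarray,
        springs: Iterable[Spring] = (),
        *,
        mobile: np.ndarray | None = None,
        disturb_box: tuple[Sequence[float], Sequence[float]] | None = None,
    ) -> None:
        positions = np.array(positions, dtype=np.float64)
        if positions.ndim != 2 or positions.shape[1] != 2:
            raise ParameterError("positions must have shape (N, 2)")
        if not np.all(np.isfinite(positions)):
            raise ParameterError("positions must be finite")
        self.positions = positions
        n = positions.shape[0]

        springs = list(springs)
        seen: set[tuple[int, int, bool]] = set()
        for s in springs:
            if s.i >= n or s.j >= n:
                raise ParameterError(
                    f"spring ({s.i}, {s.j}) references a mass index >= N={n}"
                )
            key = (*s.pair, s.plastic)
            if key in seen:
                raise ParameterError(
                    f"duplicate spring for pair {s.pair} within one layer"
                )
            seen.add(key)

        self.edge_i = np.array([s.i for s in springs], dtype=np.int64)
        self.edge_j = np.array([s.j for s in springs], dtype=np.int64)
        self.stiffness = np.array([s.stiffness for s in springs], dtype=np.float64)
        self.natural_length = np.array(
            [s.natural_length for s in springs], dtype=np.float64
        )
        self.plastic = np.array([s.plastic for s in springs], dtype=np.bool_)
        self.creep_rate = np.array([s.creep_rate for s in springs], dtype=np.float64)

        if mobile is None:
            mobile = np.ones(n, dtype=np.bool_)
        else:
            mobile = np.array(mobile, dtype=np.bool_)
            if mobile.shape != (n,):
                raise ParameterError("mobile mask must have shape (N,)")
        self.mobile = mobile
        if disturb_box is not None:
            lo, hi = (np.asarray(disturb_box[0], float), np.asarray(disturb_box[1], float))
            if lo.shape != (2,) or hi.shape != (2,) or np.any(hi <= lo):
                raise ParameterError("disturb_box must be ((x0,y0),(x1,y1)) with hi > lo")
            disturb_box = (lo, hi)
        self.disturb_box = disturb_box

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        edge_i: np.ndarray,
        edge_j: np.ndarray,
        stiffness: np.ndarray,
        natural_length: np.ndarray,
        plastic: np.ndarray,
        creep_rate: np.ndarray | None = None,
        *,
        mobile: np.ndarray | None = None,
        disturb_box=None,
    ) -> "SpringNetwork":
        """Fast path used by generators; performs only shape coercion."""
        net = cls.__new__(cls)
        net.positions = np.array(positions, dtype=np.float64)
        net.edge_i = np.asarray(edge_i, dtype=np.int64).copy()
        net.edge_j = np.asarray(edge_j, dtype=np.int64).copy()
        net.stiffness = np.asarray(stiffness, dtype=np.float64).copy()
        net.natural_length = np.asarray(natural_length, dtype=np.float64).copy()
        net.plastic = np.asarray(plastic, dtype=np.bool_).copy()
        if creep_rate is None:
            creep_rate = np.ones_like(net.stiffness)
        net.creep_rate = np.asarray(creep_rate, dtype=np.float64).copy()
        if mobile is None:
            mobile = np.ones(net.positions.shape[0], dtype=np.bool_)
        net.mobile = np.asarray(mobile, dtype=np.bool_).copy()
        if disturb_box is not None:
            disturb_box = (
                np.asarray(disturb_box[0], float),
                np.asarray(disturb_box[1], float),
            )
        net.disturb_box = disturb_box
        return net

    # -- basic views ----------------------------------------------------------

    @property
    def n_masses(self) -> int:
        return self.positions.shape[0]

    @property
    def n_springs(self) -> int:
        return self.edge_i.shape[0]

    @property
    def springs(self) -> list[Spring]:
        return [
            Spring(
                int(self.edge_i[s]),
                int(self.edge_j[s]),
                float(self.stiffness[s]),
                float(self.natural_length[s]),
                bool(self.plastic[s]),
                float(self.creep_rate[s]),
            )
            for s in range(self.n_springs)
        ]

    def copy(self) -> "SpringNetwork":
        return SpringNetwork.from_arrays(
            self.positions,
            self.edge_i,
            self.edge_j,
            self.stiffness,
            self.natural_length,
            self.plastic,
            self.creep_rate,
            mobile=self.mobile,
            disturb_box=self.disturb_box,
        )

    def without_plastic(self) -> "SpringNetwork":
        """The elastic (P-spring) subsystem on the same masses."""
        keep = ~self.plastic
        return SpringNetwork.from_arrays(
            self.positions,
            self.edge_i[keep],
            self.edge_j[keep],
            self.stiffness[keep],
            self.natural_length[keep],
            self.plastic[keep],
            self.creep_rate[keep],
            mobile=self.mobile,
            disturb_box=self.disturb_box,
        )

    # -- geometry -------------------------------------------------------------

    def spring_separations(self) -> np.ndarray:
        """Current distance r_ij for every spring."""
        d = self.positions[self.edge_i] - self.positions[self.edge_j]
        return np.hypot(d[:, 0], d[:, 1])

    def spring_stress(self) -> np.ndarray:
        """Signed Hookean stress k·(r − l) for every spring."""
        return self.stiffness * (self.spring_separations() - self.natural_length)

    def distance_vector(self) -> np.ndarray:
        """All N(N−1)/2 pairwise distances between mobile masses.

        Invariant under rigid motions (and reflections), so it identifies an
        equilibrium configuration independently of the coordinate frame.
        """
        return pdist(self.positions[self.mobile])

    def mean_natural_length(self) -> float:
        return float(self.natural_length.mean()) if self.n_springs else 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        npl = int(self.plastic.sum())
        return (
            f"SpringNetwork(n_masses={self.n_masses}, n_springs={self.n_springs}, "
            f"plastic={npl}, elastic={self.n_springs - npl})"
        )


@dataclass
class SimulationConfig:
    """Integration, disturbance, and learning parameters.

    Attributes
    ----------
    damping : mobility constant γ of the overdamped position dynamics,
        ẋ = F/γ (unit viscosity by default).
    step_size : ceiling on the Euler time step; the integrator adapts below
        it.  ``None`` resolves to 4γ / max_i Σ_{springs at i} k — a network-
        scaled estimate of the largest stable step, which the energy guard
        then polices.
    equilibrium_tolerance : max per-mass net force magnitude defining
        "settled".  ``None`` resolves to 1e−6 · k̄ · l̄ of the network.
    max_displacement : cap on any mass's per-step displacement, keeping the
        discrete path close to the continuous gradient flow when forces are
        large.  ``None`` resolves to 0.05 · l̄.
    max_settle_steps : hard step budget per settle.
    n_resets : number of state disturbances in a protocol run.
    learning_rate : per-equilibrium creep fraction η ∈ [0, 1]; each plastic
        spring moves l ← l + η(r − l) once per equilibrium visited.
    box_size : side of the square the disturbed positions are drawn from;
        ``None`` resolves to sqrt(N) · l̄ (density roughly independent of N).
    seed : RNG seed for the whole run.
    """

    damping: float = 1.0
    step_size: float | None = None
    equilibrium_tolerance: float | None = None
    max_displacement: float | None = None
    max_settle_steps: int = 200_000
    n_resets: int = 300
    learning_rate: float = 0.02
    box_size: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.damping > 0:
            raise ParameterError("damping must be > 0")
        if self.step_size is not None and not self.step_size > 0:
            raise ParameterError("step_size must be > 0")
        if self.equilibrium_tolerance is not None and not self.equilibrium_tolerance > 0:
            raise ParameterError("equilibrium_tolerance must be > 0")
        if self.max_displacement is not None and not self.max_displacement > 0:
            raise ParameterError("max_displacement must be > 0")
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ParameterError("learning_rate must lie in [0, 1]")
        if self.n_resets < 0:
            raise ParameterError("n_resets must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class EquilibriumRecord:
    """One settled configuration.

    ``energy_current`` is V under the network's current natural lengths;
    ``energy_original`` (V_o) is filled by the resettle assay — the energy the
    configuration relaxes to under a pristine copy of the original springs.
    """

    reset_index: int
    positions: np.ndarray
    distance_vector: np.ndarray
    energy_current: float
    energy_original: float | None = None
    settle_steps: int = 0
    converged: bool = True
    energy_trace: np.ndarray | None = None


@dataclass
class ProblemInstance:
    """An external problem posed to the learning network.

    ``p_springs`` is the elastic problem network (P-springs only, anchors
    included for the spin-glass embedding).  For spin-glass/MaxCut problems,
    ``couplings`` holds rows (i, j, J) over variable indices and ``variables``
    maps variable index → mass index; the binarisation reads the sign of each
    variable mass's ``spin_axis`` coordinate (ties broken to +1).
    """

    p_springs: SpringNetwork
    couplings: np.ndarray | None = None
    variables: np.ndarray | None = None
    spin_axis: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.p_springs.plastic):
            raise ParameterError("p_springs must all be non-plastic")
        if self.couplings is not None:
            self.couplings = np.asarray(self.couplings, dtype=np.float64)
            if self.variables is None:
                raise ParameterError(
                    "couplings require a binarisation (variables map)"
                )
            self.variables = np.asarray(self.variables, dtype=np.int64)
            nv = self.variables.shape[0]
            idx = self.couplings[:, :2].astype(np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= nv):
                raise ParameterError("coupling indices out of range")

    @property
    def n_variables(self) -> int:
        if self.variables is None:
            raise ContractError("problem has no binary variables")
        return int(self.variables.shape[0])

    def binarise(self, positions: np.ndarray) -> np.ndarray:
        """Spins in {−1, +1} from the variable masses' axis coordinates."""
        if self.variables is None:
            raise ContractError("problem has no binarisation map")
        coords = np.asarray(positions)[self.variables, self.spin_axis]
        return np.where(coords >= 0.0, 1, -1).astype(np.int64)

    def coupling_energy(self, spins: np.ndarray) -> float:
        """Spin-glass energy E = −Σ_(ij) J_ij s_i s_j (lower is better)."""
        if self.couplings is None:
            raise ContractError("problem has no couplings")
        spins = np.asarray(spins)
        i = self.couplings[:, 0].astype(np.int64)
        j = self.couplings[:, 1].astype(np.int64)
        return float(-(self.couplings[:, 2] * spins[i] * spins[j]).sum())
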