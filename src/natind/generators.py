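"""Generators for every network and problem family used in the experiments.

* random geometric all-plastic nets (the generic self-adaptation scenario),
* two-layer systems of elastic problem springs (P) plus a dense weak plastic
  learning layer (L),
* ±J spin-glass / MaxCut instances embedded as bistable mechanical variables.

Connectivity is independent Bernoulli per unordered pair; draws whose graph
is disconnected are rejected and redrawn (bounded number of attempts) so that
every mass participates in the energy.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import GenerationError, ParameterError
from .model import ProblemInstance, SpringNetwork

__all__ = [
    "generate_random_network",
    "generate_two_layer_problem",
    "generate_spinglass_problem",
    "spin_ground_state",
]

_MAX_REDRAWS = 100


def _pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0].astype(np.int64), iu[1].astype(np.int64)


def _is_connected(n: int, ei: np.ndarray, ej: np.ndarray) -> bool:
    if n <= 1:
        return True
    if ei.size == 0:
        return False
    adj = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp == 1


def _check_prob(p: float, name: str) -> None:
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"{name} must lie in (0, 1], got {p}")


def _check_range(rng_pair, name: str) -> tuple[float, float]:
    lo, hi = float(rng_pair[0]), float(rng_pair[1])
    if lo < 0 or hi < lo:
        raise ParameterError(f"{name} must satisfy 0 <= lo <= hi, got {rng_pair}")
    return lo, hi


def generate_random_network(
    n: int,
    connect_prob: float,
    natural_length: float = 10.0,
    stiffness: float = 10.0,
    plastic: bool = True,
    creep_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
    box_size: float | None = None,
) -> SpringNetwork:
    """Erdős–Rényi spring network with uniform spring parameters.

    Each unordered pair carries a spring with probability ``connect_prob``;
    initial positions are uniform in a square of side ``box_size`` (default
    sqrt(n)·natural_length).  Disconnected draws are rejected.
    """
    if n < 2:
        raise ParameterError("need at least n=2 masses")
    _check_prob(connect_prob, "connect_prob")
    if not stiffness > 0 or natural_length < 0:
        raise ParameterError("stiffness must be > 0 and natural_length >= 0")
    rng = np.random.default_rng(seed)
    pi, pj = _pairs(n)
    if box_size is None:
        box_size = float(np.sqrt(n) * max(natural_length, 1e-12))
    for _ in range(_MAX_REDRAWS):
        keep = rng.random(pi.size) < connect_prob
        ei, ej = pi[keep], pj[keep]
        positions = rng.uniform(0.0, box_size, size=(n, 2))
        if _is_connected(n, ei, ej):
            m = ei.size
            return SpringNetwork.from_arrays(
                positions,
                ei,
                ej,
                np.full(m, stiffness),
                np.full(m, natural_length),
                np.full(m, plastic, dtype=np.bool_),
                np.full(m, creep_rate),
            )
    raise GenerationError(
        f"no connected graph in {_MAX_REDRAWS} draws (n={n}, p={connect_prob})"
    )


def generate_two_layer_problem(
    n: int,
    p_connect: float = 0.5,
    p_length_range: tuple[float, float] = (0.0, 1.0),
    p_stiffness: float = 1.0,
    l_connect: float = 0.99,
    l_length_range: tuple[float, float] = (0.0, 1.0),
    l_stiffness: float = 0.1,
    creep_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
    box_size: float | None = None,
) -> tuple[ProblemInstance, SpringNetwork]:
    """Elastic problem layer plus a dense, much weaker plastic learning layer.

    Returns ``(problem, combined)``: the P-only network wrapped as a
    :class:`ProblemInstance`, and the combined P+L network sharing the same
    masses and initial positions.  ``l_connect=0`` yields a combined network
    identical to the P-only one.
    """
    if n < 2:
        raise ParameterError("need at least n=2 masses")
    _check_prob(p_connect, "p_connect")
    if not (0.0 <= l_connect <= 1.0):
        raise ParameterError("l_connect must lie in [0, 1]")
    p_lo, p_hi = _check_range(p_length_range, "p_length_range")
    l_lo, l_hi = _check_range(l_length_range, "l_length_range")
    if not (0 < l_stiffness < p_stiffness):
        raise ParameterError("l_stiffness must satisfy 0 < kL < kP (much weaker)")
    rng = np.random.default_rng(seed)
    pi, pj = _pairs(n)
    if box_size is None:
        mean_l = 0.5 * (p_lo + p_hi)
        box_size = float(np.sqrt(n) * max(mean_l, 1e-12))

    for _ in range(_MAX_REDRAWS):
        p_keep = rng.random(pi.size) < p_connect
        l_keep = rng.random(pi.size) < l_connect
        p_i, p_j = pi[p_keep], pj[p_keep]
        l_i, l_j = pi[l_keep], pj[l_keep]
        p_len = rng.uniform(p_lo, p_hi, size=p_i.size)
        l_len = rng.uniform(l_lo, l_hi, size=l_i.size)
        positions = rng.uniform(0.0, box_size, size=(n, 2))
        ei = np.concatenate([p_i, l_i])
        ej = np.concatenate([p_j, l_j])
        if _is_connected(n, ei, ej):
            break
    else:
        raise GenerationError("no connected combined graph within the redraw budget")

    plastic = np.concatenate(
        [np.zeros(p_i.size, np.bool_), np.ones(l_i.size, np.bool_)]
    )
    combined = SpringNetwork.from_arrays(
        positions,
        ei,
        ej,
        np.concatenate([np.full(p_i.size, p_stiffness), np.full(l_i.size, l_stiffness)]),
        np.concatenate([p_len, l_len]),
        plastic,
        np.full(ei.size, creep_rate),
    )
    p_only = SpringNetwork.from_arrays(
        positions.copy(),
        p_i,
        p_j,
        np.full(p_i.size, p_stiffness),
        p_len,
        np.zeros(p_i.size, np.bool_),
        np.full(p_i.size, creep_rate),
    )
    return ProblemInstance(p_springs=p_only), combined


def generate_spinglass_problem(
    n_vars: int,
    edge_prob: float = 0.5,
    coupling_values: tuple[float, ...] = (-1.0, 1.0),
    seed: int | np.random.Generator | None = None,
    coupling_stiffness: float = 0.8,
    anchor_stiffness: float | None = None,
    l_connect: float = 0.99,
    l_stiffness: float | None = None,
    l_length_range: tuple[float, float] = (0.0, 2.0),
    creep_rate: float = 1.0,
) -> tuple[ProblemInstance, SpringNetwork]:
    """±J spin glass embedded as a bistable mechanical network.

    Each binary variable is one mobile mass whose x-coordinate encodes the
    spin.  Bistability comes from an elastic anchor spring of natural length 1
    to an immovable pseudo-mass at the origin: along the x-axis its energy
    ½K(|x|−1)² has minima at x = ±1 with a cusp barrier between them.  A
    second anchor spring to (0, H) with natural length H pins y ≈ 0 while
    perturbing x only at O(x²/H).  A coupling J between variables u, v is a
    P-spring of natural length 0 for J > 0 (favours the same well) and 2 for
    J < 0 (favours opposite wells), stiffness ∝ |J|; binarisation is the sign
    of x.  At a clean spin configuration the elastic coupling energy is an
    affine decreasing function of −Σ J s_u s_v, so the geometric and spin
    ground states coincide (verified by exhaustive enumeration in tests).

    The default force budget balances three regimes.  Anchors default to
    2.5·(n_vars−1)·edge_prob·max|J|·k_c — a few times the expected aggregate
    coupling pull — so first-order relaxation without a learning layer
    binarises to weakly biased, near-random local optima (the problem is
    effectively hidden from a plain hill-climber).  The plastic L-layer
    defaults to an aggregate stiffness of about half the anchor scale
    (l_stiffness = anchor/(2·(n_vars−1)·l_connect)), strong enough for the
    learned length pattern to steer well choices during the descent after a
    disturbance, yet far weaker per spring than any anchor.  Coupling
    stiffness stays below max|J| so well selection, not spring compromise,
    carries the problem.  Returns ``(problem, combined)`` where combined
    adds the dense plastic L-layer between variable masses.
    """
    if n_vars < 2:
        raise ParameterError("need at least n_vars=2 variables")
    _check_prob(edge_prob, "edge_prob")
    if len(coupling_values) == 0:
        raise ParameterError("coupling_values must be nonempty")
    if not coupling_stiffness > 0:
        raise ParameterError("coupling_stiffness must be > 0")
    l_lo, l_hi = _check_range(l_length_range, "l_length_range")
    rng = np.random.default_rng(seed)

    j_max = float(np.abs(np.asarray(coupling_values, dtype=float)).max())
    if anchor_stiffness is None:
        anchor_stiffness = max(
            10.0, 2.5 * (n_vars - 1) * edge_prob * j_max * coupling_stiffness
        )
    if l_stiffness is None:
        l_stiffness = anchor_stiffness / (2.0 * (n_vars - 1) * max(l_connect, 1e-12))
    H = 10.0  # transverse pin offset; x-perturbation is O(1/H²)

    pi, pj = _pairs(n_vars)
    keep = rng.random(pi.size) < edge_prob
    ci, cj = pi[keep], pj[keep]
    J = rng.choice(np.asarray(coupling_values, dtype=float), size=ci.size)
    nz = J != 0.0  # a zero coupling is no constraint at all
    ci, cj, J = ci[nz], cj[nz], J[nz]
    couplings = np.column_stack([ci, cj, J]).astype(float)

    centre, pin = n_vars, n_vars + 1  # anchor pseudo-mass indices
    n_masses = n_vars + 2
    box_lo = np.array([-1.5, -0.75])
    box_hi = np.array([1.5, 0.75])

    positions = np.zeros((n_masses, 2))
    positions[:n_vars] = rng.uniform(box_lo, box_hi, size=(n_vars, 2))
    positions[centre] = (0.0, 0.0)
    positions[pin] = (0.0, H)
    mobile = np.ones(n_masses, dtype=np.bool_)
    mobile[[centre, pin]] = False

    var_idx = np.arange(n_vars, dtype=np.int64)
    p_ei = np.concatenate([var_idx, var_idx, ci])
    p_ej = np.concatenate(
        [np.full(n_vars, centre), np.full(n_vars, pin), cj]
    ).astype(np.int64)
    p_k = np.concatenate(
        [
            np.full(n_vars, anchor_stiffness),
            np.full(n_vars, anchor_stiffness),
            coupling_stiffness * np.abs(J),
        ]
    )
    p_l = np.concatenate(
        [np.ones(n_vars), np.full(n_vars, H), np.where(J > 0, 0.0, 2.0)]
    )
    p_plastic = np.zeros(p_ei.size, np.bool_)

    p_only = SpringNetwork.from_arrays(
        positions.copy(),
        p_ei,
        p_ej,
        p_k,
        p_l,
        p_plastic,
        np.full(p_ei.size, creep_rate),
        mobile=mobile,
        disturb_box=(box_lo, box_hi),
    )

    l_keep = rng.random(pi.size) < l_connect
    l_i, l_j = pi[l_keep], pj[l_keep]
    l_len = rng.uniform(l_lo, l_hi, size=l_i.size)
    combined = SpringNetwork.from_arrays(
        positions.copy(),
        np.concatenate([p_ei, l_i]),
        np.concatenate([p_ej, l_j]),
        np.concatenate([p_k, np.full(l_i.size, l_stiffness)]),
        np.concatenate([p_l, l_len]),
        np.concatenate([p_plastic, np.ones(l_i.size, np.bool_)]),
        np.full(p_ei.size + l_i.size, creep_rate),
        mobile=mobile,
        disturb_box=(box_lo, box_hi),
    )

    problem = ProblemInstance(
        p_springs=p_only,
        couplings=couplings,
        variables=var_idx,
        meta={"anchor_stiffness": anchor_stiffness, "pin_offset": H},
    )
    return problem, combined


def spin_ground_state(
    couplings: np.ndarray, n_vars: int
) -> tuple[np.ndarray, float]:
    """Exhaustive ground state of E = −Σ J s_i s_j (feasible for n_vars ≤ 20).

    Returns (spins, energy); the Z2-symmetric partner −spins is equivalent.
    """
    if n_vars > 20:
        raise ParameterError("exhaustive enumeration is limited to n_vars <= 20")
    couplings = np.asarray(couplings, dtype=float)
    i = couplings[:, 0].astype(np.int64)
    j = couplings[:, 1].astype(np.int64)
    J = couplings[:, 2]
    codes = np.arange(2**n_vars, dtype=np.uint64)
    # spins[v] = ±1 from bit v of each code
    bits = (codes[:, None] >> np.arange(n_vars, dtype=np.uint64)) & np.uint64(1)
    spins = bits.astype(np.int8) * 2 - 1
    energies = -(spins[:, i] * spins[:, j] @ J)
    best = int(np.argmin(energies))
    return spins[best].astype(np.int64), float(energies[best])
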