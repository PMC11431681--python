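"""Measurement procedures.

* ``resettle_energy`` — the original-system energy V_o of a learned
  configuration: settle a pristine copy of the original springs from it and
  read off V.  The side assay never mutates its inputs.
* ``pca_embed`` — 2D PCA of equilibrium distance vectors (rigid-motion
  invariant histograms of visited attractors).
* ``cluster_attractors`` — single-linkage clustering of equilibria.
* ``std_score`` — how many baseline standard deviations the learned minimum
  lies below the baseline mean (computed on log energies by default).
* ``neutrality_check`` — does an unlearned L-layer distort the P-spring
  equilibrium distribution?  (Kolmogorov–Smirnov two-sample statistic.)
* ``binarised_energy`` — spin readout and coupling energy for the
  spin-glass/MaxCut scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA

from .dynamics import disturbance_box, settle
from .errors import AssayError, ContractError
from .model import (
    EquilibriumRecord,
    ProblemInstance,
    SimulationConfig,
    SpringNetwork,
)

__all__ = [
    "resettle_energy",
    "pca_embed",
    "PCAEmbedding",
    "cluster_attractors",
    "ClusterResult",
    "std_score",
    "neutrality_check",
    "NeutralityResult",
    "binarised_energy",
]

LOG_FLOOR = 1e-12


def resettle_energy(
    original_springs: SpringNetwork,
    positions: np.ndarray,
    config: SimulationConfig,
) -> float:
    """V_o: energy after settling a pristine copy of the original system
    from the given positions.  Inputs are never mutated and no learning
    occurs, so repeated calls are identical."""
    net = original_springs.copy()
    positions = np.asarray(positions, dtype=float)
    if positions.shape != net.positions.shape:
        raise ContractError("positions do not match the original network")
    net.positions[:] = positions
    rec = settle(net, config)
    return rec.energy_current


@dataclass
class PCAEmbedding:
    coords: np.ndarray  # (n_records, 2)
    explained_variance_ratio: np.ndarray
    pca: PCA

    def transform(self, records: Sequence[EquilibriumRecord]) -> np.ndarray:
        x = np.vstack([r.distance_vector for r in records])
        return self.pca.transform(x)


def pca_embed(
    records: Sequence[EquilibriumRecord],
    fit_records: Sequence[EquilibriumRecord] | None = None,
) -> PCAEmbedding:
    """First two principal components of the equilibrium distance vectors.

    The transform is fitted on ``fit_records`` (default: ``records``, i.e.
    the baseline sample) and then applied to ``records``, so learned records
    can be projected into the baseline's coordinate system.
    """
    if fit_records is None:
        fit_records = records
    if len(fit_records) < 3:
        raise AssayError("pca_embed needs at least 3 records to fit")
    x_fit = np.vstack([r.distance_vector for r in fit_records])
    pca = PCA(n_components=2)
    pca.fit(x_fit)
    x = np.vstack([r.distance_vector for r in records])
    return PCAEmbedding(
        coords=pca.transform(x),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        pca=pca,
    )


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster label per record, ordered by first occurrence
    counts: np.ndarray  # visits per cluster
    threshold: float

    @property
    def n_clusters(self) -> int:
        return int(self.counts.shape[0])


def cluster_attractors(
    records: Sequence[EquilibriumRecord], tol: float = 0.01
) -> ClusterResult:
    """Single-linkage clustering of distance vectors.

    Two equilibria belong to one attractor cluster when a chain of records
    with consecutive Euclidean gaps below ``tol·‖mean distance vector‖``
    connects them.  Deterministic given input order: labels are renumbered by
    first occurrence.
    """
    if len(records) == 0:
        raise AssayError("cluster_attractors needs at least one record")
    x = np.vstack([r.distance_vector for r in records])
    threshold = float(tol * np.linalg.norm(x.mean(axis=0)))
    if len(records) == 1:
        return ClusterResult(np.zeros(1, np.int64), np.ones(1, np.int64), threshold)
    raw = fcluster(linkage(pdist(x), method="single"), t=threshold, criterion="distance")
    labels = np.empty(raw.shape[0], dtype=np.int64)
    remap: dict[int, int] = {}
    for idx, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[idx] = remap[lab]
    counts = np.bincount(labels)
    return ClusterResult(labels, counts, threshold)


def std_score(
    baseline_energies: np.ndarray,
    learned_min_energy: float,
    *,
    log: bool = True,
    floor: float = LOG_FLOOR,
) -> float:
    """Standard-deviation score of a learned energy against a baseline sample.

    score = (mean(b) − e) / std(b, ddof=1), with b and e taken on the log
    scale by default (equilibrium energies are closer to log-normal).
    Positive when the learned energy lies below the baseline mean; invariant
    under rescaling all energies by a positive constant.
    """
    b = np.asarray(baseline_energies, dtype=float)
    if b.size < 2:
        raise AssayError("std_score needs at least 2 baseline energies")
    e = float(learned_min_energy)
    if log:
        b = np.log(np.maximum(b, floor))
        e = float(np.log(max(e, floor)))
    sd = float(b.std(ddof=1))
    if sd == 0.0:
        raise AssayError("baseline energies have zero variance")
    return float((b.mean() - e) / sd)


@dataclass
class NeutralityResult:
    energies_p_only: np.ndarray
    energies_resettled: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    paired_median_abs_diff: float  # start-by-start |A−B|, sharper than the KS


def neutrality_check(
    problem: ProblemInstance,
    combined: SpringNetwork,
    config: SimulationConfig,
    n_samples: int = 100,
    rng: np.random.Generator | None = None,
) -> NeutralityResult:
    """Does a pristine L-layer distort the P-spring equilibrium energies?

    Sample A: settle the P-only system from random starts.  Sample B: settle
    the combined P+L system from the same starts, strip the L-springs,
    resettle, and record the P energy.  If the L-layer is initially neutral
    the two samples are drawn from nearly identical distributions (small KS
    statistic)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = disturbance_box(combined, config)
    n_mobile = int(combined.mobile.sum())
    e_a = np.empty(n_samples)
    e_b = np.empty(n_samples)
    p_net = problem.p_springs.copy()
    for s in range(n_samples):
        start = rng.uniform(lo, hi, size=(n_mobile, 2))
        p_net.positions[p_net.mobile] = start
        e_a[s] = settle(p_net, config).energy_current
        c_net = combined.copy()
        c_net.positions[c_net.mobile] = start
        settle(c_net, config)
        stripped = c_net.without_plastic()
        e_b[s] = settle(stripped, config).energy_current
    ks = ks_2samp(e_a, e_b)
    return NeutralityResult(
        e_a,
        e_b,
        float(ks.statistic),
        float(ks.pvalue),
        float(np.median(np.abs(e_a - e_b))),
    )


def binarised_energy(
    problem: ProblemInstance, positions: np.ndarray
) -> tuple[np.ndarray, float]:
    """Spin vector (sign of the variable coordinates, ties to +1) and its
    coupling energy E = −Σ J s_i s_j."""
    if problem.couplings is None:
        raise ContractError("problem has no couplings to score against")
    spins = problem.binarise(positions)
    return spins, problem.coupling_energy(spins)
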