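"""Spin-diabatic <-> spin-adiabatic machinery.

The two-component Hamiltonian in the truncated spin-diabatic basis Theta
(singlets, then the three M_S components of each triplet) is the complex
Hermitian matrix

    H = diag(scalar energies) + alpha * V_SOC

where alpha >= 1 is the SOC acceleration factor (scaling applied to the
singlet--triplet couplings only, never to the diagonal).  Diagonalizing,
H U = U E, yields the spin-adiabatic states Phi = Theta U in which the
surface-hopping dynamics runs.  A wavefunction expanded in Phi with
coefficients c has spin-diabatic amplitudes b = U c, and |b_i|^2 are the
singlet/triplet-component populations whose ensemble averages (components
summed per triplet) constitute the reported population curves.

Gauge fixing along a trajectory: eigenvectors returned by the solver carry
arbitrary phases and may reorder between steps.  ``align_gauge`` matches
columns to the previous step by maximal |overlap| (linear-sum assignment)
and rotates each matched column's phase so its overlap with the previous
column is real non-negative.  Columns belonging to a near-degenerate
eigenvalue cluster are aligned jointly by a unitary Procrustes rotation
within the cluster, since individual eigenvectors are arbitrary there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SpinHamiltonian",
    "QuasiRelStates",
    "assemble_spin_hamiltonian",
    "diagonalize_spin_hamiltonian",
    "align_gauge",
    "back_transform",
    "ensemble_populations",
    "PopulationSeries",
    "sum_triplet_components",
]

logger = logging.getLogger(__name__)

HERMITICITY_RTOL = 1e-12
DEGENERACY_GAP_HARTREE = 1e-10


@dataclass
class SpinHamiltonian:
    """Complex Hermitian two-component Hamiltonian plus its SOC scaling."""

    matrix: np.ndarray
    alpha: float
    n_singlets: int
    n_triplets: int

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]


@dataclass
class QuasiRelStates:
    """Eigen-decomposition H U = U E: spin-adiabatic energies and vectors."""

    energies: np.ndarray   # real, ascending as produced (may be permuted by alignment)
    vectors: np.ndarray    # unitary, columns are spin-adiabatic states


def assemble_spin_hamiltonian(
    scalar_energies: np.ndarray,
    soc_matrix: np.ndarray,
    alpha: float,
    n_singlets: int,
    n_triplets: int,
) -> SpinHamiltonian:
    """H = diag(E_scalar) + alpha * V_SOC.

    ``scalar_energies`` has length n_S + 3 n_T (triplet components already
    expanded); ``soc_matrix`` is the full Hermitian SOC matrix with zero
    diagonal.  Only the coupling block is scaled by alpha.
    """
    e = np.asarray(scalar_energies, dtype=float)
    v = np.asarray(soc_matrix, dtype=complex)
    n = n_singlets + 3 * n_triplets
    if e.shape != (n,) or v.shape != (n, n):
        raise ValueError("dimension mismatch between energies and SOC matrix")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    scale = max(np.abs(v).max(), 1.0)
    if np.abs(v - v.conj().T).max() > 1e-10 * scale:
        raise ValueError("SOC matrix is not Hermitian within tolerance")
    h = np.diag(e).astype(complex) + alpha * v
    return SpinHamiltonian(matrix=h, alpha=alpha, n_singlets=n_singlets, n_triplets=n_triplets)


def diagonalize_spin_hamiltonian(h: SpinHamiltonian) -> QuasiRelStates:
    """Solve H U = U E with ascending eigenvalues and unitary U."""
    m = h.matrix
    if not np.all(np.isfinite(m.real)) or not np.all(np.isfinite(m.imag)):
        raise ValueError("non-finite Hamiltonian entries")
    energies, vectors = np.linalg.eigh(m)
    return QuasiRelStates(energies=energies, vectors=vectors)


def _degenerate_clusters(energies: np.ndarray, gap: float) -> List[np.ndarray]:
    """Group indices whose energies lie within ``gap`` of a chain neighbor.

    The input need not be sorted (alignment permutes eigenvalues into
    matched-column order); clustering is done on the sorted values and
    the original indices are returned.
    """
    order = np.argsort(energies)
    clusters, current = [], [order[0]]
    for k in order[1:]:
        if energies[k] - energies[current[-1]] < gap:
            current.append(k)
        else:
            clusters.append(np.array(current))
            current = [k]
    clusters.append(np.array(current))
    return clusters


def align_gauge(
    u_prev: np.ndarray,
    u_curr: np.ndarray,
    energies: Optional[np.ndarray] = None,
    overlap: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Match and phase-fix eigenvector columns against the previous step.

    Returns ``(u_aligned, permutation)`` where ``u_aligned[:, k]`` is the
    continuation of ``u_prev[:, k]`` and ``permutation[k]`` is the original
    column index it came from (so eigenvalues must be permuted the same
    way).  ``overlap`` may supply a precomputed u_prev^dagger u_curr (e.g.
    including a basis-overlap factor); otherwise it is computed directly.
    If ``energies`` is given, clusters with gaps below 1e-10 hartree are
    aligned jointly (unitary Procrustes) to avoid arbitrary mixing.
    """
    if u_prev.shape != u_curr.shape:
        raise ValueError("unitary matrices must share dimensions")
    n = u_prev.shape[1]
    ov = overlap if overlap is not None else u_prev.conj().T @ u_curr
    row, col = linear_sum_assignment(-np.abs(ov))
    perm = np.empty(n, dtype=int)
    perm[row] = col
    if logger.isEnabledFor(logging.DEBUG):
        # ambiguity diagnostic: competing |overlap| nearly equal
        absov = np.abs(ov)
        for k in range(n):
            best = absov[k, perm[k]]
            rivals = np.delete(absov[k], perm[k])
            if rivals.size and best - rivals.max() < 1e-12:
                logger.debug("align_gauge: degenerate matching at column %d, "
                             "resolved by assignment/index order", k)
    u = u_curr[:, perm]
    ov_p = ov[:, perm]

    if energies is not None:
        e_perm = np.asarray(energies)[perm]
        clusters = _degenerate_clusters(e_perm, DEGENERACY_GAP_HARTREE)
    else:
        clusters = [np.array([k]) for k in range(n)]

    for cl in clusters:
        if len(cl) == 1:
            k = cl[0]
            z = ov_p[k, k]
            phase = z / abs(z) if abs(z) > 0 else 1.0
            u[:, k] = u[:, k] * np.conj(phase)
        else:
            # joint alignment: closest unitary to the overlap block
            m = ov_p[np.ix_(cl, cl)]
            w, _, vh = np.linalg.svd(m)
            t = w @ vh                     # polar factor of the overlap
            u[:, cl] = u[:, cl] @ t.conj().T
    return u, perm


def back_transform(u: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Spin-diabatic amplitudes b = U c of a spin-adiabatic coefficient vector."""
    c = np.asarray(c, dtype=complex)
    if u.shape[1] != c.shape[0]:
        raise ValueError("dimension mismatch between U and c")
    norm = np.linalg.norm(c)
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"coefficient vector must be normalized, |c| = {norm}")
    return u @ c


def sum_triplet_components(
    populations: np.ndarray, n_singlets: int, n_triplets: int
) -> np.ndarray:
    """Merge the three M_S components of each triplet (last axis)."""
    pops = np.asarray(populations)
    singlet = pops[..., :n_singlets]
    triplet = pops[..., n_singlets:].reshape(pops.shape[:-1] + (n_triplets, 3)).sum(axis=-1)
    return np.concatenate([singlet, triplet], axis=-1)


@dataclass
class PopulationSeries:
    """Ensemble-averaged spin-diabatic populations on a common time grid."""

    times_fs: np.ndarray            # (n_times,)
    populations: np.ndarray         # (n_times, n_S + n_T), triplet components merged
    n_singlets: int
    n_triplets: int
    n_trajectories: int = 0

    def labels(self) -> List[str]:
        return [f"S{i}" for i in range(self.n_singlets)] + [
            f"T{j + 1}" for j in range(self.n_triplets)
        ]

    def select(self, which) -> np.ndarray:
        """Summed population of a state subset.

        ``which`` is a label ("S1", "T3"), a list of labels, or one of the
        shorthands "singlets", "triplets", "excited_singlets".
        """
        labels = self.labels()
        if isinstance(which, str):
            if which == "singlets":
                which = labels[: self.n_singlets]
            elif which == "excited_singlets":
                which = labels[1 : self.n_singlets]
            elif which == "triplets":
                which = labels[self.n_singlets :]
            else:
                which = [which]
        idx = [labels.index(w) for w in which]
        return self.populations[:, idx].sum(axis=1)


def ensemble_populations(trajectories: Sequence, time_grid=None) -> PopulationSeries:
    """Average spin-diabatic populations over an ensemble of trajectories.

    Trajectories are truncated to the common time range; the per-time,
    per-state mean of |b_i|^2 is returned with the three components of
    each triplet summed.  The state sum is 1 at every time.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("empty ensemble")
    n_s = trajectories[0].n_singlets
    n_t = trajectories[0].n_triplets
    n_steps = min(len(t.times_fs) for t in trajectories)
    times = trajectories[0].times_fs[:n_steps]
    for t in trajectories:
        if not np.allclose(t.times_fs[:n_steps], times, atol=1e-9):
            raise ValueError("trajectories do not share a common time grid")
    stacked = np.stack([t.diabatic_populations[:n_steps] for t in trajectories])
    mean = stacked.mean(axis=0)
    merged = sum_triplet_components(mean, n_s, n_t)
    return PopulationSeries(
        times_fs=times.copy(),
        populations=merged,
        n_singlets=n_s,
        n_triplets=n_t,
        n_trajectories=len(trajectories),
    )
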