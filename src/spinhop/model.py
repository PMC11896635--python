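"""Model electronic-structure provider: linear-vibronic-coupling surfaces.

This module stands in for an on-the-fly quantum-chemistry backend.  It
defines harmonic nuclear modes carrying diabatic singlet and triplet
electronic surfaces in linear-vibronic-coupling (LVC) form, a geometry
dependent spin--orbit coupling (SOC) block, and transition properties
(oscillator strengths, Condon approximation).

Spin-diabatic basis ordering (asserted by every downstream module):
singlets first, in ascending vertical energy at the origin (index 0 is the
closed-shell ground state), then triplets, each as a contiguous block of
three components.  Component index 0, 1, 2 denotes M_S = -1, 0, +1.

The LVC potential matrix in the primitive diabatic basis is

    W_ii(x) = E_i + sum_k kappa_ik dx_k + sum_k 1/2 m_k w_k^2 dx_k^2
    W_ij(x) = sum_k lambda_ijk dx_k                (same-spin off-diagonal)

with dx_k = x_k - x0_k.  All states share the ground-state harmonic
curvature; crossings between surfaces arise from the state-specific
vertical energies E_i and gradients kappa.  The spin-diabatic states used
by the dynamics are the eigenstates of the same-spin blocks of W; with all
lambda = 0 they coincide with the primitive diabatic states.

Units: constructors take eV, cm^-1, amu; coordinates are per-mode
displacements in bohr (momenta in a.u.); every quantity stored on a
ModelSystem and returned by ``evaluate_model`` is in Hartree atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .constants import (
    AMU_ME,
    amu_to_me,
    cm1_to_hartree,
    ev_to_hartree,
    omega_au_from_cm1,
)

__all__ = [
    "ModeSpec",
    "ElectronicSpec",
    "SOCModulation",
    "SOCSpec",
    "ModelSystem",
    "ModelEvaluation",
    "build_lvc_model",
    "evaluate_model",
    "soc_modulation",
]


class ModelValidationError(ValueError):
    """Raised when a model definition violates a structural invariant."""


@dataclass(frozen=True)
class ModeSpec:
    """One harmonic nuclear mode.

    Parameters
    ----------
    frequency_cm1:
        Harmonic wavenumber in cm^-1, strictly positive.
    reduced_mass_amu:
        Reduced mass in amu, strictly positive.
    equilibrium:
        Coordinate origin of the mode (bohr).  Defaults to 0.
    name:
        Optional label, used to address the mode from SOC modulations.
    """

    frequency_cm1: float
    reduced_mass_amu: float
    equilibrium: float = 0.0
    name: Optional[str] = None

    def __post_init__(self):
        if not self.frequency_cm1 > 0:
            raise ModelValidationError(
                f"mode frequency must be > 0 cm^-1, got {self.frequency_cm1}"
            )
        if not self.reduced_mass_amu > 0:
            raise ModelValidationError(
                f"mode reduced mass must be > 0 amu, got {self.reduced_mass_amu}"
            )


# key of an interstate (same-spin) linear coupling: (block, i, j, mode)
CouplingKey = Tuple[str, int, int, int]


@dataclass
class ElectronicSpec:
    """Diabatic electronic structure at the origin plus linear couplings.

    ``vertical_energies_ev`` lists singlets first (ground state is index 0
    and must be the singlet minimum), then triplets.
    ``intrastate_gradients_ev`` (kappa) has shape (n_states, n_modes) in
    eV/bohr; ``interstate_couplings_ev`` (lambda) maps
    ("singlet"|"triplet", i, j, mode) -> eV/bohr with i < j indices inside
    the spin block.  ``oscillator_strengths`` has one entry per excited
    singlet (S1..S_{n_singlets-1}).
    """

    n_singlets: int
    n_triplets: int
    vertical_energies_ev: Sequence[float]
    intrastate_gradients_ev: Optional[np.ndarray] = None
    interstate_couplings_ev: Dict[CouplingKey, float] = field(default_factory=dict)
    oscillator_strengths: Optional[Sequence[float]] = None


@dataclass(frozen=True)
class SOCModulation:
    """Geometry dependence of SOC magnitudes along one coordinate.

    The magnitude of each affected SOC entry becomes

        |V|(dx) = max(0, |V0| + linear * dx + quadratic * dx^2)

    where dx is the displacement of the named mode from its equilibrium
    (in the mode's coordinate unit) and the complex phase of V0 is kept.
    ``entries`` restricts the modulation to specific (singlet, triplet,
    component) keys; None applies it to every entry.
    """

    coordinate: Union[str, int]
    linear_cm1: float = 0.0
    quadratic_cm1: float = 0.0
    entries: Optional[Tuple[Tuple[int, int, int], ...]] = None


@dataclass
class SOCSpec:
    """Singlet--triplet spin--orbit couplings in the diabatic basis.

    ``base_soc_cm1`` maps (singlet index, triplet index, component) to a
    complex coupling in cm^-1; component 0, 1, 2 is M_S = -1, 0, +1.
    """

    base_soc_cm1: Dict[Tuple[int, int, int], complex] = field(default_factory=dict)
    modulation: List[SOCModulation] = field(default_factory=list)


@dataclass
class ModelSystem:
    """Validated model: modes + electronic surfaces + SOC, all in a.u.

    Built by :func:`build_lvc_model`; fields with the ``_au`` suffix are
    precomputed atomic-unit arrays used by the dynamics.
    """

    modes: List[ModeSpec]
    electronic: ElectronicSpec
    soc: SOCSpec
    label: str = ""

    # ---- derived, atomic units (filled by build_lvc_model) ----
    masses_au: np.ndarray = None
    omegas_au: np.ndarray = None
    x0: np.ndarray = None
    energies0_au: np.ndarray = None          # (n_S + n_T,)
    kappa_au: np.ndarray = None              # (n_S + n_T, n_modes)
    lam_s_au: np.ndarray = None              # (n_S, n_S, n_modes)
    lam_t_au: np.ndarray = None              # (n_T, n_T, n_modes)
    soc_base_au: np.ndarray = None           # (n_S, n_T, 3) complex
    oscillator_strengths: np.ndarray = None  # (n_S - 1,)

    # ------------------------------------------------------------------
    @property
    def _has_interstate(self) -> bool:
        """True when same-spin lambda couplings are present (then the
        spin-diabatic basis differs from the primitive diabatic one)."""
        return bool(np.any(self.lam_s_au) or np.any(self.lam_t_au))

    @property
    def n_singlets(self) -> int:
        return self.electronic.n_singlets

    @property
    def n_triplets(self) -> int:
        return self.electronic.n_triplets

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def dimension(self) -> int:
        """Spin-diabatic basis dimension n_S + 3 n_T."""
        return self.n_singlets + 3 * self.n_triplets

    @property
    def n_states(self) -> int:
        """Number of scalar electronic states (triplets counted once)."""
        return self.n_singlets + self.n_triplets

    def mode_index(self, coordinate: Union[str, int]) -> int:
        if isinstance(coordinate, (int, np.integer)):
            idx = int(coordinate)
            if not 0 <= idx < self.n_modes:
                raise KeyError(f"mode index {idx} out of range")
            return idx
        for k, m in enumerate(self.modes):
            if m.name == coordinate:
                return k
        raise KeyError(f"no mode named {coordinate!r}")

    # ------------------------------------------------------------------
    def _check_coords(self, coords: np.ndarray) -> np.ndarray:
        x = np.asarray(coords, dtype=float)
        if x.shape != (self.n_modes,):
            raise ValueError(
                f"coords must have shape ({self.n_modes},), got {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        return x

    def harmonic(self, x: np.ndarray) -> Tuple[float, np.ndarray]:
        """Common harmonic potential and its gradient at x (a.u.)."""
        dx = x - self.x0
        k = self.masses_au * self.omegas_au**2
        return 0.5 * float(np.dot(k, dx * dx)), k * dx

    def scalar_blocks(self, coords) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Same-spin diabatic potential blocks W_S, W_T and their gradients.

        Returns (W_S, W_T, dW_S, dW_T) with dW_* of shape
        (n_modes, n, n); all in hartree / hartree-per-bohr.
        """
        x = self._check_coords(coords)
        dx = x - self.x0
        vharm, dvharm = self.harmonic(x)
        n_s, n_t = self.n_singlets, self.n_triplets
        diag = self.energies0_au + self.kappa_au @ dx + vharm

        w_s = np.diag(diag[:n_s]) + np.einsum("ijk,k->ij", self.lam_s_au, dx)
        w_t = np.diag(diag[n_s:]) + np.einsum("ijk,k->ij", self.lam_t_au, dx)

        nm = self.n_modes
        dw_s = np.transpose(self.lam_s_au, (2, 0, 1)).copy()
        dw_t = np.transpose(self.lam_t_au, (2, 0, 1)).copy()
        for k in range(nm):
            dd = self.kappa_au[:, k] + dvharm[k]
            dw_s[k][np.diag_indices(n_s)] += dd[:n_s]
            dw_t[k][np.diag_indices(n_t)] += dd[n_s:]
        return w_s, w_t, dw_s, dw_t

    def soc_blocks(self, coords) -> Tuple[np.ndarray, np.ndarray]:
        """SOC array (n_S, n_T, 3) and gradient (n_modes, n_S, n_T, 3).

        Applies the configured magnitude modulations; phases of the base
        couplings are preserved.  A magnitude driven below zero is clamped
        to zero (gradient zero there).
        """
        x = self._check_coords(coords)
        v = self.soc_base_au.copy()
        dv = np.zeros((self.n_modes,) + v.shape, dtype=complex)
        if not self.soc.modulation:
            return v, dv

        mag = np.abs(v)
        phase = np.where(mag > 0, v / np.where(mag > 0, mag, 1.0), 1.0 + 0j)
        dmag = np.zeros((self.n_modes,) + mag.shape)
        for mod in self.soc.modulation:
            k = self.mode_index(mod.coordinate)
            dxk = x[k] - self.x0[k]
            lin = cm1_to_hartree(mod.linear_cm1)
            quad = cm1_to_hartree(mod.quadratic_cm1)
            add = lin * dxk + quad * dxk * dxk
            dadd = lin + 2.0 * quad * dxk
            if mod.entries is None:
                mag = mag + add
                dmag[k] += dadd
            else:
                for key in mod.entries:
                    mag[key] += add
                    dmag[(k,) + tuple(key)] += dadd
        clamped = mag < 0
        mag = np.where(clamped, 0.0, mag)
        dmag[:, clamped] = 0.0
        return phase * mag, phase[None] * dmag

    def evaluate(self, coords, prev_vectors=None) -> "ModelEvaluation":
        """Scalar spin-diabatic states, gradients and SOC at a geometry.

        Diagonalizes the same-spin LVC blocks; energies come out in
        ascending order within each spin manifold unless ``prev_vectors``
        (a previous evaluation's (C_S, C_T)) is supplied, in which case
        columns are matched to the previous step by maximal overlap for
        continuity along a trajectory.
        """
        if not self._has_interstate:
            # diagonal same-spin blocks: the spin-diabatic basis is the
            # primitive diabatic basis, no eigensolve or rotation needed
            x = self._check_coords(coords)
            dx = x - self.x0
            vharm, dvharm = self.harmonic(x)
            n_s = self.n_singlets
            diag = self.energies0_au + self.kappa_au @ dx + vharm
            e_s, e_t = diag[:n_s], diag[n_s:]
            c_s = np.eye(n_s)
            c_t = np.eye(self.n_triplets)
            grads = self.kappa_au + dvharm[None, :]
            grad_s_mat = np.zeros((self.n_modes, n_s, n_s))
            grad_t_mat = np.zeros((self.n_modes, self.n_triplets, self.n_triplets))
            for k in range(self.n_modes):
                np.fill_diagonal(grad_s_mat[k], grads[:n_s, k])
                np.fill_diagonal(grad_t_mat[k], grads[n_s:, k])
            soc_sd, dsoc_sd = self.soc_blocks(coords)
            return ModelEvaluation(
                model=self,
                coords=np.asarray(coords, dtype=float),
                singlet_energies=e_s,
                triplet_energies=e_t,
                singlet_vectors=c_s,
                triplet_vectors=c_t,
                gradients=grads,
                singlet_grad_matrix=grad_s_mat,
                triplet_grad_matrix=grad_t_mat,
                soc=soc_sd,
                soc_gradient=dsoc_sd,
                oscillator_strengths=self.oscillator_strengths.copy(),
            )

        w_s, w_t, dw_s, dw_t = self.scalar_blocks(coords)
        e_s, c_s = np.linalg.eigh(w_s)
        e_t, c_t = np.linalg.eigh(w_t)
        if prev_vectors is not None:
            e_s, c_s = _match_real(prev_vectors[0], e_s, c_s)
            e_t, c_t = _match_real(prev_vectors[1], e_t, c_t)
        else:
            c_s = _fix_signs(c_s)
            c_t = _fix_signs(c_t)

        grad_s_mat = np.einsum("si,kst,tj->kij", c_s, dw_s, c_s)
        grad_t_mat = np.einsum("si,kst,tj->kij", c_t, dw_t, c_t)
        grad_s = np.einsum("kii->ik", grad_s_mat)
        grad_t = np.einsum("kii->ik", grad_t_mat)

        v, dv = self.soc_blocks(coords)
        soc_sd = np.einsum("si,stm,tj->ijm", c_s, v, c_t)
        dsoc_sd = np.einsum("si,kstm,tj->kijm", c_s, dv, c_t)
        return ModelEvaluation(
            model=self,
            coords=np.asarray(coords, dtype=float),
            singlet_energies=e_s,
            triplet_energies=e_t,
            singlet_vectors=c_s,
            triplet_vectors=c_t,
            gradients=np.vstack([grad_s, grad_t]),
            singlet_grad_matrix=grad_s_mat,
            triplet_grad_matrix=grad_t_mat,
            soc=soc_sd,
            soc_gradient=dsoc_sd,
            oscillator_strengths=self.oscillator_strengths.copy(),
        )


def _fix_signs(c: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each eigenvector positive."""
    if c.size == 0:
        return c
    idx = np.argmax(np.abs(c), axis=0)
    signs = np.sign(c[idx, np.arange(c.shape[1])])
    signs[signs == 0] = 1.0
    return c * signs


def _match_real(c_prev: np.ndarray, e: np.ndarray, c: np.ndarray):
    """Reorder/sign-fix real eigenvectors to follow a previous step."""
    n = c.shape[1]
    if n == 1:
        s = 1.0 if float(c_prev[:, 0] @ c[:, 0]) >= 0 else -1.0
        return e, c * s
    from scipy.optimize import linear_sum_assignment

    ov = c_prev.T @ c
    row, col = linear_sum_assignment(-np.abs(ov))
    perm = np.empty(n, dtype=int)
    perm[row] = col
    c = c[:, perm]
    e = e[perm]
    signs = np.sign(np.einsum("ij,ij->j", c_prev, c))
    signs[signs == 0] = 1.0
    return e, c * signs


@dataclass
class ModelEvaluation:
    """Everything the dynamics needs at one geometry (atomic units)."""

    model: ModelSystem
    coords: np.ndarray
    singlet_energies: np.ndarray     # (n_S,)
    triplet_energies: np.ndarray     # (n_T,)
    singlet_vectors: np.ndarray      # (n_S, n_S) real orthogonal
    triplet_vectors: np.ndarray      # (n_T, n_T)
    gradients: np.ndarray            # (n_S + n_T, n_modes), Hellmann-Feynman
    singlet_grad_matrix: np.ndarray  # (n_modes, n_S, n_S), dW_S in the eigenbasis
    triplet_grad_matrix: np.ndarray  # (n_modes, n_T, n_T)
    soc: np.ndarray                  # (n_S, n_T, 3) complex, in the scalar eigenbasis
    soc_gradient: np.ndarray         # (n_modes, n_S, n_T, 3)
    oscillator_strengths: np.ndarray

    @property
    def scalar_energies_full(self) -> np.ndarray:
        """Energies expanded to dimension n_S + 3 n_T (components equal)."""
        return np.concatenate(
            [self.singlet_energies, np.repeat(self.triplet_energies, 3)]
        )

    def soc_matrix(self) -> np.ndarray:
        """Full (N, N) Hermitian SOC matrix (unscaled) in the spin-diabatic basis."""
        return expand_soc(self.soc, self.model.n_singlets, self.model.n_triplets)


def expand_soc(soc: np.ndarray, n_singlets: int, n_triplets: int) -> np.ndarray:
    """Embed an (n_S, n_T, 3) SOC array into the full (N, N) Hermitian matrix."""
    n = n_singlets + 3 * n_triplets
    m = np.zeros((n, n), dtype=complex)
    for j in range(n_triplets):
        cols = slice(n_singlets + 3 * j, n_singlets + 3 * j + 3)
        m[:n_singlets, cols] = soc[:, j, :]
    m += m.conj().T - np.diag(np.diag(m))
    return m


# ----------------------------------------------------------------------
def build_lvc_model(
    spec: ElectronicSpec,
    modes: Sequence[ModeSpec],
    soc: Optional[SOCSpec] = None,
    label: str = "",
) -> ModelSystem:
    """Validate a model definition and precompute its atomic-unit arrays.

    Raises :class:`ModelValidationError` on dimension mismatches, negative
    frequencies/masses, a ground state that is not the singlet minimum, or
    out-of-range SOC/coupling indices.
    """
    soc = soc or SOCSpec()
    modes = list(modes)
    n_s, n_t, nm = spec.n_singlets, spec.n_triplets, len(modes)
    if n_s < 1 or n_t < 0:
        raise ModelValidationError("need n_singlets >= 1 and n_triplets >= 0")
    if nm < 1:
        raise ModelValidationError("need at least one mode")

    e0 = np.asarray(spec.vertical_energies_ev, dtype=float)
    if e0.shape != (n_s + n_t,):
        raise ModelValidationError(
            f"vertical_energies_ev must have length {n_s + n_t}, got {e0.shape}"
        )
    if e0[0] > e0[:n_s].min():
        raise ModelValidationError("state 0 must be the singlet minimum at the origin")
    if np.any(np.diff(e0[:n_s]) < 0):
        raise ModelValidationError(
            "singlet vertical energies must be ascending (basis ordering contract)"
        )

    if spec.intrastate_gradients_ev is None:
        kappa = np.zeros((n_s + n_t, nm))
    else:
        kappa = np.asarray(spec.intrastate_gradients_ev, dtype=float)
        if kappa.shape != (n_s + n_t, nm):
            raise ModelValidationError(
                f"intrastate_gradients_ev must have shape ({n_s + n_t}, {nm})"
            )

    lam_s = np.zeros((n_s, n_s, nm))
    lam_t = np.zeros((n_t, n_t, nm))
    for (block, i, j, k), val in spec.interstate_couplings_ev.items():
        tgt, nb = (lam_s, n_s) if block == "singlet" else (lam_t, n_t)
        if block not in ("singlet", "triplet"):
            raise ModelValidationError(f"unknown coupling block {block!r}")
        if not (0 <= i < nb and 0 <= j < nb and i != j and 0 <= k < nm):
            raise ModelValidationError(f"coupling key {(block, i, j, k)} out of range")
        v = ev_to_hartree(float(val))
        tgt[i, j, k] = v
        tgt[j, i, k] = v

    if spec.oscillator_strengths is None:
        osc = np.zeros(max(n_s - 1, 0))
    else:
        osc = np.asarray(spec.oscillator_strengths, dtype=float)
        if osc.shape != (n_s - 1,):
            raise ModelValidationError(
                f"oscillator_strengths must have length {n_s - 1}"
            )
        if np.any(osc < 0):
            raise ModelValidationError("oscillator strengths must be >= 0")

    soc_base = np.zeros((n_s, n_t, 3), dtype=complex)
    for (i, j, m), val in soc.base_soc_cm1.items():
        if not (0 <= i < n_s and 0 <= j < n_t and 0 <= m < 3):
            raise ModelValidationError(f"SOC key {(i, j, m)} out of range")
        soc_base[i, j, m] = cm1_to_hartree(complex(val))

    model = ModelSystem(
        modes=modes,
        electronic=spec,
        soc=soc,
        label=label,
        masses_au=np.array([amu_to_me(m.reduced_mass_amu) for m in modes]),
        omegas_au=np.array([omega_au_from_cm1(m.frequency_cm1) for m in modes]),
        x0=np.array([m.equilibrium for m in modes], dtype=float),
        energies0_au=ev_to_hartree(e0),
        kappa_au=ev_to_hartree(kappa),
        lam_s_au=lam_s,
        lam_t_au=lam_t,
        soc_base_au=soc_base,
        oscillator_strengths=osc,
    )
    for mod in soc.modulation:
        model.mode_index(mod.coordinate)  # raises on unresolvable name
    return model


def evaluate_model(model: ModelSystem, coords) -> ModelEvaluation:
    """Evaluate scalar energies, analytic gradients, SOC and dipole data.

    The returned energies/gradients are those of the spin-diabatic states
    (eigenstates of the same-spin LVC blocks); the three components of each
    triplet share the scalar energy.  See :class:`ModelEvaluation`.
    """
    return model.evaluate(coords)


def soc_modulation(model: ModelSystem, coords) -> np.ndarray:
    """Geometry-dependent full (N, N) SOC matrix in the spin-diabatic basis."""
    return model.evaluate(coords).soc_matrix()
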