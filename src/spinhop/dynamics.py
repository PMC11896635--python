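"""Fewest-switches surface hopping in the spin-adiabatic representation.

One nuclear step of length ``dt`` (default 0.5 fs) is a three-stage cycle:

1. velocity-Verlet update of coordinates/momenta with the Hellmann-Feynman
   force of the active spin-adiabatic surface;
2. diagonalization of the two-component Hamiltonian at the new geometry,
   followed by gauge alignment (column matching + phase fixing) against
   the previous step;
3. substepped unitary propagation of the electronic coefficients (default
   20 substeps, 0.025 fs) in locally diabatized form — the end-of-step
   Hamiltonian is rotated into the step-start eigenframe with the unitary
   eigenvector overlap, linearly interpolated across the substeps and
   applied as exact matrix exponentials (see
   :func:`propagate_step_ld`) — and a single fewest-switches hop decision
   per nuclear step with probabilities from the total step propagator.

No decoherence correction is applied anywhere: the electronic coefficients
evolve strictly unitarily between hops.  Accepted hops rescale the full
momentum vector by a single scalar so total energy is conserved exactly;
an upward hop the kinetic energy cannot cover is "frustrated" (rejected,
momenta unchanged, logged).

For slowly varying eigenvectors the locally diabatized step is equivalent
to integrating ``i dc/dt = (E - i T) c`` (atomic units) with the
anti-Hermitian time-derivative coupling matrix T from
:func:`tdc_estimate`; that form, with its fewest-switches flux
``g_j = max(0, 2 Re(c_a^* T_aj c_j) dt / |c_a|^2)`` (sign convention:
coherent flow out of the active state gives positive g), is exposed as
:func:`electronic_propagate` / :func:`hop_probabilities`.  The locally
diabatized form is used by the driver because it stays exact through
narrow avoided crossings traversed within a single nuclear step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import fs_to_au
from .model import ModelEvaluation, ModelSystem, expand_soc
from .spin_mixing import (
    align_gauge,
    assemble_spin_hamiltonian,
    diagonalize_spin_hamiltonian,
)
from .wigner import WignerSample

__all__ = [
    "DynamicsParams",
    "TrajState",
    "HopEvent",
    "Trajectory",
    "GaugeError",
    "nuclear_step",
    "tdc_estimate",
    "electronic_propagate",
    "hop_probabilities",
    "apply_hop",
    "run_trajectory",
    "run_ensemble",
]

logger = logging.getLogger(__name__)


class GaugeError(RuntimeError):
    """Eigenvector inputs are not gauge-aligned (diagonal overlaps far from 1)."""


@dataclass(frozen=True)
class DynamicsParams:
    """Integration protocol.  Defaults: 0.5 fs nuclear steps, 20 electronic
    substeps (0.025 fs), 200 fs horizon, trajectories started in S1."""

    dt_fs: float = 0.5
    n_substeps: int = 20
    t_max_fs: float = 200.0
    alpha: float = 1.0
    initial_state: str = "S1"
    seed: int = 0
    decoherence: str = "none"   # fixed; any other value is rejected

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt_fs must be > 0")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        if self.t_max_fs < self.dt_fs:
            raise ValueError("t_max_fs must be >= dt_fs")
        if self.decoherence != "none":
            raise ValueError("no decoherence correction is implemented")


@dataclass
class TrajState:
    """Phase-space point + electronic state at one time."""

    t_fs: float
    coords: np.ndarray
    momenta: np.ndarray
    active: int
    c: np.ndarray


@dataclass
class HopEvent:
    t_fs: float
    from_state: int
    to_state: int
    u_at_hop: np.ndarray
    accepted: bool


@dataclass
class Trajectory:
    """Per-step record of one FSSH trajectory (times in fs, rest in a.u.)."""

    n_singlets: int
    n_triplets: int
    alpha: float
    seed: int
    times_fs: np.ndarray = None
    coords: np.ndarray = None                 # (n_steps, n_modes)
    momenta: np.ndarray = None
    active: np.ndarray = None                 # (n_steps,) spin-adiabatic index
    adiabatic_populations: np.ndarray = None  # |c|^2
    diabatic_populations: np.ndarray = None   # |b|^2, components unmerged
    total_energy_au: np.ndarray = None
    hops: List[HopEvent] = field(default_factory=list)
    truncated: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.times_fs)


# ----------------------------------------------------------------------
# building blocks

def _diabatic_rows(model: ModelSystem, label: str) -> List[int]:
    """Spin-diabatic basis row indices of a state label ("S1", "T3", ...)."""
    kind, num = label[0].upper(), int(label[1:])
    if kind == "S":
        if not 0 <= num < model.n_singlets:
            raise ValueError(f"no singlet {label}")
        return [num]
    if kind == "T":
        if not 1 <= num <= model.n_triplets:
            raise ValueError(f"no triplet {label}")
        base = model.n_singlets + 3 * (num - 1)
        return [base, base + 1, base + 2]
    raise ValueError(f"bad state label {label!r}")


def _primitive_vectors(ev: ModelEvaluation, u: np.ndarray) -> np.ndarray:
    """Spin-adiabatic eigenvectors expressed in the primitive diabatic basis.

    Folds the geometry-dependent scalar eigenvectors into U so overlaps
    between consecutive steps include the rotation of the spin-diabatic
    basis itself.
    """
    if not ev.model._has_interstate:
        return u        # scalar eigenbasis == primitive basis
    n_s, n_t = ev.model.n_singlets, ev.model.n_triplets
    n_cols = u.shape[1]
    w_s = ev.singlet_vectors @ u[:n_s, :]
    if n_t == 0:
        return w_s
    u_t = u[n_s:, :].reshape(n_t, 3, n_cols)
    w_t = np.einsum("pt,tmc->pmc", ev.triplet_vectors, u_t).reshape(3 * n_t, n_cols)
    return np.vstack([w_s, w_t])


def _adiabatic_force(ev: ModelEvaluation, a: np.ndarray, alpha: float) -> np.ndarray:
    """Hellmann-Feynman force of the spin-adiabatic state with coefficients a."""
    n_s, n_t = ev.model.n_singlets, ev.model.n_triplets
    a_s = a[:n_s]
    grad = np.einsum("s,kst,t->k", a_s.conj(), ev.singlet_grad_matrix, a_s)
    if n_t:
        a_t = a[n_s:].reshape(n_t, 3)
        grad = grad + np.einsum("sm,kst,tm->k", a_t.conj(), ev.triplet_grad_matrix, a_t)
        grad = grad + 2.0 * alpha * np.einsum(
            "s,kstm,tm->k", a_s.conj(), ev.soc_gradient, a_t
        )
    force = -np.real(grad)
    if not np.all(np.isfinite(force)):
        raise FloatingPointError("non-finite force")
    return force


def _spin_states(model: ModelSystem, ev: ModelEvaluation, alpha: float):
    """Assemble + diagonalize the spin Hamiltonian at one geometry."""
    h = assemble_spin_hamiltonian(
        ev.scalar_energies_full,
        expand_soc(ev.soc, model.n_singlets, model.n_triplets),
        alpha,
        model.n_singlets,
        model.n_triplets,
    )
    qr = diagonalize_spin_hamiltonian(h)
    return qr.energies, qr.vectors


def nuclear_step(state: TrajState, model: ModelSystem, params: DynamicsParams) -> TrajState:
    """One velocity-Verlet step on the active spin-adiabatic surface.

    Standalone contract (no gauge continuity across calls): the active
    surface is identified by its index in the ascending eigenvalue order
    at each geometry.  The trajectory driver uses the same update with
    gauge-tracked surfaces instead.
    """
    dt = fs_to_au(params.dt_fs)
    m = model.masses_au
    ev = model.evaluate(state.coords)
    _, u = _spin_states(model, ev, params.alpha)
    f = _adiabatic_force(ev, u[:, state.active], params.alpha)
    x_new = state.coords + state.momenta / m * dt + 0.5 * f / m * dt * dt
    ev_new = model.evaluate(x_new)
    _, u_new = _spin_states(model, ev_new, params.alpha)
    f_new = _adiabatic_force(ev_new, u_new[:, state.active], params.alpha)
    p_new = state.momenta + 0.5 * (f + f_new) * dt
    return TrajState(
        t_fs=state.t_fs + params.dt_fs,
        coords=x_new,
        momenta=p_new,
        active=state.active,
        c=state.c,
    )


def tdc_estimate(
    u_prev: np.ndarray,
    u_curr: np.ndarray,
    dt: float,
    overlap: Optional[np.ndarray] = None,
    min_diagonal: float = 0.5,
) -> np.ndarray:
    """Finite-difference time-derivative couplings from eigenvector overlaps.

    T = (O - O^dagger) / (2 dt) with O = U_prev^dagger U_curr (or a supplied
    overlap including basis rotation).  T is anti-Hermitian by construction;
    for real eigenvectors it reduces to the antisymmetric finite-difference
    coupling matrix.  ``dt`` in atomic units.  Raises :class:`GaugeError`
    when the inputs are not gauge-aligned.
    """
    o = overlap if overlap is not None else u_prev.conj().T @ u_curr
    if min_diagonal > 0 and np.abs(np.diag(o)).min() < min_diagonal:
        raise GaugeError(
            "diagonal overlaps far from 1; align_gauge the eigenvectors first"
        )
    return (o - o.conj().T) / (2.0 * dt)


def electronic_propagate(
    c: np.ndarray,
    e_prev: np.ndarray,
    e_curr: np.ndarray,
    t_prev: np.ndarray,
    t_curr: np.ndarray,
    dt: float,
    n_substeps: int,
    active: Optional[int] = None,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Substepped unitary propagation with linear interpolation of E and T.

    Each substep applies exp(-i H_eff dtau) exactly via eigendecomposition
    of the Hermitian H_eff = diag(E) - iT evaluated at the substep
    midpoint.  When ``active`` is given, the fewest-switches hop flux is
    accumulated substep-by-substep and returned alongside the new c; the
    returned fluxes are not yet clipped to sum <= 1.  ``dt`` in a.u.
    """
    c = np.asarray(c, dtype=complex).copy()
    n = len(c)
    flux = np.zeros(n) if active is not None else None
    dtau = dt / n_substeps
    # interpolate all substep midpoints at once and batch the eigensolves
    fm = (np.arange(n_substeps) + 0.5) / n_substeps
    e_mid = np.outer(1.0 - fm, e_prev) + np.outer(fm, e_curr)     # (S, n)
    t_mid = (1.0 - fm)[:, None, None] * t_prev + fm[:, None, None] * t_curr
    h_eff = -1j * t_mid
    idx = np.arange(n)
    h_eff[:, idx, idx] += e_mid
    w, v = np.linalg.eigh(h_eff)
    phases = np.exp(-1j * w * dtau)
    for s in range(n_substeps):
        if active is not None:
            ca = c[active]
            pa = abs(ca) ** 2
            if pa > 1e-12:
                out = 2.0 * np.real(np.conj(ca) * t_mid[s, active, :] * c) * dtau / pa
                out[active] = 0.0
                flux += np.maximum(out, 0.0)
        c = v[s] @ (phases[s] * (v[s].conj().T @ c))
    if not np.all(np.isfinite(c)):
        raise FloatingPointError("electronic propagation diverged")
    return c, flux


def propagate_step_ld(
    c: np.ndarray,
    e_prev: np.ndarray,
    e_curr: np.ndarray,
    overlap: np.ndarray,
    dt: float,
    n_substeps: int,
    active: Optional[int] = None,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """One nuclear step of electronic propagation, locally diabatized.

    Works in the fixed frame of the step-start eigenstates: the end-of-step
    Hamiltonian is rotated into that frame with the (unitary) eigenvector
    overlap O, H_curr' = O diag(E_curr) O^dagger, the Hamiltonian is
    linearly interpolated across ``n_substeps`` substeps (each applied as
    an exact matrix exponential), and the result is rotated into the new
    basis with O^dagger.  In the sudden limit (a narrow avoided crossing
    traversed within one step) this reduces to amplitudes exactly
    following their diabatic character — the regime where a propagator
    built on finite-difference couplings fails by orders of magnitude.
    In the slow limit it agrees with :func:`electronic_propagate`.

    When ``active`` is given, fewest-switches hop probabilities for the
    step are computed from the total step propagator P (c_new = P c) with
    the flux-partitioning formula

        g_j = (1 - |c_k'|^2 / |c_k|^2) *
              max(0, Re(c_j' P_jk^* c_k^*)) / sum_l max(0, Re(c_l' P_lk^* c_k^*))

    (k the active state, primes end-of-step values, the sum excluding k),
    which attributes the active-state population loss to the states that
    coherently received it.  Returns ``(c_new, g)``.
    """
    c = np.asarray(c, dtype=complex)
    n = len(c)
    o = np.asarray(overlap, dtype=complex)
    h_curr = (o * e_curr[None, :]) @ o.conj().T
    fm = (np.arange(n_substeps) + 0.5) / n_substeps
    dtau = dt / n_substeps
    h_stack = fm[:, None, None] * h_curr[None]
    idx = np.arange(n)
    h_stack[:, idx, idx] += (1.0 - fm)[:, None] * e_prev[None, :]
    w, v = np.linalg.eigh(h_stack)
    phases = np.exp(-1j * w * dtau)
    y = c.copy()
    if active is not None:
        ek = np.zeros(n, dtype=complex)
        ek[active] = 1.0
        y = np.stack([c, ek], axis=1)       # propagate c and the k-column of P
    for s in range(n_substeps):
        y = v[s] @ (phases[s][:, None] * (v[s].conj().T @ y)) if y.ndim == 2 \
            else v[s] @ (phases[s] * (v[s].conj().T @ y))
    if active is None:
        c_new = o.conj().T @ y
        if not np.all(np.isfinite(c_new)):
            raise FloatingPointError("electronic propagation diverged")
        return c_new, None
    yn = o.conj().T @ y
    c_new, p_col = yn[:, 0], yn[:, 1]
    if not np.all(np.isfinite(c_new)):
        raise FloatingPointError("electronic propagation diverged")
    g = np.zeros(n)
    pk_old = abs(c[active]) ** 2
    pk_new = abs(c_new[active]) ** 2
    if pk_old > 1e-12 and pk_new < pk_old:
        recv = np.real(c_new * np.conj(p_col) * np.conj(c[active]))
        recv[active] = 0.0
        recv = np.maximum(recv, 0.0)
        total = recv.sum()
        if total > 0:
            g = (1.0 - pk_new / pk_old) * recv / total
    return c_new, g


def hop_probabilities(c: np.ndarray, t: np.ndarray, active: int, dt: float) -> np.ndarray:
    """Single-shot fewest-switches probabilities g(active -> j).

    g_j = max(0, 2 Re(c_active^* T_active,j c_j) dt / |c_active|^2), clipped
    so that the total never exceeds 1 (clipping is logged).  Returns zeros
    with a warning when the active population is numerically empty.
    """
    c = np.asarray(c, dtype=complex)
    pa = abs(c[active]) ** 2
    g = np.zeros(len(c))
    if pa < 1e-12:
        logger.warning("hop_probabilities: active population below 1e-12")
        return g
    out = 2.0 * np.real(np.conj(c[active]) * t[active, :] * c) * dt / pa
    out[active] = 0.0
    g = np.maximum(out, 0.0)
    total = g.sum()
    if total > 1.0:
        logger.info("hop_probabilities: sum %.3f > 1, renormalized", total)
        g = g / total
    return g


def apply_hop(
    state: TrajState,
    target: int,
    model: ModelSystem,
    energies: np.ndarray,
    u_at_hop: Optional[np.ndarray] = None,
) -> Tuple[TrajState, HopEvent]:
    """Attempt a hop with uniform momentum rescaling.

    If the kinetic energy covers the electronic gap, the full momentum
    vector is scaled by one factor so total energy is conserved exactly
    and the active state becomes ``target``; otherwise the hop is
    frustrated (momenta unchanged, event flagged accepted=False).
    """
    if target == state.active:
        raise ValueError("hop target equals active state")
    m = model.masses_au
    ke = float(np.sum(state.momenta**2 / (2.0 * m)))
    gap = float(energies[target] - energies[state.active])
    snapshot = u_at_hop if u_at_hop is not None else np.empty((0, 0))
    if ke - gap >= 0 and (ke > 0 or gap >= 0):
        gamma = np.sqrt((ke - gap) / ke) if ke > 0 else 0.0
        new = replace(state, momenta=state.momenta * gamma, active=target)
        return new, HopEvent(state.t_fs, state.active, target, snapshot, True)
    return state, HopEvent(state.t_fs, state.active, target, snapshot, False)


# ----------------------------------------------------------------------
def run_trajectory(
    model: ModelSystem, sample: WignerSample, params: DynamicsParams
) -> Trajectory:
    """Propagate one trajectory from a Wigner sample.

    The initial spin-adiabatic state is the eigenvector with maximal
    squared overlap with the requested spin-diabatic label (summed over
    triplet components if a triplet is requested); c starts as that basis
    vector.  Deterministic given (model, sample, params).
    """
    dt = fs_to_au(params.dt_fs)
    n_steps = int(round(params.t_max_fs / params.dt_fs))
    masses = model.masses_au
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    x = np.array(sample.coords, dtype=float)
    p = np.array(sample.momenta, dtype=float)
    ev = model.evaluate(x)
    e_ad, u = _spin_states(model, ev, params.alpha)
    rows = _diabatic_rows(model, params.initial_state)
    active = int(np.argmax(np.sum(np.abs(u[rows, :]) ** 2, axis=0)))
    n = model.dimension
    c = np.zeros(n, dtype=complex)
    c[active] = 1.0
    w_prim = _primitive_vectors(ev, u)

    n_rec = n_steps + 1
    traj = Trajectory(
        n_singlets=model.n_singlets,
        n_triplets=model.n_triplets,
        alpha=params.alpha,
        seed=params.seed,
        times_fs=np.arange(n_rec) * params.dt_fs,
        coords=np.zeros((n_rec, model.n_modes)),
        momenta=np.zeros((n_rec, model.n_modes)),
        active=np.zeros(n_rec, dtype=int),
        adiabatic_populations=np.zeros((n_rec, n)),
        diabatic_populations=np.zeros((n_rec, n)),
        total_energy_au=np.zeros(n_rec),
    )

    def record(step):
        b = u @ c
        traj.coords[step] = x
        traj.momenta[step] = p
        traj.active[step] = active
        traj.adiabatic_populations[step] = np.abs(c) ** 2
        traj.diabatic_populations[step] = np.abs(b) ** 2
        traj.total_energy_au[step] = e_ad[active] + np.sum(p**2 / (2.0 * masses))

    record(0)
    last = 0
    for step in range(1, n_rec):
        try:
            f = _adiabatic_force(ev, u[:, active], params.alpha)
            x_new = x + p / masses * dt + 0.5 * f / masses * dt * dt
            ev_new = model.evaluate(
                x_new, prev_vectors=(ev.singlet_vectors, ev.triplet_vectors)
            )
            e_asc, u_asc = _spin_states(model, ev_new, params.alpha)
            w_asc = _primitive_vectors(ev_new, u_asc)
            u_new, perm = align_gauge(
                u, u_asc, energies=e_asc, overlap=w_prim.conj().T @ w_asc
            )
            e_new = e_asc[perm]
            w_new = _primitive_vectors(ev_new, u_new)
            f_new = _adiabatic_force(ev_new, u_new[:, active], params.alpha)
            p_new = p + 0.5 * (f + f_new) * dt

            c, flux = propagate_step_ld(
                c, e_ad, e_new, w_prim.conj().T @ w_new, dt,
                params.n_substeps, active=active,
            )
            norm = np.linalg.norm(c)
            if abs(norm - 1.0) > 1e-8:
                logger.debug("renormalizing c, drift %.2e", abs(norm - 1.0))
                c = c / norm

            total = flux.sum()
            if total > 1.0:
                logger.info("hop flux sum %.3f > 1, renormalized", total)
                flux = flux / total
            x, p, ev, e_ad, u, w_prim = (
                x_new, p_new, ev_new, e_new, u_new, w_new,
            )
            r = rng.random()
            cum = np.cumsum(flux)
            hit = np.nonzero(r < cum)[0]
            if hit.size:
                target = int(hit[0])
                st = TrajState(traj.times_fs[step], x, p, active, c)
                st_new, event = apply_hop(st, target, model, e_ad, u_at_hop=u.copy())
                traj.hops.append(event)
                if event.accepted:
                    active = st_new.active
                    p = st_new.momenta
            record(step)
            last = step
            if not np.isfinite(traj.total_energy_au[step]):
                raise FloatingPointError("non-finite total energy")
        except FloatingPointError as err:
            logger.warning("trajectory truncated at step %d: %s", step, err)
            traj.truncated = True
            break

    if traj.truncated:
        keep = last + 1
        traj.times_fs = traj.times_fs[:keep]
        traj.coords = traj.coords[:keep]
        traj.momenta = traj.momenta[:keep]
        traj.active = traj.active[:keep]
        traj.adiabatic_populations = traj.adiabatic_populations[:keep]
        traj.diabatic_populations = traj.diabatic_populations[:keep]
        traj.total_energy_au = traj.total_energy_au[:keep]
    return traj


def derive_seed(base_seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2^31 for ensemble member (stream) keys."""
    ss = np.random.SeedSequence(base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_ensemble(
    model: ModelSystem,
    samples: Sequence[WignerSample],
    params: DynamicsParams,
    alphas: Sequence[float] = (2.0, 3.5, 5.0),
    t_max_per_alpha: Optional[Dict[float, float]] = None,
) -> Dict[float, List[Trajectory]]:
    """Per-alpha trajectory ensembles with independent derived seeds.

    The default protocol mirrors the accelerated-ISC recipe: SOC scaling
    factors 2, 3.5 and 5, one trajectory per Wigner sample, horizons
    configurable per alpha (e.g. 200/200/100 fs).  Trajectory (alpha_index,
    sample_index) draws its RNG stream from a seed derived from
    (params.seed, alpha_index, sample_index).
    """
    if len(alphas) == 0:
        return {}
    if len(samples) < 1:
        raise ValueError("need at least one Wigner sample")
    out: Dict[float, List[Trajectory]] = {}
    for ai, alpha in enumerate(alphas):
        t_max = params.t_max_fs
        if t_max_per_alpha and alpha in t_max_per_alpha:
            t_max = t_max_per_alpha[alpha]
        ens = []
        for i, sample in enumerate(samples):
            p_i = replace(
                params,
                alpha=float(alpha),
                t_max_fs=t_max,
                seed=derive_seed(params.seed, ai, i),
            )
            ens.append(run_trajectory(model, sample, p_i))
            if (i + 1) % 10 == 0 or i + 1 == len(samples):
                logger.info("alpha=%s: %d/%d trajectories", alpha, i + 1, len(samples))
        out[float(alpha)] = ens
    return out
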