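"""Wigner sampling of initial conditions for harmonic ensembles.

The Wigner distribution of a canonical ensemble of non-interacting quantum
harmonic oscillators at temperature T factorizes per mode into independent
Gaussians in coordinate and momentum with

    sigma_q^2 = (hbar / 2 m w) coth(hbar w / 2 k_B T)
    sigma_p^2 = (m w hbar / 2) coth(hbar w / 2 k_B T)

At T = 0 the coth factor is 1 (pure zero-point widths); in the classical
limit k_B T >> hbar w the coordinate variance tends to k_B T / m w^2 and
the mean kinetic energy per mode to k_B T / 2 (equipartition).

The default temperature throughout the package is 298 K.  Ensemble member
``i`` draws from a random stream derived deterministically from
``(seed, i)``, so sample sets are reproducible and parallelizable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .constants import KB_HARTREE, hartree_to_ev
from .model import ModeSpec, ModelValidationError

__all__ = ["WignerSample", "sample_wigner", "kinetic_energy_stats", "wigner_widths"]

DEFAULT_TEMPERATURE_K = 298.0


@dataclass(frozen=True)
class WignerSample:
    """One draw of per-mode coordinates (bohr) and momenta (a.u.)."""

    coords: np.ndarray
    momenta: np.ndarray
    seed_used: int


def _coth_factor(omega_au: np.ndarray, temperature: float) -> np.ndarray:
    """coth(hbar w / 2 k_B T), with the T = 0 limit equal to 1."""
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if temperature == 0:
        return np.ones_like(omega_au)
    x = omega_au / (2.0 * KB_HARTREE * temperature)
    return 1.0 / np.tanh(x)


def wigner_widths(
    modes: Sequence[ModeSpec], temperature: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-mode standard deviations (sigma_q, sigma_p) in atomic units."""
    masses = np.array([m.reduced_mass_amu for m in modes])
    freqs = np.array([m.frequency_cm1 for m in modes])
    if np.any(masses <= 0) or np.any(freqs <= 0):
        raise ModelValidationError("modes need positive frequency and mass")
    from .constants import amu_to_me, omega_au_from_cm1

    m_au = amu_to_me(masses)
    w_au = omega_au_from_cm1(freqs)
    c = _coth_factor(w_au, temperature)
    sigma_q = np.sqrt(c / (2.0 * m_au * w_au))
    sigma_p = np.sqrt(c * m_au * w_au / 2.0)
    return sigma_q, sigma_p


def sample_wigner(
    modes: Sequence[ModeSpec],
    temperature: float = DEFAULT_TEMPERATURE_K,
    n: int = 1,
    seed: int = 0,
) -> List[WignerSample]:
    """Draw ``n`` independent phase-space points from the Wigner distribution.

    Coordinates are centered on each mode's equilibrium, momenta on zero;
    coordinates and momenta are mutually independent.  Identical
    ``(modes, temperature, n, seed)`` give bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sigma_q, sigma_p = wigner_widths(modes, temperature)
    x0 = np.array([m.equilibrium for m in modes], dtype=float)
    out: List[WignerSample] = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        q = x0 + sigma_q * rng.standard_normal(len(modes))
        p = sigma_p * rng.standard_normal(len(modes))
        out.append(WignerSample(coords=q, momenta=p, seed_used=seed))
    return out


def kinetic_energy_stats(
    samples: Sequence[WignerSample], modes: Sequence[ModeSpec]
) -> Tuple[float, np.ndarray]:
    """Ensemble-mean kinetic energy in eV: (total, per-mode breakdown).

    The per-mode expectation is (hbar w / 4) coth(hbar w / 2 k_B T): half
    the zero-point energy at T = 0, k_B T / 2 in the classical limit.  The
    total equals the sum of the per-mode values exactly.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    from .constants import amu_to_me

    m_au = amu_to_me(np.array([m.reduced_mass_amu for m in modes]))
    p = np.stack([s.momenta for s in samples])
    per_mode_au = np.mean(p * p / (2.0 * m_au), axis=0)
    per_mode = hartree_to_ev(per_mode_au)
    return float(per_mode.sum()), per_mode
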