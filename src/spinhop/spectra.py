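"""Nuclear-ensemble absorption spectra and the non-parallelity metric.

The nuclear ensemble approach (NEA) builds an absorption cross-section by
averaging, over an ensemble of geometries (typically Wigner-sampled), the
sum over excited states of the transition oscillator strength times a
unit-area Gaussian line shape centered at that geometry's vertical
excitation energy.  The result carries no vibrational fine structure and
is reported in arbitrary units (up to a global energy-independent
prefactor), which suffices for peak positions and shift comparisons.

The non-parallelity between two potential-energy curves f and g sampled
on the same grid is

    NP(f, g) = max_R |f - g| - min_R |f - g|

It is symmetric, zero for curves differing by a constant shift, and
invariant under adding the same curve to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["SpectrumGrid", "CurvePair", "nea_spectrum", "non_parallelity"]

DEFAULT_WIDTH_EV = 0.05


@dataclass
class SpectrumGrid:
    """NEA cross-section on a uniform energy grid (arbitrary units)."""

    energies_ev: np.ndarray
    cross_section: np.ndarray
    broadening_width_ev: float
    n_configs: int
    n_states: int


@dataclass
class CurvePair:
    """Two potential-energy curves on a shared abscissa (no interpolation)."""

    grid: np.ndarray
    f_values: np.ndarray
    g_values: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.f_values, dtype=float)
        g = np.asarray(self.g_values, dtype=float)
        if f.shape != g.shape or f.ndim != 1 or len(f) < 2:
            raise ValueError("curves must be 1-D, equal length >= 2")
        self.f_values, self.g_values = f, g


def nea_spectrum(
    per_config_excitations: Sequence[Sequence[Tuple[float, float]]],
    width_ev: float = DEFAULT_WIDTH_EV,
    grid_ev=None,
) -> SpectrumGrid:
    """Ensemble-averaged spectrum from per-configuration (dE, f) lists.

    cross_section(E) = mean over configurations of
    sum_states f_state * G(E - dE_state; width), with G a unit-area
    Gaussian; the average (not the sum) over configurations keeps the
    spectrum independent of the ensemble size.  Configurations with empty
    state lists contribute zero; an empty configuration list is rejected.
    """
    if width_ev <= 0:
        raise ValueError("broadening width must be > 0")
    configs = [list(c) for c in per_config_excitations]
    if len(configs) == 0:
        raise ValueError("need at least one configuration")
    all_de = [de for c in configs for de, _ in c]
    n_states = max((len(c) for c in configs), default=0)
    if grid_ev is None:
        if not all_de:
            raise ValueError("no transitions and no grid supplied")
        lo = min(all_de) - 5.0 * width_ev
        hi = max(all_de) + 5.0 * width_ev
        grid_ev = np.linspace(lo, hi, 2000)
    grid_ev = np.asarray(grid_ev, dtype=float)

    norm = 1.0 / (width_ev * np.sqrt(2.0 * np.pi))
    sigma = np.zeros_like(grid_ev)
    for c in configs:
        for de, f in c:
            sigma += f * norm * np.exp(-0.5 * ((grid_ev - de) / width_ev) ** 2)
    sigma /= len(configs)
    return SpectrumGrid(
        energies_ev=grid_ev,
        cross_section=sigma,
        broadening_width_ev=width_ev,
        n_configs=len(configs),
        n_states=n_states,
    )


def non_parallelity(pair: CurvePair) -> float:
    """NP(f, g) = max|f - g| - min|f - g| over the shared grid (eV in, eV out)."""
    diff = np.abs(pair.f_values - pair.g_values)
    return float(diff.max() - diff.min())
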