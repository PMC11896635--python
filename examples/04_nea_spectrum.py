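"""Nuclear-ensemble absorption spectrum of a Wigner ensemble.

Samples geometries from the 298 K Wigner distribution of the crossing
template, evaluates vertical excitation energies and oscillator strengths
at each geometry, and averages Gaussian-broadened sticks into an
absorption cross-section (arbitrary units).  Also evaluates the
non-parallelity between the S1 surface and a shifted copy.
"""

import numpy as np

from spinhop import (
    CurvePair,
    FixtureSpec,
    generate_fixture,
    nea_spectrum,
    non_parallelity,
    sample_wigner,
)
from spinhop.constants import HARTREE_EV

model, _ = generate_fixture(FixtureSpec("lvc_crossing"), seed=1)
samples = sample_wigner(model.modes, temperature=298.0, n=1000, seed=5)

configs = []
for s in samples:
    ev = model.evaluate(s.coords)
    de = (ev.singlet_energies[1:] - ev.singlet_energies[0]) * HARTREE_EV
    configs.append(list(zip(de, ev.oscillator_strengths)))

spec = nea_spectrum(configs, width_ev=0.05)
peak = spec.energies_ev[np.argmax(spec.cross_section)]
print(f"NEA spectrum from {spec.n_configs} configurations:")
print(f"  peak at {peak:.3f} eV (vertical S0->S1 energy at the origin: 3.000 eV)")
print(f"  integrated intensity {np.trapezoid(spec.cross_section, spec.energies_ev):.3f}"
      " (= ensemble-mean oscillator strength)")

# non-parallelity between two potential-energy curves on a shared grid
grid = np.linspace(-0.4, 0.4, 81)
s1_ev = np.array(
    [model.evaluate(np.array([x])).singlet_energies[1] for x in grid]
) * HARTREE_EV
tilted = s1_ev + 0.05 * (grid - grid[0]) / (grid[-1] - grid[0])  # 0.05 eV tilt
print(f"  NP(S1, S1 + 0.3 eV shift)  = "
      f"{non_parallelity(CurvePair(grid, s1_ev, s1_ev + 0.3)):.3f} eV")
print(f"  NP(S1, tilted S1)          = "
      f"{non_parallelity(CurvePair(grid, s1_ev, tilted)):.3f} eV")
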