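"""Deterministic model-system templates for tests, examples and studies.

Three templates are provided:

``two_manifold_golden_rule``
    A bright singlet donor above a manifold of triplet acceptor surfaces,
    built to sit in the weak-coupling golden-rule regime: singlet-triplet
    crossings are swept repeatedly by the nuclear oscillation, each
    passage transfers a small Landau-Zener probability proportional to
    the squared SOC, so the ensemble decay is near-exponential and the
    fitted lifetime scales as alpha^-2 under SOC scaling.

``lvc_crossing``
    Minimal 2-singlet/1-triplet single-mode model with one S1/T1 crossing
    inside the thermally accessible range; handy for didactic examples.

``bodipy_like_37state``
    A 7-singlet/10-triplet surrogate (basis dimension 37) whose vertical
    energy ladder is anchored at published excitation energies of an
    iodinated BODIPY dye (S1 at 2.96 eV with f = 0.74, etc.), with SOC
    magnitudes drawn from the qualitative selection-rule categories for
    assigned state characters and a soft out-of-plane mode (25 cm^-1)
    carrying a quadratic SOC modulation that mimics the growth of SOC
    with loss of planarity.

All templates are deterministic functions of ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .model import (
    ElectronicSpec,
    ModeSpec,
    ModelSystem,
    SOCModulation,
    SOCSpec,
    build_lvc_model,
)
from .soc_rules import StateCharacter, classify_pair

__all__ = ["FixtureSpec", "generate_fixture", "TEMPLATES"]


@dataclass(frozen=True)
class FixtureSpec:
    template: str
    overrides: Tuple[Tuple[str, float], ...] = ()

    def override_map(self) -> Dict[str, float]:
        return dict(self.overrides)


def _two_manifold_golden_rule(seed: int, ov: Dict[str, float]) -> Tuple[ModelSystem, str]:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    n_triplets = int(ov.get("n_triplets", 6))
    soc_cm1 = float(ov.get("soc_cm1", 16.0))
    freqs = (320.0, 470.0, 610.0, 760.0, 910.0, 1120.0, 1340.0, 1580.0)
    masses = (8.0, 7.0, 6.0, 5.0, 4.5, 4.0, 3.5, 3.0)
    modes = [
        ModeSpec(frequency_cm1=f, reduced_mass_amu=m, name=f"mode{k}")
        for k, (f, m) in enumerate(zip(freqs, masses))
    ]
    # golden-rule construction: every state carries its own random
    # gradients over an eight-mode incommensurate bath, so each
    # singlet-triplet gap is modulated by ~0.1 eV rms and sweeps through
    # zero several times per 100 fs while vibrational dephasing kills the
    # coherent recurrences a few-mode model would show; the acceptor
    # detunings (0.03-0.10 eV) sit inside the bulk of that modulation, so
    # crossings are frequent, yet stay several times larger than the
    # scaled coupling so no channel is ever strongly mixed; and the
    # per-passage Landau-Zener transfer remains perturbative
    # (proportional to V^2) up to alpha ~ 3.  Under those conditions
    # ensemble lifetimes follow the alpha^-2 acceleration law and the
    # alpha = 1 decay is directly simulatable on a ~1 ps horizon.
    t_lo = float(ov.get("t_lo_ev", 2.900))
    t_hi = float(ov.get("t_hi_ev", 2.970))
    kmax = float(ov.get("kappa_max_ev", 0.35))
    t_energies = np.linspace(t_lo, t_hi, n_triplets)
    energies = [0.0, 3.0] + list(t_energies)
    n_modes = len(modes)
    kappa = np.zeros((2 + n_triplets, n_modes))
    kappa[1] = rng.uniform(-0.2, 0.2, n_modes)          # donor slopes
    for j in range(n_triplets):
        kappa[2 + j] = rng.uniform(-kmax, kmax, n_modes)
    soc: Dict[Tuple[int, int, int], complex] = {}
    for j in range(n_triplets):
        for m in range(3):
            phase = np.exp(1j * 2.0 * np.pi * rng.random())
            soc[(1, j, m)] = soc_cm1 / np.sqrt(3.0) * phase
    model = build_lvc_model(
        ElectronicSpec(
            n_singlets=2,
            n_triplets=n_triplets,
            vertical_energies_ev=energies,
            intrastate_gradients_ev=kappa,
            oscillator_strengths=[0.6],
        ),
        modes,
        SOCSpec(base_soc_cm1=soc),
        label=f"two_manifold_golden_rule(seed={seed})",
    )
    notes = (
        "Weak-coupling donor/acceptor model: S1 at 3.0 eV over "
        f"{n_triplets} triplets ({t_lo:.2f}-{t_hi:.2f} eV) with an "
        f"{n_modes}-mode dephasing bath; total SOC {soc_cm1:.0f} cm^-1 "
        "spread over the three components; expected near-exponential S1 "
        "decay with lifetime scaling ~ alpha^-2 while the scaled coupling "
        "stays perturbative."
    )
    return model, notes


def _lvc_crossing(seed: int, ov: Dict[str, float]) -> Tuple[ModelSystem, str]:
    soc_cm1 = float(ov.get("soc_cm1", 150.0))
    model = build_lvc_model(
        ElectronicSpec(
            n_singlets=2,
            n_triplets=1,
            vertical_energies_ev=[0.0, 3.0, 2.8],
            intrastate_gradients_ev=np.array(
                [[0.0], [0.3], [-0.5]]
            ),
            oscillator_strengths=[0.5],
        ),
        [ModeSpec(frequency_cm1=600.0, reduced_mass_amu=6.0, name="tuning")],
        SOCSpec(base_soc_cm1={(1, 0, m): soc_cm1 / np.sqrt(3.0) for m in range(3)}),
        label=f"lvc_crossing(seed={seed})",
    )
    return model, "Single-mode S1/T1 crossing model with SOC in the hundreds range."


# character assignment for the 37-state surrogate: indices into
# (S0..S6, T1..T10)
_BODIPY_CHARACTERS = {
    "S0": StateCharacter("ground_closed_shell"),
    "S1": StateCharacter("pi_pi_star"),
    "S2": StateCharacter("pi_pi_star"),
    "S3": StateCharacter("pi_pi_star"),
    "S4": StateCharacter("n_pi_star"),
    "S5": StateCharacter("pi_sigma_star", source_heavy_p=True,
                         source_orientation="out_of_plane"),
    "S6": StateCharacter("n_sigma_star"),
    "T1": StateCharacter("pi_pi_star"),
    "T2": StateCharacter("pi_pi_star"),
    "T3": StateCharacter("n_pi_star"),
    "T4": StateCharacter("pi_pi_star"),
    "T5": StateCharacter("pi_pi_star"),
    "T6": StateCharacter("n_pi_star"),
    "T7": StateCharacter("pi_sigma_star", source_heavy_p=True,
                         source_orientation="out_of_plane"),
    "T8": StateCharacter("pi_sigma_star", source_heavy_p=True,
                         source_orientation="out_of_plane"),
    "T9": StateCharacter("n_sigma_star"),
    "T10": StateCharacter("n_sigma_star"),
}

_CATEGORY_DRAW = {
    "units": (1.0, 9.0),
    "tens": (10.0, 90.0),
    "hundreds_to_2000": (150.0, 1500.0),
    "atomic_like_2300": (2000.0, 2300.0),
}


def _bodipy_like_37state(seed: int, ov: Dict[str, float]) -> Tuple[ModelSystem, str]:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    # singlet ladder anchored at published BHLYP vertical energies
    # (2.96/3.66/3.93/4.37/4.54 eV with f = 0.74/0.10/0.08/0.00/0.00);
    # S6 extends the ladder
    s_energies = [0.0, 2.96, 3.66, 3.93, 4.37, 4.54, 4.72]
    osc = [0.74, 0.10, 0.08, 0.00, 0.00, 0.00]
    t_energies = list(np.round(np.linspace(1.95, 4.65, 10), 3))
    modes = [
        ModeSpec(frequency_cm1=25.0, reduced_mass_amu=60.0, name="oop_bend"),
        ModeSpec(frequency_cm1=520.0, reduced_mass_amu=10.0, name="ring_breath"),
        ModeSpec(frequency_cm1=1250.0, reduced_mass_amu=4.0, name="cc_stretch"),
    ]
    n_s, n_t = 7, 10
    kappa = np.zeros((n_s + n_t, 3))
    kappa[1:, 1] = rng.uniform(-0.4, 0.4, n_s + n_t - 1)
    kappa[1:, 2] = rng.uniform(-0.3, 0.3, n_s + n_t - 1)
    soc: Dict[Tuple[int, int, int], complex] = {}
    labels_s = [f"S{i}" for i in range(n_s)]
    labels_t = [f"T{j + 1}" for j in range(n_t)]
    for i, ls in enumerate(labels_s):
        for j, lt in enumerate(labels_t):
            cat = classify_pair(_BODIPY_CHARACTERS[ls], _BODIPY_CHARACTERS[lt])
            lo, hi = _CATEGORY_DRAW[cat.label]
            mag = rng.uniform(lo, hi)
            for m in range(3):
                phase = np.exp(1j * 2.0 * np.pi * rng.random())
                soc[(i, j, m)] = mag / np.sqrt(3.0) * phase
    modulation = [
        SOCModulation(coordinate="oop_bend", quadratic_cm1=0.5)
    ]
    model = build_lvc_model(
        ElectronicSpec(
            n_singlets=n_s, n_triplets=n_t,
            vertical_energies_ev=s_energies + t_energies,
            intrastate_gradients_ev=kappa,
            oscillator_strengths=osc,
        ),
        modes,
        SOCSpec(base_soc_cm1=soc, modulation=modulation),
        label=f"bodipy_like_37state(seed={seed})",
    )
    notes = (
        "Surrogate iodinated-BODIPY model: 7 singlets + 10 triplets "
        "(dimension 37); singlet ladder anchored at published vertical "
        "energies; SOC magnitudes drawn from selection-rule categories; "
        "soft 25 cm^-1 out-of-plane mode modulates SOC quadratically."
    )
    return model, notes


TEMPLATES = {
    "two_manifold_golden_rule": _two_manifold_golden_rule,
    "lvc_crossing": _lvc_crossing,
    "bodipy_like_37state": _bodipy_like_37state,
}


def generate_fixture(spec: FixtureSpec, seed: int = 0) -> Tuple[ModelSystem, str]:
    """Build a template model; returns (model, expected-behavior notes)."""
    if spec.template not in TEMPLATES:
        raise KeyError(
            f"unknown template {spec.template!r}; choose from {sorted(TEMPLATES)}"
        )
    return TEMPLATES[spec.template](seed, spec.override_map())
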