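import numpy as np
import pytest

from spinhop import (
    ElectronicSpec,
    ModeSpec,
    SOCSpec,
    build_lvc_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_surface_model():
    """One harmonic singlet surface, no couplings: classical-mechanics oracle."""
    return build_lvc_model(
        ElectronicSpec(n_singlets=1, n_triplets=0, vertical_energies_ev=[0.0]),
        [ModeSpec(frequency_cm1=500.0, reduced_mass_amu=8.0)],
    )


@pytest.fixture
def two_state_model():
    """S0 + S1 + one triplet on one mode, crossing within thermal reach."""
    return build_lvc_model(
        ElectronicSpec(
            n_singlets=2,
            n_triplets=1,
            vertical_energies_ev=[0.0, 3.0, 2.8],
            intrastate_gradients_ev=np.array([[0.0], [0.3], [-0.5]]),
            oscillator_strengths=[0.5],
        ),
        [ModeSpec(frequency_cm1=600.0, reduced_mass_amu=6.0)],
        SOCSpec(base_soc_cm1={(1, 0, m): 150.0 / np.sqrt(3) for m in range(3)}),
    )


def random_unitary(n, rng):
    z = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    q, r = np.linalg.qr(z)
    return q * (np.diag(r) / np.abs(np.diag(r)))
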