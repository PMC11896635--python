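import itertools

import numpy as np
import pytest

from spinhop import (
    align_gauge,
    assemble_spin_hamiltonian,
    back_transform,
    diagonalize_spin_hamiltonian,
    ensemble_populations,
)
from spinhop.constants import cm1_to_hartree
from spinhop.dynamics import Trajectory
from spinhop.model import expand_soc
from spinhop.spin_mixing import sum_triplet_components

from conftest import random_unitary


def _soc_matrix(n_s, n_t, entries):
    soc = np.zeros((n_s, n_t, 3), complex)
    for (i, j, m), v in entries.items():
        soc[i, j, m] = v
    return expand_soc(soc, n_s, n_t)


class TestAssembly:
    def test_alpha_zero_decouples_manifolds(self):
        v = _soc_matrix(2, 1, {(1, 0, 0): cm1_to_hartree(50.0)})
        h = assemble_spin_hamiltonian(np.arange(5.0), v, 0.0, 2, 1)
        off = h.matrix - np.diag(np.diag(h.matrix))
        assert np.abs(off).max() == 0.0

    def test_alpha_scales_soc_only(self):
        v = _soc_matrix(2, 1, {(1, 0, 1): cm1_to_hartree(50.0) * (1 + 1j)})
        e = np.arange(5.0)
        h1 = assemble_spin_hamiltonian(e, v, 1.0, 2, 1)
        h2 = assemble_spin_hamiltonian(e, v, 2.0, 2, 1)
        np.testing.assert_allclose(np.diag(h2.matrix), e, atol=0)
        np.testing.assert_allclose(
            h2.matrix - np.diag(e), 2.0 * (h1.matrix - np.diag(e)), atol=0
        )

    def test_reference_dimension_37(self):
        """7 singlets + 10 triplets give the 37-dimensional spin basis."""
        n = 7 + 3 * 10
        h = assemble_spin_hamiltonian(
            np.zeros(n), np.zeros((n, n), complex), 1.0, 7, 10
        )
        assert h.matrix.shape == (37, 37)

    def test_non_hermitian_soc_rejected(self):
        v = np.zeros((5, 5), complex)
        v[0, 2] = 1e-3  # no conjugate partner
        with pytest.raises(ValueError):
            assemble_spin_hamiltonian(np.zeros(5), v, 1.0, 2, 1)


class TestDiagonalization:
    def test_zero_soc_returns_sorted_scalars(self):
        e = np.array([0.0, 3.0, 2.8, 2.8, 2.8])
        h = assemble_spin_hamiltonian(e, np.zeros((5, 5), complex), 1.0, 2, 1)
        qr = diagonalize_spin_hamiltonian(h)
        np.testing.assert_allclose(qr.energies, np.sort(e), atol=1e-15)
        # U is a signed permutation
        assert np.allclose(np.abs(qr.vectors) @ np.abs(qr.vectors).T, np.eye(5))

    def test_degenerate_pair_splits_by_coupling(self):
        """1 singlet + 1 triplet component at E0 coupled by 100 cm^-1 -> E0 +/- 100."""
        lam = cm1_to_hartree(100.0)
        e0 = 0.11
        v = _soc_matrix(1, 1, {(0, 0, 0): lam})
        h = assemble_spin_hamiltonian(np.full(4, e0), v, 1.0, 1, 1)
        qr = diagonalize_spin_hamiltonian(h)
        np.testing.assert_allclose(
            qr.energies, [e0 - lam, e0, e0, e0 + lam], atol=1e-15
        )

    def test_splitting_linear_in_alpha(self):
        lam = cm1_to_hartree(100.0)
        v = _soc_matrix(1, 1, {(0, 0, 0): lam})
        h = assemble_spin_hamiltonian(np.zeros(4), v, 2.0, 1, 1)
        qr = diagonalize_spin_hamiltonian(h)
        assert qr.energies[-1] == pytest.approx(2 * lam, rel=1e-12)

    def test_reconstruction_residual(self, rng):
        n = 8
        a = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        h = assemble_spin_hamiltonian(
            np.zeros(n), np.zeros((n, n), complex), 1.0, 2, 2
        )
        h.matrix = (a + a.conj().T) / 2
        qr = diagonalize_spin_hamiltonian(h)
        resid = h.matrix @ qr.vectors - qr.vectors * qr.energies
        assert np.linalg.norm(resid) < 1e-9 * np.linalg.norm(h.matrix)
        np.testing.assert_allclose(
            qr.vectors.conj().T @ qr.vectors, np.eye(n), atol=1e-10
        )


class TestGaugeAlignment:
    def test_pure_phase_removed(self, rng):
        u = random_unitary(5, rng)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 5))
        aligned, perm = align_gauge(u, u * phases)
        np.testing.assert_allclose(aligned, u, atol=1e-12)
        assert list(perm) == list(range(5))

    def test_column_swap_detected_against_bruteforce(self, rng):
        """Assignment agrees with exhaustive search over permutations (n <= 6)."""
        n = 5
        u = random_unitary(n, rng)
        perm_true = rng.permutation(n)
        u_swapped = u[:, perm_true]
        aligned, perm = align_gauge(u, u_swapped)
        # brute-force oracle: best permutation by total |overlap|
        ov = np.abs(u.conj().T @ u_swapped)
        best = max(
            itertools.permutations(range(n)),
            key=lambda p: sum(ov[i, p[i]] for i in range(n)),
        )
        assert tuple(perm) == best
        np.testing.assert_allclose(aligned, u, atol=1e-12)

    def test_identity_action(self, rng):
        u = random_unitary(4, rng)
        aligned, _ = align_gauge(u, u)
        np.testing.assert_allclose(aligned, u, atol=1e-12)

    def test_degenerate_subspace_jointly_aligned(self, rng):
        """Arbitrary rotation inside a degenerate eigenvalue pair is undone."""
        u = random_unitary(4, rng)
        theta = 0.7
        rot = np.eye(4, dtype=complex)
        rot[1:3, 1:3] = [[np.cos(theta), -np.sin(theta)],
                         [np.sin(theta), np.cos(theta)]]
        u_rot = u @ rot
        energies = np.array([0.0, 1.0, 1.0 + 1e-13, 2.0])
        aligned, _ = align_gauge(u, u_rot, energies=energies)
        np.testing.assert_allclose(aligned, u, atol=1e-10)


class TestBackTransform:
    def test_identity(self):
        c = np.array([1.0, 0.0, 0.0], complex)
        np.testing.assert_array_equal(back_transform(np.eye(3), c), c)

    def test_45_degree_rotation_splits_evenly(self):
        th = np.pi / 4
        u = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = back_transform(u, np.array([1.0, 0.0]))
        np.testing.assert_allclose(np.abs(b) ** 2, [0.5, 0.5], atol=1e-15)

    def test_norm_preserved_on_random_unitaries(self, rng):
        for n in (3, 7, 12):
            u = random_unitary(n, rng)
            c = rng.standard_normal(n) + 1j * rng.standard_normal(n)
            c /= np.linalg.norm(c)
            b = back_transform(u, c)
            assert abs(np.linalg.norm(b) - 1.0) < 1e-12

    def test_unnormalized_c_rejected(self):
        with pytest.raises(ValueError):
            back_transform(np.eye(2), np.array([1.0, 1.0]))


def _fake_traj(times, pops, n_s=2, n_t=1):
    t = Trajectory(n_singlets=n_s, n_triplets=n_t, alpha=1.0, seed=0)
    t.times_fs = np.asarray(times, float)
    t.diabatic_populations = np.asarray(pops, float)
    return t


class TestEnsemblePopulations:
    def test_pinned_trajectory_stays_put(self):
        times = np.arange(5) * 0.5
        pops = np.zeros((5, 5))
        pops[:, 1] = 1.0   # S1 forever
        series = ensemble_populations([_fake_traj(times, pops)])
        np.testing.assert_array_equal(series.select("S1"), np.ones(5))

    def test_two_trajectory_mean(self):
        times = np.arange(4) * 0.5
        a = np.zeros((4, 5)); a[:, 0] = 1.0
        b = np.zeros((4, 5)); b[:, 1] = 1.0
        series = ensemble_populations([_fake_traj(times, a), _fake_traj(times, b)])
        np.testing.assert_allclose(series.select("S0"), 0.5)
        np.testing.assert_allclose(series.select("S1"), 0.5)

    def test_sum_is_one_and_triplets_merged(self, rng):
        times = np.arange(6) * 0.5
        raw = rng.random((6, 8))   # 2 singlets + 2 triplets -> dim 8
        raw /= raw.sum(axis=1, keepdims=True)
        series = ensemble_populations([_fake_traj(times, raw, 2, 2)])
        assert series.populations.shape == (6, 4)
        np.testing.assert_allclose(series.populations.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_populations([])

    def test_component_merge_helper(self):
        pops = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        merged = sum_triplet_components(pops, 2, 1)
        np.testing.assert_allclose(merged, [0.1, 0.2, 0.7])
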