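import numpy as np
import pytest

from spinhop import (
    DynamicsParams,
    ElectronicSpec,
    ModeSpec,
    SOCSpec,
    TrajState,
    WignerSample,
    apply_hop,
    build_lvc_model,
    electronic_propagate,
    hop_probabilities,
    nuclear_step,
    run_ensemble,
    run_trajectory,
    tdc_estimate,
)
from spinhop.constants import FS_AU, fs_to_au
from spinhop.dynamics import GaugeError, propagate_step_ld
from conftest import random_unitary


def _state(model, x, p, active=0):
    n = model.dimension
    c = np.zeros(n, complex)
    c[active] = 1.0
    return TrajState(t_fs=0.0, coords=np.asarray(x, float),
                     momenta=np.asarray(p, float), active=active, c=c)


class TestNuclearStep:
    def test_zero_force_straight_line(self):
        """A free particle (zero-frequency limit emulated by tiny force
        region) moves as q = q0 + (p/m) t; here: at the potential minimum
        with an offset momentum, the first step is dominated by p/m dt."""
        model = build_lvc_model(
            ElectronicSpec(n_singlets=1, n_triplets=0, vertical_energies_ev=[0.0]),
            [ModeSpec(500.0, 8.0)],
        )
        params = DynamicsParams(dt_fs=0.5, t_max_fs=1.0)
        st = _state(model, [0.0], [2.0])
        out = nuclear_step(st, model, params)
        dt = fs_to_au(0.5)
        # at the minimum the force vanishes: exactly uniform motion in x
        assert out.coords[0] == pytest.approx(2.0 / model.masses_au[0] * dt, rel=1e-12)

    def test_harmonic_period_recovered(self):
        """The oscillation period 2 pi / w is reproduced to 0.1% at 0.5 fs."""
        model = build_lvc_model(
            ElectronicSpec(n_singlets=1, n_triplets=0, vertical_energies_ev=[0.0]),
            [ModeSpec(500.0, 8.0)],
        )
        params = DynamicsParams(dt_fs=0.5, t_max_fs=500.0)
        st = _state(model, [0.4], [0.0])
        xs = [st.coords[0]]
        n_steps = 400
        for _ in range(n_steps):
            st = nuclear_step(st, model, params)
            xs.append(st.coords[0])
        xs = np.array(xs)
        # period from zero crossings of x
        sign_changes = np.nonzero(np.diff(np.sign(xs)))[0]
        # linear interpolation of crossing times, one full period spans
        # two successive same-direction crossings
        t = np.arange(len(xs)) * 0.5
        crossings = []
        for i in sign_changes:
            frac = xs[i] / (xs[i] - xs[i + 1])
            crossings.append(t[i] + 0.5 * frac)
        periods = 2 * np.diff(crossings)
        expected = 2 * np.pi / model.omegas_au[0] / FS_AU
        assert np.mean(periods) == pytest.approx(expected, rel=1e-3)

    def test_energy_drift_below_1e6(self):
        """Windowed-mean total energy drifts < 1e-6 relative over 200 fs."""
        model = build_lvc_model(
            ElectronicSpec(n_singlets=1, n_triplets=0, vertical_energies_ev=[0.0]),
            [ModeSpec(500.0, 8.0)],
        )
        params = DynamicsParams(dt_fs=0.5, t_max_fs=200.0)
        st = _state(model, [0.3], [1.0])
        m, w = model.masses_au[0], model.omegas_au[0]

        def energy(s):
            return 0.5 * m * w**2 * s.coords[0] ** 2 + s.momenta[0] ** 2 / (2 * m)

        es = [energy(st)]
        for _ in range(400):
            st = nuclear_step(st, model, params)
            es.append(energy(st))
        es = np.array(es)
        # average over one vibrational period so the bounded symplectic
        # oscillation of the Verlet shadow energy cancels
        k = int(round(2 * np.pi / model.omegas_au[0] / fs_to_au(0.5)))
        early, late = es[:k].mean(), es[-k:].mean()
        assert abs(late - early) / es[0] < 1e-6


class TestTDC:
    def test_identical_unitaries_zero(self, rng):
        u = random_unitary(5, rng)
        t = tdc_estimate(u, u, fs_to_au(0.5))
        assert np.abs(t).max() < 1e-14

    def test_anti_hermitian_on_aligned_unitaries(self, rng):
        u = random_unitary(6, rng)
        # small smooth rotation of the basis
        gen = rng.standard_normal((6, 6)) * 0.01
        gen = gen - gen.T
        from scipy.linalg import expm
        u2 = u @ expm(gen)
        t = tdc_estimate(u, u2, fs_to_au(0.5))
        assert np.abs(t + t.conj().T).max() < 1e-12

    def test_planar_rotation_rate_recovered(self):
        """Two states rotating at angular rate w: T_12 -> w + O(dt^2)."""
        w_rate = 0.003   # rad / a.u.
        dt = fs_to_au(0.5)
        def u_at(t):
            th = w_rate * t
            return np.array([[np.cos(th), -np.sin(th)],
                             [np.sin(th), np.cos(th)]])
        t_est = tdc_estimate(u_at(0.0), u_at(dt), dt)
        assert t_est[0, 1] == pytest.approx(-w_rate, rel=1e-3)
        assert t_est[1, 0] == pytest.approx(w_rate, rel=1e-3)

    def test_misaligned_gauge_detected(self, rng):
        u = random_unitary(4, rng)
        swapped = u[:, [1, 0, 2, 3]]
        with pytest.raises(GaugeError):
            tdc_estimate(u, swapped, fs_to_au(0.5))


class TestElectronicPropagation:
    def test_phase_only_evolution(self):
        e = np.array([0.1, 0.25])
        t0 = np.zeros((2, 2))
        c0 = np.array([0.6, 0.8], complex)
        dt = fs_to_au(0.5)
        c1, _ = electronic_propagate(c0, e, e, t0, t0, dt, 20)
        np.testing.assert_allclose(np.abs(c1), np.abs(c0), atol=1e-12)
        np.testing.assert_allclose(c1, c0 * np.exp(-1j * e * dt), atol=1e-10)

    def test_rabi_oscillation_closed_form(self):
        """Constant coupling V between degenerate states: P2 = sin^2(V t)."""
        v = 5e-4    # hartree
        e = np.zeros(2)
        tmat = np.array([[0.0, 1j * v], [1j * v, 0.0]])  # -i*hbar*T == V coupling
        c = np.array([1.0, 0.0], complex)
        dt = fs_to_au(0.5)
        n_steps = 200
        for _ in range(n_steps):
            c, _ = electronic_propagate(c, e, e, tmat, tmat, dt, 20)
        t_total = n_steps * dt
        assert abs(c[1]) ** 2 == pytest.approx(np.sin(v * t_total) ** 2, abs=1e-6)

    def test_norm_conserved_over_400_steps(self, rng):
        """Random smooth model: |c| deviates from 1 by < 1e-8 after 400 steps."""
        n = 6
        e0 = np.sort(rng.uniform(0, 0.2, n))
        c = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        c /= np.linalg.norm(c)
        dt = fs_to_au(0.5)
        gen = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        tmat = (gen - gen.conj().T) * 1e-3
        for k in range(400):
            e1 = e0 + 1e-4 * np.sin(0.01 * k)
            c, _ = electronic_propagate(c, e0, e1, tmat, tmat, dt, 20)
            e0 = e1
        assert abs(np.linalg.norm(c) - 1.0) < 1e-8

    def test_ld_step_matches_interpolated_propagator_when_smooth(self, rng):
        """The locally diabatized step agrees with the T-matrix propagator
        for slowly varying eigenvectors."""
        from scipy.linalg import expm
        n = 5
        e_prev = np.sort(rng.uniform(0, 0.2, n))
        e_curr = e_prev + rng.uniform(-1e-4, 1e-4, n)
        gen = rng.standard_normal((n, n)) * 2e-3
        gen = gen - gen.T
        overlap = expm(gen)   # small real rotation
        c0 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        c0 /= np.linalg.norm(c0)
        dt = fs_to_au(0.5)
        c_ld, _ = propagate_step_ld(c0, e_prev, e_curr, overlap, dt, 20)
        tmat = (overlap - overlap.T) / (2 * dt)
        c_t, _ = electronic_propagate(c0, e_prev, e_curr, tmat, tmat, dt, 20)
        assert np.abs(c_ld - c_t).max() < 1e-5


class TestHopProbabilities:
    def test_zero_coupling_zero_probabilities(self):
        c = np.array([0.8, 0.6], complex)
        g = hop_probabilities(c, np.zeros((2, 2)), 0, fs_to_au(0.5))
        assert np.all(g == 0)

    def test_probabilities_match_population_flux(self):
        """Over a short interval the fewest-switches flux out of the active
        state equals its population loss (internal consistency)."""
        v = 2e-4
        e = np.zeros(2)
        tmat = np.array([[0.0, 1j * v], [1j * v, 0.0]])
        c = np.array([1.0, 0.0], complex)
        dt = fs_to_au(0.5)
        total_g = 0.0
        for _ in range(40):
            p_before = abs(c[0]) ** 2
            g = hop_probabilities(c, tmat, 0, dt)
            c, _ = electronic_propagate(c, e, e, tmat, tmat, dt, 20)
            total_g += g.sum() * p_before
        transferred = abs(c[1]) ** 2
        assert total_g == pytest.approx(transferred, rel=0.05)

    def test_pathological_sum_clipped(self):
        c = np.array([0.05, 0.999], complex)
        c /= np.linalg.norm(c)
        tmat = np.array([[0.0, 5.0], [-5.0, 0.0]])
        g = hop_probabilities(c, tmat, 0, fs_to_au(0.5))
        assert g.sum() <= 1.0 + 1e-12

    def test_empty_active_population_warns_and_zeros(self):
        c = np.array([0.0, 1.0], complex)
        g = hop_probabilities(c, np.ones((2, 2)), 0, fs_to_au(0.5))
        assert np.all(g == 0)


class TestApplyHop:
    @pytest.fixture
    def model(self, two_state_model):
        return two_state_model

    def test_downward_hop_always_accepted(self, model):
        st = _state(model, [0.0], [1.0], active=4)
        e = np.array([0.0, 0.05, 0.08, 0.08, 0.11])
        m = model.masses_au[0]
        ke_before = st.momenta[0] ** 2 / (2 * m)
        new, event = apply_hop(st, 1, model, e)
        assert event.accepted
        ke_after = new.momenta[0] ** 2 / (2 * m)
        assert ke_after - ke_before == pytest.approx(0.11 - 0.05, rel=1e-12)

    def test_frustrated_upward_hop(self, model):
        st = _state(model, [0.0], [0.5], active=0)
        e = np.array([0.0, 0.05, 0.08, 0.08, 0.11])
        new, event = apply_hop(st, 4, model, e)
        assert not event.accepted
        assert new.active == 0
        np.testing.assert_array_equal(new.momenta, st.momenta)

    def test_accepted_hop_conserves_total_energy(self, model, rng):
        m = model.masses_au[0]
        for _ in range(10):
            p = rng.uniform(2.0, 10.0)
            st = _state(model, [0.0], [p], active=0)
            e = np.sort(rng.uniform(0.0, 0.01, 5))
            tgt = int(rng.integers(1, 5))
            new, event = apply_hop(st, tgt, model, e)
            if not event.accepted:
                continue
            before = e[0] + p**2 / (2 * m)
            after = e[tgt] + new.momenta[0] ** 2 / (2 * m)
            assert abs(after - before) < 1e-8


class TestTrajectory:
    def test_alpha_zero_stays_in_s1(self, two_state_model):
        sample = WignerSample(coords=np.array([0.1]), momenta=np.array([1.0]),
                              seed_used=0)
        traj = run_trajectory(
            two_state_model, sample,
            DynamicsParams(t_max_fs=50.0, alpha=0.0, seed=3),
        )
        s1 = traj.diabatic_populations[:, 1]
        np.testing.assert_allclose(s1, 1.0, atol=1e-10)
        assert not traj.hops

    def test_identical_seeds_bit_identical(self, two_state_model):
        sample = WignerSample(coords=np.array([0.05]), momenta=np.array([2.0]),
                              seed_used=0)
        params = DynamicsParams(t_max_fs=30.0, alpha=2.0, seed=11)
        a = run_trajectory(two_state_model, sample, params)
        b = run_trajectory(two_state_model, sample, params)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.diabatic_populations, b.diabatic_populations)
        assert len(a.hops) == len(b.hops)

    def test_populations_sum_to_one(self, two_state_model):
        sample = WignerSample(coords=np.array([0.1]), momenta=np.array([3.0]),
                              seed_used=0)
        traj = run_trajectory(
            two_state_model, sample, DynamicsParams(t_max_fs=40.0, alpha=3.0, seed=5)
        )
        np.testing.assert_allclose(
            traj.diabatic_populations.sum(axis=1), 1.0, atol=1e-8
        )
        np.testing.assert_allclose(
            traj.adiabatic_populations.sum(axis=1), 1.0, atol=1e-8
        )

    def test_energy_conserved_between_hops(self, two_state_model):
        sample = WignerSample(coords=np.array([0.1]), momenta=np.array([3.0]),
                              seed_used=0)
        traj = run_trajectory(
            two_state_model, sample, DynamicsParams(t_max_fs=100.0, alpha=2.0, seed=9)
        )
        e = traj.total_energy_au
        hop_steps = {int(round(h.t_fs / 0.5)) for h in traj.hops}
        diffs = np.abs(np.diff(e))
        ok = [d for k, d in enumerate(diffs) if (k + 1) not in hop_steps]
        assert max(ok) < 2e-6   # between-hop fluctuation, hartree


class TestEnsemble:
    def test_empty_alpha_list(self, two_state_model):
        sample = WignerSample(coords=np.array([0.0]), momenta=np.array([1.0]),
                              seed_used=0)
        assert run_ensemble(two_state_model, [sample],
                            DynamicsParams(t_max_fs=5.0), alphas=[]) == {}

    def test_default_protocol_shape(self, two_state_model):
        from spinhop import sample_wigner
        samples = sample_wigner(two_state_model.modes, 298.0, 2, seed=1)
        out = run_ensemble(
            two_state_model, samples, DynamicsParams(t_max_fs=5.0, seed=4),
            alphas=(2.0, 3.5, 5.0), t_max_per_alpha={5.0: 2.5},
        )
        assert sorted(out) == [2.0, 3.5, 5.0]
        assert all(len(v) == 2 for v in out.values())
        assert out[5.0][0].times_fs[-1] == pytest.approx(2.5)
        assert out[2.0][0].times_fs[-1] == pytest.approx(5.0)

    def test_per_alpha_streams_differ(self, two_state_model):
        from spinhop import sample_wigner
        samples = sample_wigner(two_state_model.modes, 298.0, 1, seed=1)
        out = run_ensemble(
            two_state_model, samples, DynamicsParams(t_max_fs=5.0, seed=4),
            alphas=(2.0, 3.5),
        )
        assert out[2.0][0].seed != out[3.5][0].seed


class TestNoDecoherence:
    def test_decoherence_parameter_fixed_to_none(self):
        with pytest.raises(ValueError):
            DynamicsParams(decoherence="energy_based")
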