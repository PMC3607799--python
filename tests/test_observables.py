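import numpy as np
import pytest
from dataclasses import replace

from burstnet.core_numerics import SimSettings
from burstnet.observables import (array_diagram, chi_coherence,
                                  global_cycle_phase, kuramoto_like_order,
                                  mean_signal, phase_network_report,
                                  rotation_numbers,
                                  rotation_numbers_from_spikes,
                                  variance_order_parameter)
from burstnet.phase_network import PhaseNetConfig, simulate_phase_network


class TestMeanSignal:
    def test_identical_rows(self):
        V = np.tile(np.sin(np.linspace(0, 5, 50))[:, None], (1, 4))
        np.testing.assert_allclose(mean_signal(V), V[:, 0])

    def test_antisymmetric_pair_cancels(self):
        v = np.sin(np.linspace(0, 5, 50))
        V = np.column_stack([v, -v])
        np.testing.assert_allclose(mean_signal(V), 0.0, atol=1e-15)

    def test_constant_rows(self):
        V = np.tile([1.0, 2.0, 3.0], (10, 1))
        np.testing.assert_allclose(mean_signal(V), 2.0)


class TestVarianceOrderParameter:
    def test_constant_is_zero(self):
        assert variance_order_parameter(np.full(100, 3.3)) == 0.0

    def test_sinusoid_half_amplitude_squared(self):
        t = np.linspace(0, 4 * 2 * np.pi, 4000, endpoint=False)
        A = 2.5
        assert variance_order_parameter(A * np.sin(t)) == pytest.approx(
            A ** 2 / 2, rel=1e-3)

    def test_two_level_series(self):
        c = 0.7
        series = np.concatenate([np.full(50, c), np.full(50, -c)])
        assert variance_order_parameter(series) == pytest.approx(c ** 2)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            variance_order_parameter(np.array([]))


class TestKuramotoLikeOrder:
    def test_extremes_and_symmetry(self):
        assert kuramoto_like_order(np.zeros((3, 10)))[0] == pytest.approx(1.0)
        assert kuramoto_like_order(np.full((3, 10), np.pi))[0] == \
            pytest.approx(-1.0)
        even = np.linspace(0, 2 * np.pi, 100, endpoint=False)[None, :]
        assert abs(kuramoto_like_order(even)[0]) < 1e-12


class TestRotationNumbers:
    def test_constant_velocity(self):
        t = np.linspace(0, 10, 200)
        theta = np.column_stack([0.7 * t, -1.2 * t])
        np.testing.assert_allclose(rotation_numbers(t, theta), [0.7, -1.2])

    def test_silent_neuron(self):
        t = np.linspace(0, 100, 500)
        theta = np.full((500, 1), 0.42)
        assert rotation_numbers(t, theta)[0] == 0.0

    def test_from_spike_counts(self):
        t = np.arange(0, 100, 0.1)
        V = np.column_stack([25 * np.sin(2 * np.pi * (t - 1.0) / 10),
                             np.full(t.size, -50.0)])
        rho = rotation_numbers_from_spikes(t, V)
        assert rho[0] == pytest.approx(2 * np.pi * 10 / (t[-1] - t[0]),
                                       rel=0.05)
        assert rho[1] == 0.0


class TestChiCoherence:
    def test_identical_oscillators(self):
        v = np.sin(np.linspace(0, 20, 500))
        assert chi_coherence(np.tile(v[:, None], (1, 8))) == pytest.approx(1.0)

    def test_flat_population_is_zero(self):
        assert chi_coherence(np.zeros((100, 5))) == 0.0

    def test_independent_phases_scale_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 100, 2000)
        chis = {}
        for N in (25, 400):
            V = np.sin(np.add.outer(t, rng.uniform(0, 2 * np.pi, N)))
            chis[N] = chi_coherence(V)
        assert chis[400] < chis[25]
        assert chis[400] < 3.0 / np.sqrt(400)


class TestGlobalCyclePhase:
    def test_sinusoid_phases(self):
        # slightly more than two periods so two complete cycles are interior
        t = np.linspace(-0.3, 4 * np.pi + 0.3, 5000)
        times, phases = global_cycle_phase(t, -np.cos(t))
        # phase at each interior maximum is pi
        for tmax in (np.pi, 3 * np.pi):
            k = np.argmin(np.abs(times - tmax))
            assert phases[k] == pytest.approx(np.pi, abs=0.02)
        assert phases.min() >= 0.0 and phases.max() <= 2 * np.pi

    def test_two_cycles_detected(self):
        t = np.linspace(-0.3, 4 * np.pi + 0.3, 5000)
        times, phases = global_cycle_phase(t, -np.cos(t))
        # each cycle starts at phase ~0: count near-zero resets
        resets = np.flatnonzero(np.diff(phases) < -np.pi)
        assert resets.size == 1  # two complete cycles -> one reset between

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="global cycle"):
            global_cycle_phase(np.linspace(0, 1, 100), np.ones(100))


class TestArrayDiagram:
    def test_shape_and_passthrough(self):
        M = np.arange(15, dtype=float).reshape(5, 3)  # 5 times x 3 neurons
        A = array_diagram(M)
        assert A.shape == (3, 5)
        assert A[1, 2] == M[2, 1]

    def test_sorted_by_initial_phase(self):
        M = np.arange(8, dtype=float).reshape(2, 4)
        A = array_diagram(M, sort_by=np.array([0.3, -1.0, 2.0, 0.0]))
        np.testing.assert_array_equal(A[0], M[:, 1])


class TestReports:
    def test_sr_reference_has_positive_R_and_high_chi(self, sr_phase_net_traj):
        rep = phase_network_report(sr_phase_net_traj)
        assert rep.R > 0.0
        assert rep.chi > 0.5
        assert rep.f_silent == 0.0
        assert np.max(np.abs(rep.R_theta_series)) <= 1.0

    def test_incoherent_R_decreases_with_N(self):
        """Finite-size fluctuations: R at the incoherent reference point
        shrinks roughly like 1/N."""
        Rs = {}
        for N in (100, 400):
            cfg = PhaseNetConfig(N=N, K=0.01, dI=0.1, n=5,
                                 settings=SimSettings(t_end=2500.0,
                                                      t_transient=500.0,
                                                      record_every=10,
                                                      seed=5))
            rep = phase_network_report(simulate_phase_network(cfg))
            Rs[N] = rep.R
        assert Rs[400] < Rs[100]
        assert Rs[400] < Rs[100] / 2  # consistent with ~1/N decay
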