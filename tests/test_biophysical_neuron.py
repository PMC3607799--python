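import numpy as np
import pytest
from scipy.optimize import fsolve

from burstnet.biophysical_neuron import (BiophysParams, BiophysState,
                                         biophysical_rhs, default_initial_state,
                                         detect_spikes, gating_curves,
                                         group_bursts, scan_firing_onset,
                                         simulate_biophysical)
from burstnet.core_numerics import SimSettings


class TestGatingCurves:
    def test_half_activation_at_v1(self):
        p = BiophysParams()
        m, _, _, _ = gating_curves(p.v1, p)
        assert m == pytest.approx(0.5, abs=1e-14)

    def test_saturation(self):
        p = BiophysParams()
        m, w, n, _ = gating_curves(1e4, p)
        assert m == pytest.approx(1.0) and w == pytest.approx(1.0)
        assert n == pytest.approx(1.0)

    def test_printed_formula_value(self):
        # m_inf(-40) with v1=-1.2, v2=18
        p = BiophysParams()
        m, _, _, _ = gating_curves(-40.0, p)
        assert m == pytest.approx(0.5 * (1 + np.tanh(-38.8 / 18.0)), rel=1e-12)
        assert m == pytest.approx(0.0133, abs=2e-4)

    def test_paper_literal_variant_differs(self):
        canon = BiophysParams()
        lit = BiophysParams.from_variant("paper_literal")
        assert lit.v1 == 1.2 and lit.V_l == 60.0
        _, _, _, tw_c = gating_curves(-20.0, canon)
        _, _, _, tw_l = gating_curves(-20.0, lit)
        assert tw_c != tw_l


class TestRhs:
    def test_w_at_steady_state_has_zero_derivative(self):
        p = BiophysParams()
        _, w_inf, _, _ = gating_curves(-30.0, p)
        d = biophysical_rhs((-30.0, float(w_inf), 0.4, 0.2), 50.0, p)
        assert d[1] == pytest.approx(0.0, abs=1e-14)

    def test_calcium_grows_when_depleted_and_current_inward(self):
        p = BiophysParams()
        state = (-10.0, 0.1, 0.0, 0.5)  # I_Ca < 0 at V < V_Ca with n > 0
        d = biophysical_rhs(state, 60.0, p)
        assert d[2] > 0

    def test_vanishes_at_numerical_equilibrium(self):
        p = BiophysParams()
        root = fsolve(lambda y: biophysical_rhs(y, 30.0, p),
                      default_initial_state(p).as_array(), full_output=False)
        assert np.max(np.abs(biophysical_rhs(root, 30.0, p))) < 1e-8

    def test_state_clipping(self):
        s = BiophysState(V=-50.0, w=1.5, Ca=-0.2, n=-0.1)
        assert s.w == 1.0 and s.Ca == 0.0 and s.n == 0.0


class TestSingleNeuronRegimes:
    def test_quiescent_at_low_drive(self):
        traj = simulate_biophysical(
            30.0, settings=SimSettings(t_end=8000.0, t_transient=3000.0))
        V = traj.V[traj.transient_index:]
        assert V.max() - V.min() < 5.0

    def test_bursting_at_68(self, burst_traj_68):
        i0 = burst_traj_68.transient_index
        spikes = detect_spikes(burst_traj_68.t[i0:], burst_traj_68.V[i0:])
        bursts = group_bursts(spikes)
        multi = [c for c, _ in bursts if c >= 2]
        assert len(multi) >= 2  # several multi-spike bursts with gaps

    def test_tonic_at_70(self, tonic_traj_70):
        i0 = tonic_traj_70.transient_index
        spikes = detect_spikes(tonic_traj_70.t[i0:], tonic_traj_70.V[i0:])
        assert spikes.size >= 50
        isi = np.diff(spikes)
        # periodic single-spike train: no multi-spike grouping
        assert isi.max() < 3.0 * np.median(isi)

    def test_gating_bounds_along_trajectory(self, burst_traj_68):
        assert np.all(burst_traj_68.w >= 0) and np.all(burst_traj_68.w <= 1)
        assert np.all(burst_traj_68.n >= 0) and np.all(burst_traj_68.n <= 1)
        assert np.all(burst_traj_68.Ca >= 0)

    def test_within_burst_isi_is_u_shaped(self, burst_traj_68):
        """Parabolic signature: first and last ISI exceed the interior
        minimum."""
        i0 = burst_traj_68.transient_index
        spikes = detect_spikes(burst_traj_68.t[i0:], burst_traj_68.V[i0:])
        bursts = [b for b in group_bursts(spikes) if b[0] >= 4]
        assert bursts
        for _, isi in bursts:
            assert isi[0] > isi[1:-1].min()
            assert isi[-1] > isi[1:-1].min()


class TestSpikeDetection:
    def test_flat_series_no_spikes(self):
        t = np.arange(100) * 0.1
        assert detect_spikes(t, np.full(100, -50.0)).size == 0

    def test_sinusoid_one_spike_per_period(self):
        t = np.arange(0, 6 * 2 * np.pi, 0.01)
        sp = detect_spikes(t, 25 * np.sin(t - 0.5), threshold=0.0,
                           refractory=1.0)
        assert sp.size == 6
        np.testing.assert_allclose(np.diff(sp), 2 * np.pi, atol=0.02)

    def test_refractory_suppression(self):
        t = np.array([0.0, 0.05, 0.1, 0.15, 0.2])
        V = np.array([-1.0, 1.0, -1.0, 1.0, -1.0])  # two crossings 0.1 apart
        sp = detect_spikes(t, V, threshold=0.0, refractory=2.0)
        assert sp.size == 1


class TestBurstGrouping:
    def test_two_bursts(self):
        times = [0, 1, 2, 3, 23, 24, 25, 26]
        bursts = group_bursts(times, gap_factor=3.0)
        assert [c for c, _ in bursts] == [4, 4]

    def test_single_spike(self):
        assert group_bursts([5.0]) == [(1, pytest.approx(np.empty(0)))] or \
            group_bursts([5.0])[0][0] == 1

    def test_uniform_train_is_one_burst(self):
        bursts = group_bursts(np.arange(20) * 1.0, gap_factor=3.0)
        assert len(bursts) == 1 and bursts[0][0] == 20

    def test_empty(self):
        assert group_bursts([]) == []


class TestOnsetScan:
    def test_scan_semantics_above_onset(self):
        """A scan starting above the true onset returns its first value."""
        onset = scan_firing_onset(
            65.0, 70.0, 1.0,
            settings=SimSettings(t_end=12000.0, t_transient=4000.0,
                                 record_every=4))
        assert onset == 65.0

    def test_subthreshold_scan_returns_none(self):
        onset = scan_firing_onset(
            0.0, 30.0, 10.0,
            settings=SimSettings(t_end=6000.0, t_transient=2000.0,
                                 record_every=4))
        assert onset is None

    def test_onset_invariant_to_halving_dt(self):
        res = {}
        for dt in (0.05, 0.025):
            res[dt] = scan_firing_onset(
                58.0, 64.0, 1.0,
                settings=SimSettings(dt=dt, t_end=15000.0, t_transient=5000.0,
                                     record_every=4))
        assert res[0.05] == res[0.025]

    def test_step_must_be_positive(self):
        with pytest.raises(ValueError):
            scan_firing_onset(40.0, 80.0, 0.0)
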