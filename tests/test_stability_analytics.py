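import numpy as np
import pandas as pd
import pytest

from burstnet.phase_model import period_single
from burstnet.stability_analytics import (AnalyticsParams,
                                          critical_line_in_sr,
                                          critical_line_po_in,
                                          detect_in_sr_transition,
                                          drift_derivative, fit_boundaries,
                                          fixed_points, stability_eigenvalue,
                                          stationary_density, velocity_field)


class TestVelocityField:
    def test_reduces_to_free_flow(self):
        th = np.linspace(-5 * np.pi, 5 * np.pi, 11)
        np.testing.assert_allclose(
            velocity_field(th, 2.5, 0.0, 5),
            2.5 - np.cos(th) - np.cos(th / 5), rtol=1e-12)

    def test_response_vanishes_at_origin(self):
        assert velocity_field(0.0, 2.5, 0.9, 5) == pytest.approx(0.5)

    def test_printed_example(self):
        v = velocity_field(np.pi / 4, 2.5, 0.3, n=1)
        assert v == pytest.approx(2.5 - np.sqrt(2) - 0.3 * 0.5, rel=1e-12)
        assert v == pytest.approx(0.9358, abs=1e-4)


class TestFixedPoints:
    def test_fast_rotation_has_none(self):
        assert fixed_points(3.5, 0.2, n=5) == []

    def test_free_flow_roots_n1(self):
        fps = fixed_points(1.5, 0.0, n=1)
        assert len(fps) == 2
        thetas = sorted(th for th, _ in fps)
        np.testing.assert_allclose(np.abs(thetas),
                                   np.arccos(0.75), atol=1e-9)
        stabilities = {s for _, s in fps}
        assert stabilities == {"stable", "unstable"}

    def test_root_count_is_even(self):
        for I, G in [(1.5, 0.0), (1.9, 0.4), (2.001, 0.5)]:
            assert len(fixed_points(I, G, n=5)) % 2 == 0


class TestEigenvalue:
    def test_free_flow_is_marginal_at_origin(self):
        assert stability_eigenvalue(0.0, 2.0, 0.0, n=5) == 0.0

    def test_coupling_stabilizes_origin(self):
        assert stability_eigenvalue(0.0, 2.0, 0.5, n=5) == pytest.approx(-0.5)

    def test_slow_term_destabilizes_antipode(self):
        assert stability_eigenvalue(np.pi, 2.0, 0.0, n=2) == pytest.approx(0.5)

    @pytest.mark.parametrize("theta,I,G,n", [
        (0.0, 2.1, 0.3, 5), (np.pi, 2.5, 0.7, 3), (1.234, 1.8, 0.2, 1)])
    def test_matches_centered_finite_difference(self, theta, I, G, n):
        h = 1e-5
        fd = (velocity_field(theta + h, I, G, n)
              - velocity_field(theta - h, I, G, n)) / (2 * h)
        assert stability_eigenvalue(theta, I, G, n) == pytest.approx(
            float(fd), abs=1e-8)


class TestStationaryDensity:
    def test_normalized_to_one(self):
        d = stationary_density(2.5, 0.2, n=5)
        assert d.kind == "density"
        integral = np.trapezoid(d.density, d.theta)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_density_peaks_at_slowest_point(self):
        d = stationary_density(2.1, 0.1, n=5)
        v = velocity_field(d.theta, 2.1, 0.1, 5)
        assert np.argmax(d.density) == np.argmin(v)

    def test_near_constant_drift_is_near_uniform(self):
        d = stationary_density(100.0, 0.0, n=1)
        assert d.density.max() / d.density.min() < 1.05

    def test_rotation_number_prediction_matches_period(self):
        """2 pi n L equals 2 pi n / T from the quadrature oracle (Gamma=0)."""
        for I in (2.1, 2.5, 4.0):
            d = stationary_density(I, 0.0, n=5)
            assert d.rotation_number == pytest.approx(
                2 * np.pi * 5 / period_single(I, 5), rel=1e-4)

    def test_pinned_case_returns_fixed_point(self):
        d = stationary_density(1.5, 0.0, n=1)
        assert d.kind == "point_mass"
        assert d.rotation_number == 0.0
        assert d.fixed_point == pytest.approx(-np.arccos(0.75), abs=1e-6)

    def test_partition_consistency(self):
        """Root-free drift <=> normalizable rotating density, on an
        (I, Gamma) grid."""
        for I in np.linspace(1.6, 3.0, 8):
            for G in np.linspace(0.0, 0.6, 4):
                fps = fixed_points(I, G, n=5)
                dens = stationary_density(I, G, n=5)
                assert (len(fps) == 0) == (dens.kind == "density")

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            stationary_density(2.5, 0.0, n=5, resolution=16)


class TestCriticalLines:
    def test_po_in_line_through_critical_dispersion(self):
        p = AnalyticsParams()
        assert critical_line_po_in(p.dI_c, p) == 0.0
        assert critical_line_po_in(0.3, AnalyticsParams(dI_c=0.1)) == \
            pytest.approx(0.2)
        assert critical_line_po_in(0.5, p) == pytest.approx(
            2 * critical_line_po_in(0.3, p))

    def test_po_in_below_critical_rejected(self):
        with pytest.raises(ValueError, match="critical dispersion"):
            critical_line_po_in(0.05, AnalyticsParams(dI_c=0.1))

    def test_in_sr_cubic(self):
        p = AnalyticsParams()
        assert critical_line_in_sr(0.0, p) == 0.0
        assert critical_line_in_sr(0.1, p) == pytest.approx(
            (8 / np.pi) * 0.1 + (128 / np.pi ** 3) * 1e-3, rel=1e-12)
        assert critical_line_in_sr(0.1, p) == pytest.approx(0.2587, abs=1e-4)
        dI = np.linspace(0, 1, 50)
        assert np.all(np.diff(critical_line_in_sr(dI, p)) > 0)

    def test_fit_recovers_synthetic_boundaries(self):
        em_true, dIc_true = 0.8, 0.15
        rows = []
        for dI in np.arange(0.2, 0.65, 0.05):
            for K in np.arange(0.02, 1.0, 0.02):
                label = "PO" if K > em_true * (dI - dIc_true) else "IN"
                rows.append({"K": round(K, 3), "dI": round(dI, 3),
                             "label": label})
        fitted = fit_boundaries(pd.DataFrame(rows))
        assert fitted.eps_pert * fitted.m == pytest.approx(em_true, rel=0.1)
        assert fitted.dI_c == pytest.approx(dIc_true, abs=0.03)

    def test_numerical_in_sr_transition_increases_with_dispersion(self):
        """Bisection in K at fixed dI: the synchrony onset coupling grows
        with heterogeneity, as the Hopf line predicts. Dispersions sit
        inside the coherent sliver of the mean-field normalization."""
        ks = [detect_in_sr_transition(dI, N=200, n=1, master_seed=3)
              for dI in (0.0003, 0.0005, 0.001)]
        assert all(np.isfinite(ks))
        assert ks[0] < ks[1] < ks[2]
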