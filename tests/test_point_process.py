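"""Renewal densities, the rescaling integral, and the sequence likelihood."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import caspike as cs
from caspike.point_process import DomainError, ParameterError


def grid(values, delta=0.1):
    return cs.IntensityGrid(np.asarray(values, dtype=float), delta)


class TestRescaleIntegral:
    def test_zero_intensity(self):
        assert cs.rescale_integral(grid(np.zeros(101)), 0, 10) == 0

    def test_constant_rate_closed_form(self):
        assert cs.rescale_integral(grid(np.full(101, 2.0)), 1, 4) == pytest.approx(6.0)

    def test_xdet_antiderivative(self):
        # antiderivative 0.5 sin t + sin(t/2) + t over one slow period [0, 2pi]
        delta = 1e-3
        n = int(round(2 * np.pi / delta))
        x = grid(cs.x_det(np.arange(n + 1) * delta), delta)
        assert cs.rescale_integral(x, 0, x.t_end) == pytest.approx(2 * np.pi, abs=5e-3)

    def test_additivity_and_monotonicity(self):
        rng = np.random.default_rng(0)
        x = grid(rng.uniform(0, 3, 101))
        a, b, c = 0.5, 3.1, 7.9
        full = cs.rescale_integral(x, a, c)
        assert full == pytest.approx(
            cs.rescale_integral(x, a, b) + cs.rescale_integral(x, b, c), rel=1e-12
        )
        vals = [cs.rescale_integral(x, 0, t) for t in np.arange(0, 10.1, 0.5)]
        assert np.all(np.diff(vals) >= 0)

    def test_out_of_window_raises(self):
        with pytest.raises(DomainError):
            cs.rescale_integral(grid(np.ones(101)), -1, 5)
        with pytest.raises(DomainError):
            cs.rescale_integral(grid(np.ones(101)), 0, 11)

    def test_negative_intensity_rejected_at_construction(self):
        with pytest.raises(ValueError):
            grid([-1.0, 1.0])


class TestISIDensity:
    def test_unit_rate_poisson_lag_one(self, unit_intensity):
        d = cs.isi_density(cs.ISIModel("IP"), unit_intensity, 1, 2)
        assert d == pytest.approx(np.exp(-1))

    def test_ig_shape_two_closed_form(self, unit_intensity):
        d = cs.isi_density(cs.ISIModel("IG", 2.0), unit_intensity, 0, 1)
        assert d == pytest.approx(4 * np.exp(-2))

    @given(st.floats(0.1, 3), st.floats(0.2, 6))
    def test_ig_gamma_one_equals_ip(self, y_prev, lag):
        x = grid(1 + 0.8 * np.sin(np.arange(201) * 0.05), 0.05)
        a, b = y_prev, y_prev + lag
        assert cs.isi_density(cs.ISIModel("IG", 1.0), x, a, b) == pytest.approx(
            cs.isi_density(cs.ISIModel("IP"), x, a, b), rel=1e-12
        )

    @pytest.mark.parametrize("family,shape", [("IP", None), ("IG", 3.0), ("IIG", 1.5)])
    def test_constant_intensity_time_homogeneous(self, family, shape):
        x = grid(np.full(401, 1.7), 0.05)
        m = cs.ISIModel(family, shape)
        d1 = cs.isi_density(m, x, 1.0, 3.5)
        d2 = cs.isi_density(m, x, 8.0, 10.5)
        assert d1 == pytest.approx(d2, rel=1e-12)

    @pytest.mark.parametrize("family,shape", [("IP", None), ("IG", 4.0), ("IIG", 1.2)])
    def test_density_integrates_to_at_most_one(self, family, shape):
        # constant extension: integrate over the lag with fine quadrature
        m = cs.ISIModel(family, shape)
        c = 1.3
        x = grid(np.full(4001, c), 0.05)
        lags = np.arange(1, 3800) * 0.05
        dens = np.array([cs.isi_density(m, x, 0, lag) for lag in lags])
        assert np.trapezoid(dens, lags) <= 1.0 + 1e-6

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(ParameterError):
            cs.ISIModel("IG", 0.0)
        with pytest.raises(ParameterError):
            cs.ISIModel("IIG", -1.0)


class TestConditionalIntensity:
    def test_ip_hazard_equals_intensity(self):
        x = grid(1 + 0.8 * np.sin(np.arange(201) * 0.05), 0.05)
        for t in (0.5, 3.05, 7.2):
            assert cs.conditional_intensity(cs.ISIModel("IP"), x, t, 0.1) == pytest.approx(
                float(x.values[int(round(t / 0.05))]), rel=1e-12
            )

    def test_ig_gamma_two_hazard_value(self, unit_intensity):
        # Gamma(2, rate 2) hazard 4v/(1+2v) at v = 0.5 is 1
        q = cs.conditional_intensity(cs.ISIModel("IG", 2.0), unit_intensity, 0.5, 0.0)
        assert q == pytest.approx(1.0)

    @pytest.mark.parametrize("model", [cs.ISIModel("IG", 3.0), cs.ISIModel("IIG", 1.0)])
    def test_refractory_suppression_near_last_spike(self, model):
        # hazard vanishes as t -> y_last+ for shape-suppressed families
        x = grid(np.ones(1001), 0.01)
        q_near = cs.conditional_intensity(model, x, 0.05, 0.0)
        q_mid = cs.conditional_intensity(model, x, 1.0, 0.0)
        assert q_near < 0.05 * q_mid

    def test_requires_t_after_last_spike(self, unit_intensity):
        with pytest.raises(DomainError):
            cs.conditional_intensity(cs.ISIModel("IP"), unit_intensity, 1.0, 2.0)


class TestSequenceLogDensity:
    def test_single_spike_closed_form(self):
        y = cs.SpikeSequence(np.array([1.0]), t_end=2.0, delta=0.1)
        x = grid(np.ones(21))
        assert cs.sequence_log_density(y, x, cs.ISIModel("IP")) == pytest.approx(-2.0)

    def test_empty_sequence_survival(self):
        y = cs.SpikeSequence(np.empty(0), t_end=10.0, delta=0.1)
        x = grid(np.full(101, 1.4))
        for fam, shape in (("IP", None), ("IG", 3.0)):
            assert cs.sequence_log_density(y, x, cs.ISIModel(fam, shape)) == pytest.approx(-14.0)

    def test_matches_termwise_product_oracle(self):
        """Independent term-by-term evaluation: Poisson boundary terms plus
        Gamma(gamma, rate gamma) renewal densities of the rescaled ISIs."""
        rng = np.random.default_rng(7)
        delta = 0.1
        xv = rng.uniform(0.5, 3.0, 121)
        x = grid(xv, delta)
        idx = np.array([11, 30, 52, 80, 104])
        y = cs.SpikeSequence(idx * delta, t_end=12.0, delta=delta)
        gamma = 6.2
        Xseg = lambda a, b: xv[a:b].sum() * delta
        oracle = np.log(xv[idx[0]]) - Xseg(0, idx[0]) - Xseg(idx[-1], 120)
        for a, b in zip(idx[:-1], idx[1:]):
            X = Xseg(a, b)
            oracle += np.log(xv[b]) + stats.gamma.logpdf(X, gamma, scale=1 / gamma)
        val = cs.sequence_log_density(y, x, cs.ISIModel("IG", gamma))
        assert val == pytest.approx(oracle, rel=1e-10)

    def test_spike_outside_window_raises(self):
        x = grid(np.ones(21))
        y = cs.SpikeSequence(np.array([1.0]), t_end=4.0, delta=0.1)
        with pytest.raises(DomainError):
            cs.sequence_log_density(y, x, cs.ISIModel("IP"))


class TestInvariants:
    def test_spike_sequence_ordering_enforced(self):
        with pytest.raises(ValueError):
            cs.SpikeSequence(np.array([2.0, 1.0]), t_end=5.0, delta=0.1)
        with pytest.raises(ValueError):
            cs.SpikeSequence(np.array([-1.0]), t_end=5.0, delta=0.1)

    def test_frame_spacing_validation(self):
        s = cs.SpikeSequence(np.array([1.0, 1.01]), t_end=5.0, delta=0.1)
        with pytest.raises(ValueError):
            s.validate_frame_spacing()

    def test_ig_equals_ip_at_shape_one_for_log_density(self, ig_cells, xdet_fine):
        y = ig_cells[0]
        v1 = cs.sequence_log_density(y, xdet_fine, cs.ISIModel("IG", 1.0))
        v2 = cs.sequence_log_density(y, xdet_fine, cs.ISIModel("IP"))
        assert v1 == pytest.approx(v2, rel=1e-12)
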