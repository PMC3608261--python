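"""Q-ball, DOT propagator shells, and the DOT-ODF reconstructions."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import spherical_jn

from hardiopt import peak_analysis as pk
from hardiopt import reconstruction as rc
from hardiopt import signal_sim as sim
from hardiopt import sphere_math as sm

D0 = 2.02e-3  # mm^2/s


def isotropic_signal(scheme, b, d=D0):
    return np.full(scheme.n_gradients, np.exp(-b * d))


class TestEstimateADC:
    def test_inverts_monoexponential_decay(self, scheme_72):
        adc = rc.estimate_adc(np.full(72, np.exp(-1.0)), scheme_72, b=1000.0)
        assert np.allclose(adc.d_values, 1.0e-3)

    def test_recovers_free_water_diffusivity(self, scheme_72):
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 2000.0), scheme_72, 2000.0)
        assert np.allclose(adc.d_values, D0, rtol=1e-12)
        assert adc.n_clamped == 0

    def test_degenerate_values_clamped_and_flagged(self, scheme_72):
        e = isotropic_signal(scheme_72, 1000.0)
        e[0] = 1.2  # noise pushed above baseline
        e[1] = 0.0
        adc = rc.estimate_adc(e, scheme_72, 1000.0)
        assert adc.n_clamped == 2
        assert adc.d_values[0] == pytest.approx(-np.log(1 - 1e-6) / 1000.0)
        assert adc.d_values[1] == pytest.approx(rc.D_MAX_CLAMP)

    def test_all_nonpositive_rejected(self, scheme_72):
        with pytest.raises(ValueError, match="non-positive"):
            rc.estimate_adc(np.zeros(72), scheme_72, 1000.0)


class TestQballODF:
    def test_isotropic_signal_gives_constant_odf(self, scheme_72, mesh4):
        k = float(np.exp(-1000 * D0))
        odf = rc.qball_odf(isotropic_signal(scheme_72, 1000.0), scheme_72, lmax=6)
        values = odf.sample(mesh4)
        assert np.abs(values - 2 * np.pi * k).max() < 1e-10

    def test_matches_numerical_funk_radon_transform(self, scheme_72, mesh4):
        """Great-circle quadrature of the SH-interpolated signal is the
        independent definition of the transform; the analytical eigenvalue
        route must agree."""
        prot = sim.protocol_for_b(2000)
        signal = sim.crossing_signal(sim.two_fiber_phantom(60.0), scheme_72, prot)
        lmax = 6
        odf = rc.qball_odf(signal, scheme_72, lmax=lmax)
        fitted = sm.fit_sh(signal.attenuations, scheme_72.directions, lmax)
        probe = mesh4.vertices[::97]
        n_quad = 720
        t = np.linspace(0.0, 2 * np.pi, n_quad, endpoint=False)
        numerical = []
        for u in probe:
            # orthonormal frame spanning the great circle perpendicular to u
            a = np.array([1.0, 0.0, 0.0])
            if abs(u @ a) > 0.9:
                a = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(u, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            circle = np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2)
            numerical.append(fitted.evaluate(circle).mean() * 2 * np.pi)
        numerical = np.array(numerical)
        analytic = odf.sample(probe)
        rel = np.abs(analytic - numerical).max() / np.abs(numerical).max()
        assert rel < 1e-3

    def test_single_fiber_maximum_on_axis(self, scheme_72, mesh5):
        prot = sim.protocol_for_b(3000)
        fib = sim.FiberPopulation(axis=[0, 0, 1])
        signal = sim.crossing_signal([fib], scheme_72, prot)
        odf = rc.qball_odf(signal, scheme_72, lmax=6)
        peaks = pk.find_maxima(odf.sample(mesh5), mesh5, 0.5)
        assert len(peaks) == 1
        ang = np.degrees(np.arccos(abs(peaks.directions[0] @ fib.axis)))
        assert ang <= 1.5  # within order-5 mesh resolution

    def test_underdetermined_raises(self):
        scheme = sim.generate_gradient_scheme(24, seed=1)
        with pytest.raises(ValueError, match="45"):
            rc.qball_odf(np.ones(24), scheme, lmax=8)


class TestRadialCoefficients:
    @pytest.mark.parametrize(
        "l,expected",
        [(0, 1 / (8 * np.pi)), (2, 1 / (16 * np.pi)), (4, 3 / (64 * np.pi)),
         (6, 5 / (128 * np.pi)), (8, 35 / (1024 * np.pi))],
    )
    def test_closed_form_table(self, l, expected):
        assert rc.radial_coefficient(l) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("l", [0, 2, 4, 6, 8])
    def test_bessel_integral_route_agrees(self, l):
        assert abs(
            rc.radial_coefficient_quadrature(l) - rc.radial_coefficient(l)
        ) < 1e-6

    def test_strictly_decreasing_in_l(self):
        vals = [rc.radial_coefficient(l) for l in (0, 2, 4, 6, 8)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_odd_degree_rejected(self):
        with pytest.raises(ValueError):
            rc.radial_coefficient(3)


class TestAnalyticalDOTODF:
    def test_isotropic_closed_form(self, scheme_72, mesh4):
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 1000.0), scheme_72,
                              1000.0, lmax=6)
        odf = rc.dot_odf_analytical(adc, t_ms=24.0)
        values = odf.sample(mesh4)
        expected = 1.0 / (8 * np.pi * 0.024 * D0)
        assert expected == pytest.approx(821.0, abs=0.5)
        assert np.abs(values / expected - 1.0).max() < 1e-8

    def test_degree0_scaling_linearity(self, scheme_72):
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 1000.0), scheme_72,
                              1000.0, lmax=4)
        odf = rc.dot_odf_analytical(adc, t_ms=24.0)
        expected = rc.radial_coefficient(0) / 0.024 * adc.sh_reciprocal.coeffs[0]
        assert odf.sh.coeffs[0] == pytest.approx(expected, rel=1e-12)
        assert np.abs(odf.sh.coeffs[1:]).max() < 1e-8 * abs(odf.sh.coeffs[0])

    def test_agrees_with_numerical_dot_odf_on_crossing(self, scheme_72, mesh4):
        prot = sim.protocol_for_b(2000)
        signal = sim.crossing_signal(sim.two_fiber_phantom(60.0), scheme_72, prot)
        adc = rc.estimate_adc(signal, scheme_72, 2000.0, lmax=6)
        analytic = rc.dot_odf_analytical(adc, prot.t_ms).sample(mesh4)
        numeric = rc.dot_odf_numerical(adc, prot.t_ms).sample(mesh4)
        gap = np.abs(analytic - numeric).max() / np.abs(analytic).max()
        assert gap < 0.01

    def test_rejects_bad_inputs(self, scheme_72):
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 1000.0), scheme_72,
                              1000.0, lmax=4)
        with pytest.raises(ValueError, match="positive"):
            rc.dot_odf_analytical(adc, t_ms=-1.0)


class TestDOTPdfShell:
    def test_isotropic_gaussian_propagator(self, scheme_72, mesh4):
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 1500.0), scheme_72,
                              1500.0, lmax=4)
        t_ms = 26.5
        for r0_um in (0.0, 8.0, 16.0):
            shell = rc.dot_pdf_shell(adc, r0_um * 1e-3, t_ms, lmax=4)
            td = t_ms * 1e-3 * D0
            expected = (4 * np.pi * td) ** -1.5 * np.exp(-(r0_um * 1e-3) ** 2 / (4 * td))
            values = shell.sample(mesh4)
            assert np.abs(values / expected - 1.0).max() < 1e-6

    def test_crossing_shell_maxima_on_fiber_axes(self, scheme_72, mesh5):
        prot = sim.protocol_for_b(1500)
        phantom = sim.two_fiber_phantom(90.0)
        signal = sim.crossing_signal(phantom, scheme_72, prot)
        adc = rc.estimate_adc(signal, scheme_72, 1500.0, lmax=6)
        shell = rc.dot_pdf_shell(adc, 16e-3, prot.t_ms, lmax=6)
        peaks = pk.find_maxima(shell.sample(mesh5), mesh5, 0.5)
        match = pk.angular_error(np.array([f.axis for f in phantom]), peaks)
        assert match.success
        assert match.error_deg <= 2.0  # order-5 mesh resolution + fit bias


class TestNumericalDOTODF:
    def test_isotropic_uniform_weight_converges(self, scheme_72, mesh4):
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 1000.0), scheme_72,
                              1000.0, lmax=4)
        odf = rc.dot_odf_numerical(adc, 24.0)
        expected = 1.0 / (8 * np.pi * 0.024 * D0)
        assert np.abs(odf.sample(mesh4) / expected - 1.0).max() < 0.005

    def test_isotropic_modf_is_normalized_density(self, scheme_72, mesh4):
        # closed form: Int r^2 (4 pi t D)^{-3/2} exp(-r^2/4tD) dr = 1/(4 pi)
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 1000.0), scheme_72,
                              1000.0, lmax=4)
        modf = rc.dot_odf_numerical(adc, 24.0, weight="r_squared")
        values = modf.sample(mesh4)
        assert np.abs(values * 4 * np.pi - 1.0).max() < 0.01
        sphere_integral = (modf.sample(mesh4) * mesh4.vertex_weights).sum()
        assert sphere_integral == pytest.approx(1.0, abs=0.01)

    def test_doubling_steps_is_converged(self, scheme_72, mesh4):
        prot = sim.protocol_for_b(2000)
        signal = sim.crossing_signal(sim.two_fiber_phantom(60.0), scheme_72, prot)
        adc = rc.estimate_adc(signal, scheme_72, 2000.0, lmax=6)
        a = rc.dot_odf_numerical(adc, prot.t_ms, n_steps=64).sample(mesh4)
        b = rc.dot_odf_numerical(adc, prot.t_ms, n_steps=128).sample(mesh4)
        assert np.abs(a - b).max() / np.abs(a).max() < 1e-3

    def test_truncation_warning(self, scheme_72):
        adc = rc.estimate_adc(isotropic_signal(scheme_72, 1000.0), scheme_72,
                              1000.0, lmax=4)
        with pytest.warns(RuntimeWarning, match="truncation"):
            rc.dot_odf_numerical(adc, 24.0, r0_max_mm=1e-3)


class TestMethodTrends:
    def test_noiseless_error_nonincreasing_in_b(self, scheme_72, mesh5):
        """Higher diffusion weighting sharpens noiseless 60-degree crossings."""
        axes = np.array([f.axis for f in sim.two_fiber_phantom(60.0)])
        errors = {}
        for b in (1000.0, 2000.0, 3000.0):
            prot = sim.protocol_for_b(b)
            signal = sim.crossing_signal(sim.two_fiber_phantom(60.0), scheme_72, prot)
            odf = rc.qball_odf(signal, scheme_72, lmax=6)
            peaks = pk.find_maxima(odf.sample(mesh5), mesh5, 0.5)
            match = pk.angular_error(axes, peaks)
            errors[b] = match.error_deg if match.success else np.inf
        assert errors[3000.0] <= errors[1000.0] + 1e-9

    def test_90_degree_crossing_resolved_at_low_b_low_order(self, scheme_72, mesh5):
        phantom = sim.two_fiber_phantom(90.0)
        prot = sim.protocol_for_b(1000)
        signal = sim.crossing_signal(phantom, scheme_72, prot)
        axes = np.array([f.axis for f in phantom])
        for odf in (
            rc.qball_odf(signal, scheme_72, lmax=4),
            rc.dot_odf_analytical(
                rc.estimate_adc(signal, scheme_72, 1000.0, lmax=4), prot.t_ms
            ),
        ):
            peaks = pk.find_maxima(odf.sample(mesh5), mesh5, 0.5)
            match = pk.angular_error(axes, peaks)
            assert match.success
            assert match.error_deg <= 1.0 + pk.mesh_resolution_deg(5)


def test_bessel_integral_quadrature_oracle():
    """Direct check of the l=6 radial integral against its closed form."""
    value, _ = quad(lambda x: spherical_jn(6, x), 0.0, 400.0, limit=800)
    tail = [
        quad(lambda x: spherical_jn(6, x), 400 + k * np.pi, 400 + (k + 1) * np.pi)[0]
        for k in range(20)
    ]
    partial = value + np.cumsum(tail)
    estimate = partial[-10:].mean() / (4 * np.pi**2)
    assert estimate == pytest.approx(5 / (128 * np.pi), abs=1e-6)
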