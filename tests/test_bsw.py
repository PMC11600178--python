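"""Spectrum closed forms are checked against direct quadrature oracles
and the fit against self-generated curves."""

import numpy as np
import pytest
from scipy.integrate import quad

from microrheo import bsw
from microrheo.errors import GridError
from microrheo.msd import MSDCurve


def simple_spectrum(alpha=(0.4, 0.9, 1.6), taus=(0.01, 1.0, 100.0, 1e4),
                    C=100.0, **kw):
    return bsw.BSWSpectrum.from_alpha(np.array(taus), np.array(alpha), C,
                                      **kw)


def msd_quadrature(spec, t):
    """Direct numerical integration of the defining τ-integral."""
    def f1(x):
        return 1.0 - np.exp(-x) * (1.0 + x)

    tot = 0.0
    for j in range(spec.n_max):
        tot += quad(lambda u: spec.g[j] * u ** (spec.alpha[j] - 1)
                    * f1(t / u), spec.tau[j], spec.tau[j + 1], limit=500)[0]
    return tot + spec.g0 * float(spec._terminal(np.atleast_1d(t))[0])


def fourier_damped(spec, w, eps_fracs=(0.04, 0.02, 0.01)):
    """Damped one-sided transform, Richardson-extrapolated to zero
    damping: the independent oracle for the closed-form transform."""
    vals = []
    for ef in eps_fracs:
        eps = ef * w
        L = 60.0 / eps
        f = (lambda t: float(spec.eval_msd(t)) * np.exp(-eps * t)
             if t > 0 else 0.0)  # noqa: E731
        re = quad(f, 0, L, weight="cos", wvar=w, limit=20000)[0]
        im = -quad(f, 0, L, weight="sin", wvar=w, limit=20000)[0]
        s = eps + 1j * w
        g0, tm = spec.g0, spec.tau_max
        tail = 0.0
        if L > 3 * tm:  # asymptote g0·(t/tm + 1 − β − τv/tm)
            off = g0 * (1.0 - spec.beta - spec.tau_v / tm)
            tail = np.exp(-s * L) * (g0 / tm * (L / s + 1 / s ** 2)
                                     + off / s)
        vals.append(re + 1j * im + tail)
    v1, v2, v3 = vals
    return (8 * v3 - 6 * v2 + v1) / 3.0


class TestClosedForms:
    def test_short_time_ballistic_limit(self):
        spec = simple_spectrum()
        t = spec.tau[0] / 100
        assert spec.eval_msd(t) == pytest.approx(spec.C * t * t, rel=0.01)

    def test_long_time_diffusive_slope(self):
        spec = simple_spectrum()
        t = 100 * spec.tau_max
        slope = np.log(spec.eval_msd(2 * t) / spec.eval_msd(t)) / np.log(2)
        assert slope == pytest.approx(1.0, rel=0.01)

    def test_g0_equals_spectrum_integral(self):
        spec = simple_spectrum()
        total = sum(quad(lambda u: spec.g[j] * u ** (spec.alpha[j] - 1),
                         spec.tau[j], spec.tau[j + 1])[0]
                    for j in range(spec.n_max))
        assert spec.g0 == pytest.approx(total, rel=1e-10)

    @pytest.mark.parametrize("t", [1e-4, 1e-2, 0.5, 5.0, 5e3, 1e5])
    def test_eval_matches_quadrature(self, t):
        spec = simple_spectrum()
        assert spec.eval_msd(t) == pytest.approx(msd_quadrature(spec, t),
                                                 rel=1e-6)

    def test_eval_matches_quadrature_with_terminal_gating(self):
        spec = simple_spectrum(tau_v=0.003, beta=0.4)
        for t in (1e-3, 1.0, 1e3):
            assert spec.eval_msd(t) == pytest.approx(
                msd_quadrature(spec, t), rel=1e-6)

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            simple_spectrum().eval_msd(np.array([0.0, 1.0]))

    def test_diffusive_limit_transform(self):
        # deep in the terminal regime MSD ≈ 2dD·t and the one-sided
        # transform must approach −(g0/τmax)/ω² (i.e. −6D/ω² for d=3)
        spec = simple_spectrum()
        w = 1e-8
        got = complex(spec.fourier(w))
        assert got.real == pytest.approx(-(spec.g0 / spec.tau_max) / w ** 2,
                                         rel=1e-6)

    def test_ballistic_limit_transform(self):
        # far above every spectral frequency the transform approaches
        # the pure-ballistic result 2iC/ω³
        spec = simple_spectrum()
        w = 1e5 / spec.tau[0]
        got = complex(spec.fourier(w))
        want = 2j * spec.C / w ** 3
        assert got.imag == pytest.approx(want.imag, rel=1e-3)

    @pytest.mark.parametrize("w", [1e-3, 1e-1, 1.0, 10.0, 100.0])
    def test_fourier_matches_damped_quadrature(self, w):
        spec = simple_spectrum()
        got = complex(spec.fourier(w))
        ref = fourier_damped(spec, w)
        assert abs(got - ref) / abs(ref) < 0.01

    def test_fourier_quadrature_on_random_spectra(self, rng):
        # property-based closed-form/quadrature equivalence
        for _ in range(8):
            n = rng.integers(1, 4)
            knots = np.sort(rng.uniform(-2, 3, n + 1))
            taus = 10.0 ** knots
            if np.min(np.diff(knots)) < 0.3:
                continue
            alpha = rng.uniform(-1.5, 2.5, n)
            spec = bsw.BSWSpectrum.from_alpha(taus, alpha, C=10.0)
            w = 10.0 ** rng.uniform(-1, 1) / np.median(taus)
            got = complex(spec.fourier(w))
            ref = fourier_damped(spec, w)
            assert abs(got - ref) / abs(ref) < 0.01

    def test_pole_alpha_values_finite(self):
        # α = −1, −2 sit on ₂F₁ parameter poles: nudged, not NaN
        spec = bsw.BSWSpectrum.from_alpha(
            np.array([0.01, 1.0, 100.0]), np.array([-2.0, -1.0]), C=5.0)
        out = spec.fourier(np.array([0.3, 3.0]))
        assert np.all(np.isfinite(out))


class TestFit:
    def _make_curve(self, spec, d=3):
        lags = np.geomspace(spec.tau[0] / 30, spec.tau_max * 30, 120)
        return MSDCurve(lags=lags, msd=spec.eval_msd(lags), d=d)

    def test_alpha_recovery_roundtrip(self):
        alpha_true = np.array([0.4, 0.9, 1.6])
        taus = np.array([0.05, 1.0, 20.0, 400.0])
        spec0 = bsw.BSWSpectrum.from_alpha(taus, alpha_true, C=50.0)
        curve = self._make_curve(spec0)
        curve.C = 50.0
        fitted = bsw.fit(curve, n_max=3, tau_grid=taus)
        np.testing.assert_allclose(fitted.alpha, alpha_true, atol=1e-3)

    def test_pure_ballistic_curve_recovers_C(self):
        # the smooth kernels carry O(t/τ_v) corrections below τ₀, so the
        # recovery is exact only in the deep-ballistic limit
        spec0 = simple_spectrum(C=7.5)
        lags = np.geomspace(1e-6, 1e-5, 30)  # far below τ₀ = 0.01
        curve = MSDCurve(lags=lags, msd=spec0.eval_msd(lags), d=3)
        from microrheo.msd import fit_limits
        C, _ = fit_limits(curve, (lags[0], lags[-1]), (lags[0], lags[-1]))
        assert C == pytest.approx(7.5, rel=1e-3)

    def test_chi2_decreases_with_modes(self):
        # richer spectra fit a structured curve at least as well
        spec0 = simple_spectrum(alpha=(2.0, 0.3, 1.2),
                                taus=(0.05, 0.8, 15.0, 300.0), C=20.0)
        curve = self._make_curve(spec0)
        chi1 = bsw.fit(curve, n_max=1, polish_only=True).chi2
        curve2 = self._make_curve(spec0)
        chi3 = bsw.fit(curve2, n_max=3, polish_only=True).chi2
        assert chi3 <= chi1 + 1e-12

    def test_fit_deterministic(self):
        spec0 = simple_spectrum()
        c1 = self._make_curve(spec0)
        c2 = self._make_curve(spec0)
        f1 = bsw.fit(c1, n_max=2, polish_only=True)
        f2 = bsw.fit(c2, n_max=2, polish_only=True)
        np.testing.assert_array_equal(f1.alpha, f2.alpha)

    def test_narrow_curve_rejected(self):
        lags = np.geomspace(1.0, 50.0, 30)
        curve = MSDCurve(lags=lags, msd=lags ** 2, d=3)
        with pytest.raises(GridError):
            bsw.fit(curve, n_max=2)

    def test_serialization_roundtrip(self):
        spec = simple_spectrum(tau_v=0.002, beta=0.3)
        back = bsw.BSWSpectrum.from_json(spec.to_json())
        np.testing.assert_allclose(back.g, spec.g)
        assert back.beta == spec.beta and back.tau_v == spec.tau_v
        t = np.array([0.1, 10.0])
        np.testing.assert_allclose(back.eval_msd(t), spec.eval_msd(t))
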