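"""Power-law (BSW-like) relaxation-spectrum parametrization of the MSD.

The probe MSD is written as a superposition of relaxation modes drawn
from a Baumgaertel–Schausberger–Winter-like windowed power-law spectrum

    h(τ) = g_j · τ^{α_j − 1}   on  τ_{j−1} < τ ≤ τ_j ,  j = 1…n_max,

with mode weights chained by continuity of h at the window boundaries,
g_j = g_{j−1} τ_{j−1}^{α_{j−1} − α_j}.  The MSD itself is

    MSD(t) = ∫_{τ₀}^{τ_max} h(τ) f¹(t/τ) dτ  +  g₀ f⁰(t/τ_max),

    f¹(x) = 1 − e^{−x}(1 + x)   (retardation mode: ballistic x²/2 onset,
                                 saturating at 1)
    f⁰(x) = x (1 − e^{−x})²     (terminal diffusion: cubic onset,
                                 approaches its asymptote from below)

with g₀ = Σ_j g_j (τ_j^{α_j} − τ_{j−1}^{α_j})/α_j = ∫ h dτ.  The first
term saturates at the plateau g₀ around t = τ_max — the terminal
relaxation time, where the diffusive term takes over — and the
long-time asymptote is g₀ t/τ_max + g₀, i.e. free diffusion with
D = g₀/(2d τ_max) offset upward by the plateau, as for any
viscoelastic liquid.  The short-time limit is ballistic with

    C = ½ Σ_j g_j (τ_{j−1}^{α_j−2} − τ_j^{α_j−2})/(2 − α_j),

linear in g₁ through the chain, so the measured ballistic slope fixes
every weight once the α_j are chosen.  The time-domain closed form
uses upper incomplete gamma functions Γ(−α, t/τ), Γ(1−α, t/τ) (the
generalized exponential-integral family); the one-sided Fourier
transform (kernel e^{−iωt}, Abel-regularized linear tail) reduces to
Gauss-hypergeometric ₂F₁ bracket evaluations [x(τ)] from τ_{j−1} to
τ_j.  Both are validated against direct quadrature in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from ._special import hyp2f1, upper_gamma
from .errors import FitError, GridError, NumericError, WindowError
from .msd import MSDCurve, fit_limits

#: switchover width for the removable singularities at α=2 and α=0
_ALPHA2_EPS = 1e-6
#: arguments beyond which e^{-x} corrections are dropped exactly
_X_BIG = 50.0
#: half-width of the nudge window around the ₂F₁ poles (α = −1, −2, −3…)
_POLE_EPS = 1e-6


def _pow_int(a: float, ta: float, tb: float) -> float:
    """∫_ta^tb τ^{a−3} dτ = (ta^{a−2} − tb^{a−2})/(2−a), with the log
    form at the removable point a→2."""
    if abs(a - 2.0) < _ALPHA2_EPS:
        return float(np.log(tb / ta))
    return (ta ** (a - 2.0) - tb ** (a - 2.0)) / (2.0 - a)


def _pow_int_partial(a: float, ta, tb) -> np.ndarray:
    """Vectorized ∫ τ^{a−3} dτ between arrays ta and tb (ta <= tb)."""
    ta = np.asarray(ta, float)
    tb = np.asarray(tb, float)
    if abs(a - 2.0) < _ALPHA2_EPS:
        return np.log(tb / ta)
    return (ta ** (a - 2.0) - tb ** (a - 2.0)) / (2.0 - a)


def _pow_int0(a: float, ta, tb):
    """∫ τ^{a−1} dτ = (tb^a − ta^a)/a, log form at the removable a→0."""
    ta = np.asarray(ta, float)
    tb = np.asarray(tb, float)
    if abs(a) < _ALPHA2_EPS:
        out = np.log(tb / ta)
    else:
        out = (tb ** a - ta ** a) / a
    return out


@dataclass
class BSWSpectrum:
    """Fitted windowed power-law spectrum.

    tau : (n_max+1,) knots τ₀ < τ₁ < … < τ_max, ns
    alpha : (n_max,) exponents
    g : (n_max,) weights (Å²/ns^{α_j+1} convention of h above)
    g0 : terminal weight, Å²
    C : ballistic coefficient, Å²/ns²
    """

    tau: np.ndarray
    alpha: np.ndarray
    g: np.ndarray
    g0: float
    C: float
    tau_v: float = 0.0
    beta: float = 0.0
    chi2: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, float)
        self.alpha = np.asarray(self.alpha, float)
        self.g = np.asarray(self.g, float)
        if self.n_max < 1:
            raise GridError("need at least one mode")
        if np.any(np.diff(self.tau) <= 0):
            raise GridError("tau knots must be strictly increasing")
        if len(self.alpha) != self.n_max or len(self.g) != self.n_max:
            raise GridError("alpha/g must have n_max entries")

    @property
    def n_max(self) -> int:
        return len(self.tau) - 1

    @property
    def tau_max(self) -> float:
        return float(self.tau[-1])

    def D(self, d: int) -> float:
        """Long-time diffusion coefficient implied by the spectrum."""
        return self.g0 / (2 * d * self.tau_max)

    def h(self, tau: np.ndarray) -> np.ndarray:
        """The spectrum h(τ) itself (zero outside (τ₀, τ_max])."""
        tau = np.asarray(tau, float)
        out = np.zeros_like(tau)
        for j in range(self.n_max):
            m = (tau > self.tau[j]) & (tau <= self.tau[j + 1])
            out[m] = self.g[j] * tau[m] ** (self.alpha[j] - 1.0)
        return out

    # ------------------------------------------------------------ algebra

    @classmethod
    def from_alpha(cls, tau: np.ndarray, alpha: np.ndarray, C: float,
                   tau_v: float = 0.0, beta: float = 0.0) -> "BSWSpectrum":
        """Build the full spectrum from knots, exponents and the measured
        ballistic coefficient; g₁ follows exactly from the linear relation
        C = g₁·K(α, τ) (all weights are proportional to g₁).

        ``tau_v`` is the probe's inertial (velocity-relaxation) time
        gating the terminal term's onset; ``beta`` ∈ [0, 1) is the
        fraction of the plateau removed from the diffusive-asymptote
        offset (the solvent-channel correction).  ``beta > 0`` requires
        ``tau_v > 0``.
        """
        tau = np.asarray(tau, float)
        alpha = np.asarray(alpha, float)
        if tau_v <= 0:
            # gate the terminal onset at the shortest knot so the
            # ballistic limit MSD → Ct² holds for any spectrum
            tau_v = float(tau[0]) / 3.0
        n = len(alpha)
        chain = np.ones(n)
        for j in range(1, n):
            chain[j] = chain[j - 1] * tau[j] ** (alpha[j - 1] - alpha[j])
        g0_per_g1 = float(np.sum(
            [chain[j] * _pow_int0(alpha[j], tau[j], tau[j + 1])
             for j in range(n)]))
        K = 0.5 * float(np.sum(
            [chain[j] * _pow_int(alpha[j], tau[j], tau[j + 1])
             for j in range(n)]))
        if tau_v > 0:
            K += g0_per_g1 * (0.5 - beta) / (tau_v * tau[-1])
        if K <= 0:
            raise FitError("degenerate spectrum: non-positive ballistic sum")
        g1 = C / K
        g = g1 * chain
        return cls(tau=tau, alpha=alpha, g=g, g0=g1 * g0_per_g1, C=C,
                   tau_v=tau_v, beta=beta)

    # --------------------------------------------------------- evaluation

    def eval_msd(self, t: np.ndarray) -> np.ndarray:
        """Closed-form MSD(t), Å², for t > 0 (ns).

        The mode integral ∫ τ^{α−1} f¹(t/τ) dτ evaluates to
        [τ^α/α] − t^α·[Γ(−α, t/τ) + Γ(1−α, t/τ)] bracketed over each
        window (generalized exponential-integral family); the terminal
        term is g₀ f⁰(t/τ_max).
        """
        t = np.asarray(t, float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if np.any(t <= 0):
            raise ValueError("eval_msd requires t > 0")
        with np.errstate(under="ignore"):
            tot = self.g0 * self._terminal(t)
        for j in range(self.n_max):
            a, ta, tb = self.alpha[j], self.tau[j], self.tau[j + 1]
            pw = _pow_int0(a, ta, tb)
            expo = np.zeros_like(t)
            for tk, sign in ((tb, 1.0), (ta, -1.0)):
                u = t / tk
                m = u <= _X_BIG
                if np.any(m):
                    term = upper_gamma(-a, u[m]) + upper_gamma(1 - a, u[m])
                    expo[m] += sign * t[m] ** a * term
            tot = tot + self.g[j] * (pw - expo)
        return tot[0] if scalar else tot

    def _terminal(self, t: np.ndarray) -> np.ndarray:
        """Terminal kernel f⁰: inertially gated diffusion with a
        reduced asymptote offset.

        f⁰ = Λ(t) − β(1−e^{−t/τ_max})(1−e^{−t/τ_v}), with
        Λ = t/τ_max − (τ_v/τ_max)(1−e^{−t/τ_v}); asymptote
        t/τ_max − τ_v/τ_max − β, so the diffusive line is offset by
        +g₀(1−β) once the first term's plateau is added.
        """
        tm = self.tau_max
        x = t / tm
        if self.tau_v > 0:
            ev = -np.expm1(-t / self.tau_v)
            lam = x - (self.tau_v / tm) * ev
        else:
            ev = 1.0
            lam = x
        out = lam
        if self.beta:
            out = out - self.beta * (-np.expm1(-x)) * ev
        return out

    def fourier(self, omega: np.ndarray) -> np.ndarray:
        """One-sided Fourier transform MSD(ω) = ∫₀^∞ MSD(t) e^{−iωt} dt
        (Abel-regularized linear tail).  Complex, Å²·ns.

        Per mode window ∫ τ^{α−1} f̂¹(ω; τ) dτ with
        f̂¹ = 1/s − τ/(1+sτ) − τ/(1+sτ)², s = iω; the rational parts
        integrate to ₂F₁ bracket evaluations [x(τ)] from τ_{j−1} to
        τ_j, and the terminal term is elementary.
        """
        omega = np.asarray(omega, float)
        scalar = omega.ndim == 0
        omega = np.atleast_1d(omega)
        if np.any(omega <= 0):
            raise ValueError("fourier requires omega > 0")
        s = 1j * omega
        tm = self.tau_max
        # terminal term: Λ − β(1−e^{−t/tm})(1−e^{−t/τv})
        out = (self.g0 / tm) / s ** 2
        if self.tau_v > 0:
            tv = self.tau_v
            out = out - (self.g0 * tv / tm) * (1.0 / s - 1.0 / (s + 1.0 / tv))
            if self.beta:
                out = out - self.g0 * self.beta * (
                    1.0 / s - 1.0 / (s + 1.0 / tm) - 1.0 / (s + 1.0 / tv)
                    + 1.0 / (s + 1.0 / tm + 1.0 / tv))
        # saturation plateaus of the mode integrals: g0/s in total
        out = out + self.g0 / s
        for j in range(self.n_max):
            a, ta, tb = self.alpha[j], self.tau[j], self.tau[j + 1]
            for k, w in enumerate(omega):
                out[k] -= self.g[j] * (self._window_ft(a, tb, w)
                                       - self._window_ft(a, ta, w))
        if not np.all(np.isfinite(out)):
            raise NumericError("spectrum transform returned non-finite values")
        return out[0] if scalar else out

    @staticmethod
    def _window_ft(a: float, tk: float, w: float) -> complex:
        """Antiderivative ∫ τ^a [1/(1+iωτ) + 1/(1+iωτ)²] dτ at τ = tk
        via ₂F₁ (mpmath's analytic continuation covers all |ωτ|).

        Negative-integer a (poles of the prefactor/₂F₁ parameters) are
        removable; a is nudged off the pole, exact to ~1e-6.
        """
        if a <= -0.5 and abs(a - round(a)) < _POLE_EPS:
            a = round(a) + _POLE_EPS
        z = complex(-1j * w * tk)
        try:
            h = hyp2f1(1.0, 1.0 + a, 2.0 + a, z) + \
                hyp2f1(2.0, 1.0 + a, 2.0 + a, z)
        except Exception as exc:  # pragma: no cover - mpmath breakdown
            raise NumericError(f"2F1 evaluation failed at ωτ={w * tk}") from exc
        return (tk ** (1.0 + a) / (1.0 + a)) * h

    # -------------------------------------------------------------- export

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n_max": self.n_max, "tau": self.tau.tolist(),
            "alpha": self.alpha.tolist(), "g": self.g.tolist(),
            "g0": self.g0, "C": self.C, "tau_v": self.tau_v,
            "beta": self.beta, "chi2": self.chi2}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "BSWSpectrum":
        d = json.loads(text)
        return cls(tau=np.array(d["tau"]), alpha=np.array(d["alpha"]),
                   g=np.array(d["g"]), g0=d["g0"], C=d["C"],
                   tau_v=d.get("tau_v", 0.0), beta=d.get("beta", 0.0),
                   chi2=d.get("chi2", np.nan))


def ballistic_knee(curve: MSDCurve, departure: float = 0.5) -> float:
    """Lag where the MSD first drops below ``departure``×(C t²): the end
    of the inertial (ballistic) regime and the natural shortest
    relaxation time of the spectrum."""
    if curve.C is None:
        fit_limits(curve, (curve.lags[0], curve.lags[0] * 3.16),
                   (curve.lags[-1] / 3.16, curve.lags[-1]))
    below = curve.msd < departure * curve.C * curve.lags ** 2
    idx = np.flatnonzero(below)
    return float(curve.lags[idx[0]]) if len(idx) else float(curve.lags[-1] / 3)


def terminal_time(curve: MSDCurve) -> float:
    """Estimate the terminal relaxation time τ_max of the spectrum.

    In the model the diffusive asymptote is MSD = 2dD·(t + τ_max), so
    the chord MSD/t equals twice the terminal slope exactly at
    t = τ_max; the estimate is the first post-knee lag where
    MSD ≤ 2·(2d·D)·t, with D from the last half-decade of lags.
    Falls back to a third of the longest lag when the data never turn
    diffusive in range.
    """
    if curve.D is None:
        fit_limits(curve, (curve.lags[0], curve.lags[0] * 3.16),
                   (curve.lags[-1] / 3.16, curve.lags[-1]))
    knee = ballistic_knee(curve)
    slope = 2.0 * curve.d * curve.D
    mask = (curve.lags > 3.0 * knee) & (curve.msd <= 2.0 * slope * curve.lags)
    idx = np.flatnonzero(mask)
    cap = curve.lags[-1] / 3.0
    if len(idx) == 0:
        return float(cap)
    return float(min(curve.lags[idx[0]], cap))


def default_tau_grid(curve: MSDCurve, n_max: int) -> np.ndarray:
    """n_max+1 log-equidistant knots from half the ballistic-departure
    knee (clipped to [3×shortest lag, longest/30]) to the terminal-time
    estimate.

    Starting the grid at the knee keeps spectrum weight out of the
    inertia-dominated window; ending it at the terminal time keeps the
    diffusive tail in the f⁰ term, where it belongs.
    """
    lo = float(np.clip(0.5 * ballistic_knee(curve), 3.0 * curve.lags[0],
                       curve.lags[-1] / 30.0))
    hi = float(max(terminal_time(curve), 10.0 * lo))
    if hi <= lo:
        raise GridError("lag range too short for a spectrum grid")
    return np.geomspace(lo, hi, n_max + 1)


def _chi2(spec: BSWSpectrum, curve: MSDCurve,
          diffusivity_weight: float = 0.0) -> float:
    model = spec.eval_msd(curve.lags)
    good = curve.msd > 0
    r = (model[good] - curve.msd[good]) / curve.msd[good]
    out = float(np.dot(r, r))
    if diffusivity_weight > 0.0 and curve.D is not None:
        out += diffusivity_weight * (spec.D(curve.d) / curve.D - 1.0) ** 2
    return out


def fit(curve: MSDCurve, n_max: int = 3,
        tau_grid: np.ndarray | None = None,
        alpha_bounds: tuple[float, float] = (-3.0, 3.0),
        diffusivity_weight: float = 30.0,
        polish_only: bool = False) -> BSWSpectrum:
    """Fit the spectrum to an MSD curve.

    Interior τ knots are log-equidistant; the exponents α_j minimize
    the χ² of relative residuals on the log-spaced lags (each decade
    weighted equally by the grid construction).  C comes from the
    curve's ballistic fit (computed over the first half-decade of lags
    when absent).

    When ``tau_grid`` is given, the knots are held exactly there.  By
    default the endpoint knots are free within data-driven bounds
    (around the ballistic knee for τ₀ and between it and a third of
    the longest lag for τ_max), since τ_max is the terminal relaxation
    time that ties the diffusivity D = g₀/(2d τ_max) to the spectrum
    weight: fixing it a priori over-constrains the terminal regime.

    A penalty ``diffusivity_weight·(D_model/D_data − 1)²`` keeps the
    spectrum's terminal diffusivity g₀/(2dτ_max) consistent with the
    measured long-time slope, which the in-range residuals alone
    constrain only weakly; ``chi2`` reported on the result excludes
    the penalty.

    Negative exponents are allowed: after the inertial knee the
    spectrum must often decay faster than τ⁻¹, which the continuity
    chaining cannot express with positive α alone.  The optimizer is a
    deterministic two-stage search — multi-start bounded Powell on the
    exponents, then a seeded differential-evolution refinement over
    exponents and endpoint knots (skipped when ``polish_only``); ties
    break toward the lowest χ².
    """
    if curve.lags[-1] / curve.lags[0] < 1e3:
        raise GridError("curve must span at least 3 decades of lag")
    if curve.C is None or curve.D is None:
        keep_C = curve.C
        try:
            fit_limits(curve, (curve.lags[0], curve.lags[0] * 3.16),
                       (curve.lags[-1] / 3.16, curve.lags[-1]))
        except WindowError as exc:
            raise FitError("cannot determine ballistic coefficient") from exc
        if keep_C is not None:
            curve.C = keep_C
    C = float(curve.C)

    tau_v = float(curve.tau_v) if getattr(curve, "tau_v", None) else 0.0
    fit_beta = tau_v > 0.0
    fixed = tau_grid is not None
    if fixed:
        tau0 = np.asarray(tau_grid, float)
        if len(tau0) != n_max + 1:
            raise GridError("tau_grid must provide n_max+1 knots")
        if tau0[0] < curve.lags[0] or tau0[-1] > curve.lags[-1]:
            raise GridError("tau grid outside the data lag range")
    else:
        tau0 = default_tau_grid(curve, n_max)

    def spectrum_for(x: np.ndarray) -> BSWSpectrum:
        beta = x[-1] if fit_beta else 0.0
        if fixed:
            tau, alpha = tau0, x[:n_max]
        else:
            alpha = x[:n_max]
            tau = np.geomspace(np.exp(x[n_max]), np.exp(x[n_max + 1]),
                               n_max + 1)
        return BSWSpectrum.from_alpha(tau, alpha, C, tau_v=tau_v, beta=beta)

    def objective(x: np.ndarray) -> float:
        try:
            val = _chi2(spectrum_for(x), curve, diffusivity_weight)
            return val if np.isfinite(val) else 1e30
        except (FitError, GridError, FloatingPointError, OverflowError):
            return 1e30

    lo0, hi0 = np.log(tau0[0]), np.log(tau0[-1])
    knot_bounds = [(np.log(3.0 * curve.lags[0]), np.log(curve.lags[-1] / 9.0)),
                   (np.log(30.0 * curve.lags[0]), np.log(curve.lags[-1] / 3.0))]

    def pack(alpha):
        out = alpha if fixed else np.concatenate([alpha, [lo0, hi0]])
        return np.concatenate([out, [0.0]]) if fit_beta else out

    starts = [np.full(n_max, 0.5), np.full(n_max, 1.0),
              np.linspace(-1.0, 2.0, n_max)]
    bounds = [alpha_bounds] * n_max + ([] if fixed else knot_bounds) \
        + ([(0.0, 0.99)] if fit_beta else [])
    best_x, best_f = None, np.inf
    for a0 in starts:
        res = optimize.minimize(
            objective, pack(a0), method="Powell", bounds=bounds,
            options={"xtol": 1e-10, "ftol": 1e-14, "maxiter": 20000})
        if res.fun < best_f - 1e-15:
            best_x, best_f = res.x, res.fun
    if not polish_only:
        ndim = len(bounds)
        rng_pop = np.random.default_rng(0).uniform(size=(20 * ndim, ndim))
        lob = np.array([b[0] for b in bounds])
        hib = np.array([b[1] for b in bounds])
        init = np.vstack([best_x, [pack(a) for a in starts],
                          lob + rng_pop * (hib - lob)])
        res = optimize.differential_evolution(
            objective, bounds, init=init, seed=0,
            tol=1e-12, maxiter=500, polish=True)
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_x is None or not np.all(np.isfinite(best_x)) or best_f >= 1e30:
        raise FitError("spectrum fit did not converge")
    spec = spectrum_for(best_x)
    spec.chi2 = _chi2(spec, curve)
    return spec
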