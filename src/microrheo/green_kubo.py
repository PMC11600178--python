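"""Bulk rheology from equilibrium pressure-tensor fluctuations.

The shear relaxation modulus is estimated with the five-component
isotropic average over the traceless stress,

    G(t) = V/(5 k_B T) · [C_xy + C_xz + C_yz]
         + V/(30 k_B T) · [C_Nxy + C_Nxz + C_Nyz],

where C_ab is the autocorrelation of the off-diagonal component P_ab and
C_Nab that of the normal-stress difference N_ab = P_aa − P_bb (the 1/30
weight makes each N-channel statistically equivalent to an off-diagonal
channel for an isotropic medium).  η follows from the Green–Kubo
integral ∫₀^∞ G dt, evaluated numerically at short times and
analytically from a Maxwell-mode fit at long times; the same modes give
closed-form G′(ω), G″(ω).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import InputError, NumericError
from .igser import ComplexModulus
from .io import StressSeries
from .units import KB

# Eq-10 channel weights: off-diagonal and normal-difference terms of the
# isotropic 5-component estimator (Daivis & Evans convention).
_W_OFF = 1.0 / 5.0
_W_NORM = 1.0 / 30.0


@dataclass
class RelaxationModulus:
    """G(t) in kcal/(mol·Å³) on a uniform time grid (ns)."""

    t: np.ndarray
    G: np.ndarray
    V: float
    T: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.G = np.asarray(self.G, float)


@dataclass
class MaxwellModes:
    """Discrete Maxwell modes (G_i, τ_i); τ strictly increasing."""

    G: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, float)
        self.tau = np.asarray(self.tau, float)
        if np.any(self.G < 0):
            raise InputError("mode amplitudes must be non-negative")
        if np.any(np.diff(self.tau) <= 0):
            raise InputError("mode times must be strictly increasing")

    def eval(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return np.sum(self.G[:, None]
                      * np.exp(-t[None, :] / self.tau[:, None]), axis=0)

    @property
    def eta(self) -> float:
        """Zero-shear viscosity Σ G_i τ_i of the mode set."""
        return float(np.sum(self.G * self.tau))


def acf_fft(x: np.ndarray) -> np.ndarray:
    """Unbiased autocorrelation ⟨x(0)x(m·dt)⟩ of a mean-free series."""
    x = np.asarray(x, float)
    N = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * N)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:N]
    return acf / (N - np.arange(N))


def relaxation_modulus(stress: StressSeries,
                       max_lag_fraction: float = 0.5) -> RelaxationModulus:
    """Shear relaxation modulus from the six pressure-tensor components.

    Components are de-meaned before correlation (only fluctuations carry
    the shear response); lags are truncated at ``max_lag_fraction`` of
    the series to avoid the noisy tail of the unbiased estimator.
    """
    P = stress.components
    if P.shape[1] != 6:
        raise InputError("need all six stress components")
    nlag = max(2, int(stress.components.shape[0] * max_lag_fraction))
    xx, yy, zz, xy, xz, yz = (P[:, k] - P[:, k].mean() for k in range(6))
    off = sum(acf_fft(c)[:nlag] for c in (xy, xz, yz))
    norm = sum(acf_fft(a - b)[:nlag]
               for a, b in ((xx, yy), (xx, zz), (yy, zz)))
    pref = stress.volume / (KB * stress.temperature)
    G = pref * (_W_OFF * off + _W_NORM * norm)
    t = stress.dt * np.arange(nlag)
    return RelaxationModulus(t=t, G=G, V=stress.volume, T=stress.temperature)


def default_t_switch(G: RelaxationModulus, level: float = 0.05) -> float:
    """First time G(t) falls below ``level``·G(0) (fit-from-here default)."""
    below = np.where(G.G < level * G.G[0])[0]
    return float(G.t[below[0]]) if len(below) else float(G.t[len(G.t) // 2])


def fit_modes(G: RelaxationModulus, n_modes: int = 4,
              t_start: float | None = None,
              t_end: float | None = None) -> MaxwellModes:
    """Non-negative least squares for mode amplitudes at fixed τ_i
    log-equidistant between ``t_start`` and ``t_end`` (grid end)."""
    if t_start is None:
        t_start = default_t_switch(G)
    if t_end is None:
        t_end = float(G.t[-1])
    if not (G.t[0] <= t_start <= G.t[-1] and t_start < t_end):
        raise InputError("t_start outside the G(t) grid")
    taus = np.geomspace(t_start, t_end, n_modes)
    m = G.t >= t_start
    A = np.exp(-G.t[m][:, None] / taus[None, :])
    amps, resid = optimize.nnls(A, G.G[m])
    if np.all(amps == 0) and np.any(G.G[m] != 0):
        warnings.warn("Maxwell-mode fit returned the zero solution",
                      stacklevel=2)
    modes = MaxwellModes(G=amps, tau=taus)
    modes.residual = float(resid)  # type: ignore[attr-defined]
    return modes


def gk_viscosity(G: RelaxationModulus, modes: MaxwellModes,
                 t_switch: float | None = None) -> float:
    """η_GK: trapezoidal ∫₀^{t_switch} G dt plus the analytic tail
    Σ G_i τ_i e^{−t_switch/τ_i} of the fitted modes."""
    if t_switch is None:
        t_switch = default_t_switch(G)
    m = G.t <= t_switch
    short = float(np.trapezoid(G.G[m], G.t[m])) if np.sum(m) > 1 else 0.0
    tail = float(np.sum(modes.G * modes.tau * np.exp(-t_switch / modes.tau)))
    eta = short + tail
    if eta < 0:
        raise NumericError("negative Green-Kubo viscosity (pathological G)")
    return eta


def gk_moduli(source: RelaxationModulus | MaxwellModes,
              omega: np.ndarray) -> ComplexModulus:
    """G′(ω), G″(ω).

    Maxwell modes use the exact closed forms
    G′ = Σ G_i ω²τ_i²/(1+ω²τ_i²), G″ = Σ G_i ωτ_i/(1+ω²τ_i²); a raw
    G(t) is transformed numerically with an exponential damping window.
    """
    omega = np.asarray(omega, float)
    if isinstance(source, MaxwellModes):
        wt = omega[:, None] * source.tau[None, :]
        gp = np.sum(source.G[None, :] * wt ** 2 / (1 + wt ** 2), axis=1)
        gpp = np.sum(source.G[None, :] * wt / (1 + wt ** 2), axis=1)
    else:
        t, g = source.t, source.G
        eps = 2.0 / t[-1]  # damping so the truncated tail is negligible
        gp = np.empty_like(omega)
        gpp = np.empty_like(omega)
        for k, w in enumerate(omega):
            ker = g * np.exp(-eps * t)
            # G* (ω) = iω ∫ G(t) e^{-iωt} dt
            re = np.trapezoid(ker * np.cos(w * t), t)
            im = -np.trapezoid(ker * np.sin(w * t), t)
            gst = 1j * w * (re + 1j * im)
            gp[k], gpp[k] = gst.real, gst.imag
    return ComplexModulus(omega=omega, G_prime=gp, G_double_prime=gpp)
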