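"""Inertial generalized Stokes–Einstein inversion of probe motion.

Chain: MSD(ω) → friction → complex modulus → (ω_c, τ, η).

With the one-sided transform convention e^{−iωt}, the frequency-domain
GLE of a passive probe gives the friction directly from the MSD,

    Z*(ω) = − 2 d k_B T / (ω² MSD(ω)) − iω m_eff ,

where m_eff = m_bare + m_add includes the added (displaced-medium) mass
m_add = (2/3)π R_h³ ρ.  The friction is then balanced against the
continuum unsteady-Stokes drag of a no-slip sphere in a viscoelastic
medium — generalized Stokes drag plus Basset (medium-inertia) force —

    Z*(ω) = 6π R_h G*(ω)/(iω) + 6π R_h² sqrt(ρ G*(ω)),

a quadratic in sqrt(G*); the branch with Re sqrt(G*) > 0 is the passive
(dissipative) medium.  All inputs in real units (Å, ns, kcal/mol,
g/mol); masses and densities are converted internally to the
energy-consistent system (see :mod:`microrheo.units`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import NumericError, TerminalRegionError, WindowError
from .units import KB, MASS_TO_ENERGY

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeSpec:
    """Probe particle for the continuum inversion (radii Å, masses g/mol)."""

    R_b: float
    R_h: float
    m_bare: float
    m_add: float = 0.0
    interaction_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.R_b <= self.R_h):
            raise ValueError("need R_h >= R_b > 0")

    @property
    def m_eff(self) -> float:
        return self.m_bare + self.m_add


@dataclass(frozen=True)
class MediumSpec:
    """Dense-phase medium: mass density ρ g/(mol·Å³), temperature K."""

    rho: float
    T: float

    def __post_init__(self) -> None:
        if self.rho < 0 or self.T <= 0:
            raise ValueError("need rho >= 0 and T > 0")


@dataclass
class FrictionSpectrum:
    """Complex friction Z*(ω); units kcal·ns/(mol·Å²)."""

    omega: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, float)
        self.Z = np.asarray(self.Z, complex)
        if not np.all(np.isfinite(self.Z)):
            raise NumericError("friction spectrum contains non-finite values")


@dataclass
class ComplexModulus:
    """G′(ω), G″(ω) in kcal/(mol·Å³) on a 1/ns frequency grid.

    ``valid`` masks frequencies where the root selection succeeded.
    Derived scalars (ω_c, τ, η) are attached by :func:`crossover` and
    :func:`terminal_viscosity`.
    """

    omega: np.ndarray
    G_prime: np.ndarray
    G_double_prime: np.ndarray
    valid: np.ndarray | None = None
    omega_c: float | None = field(default=None)
    tau: float | None = field(default=None)
    eta: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, float)
        self.G_prime = np.asarray(self.G_prime, float)
        self.G_double_prime = np.asarray(self.G_double_prime, float)
        if self.valid is None:
            self.valid = np.ones_like(self.omega, bool)


def added_mass(R_h: float, rho: float) -> float:
    """Added mass (g/mol) of the accelerating sphere: half the displaced
    medium mass, (2/3)·π·R_h³·ρ."""
    if R_h <= 0 or rho < 0:
        raise ValueError("need R_h > 0 and rho >= 0")
    return (2.0 / 3.0) * np.pi * R_h ** 3 * rho


def friction_from_msd(msd_fourier: np.ndarray, d: int, T: float,
                      m_eff: float, omega: np.ndarray) -> FrictionSpectrum:
    """Friction Z*(ω) from the one-sided-transformed MSD.

    ``m_eff`` in g/mol (pass 0 to drop probe inertia); ``d`` is the
    number of tracked dimensions of the MSD.
    """
    omega = np.asarray(omega, float)
    msd_fourier = np.asarray(msd_fourier, complex)
    if msd_fourier.shape != omega.shape:
        raise NumericError("MSD(ω) and ω grids differ")
    if np.any(~np.isfinite(msd_fourier)) or np.any(msd_fourier == 0):
        raise NumericError("MSD(ω) contains zeros or non-finite values")
    m = m_eff * MASS_TO_ENERGY
    Z = -2.0 * d * KB * T / (omega ** 2 * msd_fourier) - 1j * omega * m
    return FrictionSpectrum(omega=omega, Z=Z)


def modulus_from_friction(Z: FrictionSpectrum, probe: ProbeSpec,
                          medium: MediumSpec,
                          basset: bool = True) -> ComplexModulus:
    """Solve the IGSER balance for G*(ω) at each frequency.

    With the Basset term the balance is quadratic in x = sqrt(G*):
    x² + iω R_h sqrt(ρ) x − iω Z*/(6π R_h) = 0; the root with
    Re x > 0 is kept.  Frequencies with no admissible root are masked
    (``valid``), never silently dropped.
    """
    w = Z.omega
    R = probe.R_h
    rho_c = medium.rho * MASS_TO_ENERGY if basset else 0.0
    b = 1j * w * R * np.sqrt(rho_c)
    c = -1j * w * Z.Z / (6.0 * np.pi * R)
    disc = np.sqrt(b * b - 4.0 * c)
    r1, r2 = (-b + disc) / 2.0, (-b - disc) / 2.0
    # the physical branch connects to the principal sqrt as ρ→0
    pick = np.where(r1.real >= r2.real, r1, r2)
    valid = pick.real > 0
    G = pick ** 2
    G = np.where(valid, G, np.nan + 1j * np.nan)
    if not np.all(valid):
        log.warning("IGSER root selection failed at %d/%d frequencies",
                    int(np.sum(~valid)), len(valid))
    return ComplexModulus(omega=w, G_prime=G.real,
                          G_double_prime=G.imag, valid=valid)


def crossover(mod: ComplexModulus) -> tuple[float, float] | None:
    """Lowest-frequency crossing of G′ and G″ with G″ > G′ below and
    G′ > G″ above, located by log–log interpolation.  Returns
    (ω_c, τ = 1/ω_c) or None ("no dominant elastic response")."""
    m = mod.valid & (mod.G_prime > 0) & (mod.G_double_prime > 0)
    w = mod.omega[m]
    s = np.log(mod.G_prime[m]) - np.log(mod.G_double_prime[m])
    if len(w) < 2:
        return None
    sign_change = np.where((s[:-1] < 0) & (s[1:] >= 0))[0]
    if len(sign_change) == 0:
        return None
    if len(sign_change) > 1:
        log.info("multiple G'/G'' crossings (%d); taking the lowest",
                 len(sign_change))
    i = sign_change[0]
    lw = np.log(w[i]) + (0.0 - s[i]) * (np.log(w[i + 1]) - np.log(w[i])) \
        / (s[i + 1] - s[i])
    wc = float(np.exp(lw))
    mod.omega_c, mod.tau = wc, 1.0 / wc
    return wc, 1.0 / wc


def terminal_viscosity(mod: ComplexModulus,
                       terminal_window: tuple[float, float] | None = None,
                       slope_tol: float = 0.05) -> float:
    """Terminal viscosity η = ⟨G″/ω⟩ over a window where G″ ∝ ω.

    Default window: the lowest decade of the valid grid (below ω_c when
    a crossover was found).  The log–log slope of G″ must be within
    ``slope_tol`` of 1, otherwise the window is not terminal.
    """
    m = mod.valid & (mod.G_double_prime > 0)
    if terminal_window is None:
        upper = mod.omega[m][0] * 10.0
        if mod.omega_c is not None:
            upper = min(upper, mod.omega_c / 3.0)
        terminal_window = (mod.omega[m][0], upper)
    lo, hi = terminal_window
    if hi <= lo:
        raise WindowError("terminal window must satisfy lo < hi")
    sel = m & (mod.omega >= lo) & (mod.omega <= hi)
    if np.sum(sel) < 2:
        raise WindowError("terminal window contains fewer than 2 points")
    lx = np.log(mod.omega[sel])
    ly = np.log(mod.G_double_prime[sel])
    slope = np.polyfit(lx, ly, 1)[0]
    if abs(slope - 1.0) > slope_tol:
        raise TerminalRegionError(
            f"G'' slope {slope:.3f} not terminal in window {terminal_window}")
    eta = float(np.mean(mod.G_double_prime[sel] / mod.omega[sel]))
    mod.eta = eta
    return eta


def analyze_msd(curve, probe: ProbeSpec, medium: MediumSpec,
                omega: np.ndarray, n_max: int = 5,
                tau_grid: np.ndarray | None = None,
                basset: bool = True) -> ComplexModulus:
    """End-to-end inversion: MSD curve → spectrum fit → friction →
    modulus, with crossover and terminal viscosity attached.

    The short-time (inertial-Langevin) and long-time asymptotes are
    fitted first when absent from the curve.  The terminal window is
    placed at (ω_c/100, ω_c/30) when a crossover exists — low enough
    for G″ ∝ ω, high enough that the transform is still anchored by
    in-band data rather than extrapolation — and at the lowest decade
    of the grid otherwise.
    """
    from . import bsw, msd as msd_mod

    if curve.C is None or curve.tau_v is None:
        msd_mod.fit_ballistic_inertial(curve)
    if curve.D is None:
        msd_mod.fit_limits(curve, (curve.lags[0], curve.lags[0] * 4),
                           (curve.lags[-1] / 20, curve.lags[-1]))
        msd_mod.fit_ballistic_inertial(curve)
    spec = bsw.fit(curve, n_max=n_max, tau_grid=tau_grid)
    mw = spec.fourier(omega)
    Z = friction_from_msd(mw, curve.d, medium.T, probe.m_eff, omega)
    mod = modulus_from_friction(Z, probe, medium, basset=basset)
    co = crossover(mod)
    window = None
    if co is not None and co[0] / 30 > omega[0]:
        window = (max(co[0] / 100, omega[0]), co[0] / 30)
    try:
        terminal_viscosity(mod, window)
    except (TerminalRegionError, WindowError) as exc:
        warnings.warn(f"terminal viscosity unavailable: {exc}", stacklevel=2)
    mod.spectrum = spec  # type: ignore[attr-defined]
    return mod
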