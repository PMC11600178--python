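"""Synthetic ground truth: a probe obeying the generalized Langevin
equation in a medium with exactly known moduli.

    m dv/dt = −∫₀ᵗ ζ(t−s) v(s) ds + F_B(t),        F_ex = 0,

with an exponential (Maxwell) memory kernel per mode,
ζ(t) = Σ_i (c_i/τ_i) e^{−t/τ_i}.  Each mode is integrated by Markovian
embedding: an auxiliary Ornstein–Uhlenbeck force u_i with

    du_i = −(u_i + c_i v) dt/τ_i + (√(2 k_B T c_i)/τ_i) dW_i ,

so the colored noise satisfies fluctuation–dissipation with the same
kernel by construction and the integration is O(N).  The corresponding
medium has G*(ω) = iω ζ̂(ω)/(6π R_h) with ζ̂(ω) = Σ c_i/(1+iωτ_i): a
multi-mode Maxwell fluid with G₀_i = c_i/(6π R_h τ_i), η = Σ c_i/(6π R_h).

The generator deliberately contains no Basset/added-mass forces (the
kernel absorbs all drag), so the inversion chain is validated in its
low-medium-inertia limit; the inertial terms are exercised separately
with algebraic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import InputError
from .green_kubo import MaxwellModes
from .igser import ComplexModulus
from .io import StressSeries, Trajectory
from .units import KB, MASS_TO_ENERGY

_STABILITY_FACTOR = 50  # dt must resolve the fastest kernel time


@dataclass(frozen=True)
class GLEModel:
    """Probe-in-Maxwell-fluid model.

    kernel : ("newtonian", ζ₀) | ("maxwell", ζ₀, τ_M) |
             ("multi_maxwell", [(ζ_i, τ_i), …]) |
             ("jeffreys", ζ_N, [(ζ_i, τ_i), …]) with ζ in g/(mol·ns)
             (per-mode time-integrated friction) and τ in ns; the
             Jeffreys form adds an instantaneous (solvent/thermostat)
             drag ζ_N on top of the Maxwell modes
    m : probe mass g/mol;  T : K;  dt : ns;  n_steps, seed, n_probes
    R_h_nominal : Å, converts the kernel to moduli via ζ = 6πηR_h
    """

    kernel: tuple
    m: float
    T: float
    dt: float
    n_steps: int
    seed: int
    n_probes: int = 1
    R_h_nominal: float = 10.6

    def __post_init__(self) -> None:
        if self.kernel[0] not in ("newtonian", "maxwell", "multi_maxwell",
                                  "jeffreys"):
            raise InputError(f"unknown kernel {self.kernel[0]!r}")
        if self.m <= 0 or self.T <= 0 or self.dt <= 0 or self.n_steps < 1:
            raise InputError("invalid model parameters")
        taus = [t for _, t in self.modes()] or [np.inf]
        if self.kernel[0] != "newtonian" and \
                self.dt > min(taus) / _STABILITY_FACTOR:
            raise InputError(
                f"dt must be <= min kernel time / {_STABILITY_FACTOR}")

    def modes(self) -> list[tuple[float, float]]:
        """Maxwell part of the kernel as [(c_i, τ_i)], c in g/(mol·ns)."""
        kind = self.kernel[0]
        if kind == "newtonian":
            return []
        if kind == "maxwell":
            return [(self.kernel[1], self.kernel[2])]
        if kind == "jeffreys":
            return list(self.kernel[2])
        return list(self.kernel[1])

    @property
    def zeta_newtonian(self) -> float:
        """Instantaneous drag component, g/(mol·ns)."""
        if self.kernel[0] == "newtonian":
            return self.kernel[1]
        if self.kernel[0] == "jeffreys":
            return self.kernel[1]
        return 0.0

    @property
    def zeta0(self) -> float:
        """Zero-frequency friction ζ_N + Σ c_i, g/(mol·ns)."""
        return float(self.zeta_newtonian
                     + sum(c for c, _ in self.modes()))

    @classmethod
    def maxwell_fluid(cls, G0: float, tau_M: float, R_h: float, m: float,
                      T: float, dt: float, n_steps: int, seed: int,
                      n_probes: int = 1) -> "GLEModel":
        """Build the model whose medium is a single-mode Maxwell fluid
        with plateau modulus G₀ (kcal/(mol·Å³)) and relaxation τ_M."""
        c_energy = 6.0 * np.pi * R_h * G0 * tau_M    # kcal·ns/(mol·Å²)
        c = c_energy / MASS_TO_ENERGY                # g/(mol·ns)
        return cls(kernel=("maxwell", c, tau_M), m=m, T=T, dt=dt,
                   n_steps=n_steps, seed=seed, n_probes=n_probes,
                   R_h_nominal=R_h)


@dataclass
class GroundTruth:
    """Analytic reference for a :class:`GLEModel`."""

    omega: np.ndarray
    G_prime: np.ndarray
    G_double_prime: np.ndarray
    eta_true: float                  # kcal·ns/(mol·Å³)
    tau_true: float | None           # ns (None for newtonian)
    t: np.ndarray | None = None
    msd_true: np.ndarray | None = None   # Å², per-probe, 3D
    D_true: float = field(default=np.nan)  # Å²/ns


def simulate(model: GLEModel, burn_in: float | None = None,
             chunk: int = 100_000) -> Trajectory:
    """Integrate the passive GLE forward; returns single-bead probe
    trajectories (free space, no box), deterministic given the seed.

    Velocity-Verlet drift/kick with an exact OU update of each auxiliary
    force per step (B-A-O-A-B splitting); Maxwell–Boltzmann velocities
    and stationary auxiliary forces at t=0, plus a burn-in of ten times
    the slowest kernel time by default.
    """
    rng = np.random.default_rng(model.seed)
    n_cols = model.n_probes * 3
    m_c = model.m * MASS_TO_ENERGY
    kT = KB * model.T
    dt = model.dt

    modes = [(c * MASS_TO_ENERGY, tau) for c, tau in model.modes()]
    newt = len(modes) == 0
    zn = model.zeta_newtonian * MASS_TO_ENERGY

    v = rng.normal(0.0, np.sqrt(kT / m_c), n_cols)
    x = np.zeros(n_cols)
    us = None
    th = np.exp(-zn * dt / m_c) if zn > 0 else 1.0
    sig_v = np.sqrt(kT / m_c * (1.0 - th * th))
    if not newt:
        us = np.stack([rng.normal(0.0, np.sqrt(kT * c / tau), n_cols)
                       for c, tau in modes])
        th_u = np.array([np.exp(-dt / tau) for _, tau in modes])
        sig_u = np.array([np.sqrt(kT * c / tau * (1 - e * e))
                          for (c, tau), e in zip(modes, th_u)])
        cs = np.array([c for c, _ in modes])

    if burn_in is None:
        burn_in = 0.0 if newt else 10.0 * max(tau for _, tau in modes)
    n_burn = int(np.ceil(burn_in / dt))

    out = np.empty((model.n_steps + 1, n_cols))

    def run(n_do: int, sink: np.ndarray | None, offset: int) -> None:
        nonlocal v, x, us
        done = 0
        while done < n_do:
            nb = min(chunk, n_do - done)
            if newt:
                noise = rng.normal(size=(nb, n_cols))
                for s in range(nb):
                    x += 0.5 * dt * v
                    v = th * v + sig_v * noise[s]
                    x += 0.5 * dt * v
                    if sink is not None:
                        sink[offset + done + s] = x
            else:
                noise = rng.normal(size=(nb, len(modes), n_cols))
                noise_v = (rng.normal(size=(nb, n_cols)) if zn > 0
                           else None)
                for s in range(nb):
                    v += (0.5 * dt / m_c) * us.sum(axis=0)
                    x += 0.5 * dt * v
                    u_ss = -cs[:, None] * v[None, :]
                    us = u_ss + (us - u_ss) * th_u[:, None] \
                        + sig_u[:, None] * noise[s]
                    if zn > 0:
                        v = th * v + sig_v * noise_v[s]
                    v += (0.5 * dt / m_c) * us.sum(axis=0)
                    x += 0.5 * dt * v
                    if sink is not None:
                        sink[offset + done + s] = x
            done += nb

    run(n_burn, None, 0)
    out[0] = x
    run(model.n_steps, out, 1)

    times = dt * np.arange(model.n_steps + 1)
    pos = out.reshape(model.n_steps + 1, model.n_probes, 3)
    roles = np.array(["probe_bead"] * model.n_probes, dtype=object)
    return Trajectory(times=times, positions=pos, roles=roles,
                      probe_ids=np.arange(model.n_probes),
                      box=None, periodic=np.zeros(3, bool))


def _vacf_poles(model: GLEModel) -> tuple[np.ndarray, np.ndarray]:
    """Poles/residues of the per-component VACF Laplace transform
    C_v(s) = kT/m · Π(1+sτ)/[s·Π(1+sτ) + Σ(c_i/m)Π_{k≠i}(1+sτ_k)]."""
    m_c = model.m * MASS_TO_ENERGY
    kT = KB * model.T
    modes = [(c * MASS_TO_ENERGY, tau) for c, tau in model.modes()]
    zn = model.zeta_newtonian * MASS_TO_ENERGY
    if not modes:  # newtonian: single exponential
        g = zn / m_c
        return np.array([-g]), np.array([kT / m_c])
    num = np.poly1d([1.0])
    for _, tau in modes:
        num = num * np.poly1d([tau, 1.0])
    den = (np.poly1d([1.0, 0.0]) + np.poly1d([zn / m_c])) * num
    for i, (c, tau) in enumerate(modes):
        rest = np.poly1d([c / m_c])
        for k, (_, tk) in enumerate(modes):
            if k != i:
                rest = rest * np.poly1d([tk, 1.0])
        den = den + rest
    poles = np.roots(den.coeffs)
    res = np.array([np.polyval(num.coeffs, p) / np.polyval(
        np.polyder(den.coeffs), p) for p in poles])
    return poles, (kT / m_c) * res


def vacf_true(model: GLEModel, t: np.ndarray) -> np.ndarray:
    """Exact per-component velocity autocorrelation of the GLE."""
    poles, res = _vacf_poles(model)
    t = np.asarray(t, float)
    return np.real(np.sum(res[:, None] * np.exp(poles[:, None] * t[None, :]),
                          axis=0))


def msd_true(model: GLEModel, t: np.ndarray, d: int = 3) -> np.ndarray:
    """Exact d-dimensional MSD: 2d ∫₀ᵗ (t−s) C_v(s) ds in closed form."""
    poles, res = _vacf_poles(model)
    t = np.asarray(t, float)
    out = np.zeros_like(t, complex)
    for p, A in zip(poles, res):
        out += A * (np.exp(p * t) - 1.0 - p * t) / (p * p)
    return 2.0 * d * np.real(out)


def ground_truth(model: GLEModel, omega: np.ndarray,
                 t: np.ndarray | None = None) -> GroundTruth:
    """Exact moduli, viscosity, relaxation time and MSD of the model."""
    omega = np.asarray(omega, float)
    R = model.R_h_nominal
    modes = [(c * MASS_TO_ENERGY, tau) for c, tau in model.modes()]
    zn = model.zeta_newtonian * MASS_TO_ENERGY
    zeta_w = np.full_like(omega, zn, dtype=complex)
    if modes:
        zeta_w = zeta_w + np.sum(
            [c / (1.0 + 1j * omega * tau) for c, tau in modes], axis=0)
        tau_true = float(max(tau for _, tau in modes))
    else:
        tau_true = None
    eta = model.zeta0 * MASS_TO_ENERGY / (6.0 * np.pi * R)
    G = 1j * omega * zeta_w / (6.0 * np.pi * R)
    D = KB * model.T / (model.zeta0 * MASS_TO_ENERGY)
    gt = GroundTruth(omega=omega, G_prime=G.real, G_double_prime=G.imag,
                     eta_true=eta, tau_true=tau_true, D_true=D)
    if t is not None:
        gt.t = np.asarray(t, float)
        gt.msd_true = msd_true(model, gt.t)
    return gt


def moduli_true(model: GLEModel, omega: np.ndarray) -> ComplexModulus:
    gt = ground_truth(model, omega)
    return ComplexModulus(omega=gt.omega, G_prime=gt.G_prime,
                          G_double_prime=gt.G_double_prime)


def synth_stress(modes: MaxwellModes, V: float, T: float, dt: float,
                 n_steps: int, seed: int) -> StressSeries:
    """Synthetic pressure-tensor series whose relaxation modulus is
    ΣG_i e^{−t/τ_i} under the five-component isotropic estimator.

    Off-diagonal channels: independent OU sums with per-mode variance
    (k_BT/V)·G_i; diagonal channels: independent OU sums with twice that
    variance, so each normal-difference ACF is 4× an off-diagonal ACF
    (isotropic consistency).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    kTV = KB * T / V
    t = dt * np.arange(n_steps)
    comps = np.zeros((n_steps, 6))
    for k in range(6):
        var = 2.0 * kTV if k < 3 else kTV  # xx,yy,zz then xy,xz,yz
        for G_i, tau_i in zip(modes.G, modes.tau):
            if G_i == 0:
                continue
            th = np.exp(-dt / tau_i)
            sig = np.sqrt(var * G_i * (1 - th * th))
            eps = rng.normal(size=n_steps) * sig
            eps[0] = rng.normal() * np.sqrt(var * G_i)  # stationary start
            comps[:, k] += lfilter([1.0], [1.0, -th], eps)
    return StressSeries(times=t, components=comps, volume=V, temperature=T)
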