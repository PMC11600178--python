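"""Hydropathy-scale (HPS) residue-level model utilities.

One bead per residue; nonbonded pairs interact through an
Ashbaugh–Hatch-modified Lennard-Jones potential whose attractive depth
scales with the mean hydropathy λ of the pair, plus Debye–Hückel
screened electrostatics for the charged residues.  The module also
provides the sequence charge-patterning descriptor nSCD and the
semidilute correlation-length criterion used to pick a probe size.

Hydropathy tables: Kapcha–Rossky (``kr``) and Urry (``urry``) scales as
published for this model class, shipped in ``data/hps_params.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError

# Coulomb constant e²/(4πϵ₀) in kcal·Å/mol, from CODATA values
_E_CHARGE = 1.602176634e-19      # C
_EPS0 = 8.8541878128e-12         # F/m
_NA = 6.02214076e23              # 1/mol
_J_PER_KCAL = 4184.0
COULOMB_KCAL_A = (_E_CHARGE ** 2 / (4.0 * np.pi * _EPS0)) \
    * 1e10 * _NA / _J_PER_KCAL   # ≈ 332.06 kcal·Å/mol


@dataclass(frozen=True)
class HPSParams:
    """Force-field constants (model defaults, overridable)."""

    eps_hps: float = 0.2          # kcal/mol, vdW interaction strength
    k_bond: float = 20.0          # kcal/(mol Å²), harmonic bond constant
    r0: float = 3.8               # Å, equilibrium bond length
    eps_r: float = 80.0           # relative permittivity
    debye_l: float = 10.0         # Å, screening length
    vdw_cutoff_sigma: float = 4.0  # cutoff in units of σ
    elec_cutoff: float = 35.0     # Å
    his_charge: float = 0.0       # histidine charge convention


DEFAULT_PARAMS = HPSParams()


def _table() -> pd.DataFrame:
    with resources.files("microrheo.data").joinpath("hps_params.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t").set_index("res")


_TABLE = _table()


def residue_params(scale: str = "kr") -> pd.DataFrame:
    """Per-residue mass (g/mol), charge (e), σ (Å) and hydropathy λ."""
    col = {"kr": "lambda_kr", "urry": "lambda_urry"}.get(scale)
    if col is None:
        raise InputError(f"unknown hydropathy scale {scale!r}")
    df = _TABLE[["mass", "charge", "sigma", col]].copy()
    return df.rename(columns={col: "lambda"})


@dataclass
class SequenceRecord:
    """An amino-acid sequence with per-residue charges and its nSCD."""

    residues: str
    charges: np.ndarray
    nSCD: float

    @classmethod
    def from_sequence(cls, seq: str,
                      params: HPSParams = DEFAULT_PARAMS) -> "SequenceRecord":
        charges = assign_charges(seq, params)
        return cls(residues=seq, charges=charges,
                   nSCD=nscd_from_charges(charges))


def assign_charges(seq: str, params: HPSParams = DEFAULT_PARAMS) -> np.ndarray:
    """E/D → −1, K/R → +1, H → ``params.his_charge`` (0 by default)."""
    table = {"E": -1.0, "D": -1.0, "K": 1.0, "R": 1.0, "H": params.his_charge}
    unknown = set(seq) - set(_TABLE.index)
    if unknown:
        raise InputError(f"unknown residues: {sorted(unknown)}")
    return np.array([table.get(aa, 0.0) for aa in seq])


# -------------------------------------------------------------- energies

def bond_energy(r: float, params: HPSParams = DEFAULT_PARAMS) -> float:
    """Harmonic bond U = ½ k_b (r − r0)² (engine convention with the ½)."""
    if np.any(np.asarray(r) <= 0):
        raise InputError("r must be positive")
    return 0.5 * params.k_bond * (np.asarray(r, float) - params.r0) ** 2


def lj_energy(r, sigma: float, eps: float):
    sr6 = (sigma / np.asarray(r, float)) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def vdw_energy(r, lambda_i: float, lambda_j: float,
               sigma_i: float, sigma_j: float,
               eps: float = DEFAULT_PARAMS.eps_hps,
               cutoff_sigma: float = DEFAULT_PARAMS.vdw_cutoff_sigma):
    """Ashbaugh–Hatch hydropathy-scaled LJ with arithmetic mixing.

    U = U_LJ + (1−λ)ε for r ≤ 2^{1/6}σ, U = λ·U_LJ beyond, truncated to
    zero (plain truncation, no shift) at ``cutoff_sigma``·σ.
    """
    r = np.asarray(r, float)
    lam = 0.5 * (lambda_i + lambda_j)
    sig = 0.5 * (sigma_i + sigma_j)
    ulj = lj_energy(r, sig, eps)
    rmin = 2.0 ** (1.0 / 6.0) * sig
    out = np.where(r <= rmin, ulj + (1.0 - lam) * eps, lam * ulj)
    out = np.where(r > cutoff_sigma * sig, 0.0, out)
    return float(out) if out.ndim == 0 else out


def coulomb_energy(r, q_i: float, q_j: float,
                   params: HPSParams = DEFAULT_PARAMS):
    """Debye–Hückel screened Coulomb, kcal/mol, truncated at 35 Å."""
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise InputError("r must be positive")
    u = COULOMB_KCAL_A * q_i * q_j / (params.eps_r * r) \
        * np.exp(-r / params.debye_l)
    out = np.where(r > params.elec_cutoff, 0.0, u)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------- sequence descriptor

def scd(charges: np.ndarray) -> float:
    """Sequence charge decoration: (1/N)·Σ_{i<j} q_i q_j √(j−i)."""
    q = np.asarray(charges, float)
    N = len(q)
    i, j = np.triu_indices(N, k=1)
    return float(np.sum(q[i] * q[j] * np.sqrt(j - i)) / N)


def _alternating(charges: np.ndarray) -> np.ndarray:
    """Maximally alternating arrangement of the same charge multiset:
    interleave +/− as evenly as possible, neutral residues spread last."""
    q = np.sort(np.asarray(charges, float))[::-1]
    pos = list(q[q > 0]); neg = list(q[q < 0]); neu = list(q[q == 0])
    out = []
    while pos or neg:
        if len(pos) >= len(neg) and pos:
            out.append(pos.pop())
            if neg:
                out.append(neg.pop())
        else:
            out.append(neg.pop())
            if pos:
                out.append(pos.pop())
    # distribute neutrals evenly through the charged backbone
    if neu:
        step = max(1, len(out) // (len(neu) + 1))
        for k, z in enumerate(neu):
            out.insert(min(len(out), (k + 1) * step + k), z)
    return np.array(out)


def _diblock(charges: np.ndarray) -> np.ndarray:
    """Maximally segregated arrangement: +block, neutrals, −block."""
    q = np.asarray(charges, float)
    return np.concatenate([q[q > 0], q[q == 0], q[q < 0]])


def nscd_from_charges(charges: np.ndarray) -> float:
    """Normalized SCD ∈ [0,1]: 0 for the alternating arrangement of the
    composition, 1 for the diblock arrangement."""
    q = np.asarray(charges, float)
    if np.sum(q != 0) < 2:
        raise InputError("nSCD needs at least two charged residues")
    s = scd(q)
    s_min = scd(_alternating(q))
    s_max = scd(_diblock(q))
    if s_max == s_min:
        raise InputError("degenerate composition: SCD extremes coincide")
    return float((s - s_min) / (s_max - s_min))


def nscd(seq: str, params: HPSParams = DEFAULT_PARAMS) -> float:
    """nSCD of an amino-acid sequence (charges per :func:`assign_charges`)."""
    return nscd_from_charges(assign_charges(seq, params))


# ------------------------------------------------ probe-medium criteria

@dataclass(frozen=True)
class CorrelationLengthResult:
    xi: float          # Å
    rho_star: float    # g/(mol Å³), overlap concentration
    Re: float          # Å
    Mw: float          # g/mol
    nu: float


def correlation_length(rho: float, Re: float, Mw: float,
                       nu: float = 0.5) -> CorrelationLengthResult:
    """Semidilute correlation length ξ = Re (ρ/ρ*)^{ν/(1−3ν)} with the
    overlap concentration ρ* = 3Mw/(4π Re³) in per-mole units.  With the
    ideal-chain exponent ν = 1/2 this reduces to ξ = Re·ρ*/ρ."""
    if min(rho, Re, Mw) <= 0:
        raise InputError("rho, Re, Mw must be positive")
    if abs(nu - 1.0 / 3.0) < 1e-9:
        raise InputError("nu = 1/3 is singular in the semidilute scaling")
    if not (1.0 / 3.0 < nu < 1.0):
        raise InputError("nu must lie in (1/3, 1)")
    rho_star = 3.0 * Mw / (4.0 * np.pi * Re ** 3)
    xi = Re * (rho / rho_star) ** (nu / (1.0 - 3.0 * nu))
    return CorrelationLengthResult(xi=float(xi), rho_star=float(rho_star),
                                   Re=Re, Mw=Mw, nu=nu)


def probe_size_criterion(R_h: float, xi: float) -> dict:
    """Continuum-validity check R_h/ξ ≥ 1.5, with the recommended
    efficiency band [1.5ξ, 2ξ] flagged."""
    if R_h <= 0 or xi <= 0:
        raise InputError("R_h and xi must be positive")
    ratio = R_h / xi
    verdict = "ok" if ratio >= 1.5 else "too_small"
    note = ""
    if verdict == "ok" and ratio > 2.0:
        note = "above recommended band [1.5, 2.0]: sampling is slower"
    return {"verdict": verdict, "ratio": ratio, "note": note}


def interaction_window_check(eps_ratio: float) -> dict:
    """Classify the probe–protein interaction strength ε/ε_HPS.

    < 0.75 : slip at the probe surface (below_no_slip)
    [1, 1.5] : optimal window (macroscopic viscosity recovered)
    ≥ 1.75 : chains adsorb onto the probe (adsorption_risk)
    Values in the gaps classify to the nearest band with a warning note.
    """
    if eps_ratio < 0:
        raise InputError("eps_ratio must be >= 0")
    note = ""
    if eps_ratio < 0.75:
        verdict = "below_no_slip"
    elif eps_ratio < 1.0:
        verdict = "below_no_slip" if eps_ratio < 0.875 else "optimal"
        note = "between the no-slip threshold and the optimal window"
    elif eps_ratio <= 1.5:
        verdict = "optimal"
    elif eps_ratio < 1.75:
        verdict = "optimal" if eps_ratio < 1.625 else "adsorption_risk"
        note = "between the optimal window and the adsorption threshold"
    else:
        verdict = "adsorption_risk"
    return {"verdict": verdict, "eps_ratio": eps_ratio, "note": note}


def with_his_charge(params: HPSParams, q: float) -> HPSParams:
    """Convenience: copy the parameter set with a different H charge."""
    return replace(params, his_charge=q)
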