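"""Rough-sphere probe construction and probe-medium diagnostics.

The probe is carved from an FCC lattice of small LJ beads (σ = 1.5 Å,
m = 100 g/mol), with "lattice spacing" meaning the cubic-cell edge
a = 2.12 Å so nearest neighbors (corner–face) sit at a/√2 ≈ 1.5 Å,
just touching.  Neighboring beads are tied by stiff harmonic bonds into
a single rigid-ish body.  Diagnostics: gyration radius and relative
shape anisotropy κ² (0 for a sphere), hydrodynamic radius from the
first RDF peak between probe center and protein residues, and the
no-slip check on residue velocity profiles around a dragged probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import GridError, InputError, SelectionError
from .io import Trajectory

BEAD_MASS = 100.0     # g/mol
BEAD_SIGMA = 1.5      # Å
BOND_K = 250.0        # kcal/(mol Å²)
DEFAULT_SPACING = 2.12  # Å, FCC cubic cell edge


@dataclass
class ProbeStructure:
    """Beads and bonds of a carved FCC probe."""

    bead_positions: np.ndarray           # (n, 3) Å, centered on a lattice site
    bonds: np.ndarray                    # (m, 2) int pairs
    R_b: float                           # carve radius Å
    lattice_spacing: float = DEFAULT_SPACING
    bead_mass: float = BEAD_MASS
    bead_sigma: float = BEAD_SIGMA
    bond_k: float = BOND_K

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def m_bare(self) -> float:
        return self.bead_mass * self.n_beads

    def min_interbead_distance(self) -> float:
        if self.n_beads < 2:
            raise InputError("single-bead probe has no interbead distance")
        d, _ = cKDTree(self.bead_positions).query(self.bead_positions, k=2)
        return float(d[:, 1].min())

    def is_connected(self) -> bool:
        if self.n_beads == 1:
            return True
        if len(self.bonds) == 0:
            return False
        i, j = self.bonds.T
        adj = coo_matrix((np.ones(len(i)), (i, j)),
                         shape=(self.n_beads, self.n_beads))
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1

    def to_xyz(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_beads}\nprobe R_b={self.R_b}\n")
            for x, y, z in self.bead_positions:
                fh.write(f"P {x!r} {y!r} {z!r}\n")

    def to_lammps_data(self, path: str | Path, box_pad: float = 10.0) -> None:
        """Minimal LAMMPS data file (atoms + bonds, one type each)."""
        L = 2 * (self.R_b + box_pad)
        lines = ["probe particle data", "",
                 f"{self.n_beads} atoms", f"{len(self.bonds)} bonds", "",
                 "1 atom types", "1 bond types", "",
                 f"{-L/2} {L/2} xlo xhi", f"{-L/2} {L/2} ylo yhi",
                 f"{-L/2} {L/2} zlo zhi", "", "Masses", "",
                 f"1 {self.bead_mass}", "", "Atoms", ""]
        for k, (x, y, z) in enumerate(self.bead_positions, 1):
            lines.append(f"{k} 1 1 {x} {y} {z}")
        lines += ["", "Bonds", ""]
        for k, (i, j) in enumerate(self.bonds, 1):
            lines.append(f"{k} 1 {i + 1} {j + 1}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ProbeGeometry:
    Rg: float
    kappa2: float
    R_h: float | None = None
    m_bare: float | None = None


def build_probe(R_b: float, lattice_spacing: float = DEFAULT_SPACING,
                bond_cut: float | None = None) -> ProbeStructure:
    """Carve a sphere of radius ``R_b`` from an FCC lattice centered on a
    lattice site; bond bead pairs closer than ``bond_cut`` (default
    1.05× the nearest-neighbor distance a/√2)."""
    if R_b <= 0:
        raise InputError("R_b must be positive")
    a = lattice_spacing
    nn = a / np.sqrt(2.0)
    if bond_cut is None:
        bond_cut = 1.05 * nn
    n = int(np.ceil(R_b / a)) + 1
    grid = np.arange(-n, n + 1)
    ii, jj, kk = np.meshgrid(grid, grid, grid, indexing="ij")
    corners = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    basis = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                      [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
    pts = (corners[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    keep = np.einsum("ij,ij->i", pts, pts) <= R_b ** 2 + 1e-9
    pos = pts[keep]
    if len(pos) == 1:
        warnings.warn("carve radius below the first shell: single-bead probe",
                      stacklevel=2)
        bonds = np.empty((0, 2), int)
    else:
        pairs = cKDTree(pos).query_pairs(bond_cut, output_type="ndarray")
        bonds = np.sort(pairs, axis=1)
    return ProbeStructure(bead_positions=pos, bonds=bonds, R_b=R_b,
                          lattice_spacing=lattice_spacing)


def geometry(positions: np.ndarray) -> ProbeGeometry:
    """Gyration radius and relative shape anisotropy of bead positions.

    ``positions`` may be (n, 3) or (n_frames, n, 3); frames are averaged.
    κ² = 1 − 3(λ₁λ₂+λ₁λ₃+λ₂λ₃)/(λ₁+λ₂+λ₃)² from the gyration-tensor
    eigenvalues (0 for a sphere, 1 for a rod).
    """
    pos = np.asarray(positions, float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.shape[1] < 4:
        warnings.warn("fewer than 4 beads: gyration tensor is degenerate",
                      stacklevel=2)
    rg2s, k2s = [], []
    for frame in pos:
        c = frame - frame.mean(axis=0)
        S = c.T @ c / len(c)
        lam = np.sort(np.linalg.eigvalsh(S))[::-1]
        tr = lam.sum()
        rg2s.append(tr)
        k2s.append(1.0 - 3.0 * (lam[0] * lam[1] + lam[0] * lam[2]
                                + lam[1] * lam[2]) / tr ** 2
                   if tr > 0 else 0.0)
    return ProbeGeometry(Rg=float(np.sqrt(np.mean(rg2s))),
                         kappa2=float(np.mean(k2s)))


def rdf_probe_residue(traj: Trajectory, r_max: float, bin_width: float,
                      residue_role: str = "residue"
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function between probe centers of mass and
    residue beads, averaged over frames; standard shell-volume/density
    normalization with minimum-image distances."""
    if traj.box is None:
        raise GridError("RDF requires a box")
    if r_max >= 0.5 * np.min(traj.box):
        raise GridError("r_max must be below half the smallest box edge")
    res_sel = np.where(traj.roles == residue_role)[0]
    if len(res_sel) == 0:
        raise SelectionError("no residue particles in trajectory")
    centers = traj.probe_centers()            # (nf, np, 3)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    L = traj.box
    nf, ncen = centers.shape[:2]
    for f in range(nf):
        d = traj.positions[f, res_sel][None, :, :] - centers[f][:, None, :]
        d -= L[None, None, :] * np.round(d / L[None, None, :])
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).ravel()
        counts += np.histogram(r, bins=edges)[0]
    rho = len(res_sel) / np.prod(L)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (nf * ncen * rho * shell)
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    return r_mid, g


def hydrodynamic_radius(r: np.ndarray, g: np.ndarray,
                        min_height: float = 1.1) -> float:
    """First local maximum of g(r) above 1 (and above ``min_height``, a
    guard against baseline noise), refined by a parabola through the
    peak bin and its neighbors."""
    r = np.asarray(r, float)
    g = np.asarray(g, float)
    for i in range(1, len(g) - 1):
        if g[i] > max(1.0, min_height) and g[i] >= g[i - 1] \
                and g[i] > g[i + 1]:
            y0, y1, y2 = g[i - 1], g[i], g[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                shift = 0.5 * (y0 - y2) / denom
                shift = float(np.clip(shift, -1.0, 1.0))
            else:
                shift = 0.0
            return float(r[i] + shift * (r[1] - r[0]))
    raise InputError("no RDF peak above 1: no structure around the probe")


@dataclass
class VelocityProfile:
    r_bins: np.ndarray        # bin centers, Å
    v_x: np.ndarray           # mean residue v_x per bin, Å/ns (NaN if empty)
    v_x_probe: float
    no_slip_diagnostic: float = field(init=False)

    def __post_init__(self) -> None:
        first = np.flatnonzero(np.isfinite(self.v_x))
        self.no_slip_diagnostic = (float(self.v_x[first[0]] / self.v_x_probe)
                                   if len(first) else np.nan)


def velocity_profile(traj: Trajectory, v_x_probe: float,
                     bins: np.ndarray,
                     velocities: np.ndarray | None = None
                     ) -> VelocityProfile:
    """Mean residue x-velocity versus radial distance from the probe
    center; the first-bin value over ``v_x_probe`` is the no-slip
    diagnostic (1 = no slip, 0 = full slip).

    Residue velocities default to central finite differences of the
    (unwrapped) positions.
    """
    res_sel = np.where(traj.roles == "residue")[0]
    if len(res_sel) == 0:
        raise SelectionError("no residue particles")
    centers = traj.probe_centers()[:, 0, :]
    pos = traj.positions[:, res_sel, :]
    if velocities is None:
        if traj.n_frames < 3:
            raise GridError("need >= 3 frames for finite-difference velocities")
        v = np.gradient(pos, traj.times, axis=0)
    else:
        v = np.asarray(velocities, float)[:, res_sel, :] \
            if velocities.shape[1] == traj.n_particles else velocities
    d = pos - centers[:, None, :]
    if traj.box is not None:
        d -= traj.box * np.round(d / traj.box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).ravel()
    vx = v[:, :, 0].ravel()
    idx = np.digitize(r, bins) - 1
    nb = len(bins) - 1
    out = np.full(nb, np.nan)
    for b in range(nb):
        m = idx == b
        if np.any(m):
            out[b] = vx[m].mean()
    if np.any(np.isnan(out)):
        warnings.warn("empty radial bins masked as NaN", stacklevel=2)
    mid = 0.5 * (bins[1:] + bins[:-1])
    return VelocityProfile(r_bins=mid, v_x=out, v_x_probe=v_x_probe)
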