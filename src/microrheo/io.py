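"""Trajectory and stress-series containers plus readers/writers.

Supported trajectory formats: LAMMPS text dump (``lammps_dump``), HOOMD
GSD (``gsd``, available only when the optional :mod:`gsd` package is
installed), extended XYZ (``xyz``) and a native tabular dialect
(``csv``, header ``time,id,x,y,z``).  Boxes are orthorhombic only;
coordinates are stored exactly as found in the file and unwrapped
explicitly with :func:`unwrap` before any displacement analysis.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (AmbiguityError, BoxError, FormatError, InputError,
                     SelectionError, TimingError)

ROLES = ("probe_bead", "probe_center", "residue")

#: relative tolerance on uniform frame spacing
_DT_RTOL = 1e-6


@dataclass
class Trajectory:
    """Frames of particle positions with per-particle roles.

    times : (n_frames,) ns, strictly increasing, uniform
    positions : (n_frames, n_particles, 3) Å
    roles : (n_particles,) strings from :data:`ROLES`
    probe_ids : (n_particles,) int, −1 for non-probe particles; beads of
        probe *k* carry the value *k*
    box : (3,) Å orthorhombic edge lengths (may be None for free space)
    periodic : (3,) bool
    """

    times: np.ndarray
    positions: np.ndarray
    roles: np.ndarray
    probe_ids: np.ndarray
    box: np.ndarray | None = None
    periodic: np.ndarray = field(default_factory=lambda: np.ones(3, bool))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.probe_ids = np.asarray(self.probe_ids, int)
        if self.box is not None:
            self.box = np.asarray(self.box, float)
        self.periodic = np.asarray(self.periodic, bool)
        self.validate()

    def validate(self) -> None:
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise InputError("positions must have shape (n_frames, n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions contain non-finite values")
        dt = np.diff(self.times)
        if len(dt) and np.any(dt <= 0):
            raise TimingError("frame times must be strictly increasing")
        if len(dt) > 1:
            if np.max(np.abs(dt - dt[0])) > _DT_RTOL * abs(dt[0]):
                raise TimingError("frame spacing non-uniform beyond tolerance")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise InputError(f"unknown particle roles: {sorted(bad)}")
        for pid in np.unique(self.probe_ids):
            if pid >= 0 and not np.any(self.probe_ids == pid):
                raise SelectionError(f"probe id {pid} groups no beads")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise TimingError("need at least two frames for a timestep")
        return float(self.times[1] - self.times[0])

    def probe_labels(self) -> np.ndarray:
        """Sorted distinct probe ids present (>= 0)."""
        ids = np.unique(self.probe_ids)
        return ids[ids >= 0]

    def probe_centers(self) -> np.ndarray:
        """Per-frame center of mass of each probe's beads, shape
        (n_frames, n_probes, 3).  Beads are equal-mass."""
        labels = self.probe_labels()
        if len(labels) == 0:
            raise SelectionError("trajectory contains no probe beads")
        out = np.empty((self.n_frames, len(labels), 3))
        for k, lab in enumerate(labels):
            sel = self.probe_ids == lab
            out[:, k, :] = self.positions[:, sel, :].mean(axis=1)
        return out


@dataclass
class StressSeries:
    """Six pressure-tensor components over time.

    components columns follow ``(xx, yy, zz, xy, xz, yz)``; units are
    kcal/(mol·Å³) unless the caller tracks another convention.  ``volume``
    (Å³) and ``temperature`` (K) feed the Green–Kubo normalization.
    """

    times: np.ndarray
    components: np.ndarray
    volume: float
    temperature: float

    COLUMNS = ("Pxx", "Pyy", "Pzz", "Pxy", "Pxz", "Pyz")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.components = np.asarray(self.components, float)
        if self.components.ndim != 2 or self.components.shape[1] != 6:
            raise InputError("stress needs all six components "
                             "(xx, yy, zz, xy, xz, yz)")
        dt = np.diff(self.times)
        if len(dt) > 1 and np.max(np.abs(dt - dt[0])) > _DT_RTOL * abs(dt[0]):
            raise TimingError("stress sampling non-uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------- readers

def _read_csv_traj(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time", "id", "x", "y", "z"]
    if list(df.columns[:5]) != expected:
        raise FormatError(f"CSV trajectory needs header {expected}")
    times = np.sort(df["time"].unique())
    ids = np.sort(df["id"].unique())
    pos = np.empty((len(times), len(ids), 3))
    df = df.sort_values(["time", "id"])
    for ax, col in enumerate(("x", "y", "z")):
        pos[:, :, ax] = df[col].to_numpy().reshape(len(times), len(ids))
    return times, ids, pos


def _read_lammps_dump(path: Path):
    """Parse a LAMMPS text dump (``ITEM:`` headers).  Returns
    (steps, types, positions, box)."""
    steps, frames, types, box = [], [], None, None
    with open(path) as fh:
        line = fh.readline()
        while line:
            if not line.startswith("ITEM: TIMESTEP"):
                raise FormatError("expected ITEM: TIMESTEP in LAMMPS dump")
            steps.append(int(fh.readline()))
            if not fh.readline().startswith("ITEM: NUMBER OF ATOMS"):
                raise FormatError("expected ITEM: NUMBER OF ATOMS")
            natoms = int(fh.readline())
            bounds_hdr = fh.readline()
            if not bounds_hdr.startswith("ITEM: BOX BOUNDS"):
                raise BoxError("LAMMPS dump missing ITEM: BOX BOUNDS")
            if "xy" in bounds_hdr:
                raise BoxError("triclinic boxes are not supported")
            edges = []
            for _ in range(3):
                lo, hi = map(float, fh.readline().split()[:2])
                edges.append(hi - lo)
            box = np.array(edges)
            atoms_hdr = fh.readline()
            if not atoms_hdr.startswith("ITEM: ATOMS"):
                raise FormatError("expected ITEM: ATOMS")
            cols = atoms_hdr.split()[2:]
            try:
                ci = [cols.index(c) for c in ("id", "type", "x", "y", "z")]
            except ValueError as exc:
                raise FormatError("dump must provide id type x y z") from exc
            rows = np.array([fh.readline().split() for _ in range(natoms)])
            order = np.argsort(rows[:, ci[0]].astype(int))
            rows = rows[order]
            if types is None:
                types = rows[:, ci[1]]
            frames.append(rows[:, [ci[2], ci[3], ci[4]]].astype(float))
            line = fh.readline()
    return np.array(steps), types, np.array(frames), box


def _read_xyz(path: Path):
    """Multi-frame XYZ; returns (n_frames, n, 3) positions and names."""
    frames, names = [], None
    with open(path) as fh:
        line = fh.readline()
        while line.strip():
            natoms = int(line)
            fh.readline()  # comment
            rows = [fh.readline().split() for _ in range(natoms)]
            if names is None:
                names = np.array([r[0] for r in rows])
            frames.append(np.array([r[1:4] for r in rows], float))
            line = fh.readline()
            if not line:
                break
    return names, np.array(frames)


def read_trajectory(path: str | Path, format: str,
                    role_map: Mapping[str, str] | None = None,
                    dt: float | None = None,
                    box: Sequence[float] | None = None,
                    probe_groups: Mapping[int, Sequence[int]] | None = None,
                    ) -> Trajectory:
    """Read a trajectory file into a :class:`Trajectory`.

    Parameters
    ----------
    format : one of ``lammps_dump``, ``gsd``, ``xyz``, ``csv``
    role_map : maps the file's particle type/species labels to a role in
        ``{probe_bead, probe_center, residue}``; unknown labels default
        to ``residue`` when the map is omitted.
    dt : frame spacing in ns, required where the format stores no times
        (``xyz``) or only step numbers (``lammps_dump``, ``gsd``).
    box : orthorhombic edge lengths (Å), required for formats that do
        not store the box (``xyz``, ``csv``).
    probe_groups : optional explicit mapping probe-id → particle indices;
        by default all ``probe_bead`` particles form a single probe.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    if format == "csv":
        times, _ids, pos = _read_csv_traj(path)
        labels = np.array(["particle"] * pos.shape[1])
        file_box = None
    elif format == "xyz":
        labels, pos = _read_xyz(path)
        if dt is None:
            raise TimingError("xyz stores no times; pass dt")
        times = dt * np.arange(pos.shape[0])
        file_box = None
    elif format == "lammps_dump":
        steps, labels, pos, file_box = _read_lammps_dump(path)
        if dt is None:
            raise TimingError("pass dt (ns per step) for lammps_dump")
        times = steps * dt
    elif format == "gsd":
        try:
            import gsd.hoomd  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise FormatError("gsd support requires the 'gsd' package") from exc
        with gsd.hoomd.open(str(path)) as fh:  # pragma: no cover
            frames = [fr for fr in fh]
            pos = np.array([fr.particles.position for fr in frames], float)
            typeids = frames[0].particles.typeid
            names = frames[0].particles.types
            labels = np.array([names[t] for t in typeids])
            file_box = np.asarray(frames[0].configuration.box[:3], float)
            steps = np.array([fr.configuration.step for fr in frames])
            if dt is None:
                raise TimingError("pass dt (ns per step) for gsd")
            times = steps * dt
    else:
        raise FormatError(f"unknown trajectory format: {format!r}")

    use_box = np.asarray(box, float) if box is not None else file_box
    # the native CSV dialect stores probe centers: one probe per particle
    default_role = "probe_bead" if format == "csv" else "residue"
    role_map = dict(role_map or {})
    roles = np.array([role_map.get(str(lab), default_role)
                      for lab in labels], dtype=object)

    probe_ids = np.full(len(labels), -1, int)
    if probe_groups is not None:
        for pid, idx in probe_groups.items():
            probe_ids[np.asarray(idx, int)] = int(pid)
    elif format == "csv" and not role_map:
        probe_ids = np.arange(len(labels))
    else:
        probe_ids[np.isin(roles, ("probe_bead", "probe_center"))] = 0

    return Trajectory(times=times, positions=pos, roles=roles,
                      probe_ids=probe_ids, box=use_box,
                      periodic=np.array([use_box is not None] * 3))


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "csv") -> None:
    """Write the native tabular dialect (or XYZ).  CSV round-trips
    positions bit-exactly (shortest-repr floats)."""
    path = Path(path)
    if format == "csv":
        nf, n = traj.n_frames, traj.n_particles
        df = pd.DataFrame({
            "time": np.repeat(traj.times, n),
            "id": np.tile(np.arange(n), nf),
            "x": traj.positions[:, :, 0].ravel(),
            "y": traj.positions[:, :, 1].ravel(),
            "z": traj.positions[:, :, 2].ravel(),
        })
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "xyz":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.n_particles}\n")
                fh.write(f"t={traj.times[f]!r}\n")
                for i in range(traj.n_particles):
                    x, y, z = traj.positions[f, i]
                    fh.write(f"{traj.roles[i][:2]} {x!r} {y!r} {z!r}\n")
    else:
        raise FormatError(f"unsupported output format: {format!r}")


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic-boundary jumps so displacements are continuous.

    Uses the minimum-image convention frame to frame; correct whenever no
    particle truly moves more than half a box edge between stored frames
    (an undersampled trajectory is indistinguishable from a wrapped one,
    so that case cannot be detected post hoc and is documented as a
    user responsibility).
    """
    if traj.box is None:
        raise BoxError("unwrap requires a box")
    if not np.any(traj.periodic):
        return traj
    pos = traj.positions.copy()
    L = traj.box
    dr = np.diff(pos, axis=0)
    for ax in range(3):
        if traj.periodic[ax]:
            dr[:, :, ax] -= L[ax] * np.round(dr[:, :, ax] / L[ax])
    pos[1:] = pos[0] + np.cumsum(dr, axis=0)
    return Trajectory(times=traj.times, positions=pos, roles=traj.roles,
                      probe_ids=traj.probe_ids, box=traj.box,
                      periodic=np.zeros(3, bool))


def wrap(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap free-space coordinates into [0, L) per axis."""
    box = np.asarray(box, float)
    return np.mod(positions, box)


# ------------------------------------------------------------- stress I/O

def read_stress_series(path: str | Path, volume: float,
                       temperature: float) -> StressSeries:
    """Read the TSV dialect ``time,Pxx,Pyy,Pzz,Pxy,Pxz,Pyz``."""
    df = pd.read_csv(path, sep="\t")
    need = ["time", *StressSeries.COLUMNS]
    if list(df.columns[:7]) != need:
        raise InputError(f"stress TSV needs header {need}")
    return StressSeries(times=df["time"].to_numpy(),
                        components=df[list(StressSeries.COLUMNS)].to_numpy(),
                        volume=volume, temperature=temperature)


def write_stress_series(stress: StressSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time": stress.times})
    for k, col in enumerate(StressSeries.COLUMNS):
        df[col] = stress.components[:, k]
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read amino-acid sequences keyed by record id."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
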