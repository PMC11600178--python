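"""Mean-square displacement of probe centers of mass.

The estimator is the standard time-origin average

    MSD(m·dt) = < |r(n+m) − r(n)|² >_n ,

computed with the FFT decomposition (Kubo/“order-N” algorithm) and
averaged with equal weight over probes.  A restrained-probe mode tracks
only the unrestrained axes (``dims``) and records ``d = 2`` so every
downstream frequency-domain formula uses the right dimensionality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, GridError, SelectionError, WindowError
from .io import Trajectory

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class MSDCurve:
    """MSD on a lag grid.

    lags : ns, strictly positive and increasing (lag 0 is implicit)
    msd : Å²
    d : number of tracked dimensions (2 or 3)
    n_probes : probes averaged
    C : ballistic coefficient Å²/ns² (optional, see :func:`fit_limits`)
    D : diffusion coefficient Å²/ns (optional)
    tau_v : probe velocity-relaxation time ns (optional, see
        :func:`fit_ballistic_inertial`)
    """

    lags: np.ndarray
    msd: np.ndarray
    d: int
    n_probes: int = 1
    C: float | None = None
    D: float | None = None
    tau_v: float | None = None
    crowding_warning: bool = field(default=False)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.msd = np.asarray(self.msd, float)
        if self.d not in (2, 3):
            raise DimensionError("d must be 2 or 3")
        if self.n_probes < 1:
            raise SelectionError("n_probes must be >= 1")
        if np.any(self.msd < -1e-12):
            raise ValueError("MSD must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        """Write ``lag_ns\\tmsd_A2`` plus a JSON sidecar of metadata."""
        import pandas as pd
        pd.DataFrame({"lag_ns": self.lags, "msd_A2": self.msd}).to_csv(
            path, sep="\t", index=False)
        side = {"d": self.d, "n_probes": self.n_probes,
                "C": self.C, "D": self.D}
        Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def msd_fft(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of one walker, all integer lags 0..N−1.

    x : (N, k) positions (k = tracked axes).  Uses the FFT split
    MSD(m) = S1(m) − 2·S2(m) with S2 the positional autocorrelation.
    """
    x = np.asarray(x, float)
    N = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * N)))
    sq = np.sum(x * x, axis=1)
    # S2 via FFT per axis
    s2 = np.zeros(N)
    for ax in range(x.shape[1]):
        f = np.fft.rfft(x[:, ax], nfft)
        acf = np.fft.irfft(f * np.conj(f), nfft)[:N]
        s2 += acf
    # S1 recursion
    sumsq = 2.0 * np.sum(sq)
    s1 = np.empty(N)
    s1[0] = sumsq
    for m in range(1, N):
        sumsq -= sq[m - 1] + sq[N - m]
        s1[m] = sumsq
    counts = N - np.arange(N)
    return s1 / counts - 2.0 * s2 / counts


def msd_brute(x: np.ndarray) -> np.ndarray:
    """O(N²) reference estimator, identical contract to :func:`msd_fft`."""
    x = np.asarray(x, float)
    N = x.shape[0]
    out = np.zeros(N)
    for m in range(1, N):
        d = x[m:] - x[:-m]
        out[m] = np.mean(np.sum(d * d, axis=1))
    return out


def _lag_indices(N: int, dt: float, lag_grid, points_per_decade: int = 30
                 ) -> np.ndarray:
    if isinstance(lag_grid, (list, tuple, np.ndarray)):
        idx = np.round(np.asarray(lag_grid, float) / dt).astype(int)
        if np.any(idx < 1) or np.any(idx >= N):
            raise GridError("explicit lags outside trajectory range")
        return np.unique(idx)
    if lag_grid == "linear":
        return np.arange(1, N)
    if lag_grid == "log":
        raw = np.unique(np.round(np.logspace(
            0, np.log10(N - 1),
            max(2, int(points_per_decade * np.log10(max(N - 1, 2))))
        )).astype(int))
        return raw[(raw >= 1) & (raw < N)]
    raise GridError(f"unknown lag grid {lag_grid!r}")


def compute_msd(traj: Trajectory, probe_selection=None,
                dims: str = "xyz", lag_grid="log",
                points_per_decade: int = 30,
                max_lag_fraction: float = 0.1) -> MSDCurve:
    """Multi-probe, all-origin MSD of the probe centers of mass.

    ``dims`` is an axis mask such as ``"xyz"`` or ``"xy"`` (restrained
    probes); positions must already be unwrapped.  Lags beyond
    ``max_lag_fraction`` of the trajectory are dropped for the ``log``
    and ``linear`` grids (too few independent origins); explicit grids
    are honoured as given.
    """
    axes = sorted({_AXIS[c] for c in dims})
    if len(axes) < 2:
        raise DimensionError("need at least two tracked axes")
    if traj.n_frames < 2:
        raise GridError("need at least two frames")
    centers = traj.probe_centers()  # (nf, np, 3)
    labels = list(traj.probe_labels())
    if probe_selection is not None:
        missing = set(probe_selection) - set(labels)
        if missing:
            raise SelectionError(f"unknown probe ids {sorted(missing)}")
        cols = [labels.index(p) for p in probe_selection]
        centers = centers[:, cols, :]
    n_probes = centers.shape[1]
    dt = traj.dt
    idx = _lag_indices(traj.n_frames, dt, lag_grid, points_per_decade)
    if isinstance(lag_grid, str):
        cap = max(2, int(max_lag_fraction * (traj.n_frames - 1)))
        idx = idx[idx <= cap]
    acc = np.zeros(traj.n_frames)
    for p in range(n_probes):
        acc += msd_fft(centers[:, p, :][:, axes])
    acc /= n_probes
    return MSDCurve(lags=idx * dt, msd=np.maximum(acc[idx], 0.0),
                    d=len(axes), n_probes=n_probes)


def average_probes(curves: list[MSDCurve],
                   volume_fraction: float | None = None) -> MSDCurve:
    """Pointwise mean of per-probe curves on identical grids.

    Sets a crowding flag (and emits a warning) above a probe volume
    fraction of 0.1, beyond which probe–probe interactions bias the
    measured viscosity.
    """
    ref = curves[0]
    for c in curves[1:]:
        if c.d != ref.d or len(c.lags) != len(ref.lags) or \
                not np.allclose(c.lags, ref.lags, rtol=1e-12):
            raise GridError("curves must share lag grid and d")
    flag = False
    if volume_fraction is not None and volume_fraction > 0.1:
        flag = True
        warnings.warn("probe volume fraction above 0.1: probe-probe "
                      "interactions may bias the measurement", stacklevel=2)
    return MSDCurve(lags=ref.lags.copy(),
                    msd=np.mean([c.msd for c in curves], axis=0),
                    d=ref.d, n_probes=sum(c.n_probes for c in curves),
                    crowding_warning=flag)


def fit_limits(curve: MSDCurve, ballistic_window: tuple[float, float],
               diffusive_window: tuple[float, float],
               ballistic_correction: bool = False) -> tuple[float, float]:
    """Fit the two asymptotes of the MSD.

    C is the least-squares slope of MSD against t² in the ballistic
    window (MSD = Ct²); D is the slope of MSD against t in the diffusive
    window divided by 2d (MSD = 2d·D·t).  Both windows need ≥3 points.
    With ``ballistic_correction`` the ballistic fit includes a cubic
    term, MSD = Ct² + Bt³, which removes the O(t/τ_v) friction bias of
    an inertial probe when the window is not asymptotically short.
    The fitted values are stored on the curve and returned.
    """
    out = []
    for (lo, hi), power in ((ballistic_window, 2), (diffusive_window, 1)):
        if lo <= 0 or hi <= lo:
            raise WindowError("window must satisfy 0 < lo < hi")
        m = (curve.lags >= lo) & (curve.lags <= hi)
        if m.sum() < 3:
            raise WindowError("window must contain at least 3 lags")
        t = curve.lags[m]
        if power == 2 and ballistic_correction:
            A = np.stack([t ** 2, t ** 3], axis=1)
            coef, *_ = np.linalg.lstsq(A, curve.msd[m], rcond=None)
            out.append(float(coef[0]))
        elif power == 2:
            tp = t ** 2
            # slope through the origin: MSD(0) = 0 exactly
            out.append(float(np.dot(tp, curve.msd[m]) / np.dot(tp, tp)))
        else:
            # slope with intercept: the diffusive asymptote of a
            # viscoelastic liquid is 2dD·t plus a plateau offset
            out.append(float(np.polyfit(t, curve.msd[m], 1)[0]))
    C = out[0]
    D = out[1] / (2 * curve.d)
    curve.C, curve.D = C, D
    return C, D


def fit_ballistic_inertial(curve: MSDCurve,
                           max_lag: float | None = None
                           ) -> tuple[float, float]:
    """Fit the inertial short-time form MSD = 2Cτ_v²(x − 1 + e^{−x}),
    x = t/τ_v, over the earliest lags (default: the first 1.5 decades).

    Returns (C, τ_v) and stores them on the curve.  This removes the
    O(t/τ_v) friction bias that a plain MSD-vs-t² fit suffers when the
    sampled lags are not asymptotically short.
    """
    from scipy.optimize import curve_fit

    if max_lag is None:
        max_lag = curve.lags[0] * 12.0
    m = curve.lags <= max_lag
    if m.sum() < 4:
        raise WindowError("too few lags for the inertial ballistic fit")

    def form(t, C, tv):
        x = t / tv
        return 2.0 * C * tv ** 2 * (x - 1.0 + np.exp(-x))

    C0 = curve.msd[0] / curve.lags[0] ** 2
    popt, _ = curve_fit(form, curve.lags[m], curve.msd[m],
                        p0=(C0, curve.lags[0] * 5.0),
                        bounds=([0.0, curve.lags[0] / 30.0],
                                [np.inf, curve.lags[-1]]), maxfev=20000)
    curve.C, curve.tau_v = float(popt[0]), float(popt[1])
    return float(popt[0]), float(popt[1])
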