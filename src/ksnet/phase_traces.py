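"""Point traces and three-phase changepoint segmentation.

At a fixed interior grid position the local balance of reaction,
diffusion and chemotaxis can be followed through time via the series
``u``, ``lap(u)``, ``grad u . grad v``, ``v`` and ``lap(v)``.  The
chemoattractant trace shows three successive slopes (very fast / fast /
slow); :func:`segment_phases` operationalizes that visual observation as
a continuous two-breakpoint piecewise-linear least-squares fit, found by
exhaustive search over the sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_ops import grad_dot, laplacian
from .pde_sim import Trajectory

__all__ = ["PointTrace", "PhaseSegmentation", "extract_trace", "segment_phases"]

#: slopes closer than this (relative) across all segments flag a degenerate fit
DEGENERATE_SLOPE_RTOL = 1e-8


@dataclass
class PointTrace:
    """Time series of local field quantities at one grid position."""

    position: tuple
    times: np.ndarray
    u: np.ndarray
    lap_u: np.ndarray
    grad_uv: np.ndarray
    v: np.ndarray
    lap_v: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("u", "lap_u", "grad_uv", "v", "lap_v"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length != times length")


@dataclass
class PhaseSegmentation:
    """Two breakpoints and per-phase slopes of a piecewise-linear fit."""

    t1: float
    t2: float
    slopes: tuple
    sse: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError("breakpoints must satisfy t1 < t2")


def extract_trace(traj: Trajectory, pos: tuple) -> PointTrace:
    """Evaluate u, lap(u), grad u . grad v, v, lap(v) at ``pos`` per snapshot.

    ``pos`` is ``(i, j) = (row, col)`` and must be interior (boundary
    stencils have mirrored semantics and are rejected).
    """
    i, j = pos
    ny, nx = traj.u_snapshots.shape[1:]
    if not (1 <= i <= ny - 2 and 1 <= j <= nx - 2):
        raise ValueError(f"position {pos} not interior to {ny}x{nx} grid")
    h = traj.config.params.h
    n = len(traj.times)
    series = {k: np.empty(n) for k in ("u", "lap_u", "grad_uv", "v", "lap_v")}
    for k in range(n):
        u, v = traj.u_snapshots[k], traj.v_snapshots[k]
        series["u"][k] = u[i, j]
        series["v"][k] = v[i, j]
        series["lap_u"][k] = laplacian(u, h)[i, j]
        series["lap_v"][k] = laplacian(v, h)[i, j]
        series["grad_uv"][k] = grad_dot(u, v, h)[i, j]
    return PointTrace(position=(i, j), times=np.asarray(traj.times, dtype=float),
                      **series)


def segment_phases(trace: PointTrace, on: str = "v") -> PhaseSegmentation:
    """Best continuous 3-segment piecewise-linear fit to one trace series.

    Exhaustive search over all breakpoint pairs on the sampling grid
    (each segment keeps at least two samples), solving the 4-parameter
    least-squares problem for every pair via precomputed normal
    equations.  Slopes are returned per segment in time order.
    """
    if on not in ("u", "v"):
        raise ValueError("segmentation supports on='u' or 'v'")
    t = trace.times
    y = getattr(trace, on)
    n = len(t)
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")

    # candidate breakpoints at interior sample times, >=2 samples/segment
    cand = np.arange(2, n - 2)
    # hinge columns r_k(t) = max(t - t_k, 0)
    R = np.maximum(t[None, :] - t[cand, None], 0.0)   # (m, n)
    ones = np.ones(n)

    # inner products reused across all pairs
    s_11, s_1t, s_tt = n, t.sum(), (t * t).sum()
    s_1y, s_ty, s_yy = y.sum(), (t * y).sum(), (y * y).sum()
    r_1 = R.sum(axis=1)
    r_t = R @ t
    r_y = R @ y
    RR = R @ R.T

    ii, jj = np.triu_indices(len(cand), k=2)  # breakpoints two samples apart
    m = len(ii)
    G = np.empty((m, 4, 4))
    G[:, 0, 0] = s_11
    G[:, 0, 1] = G[:, 1, 0] = s_1t
    G[:, 1, 1] = s_tt
    G[:, 0, 2] = G[:, 2, 0] = r_1[ii]
    G[:, 0, 3] = G[:, 3, 0] = r_1[jj]
    G[:, 1, 2] = G[:, 2, 1] = r_t[ii]
    G[:, 1, 3] = G[:, 3, 1] = r_t[jj]
    G[:, 2, 2] = RR[ii, ii]
    G[:, 2, 3] = G[:, 3, 2] = RR[ii, jj]
    G[:, 3, 3] = RR[jj, jj]
    rhs = np.empty((m, 4))
    rhs[:, 0] = s_1y
    rhs[:, 1] = s_ty
    rhs[:, 2] = r_y[ii]
    rhs[:, 3] = r_y[jj]

    try:
        beta = np.linalg.solve(G, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:  # collinear corner case
        beta = (np.linalg.pinv(G) @ rhs[..., None])[..., 0]
    sse = s_yy - 2.0 * np.einsum("mk,mk->m", beta, rhs) \
        + np.einsum("mk,mkl,ml->m", beta, G, beta)
    sse = np.maximum(sse, 0.0)

    best = int(np.argmin(sse))
    b = beta[best]
    slopes = (b[1], b[1] + b[2], b[1] + b[2] + b[3])
    scale = max(abs(s) for s in slopes) or 1.0
    degenerate = (max(slopes) - min(slopes)) / scale < DEGENERATE_SLOPE_RTOL
    return PhaseSegmentation(
        t1=float(t[cand[ii[best]]]),
        t2=float(t[cand[jj[best]]]),
        slopes=tuple(float(s) for s in slopes),
        sse=float(sse[best]),
        degenerate=bool(degenerate),
    )
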