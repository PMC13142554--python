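"""Chemoattractant reconstruction from consecutive cell-density frames.

Given two frames ``u(t)`` and ``u(t+dt)`` the balance

    (u_next - u_t)/dt = f(u_t) - b * div(u_t grad v) + du * lap(u_t)

is an elliptic equation for ``v``.  It is discretized in conservative
form, giving a symmetric positive semi-definite 5-point operator whose
kernel is exactly the constants whenever ``u > 0``; both the right-hand
side and the solution are therefore projected to mean zero (the gauge),
and the system is solved with restarted GMRES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import gmres

from .grid_ops import check_field, laplacian
from .kinetics import Params, reaction_f

__all__ = [
    "FramePair",
    "Reconstruction",
    "preprocess_frame",
    "assemble_rhs",
    "assemble_operator",
    "solve_v",
    "reconstruct_sequence",
]

DEFAULT_FLOOR = 1e-3
DEFAULT_TOL = 1e-8
DEFAULT_RESTART = 50
DEFAULT_MAXITER = 5000


@dataclass
class FramePair:
    """Two consecutive positive density frames and the model constants."""

    u_t: np.ndarray
    u_next: np.ndarray
    frame_dt: float = 1.0
    params: Params = field(default_factory=Params)

    def __post_init__(self) -> None:
        self.u_t = check_field(self.u_t, "u_t")
        self.u_next = check_field(self.u_next, "u_next")
        if self.u_t.shape != self.u_next.shape:
            raise ValueError(
                f"frame shapes differ: {self.u_t.shape} vs {self.u_next.shape}")
        if self.frame_dt <= 0:
            raise ValueError(f"frame_dt must be > 0, got {self.frame_dt}")
        if np.min(self.u_t) <= 0:
            raise ValueError(
                "u_t must be strictly positive (ellipticity); "
                "apply preprocess_frame with a floor first")


@dataclass
class Reconstruction:
    """A mean-zero chemoattractant field with solver metadata."""

    v: np.ndarray
    residual: float
    iterations: int
    converged: bool


def preprocess_frame(image: np.ndarray,
                     floor: float = DEFAULT_FLOOR,
                     smooth_sigma: Optional[float] = None) -> np.ndarray:
    """Min-max rescale a grayscale raster to [0, 1], smooth, floor at eps.

    Multi-channel rasters are averaged to one channel first.  Constant
    images are rejected (the rescale is degenerate).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    img = check_field(img, "image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise ValueError("constant image: min-max rescale is degenerate")
    out = (img - lo) / (hi - lo)
    if smooth_sigma:
        out = gaussian_filter(out, smooth_sigma, mode="nearest")
    return np.maximum(out, floor)


def assemble_rhs(pair: FramePair) -> np.ndarray:
    """Mean-zero source term of the elliptic solve.

    ``r = (1/b) [ (u_next - u_t)/frame_dt - f(u_t) - du * lap(u_t) ]``
    minus its mean (compatibility with the constant nullspace).
    """
    p = pair.params
    r = ((pair.u_next - pair.u_t) / pair.frame_dt
         - reaction_f(pair.u_t, p)
         - p.du * laplacian(pair.u_t, p.h)) / p.b
    return r - r.mean()


def assemble_operator(u: np.ndarray, h: float = 1.0) -> sp.csr_matrix:
    """Sparse ``-div(u grad .)`` with zero-flux faces dropped.

    Arithmetic face averaging of ``u``; the matrix is symmetric positive
    semi-definite with nullspace exactly the constants when ``u > 0``.
    """
    u = check_field(u, "u")
    if np.min(u) <= 0:
        raise ValueError("u must be strictly positive for ellipticity")
    ny, nx = u.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    inv_h2 = 1.0 / (h * h)

    rows, cols, vals = [], [], []
    for (ca, cb) in (((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
                     ((slice(None), slice(None, -1)), (slice(None), slice(1, None)))):
        a, b_ = idx[ca].ravel(), idx[cb].ravel()
        w = (0.5 * (u[ca] + u[cb])).ravel() * inv_h2
        rows += [a, b_, a, b_]
        cols += [a, b_, b_, a]
        vals += [w, w, -w, -w]
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return A.tocsr()


def solve_v(pair: FramePair,
            tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAXITER,
            restart: int = DEFAULT_RESTART,
            x0: Optional[np.ndarray] = None) -> Reconstruction:
    """Restarted-GMRES solve of the gauge-fixed elliptic system.

    The solution is defined up to an additive constant; any constant in
    the initial guess ``x0`` is removed again by the final mean-zero
    projection.
    """
    p = pair.params
    A = assemble_operator(pair.u_t, p.h)
    r = assemble_rhs(pair).ravel()
    shape = pair.u_t.shape

    r_norm = np.linalg.norm(r)
    # roundoff-level sources have no information content; the mean-zero
    # solution is zero
    if r_norm <= 1e-13 * np.sqrt(r.size) * max(1.0, float(np.max(pair.u_t))):
        return Reconstruction(np.zeros(shape), 0.0, 0, True)

    iters = 0

    def count(_):
        nonlocal iters
        iters += 1

    x, info = gmres(A, r, x0=None if x0 is None else np.ravel(x0),
                    rtol=tol, atol=0.0, restart=restart,
                    maxiter=max(1, max_iter // restart),
                    callback=count, callback_type="pr_norm")
    x = x - x.mean()  # gauge: mean-zero representative
    rel_res = np.linalg.norm(A @ x - r) / r_norm
    converged = (info == 0) and (rel_res <= max(tol * 10, 1e-15))
    return Reconstruction(x.reshape(shape), float(rel_res), iters, bool(converged))


def reconstruct_sequence(frames: Sequence[np.ndarray],
                         params: Optional[Params] = None,
                         frame_dt: float = 1.0,
                         tol: float = DEFAULT_TOL,
                         max_iter: int = DEFAULT_MAXITER) -> list[Reconstruction]:
    """Solve each consecutive pair of a frame sequence; failures do not abort."""
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    params = params or Params()
    out = []
    for ut, un in zip(frames[:-1], frames[1:]):
        try:
            pair = FramePair(u_t=ut, u_next=un, frame_dt=frame_dt, params=params)
            out.append(solve_v(pair, tol=tol, max_iter=max_iter))
        except (ValueError, np.linalg.LinAlgError):
            out.append(Reconstruction(np.full(np.shape(ut), np.nan),
                                      np.inf, 0, False))
    return out
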