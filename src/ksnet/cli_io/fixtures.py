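"""Synthetic frame-pair generators for the inverse solver.

Real microscopy frames are not distributed with the package; these
fixtures stand in for them.  The ``gaussian-bumps`` kind builds a smooth
positive density and a known mean-zero chemoattractant field, then takes
one forward-Euler step of the density balance so the inverse solve has
an exact discrete oracle.  The ``simulated-network`` kind takes two
snapshots from a short network-regime simulation together with the
simulator's chemoattractant field.
"""

from __future__ import annotations

import numpy as np

from ..grid_ops import chemotaxis_div, laplacian
from ..inverse_chemo import FramePair
from ..kinetics import Params, reaction_f
from ..pde_sim import SimConfig, simulate

__all__ = ["make_fixture_framepair", "euler_density_step", "gaussian_bump"]


def gaussian_bump(shape: tuple, center: tuple, sigma: float,
                  amplitude: float = 1.0) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    return amplitude * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                              / (2.0 * sigma ** 2))


def euler_density_step(u: np.ndarray, v: np.ndarray, p: Params,
                       dt: float) -> np.ndarray:
    """One explicit Euler step of the density balance with frozen v.

    This is exactly the discrete model the inverse solver assumes, so a
    pair built this way has a known reconstruction.
    """
    return u + dt * (reaction_f(u, p) - p.b * chemotaxis_div(u, v, p.h)
                     + p.du * laplacian(u, p.h))


def make_fixture_framepair(kind: str = "gaussian-bumps", seed: int = 0,
                           shape: tuple = (64, 64),
                           params: Params | None = None,
                           frame_dt: float = 1e-3):
    """Build a (FramePair, ground-truth v) pair for inverse-solver tests.

    ``gaussian-bumps``: smooth positive u (0.2 + random bumps) and a
    mean-zero two-bump difference field v*, with ``u_next`` one Euler
    step ahead.  ``simulated-network``: two consecutive snapshots of a
    short gamma=0.25 run plus the simulator's v at the first snapshot
    (v is only approximately stationary there, so the recovery is
    approximate by construction).
    """
    params = params or Params()
    rng = np.random.default_rng(seed)
    ny, nx = shape

    if kind == "gaussian-bumps":
        u = np.full(shape, 0.2)
        for _ in range(3):
            c = rng.uniform(0.2, 0.8, size=2) * (ny, nx)
            u = u + gaussian_bump(shape, c, sigma=rng.uniform(5, 10),
                                  amplitude=rng.uniform(0.3, 0.6))
        c1 = rng.uniform(0.2, 0.45, size=2) * (ny, nx)
        c2 = rng.uniform(0.55, 0.8, size=2) * (ny, nx)
        v = (gaussian_bump(shape, c1, sigma=ny / 8.0)
             - gaussian_bump(shape, c2, sigma=ny / 8.0))
        v = v - v.mean()
        u_next = euler_density_step(u, v, params, frame_dt)
        pair = FramePair(u_t=u, u_next=u_next, frame_dt=frame_dt, params=params)
        return pair, v

    if kind == "simulated-network":
        t0, t1 = 3.0, 3.1
        cfg = SimConfig(params=Params(**{**params.to_dict(), "gamma": 0.25}),
                        nx=nx, ny=ny, t_end=t1, dt=0.005,
                        snapshot_times=[t0, t1], seed=seed, diag_every=100)
        traj = simulate(cfg)
        u0, u1 = traj.u_snapshots[0], traj.u_snapshots[1]
        v0 = traj.v_snapshots[0]
        floor = 1e-3
        pair = FramePair(u_t=np.maximum(u0, floor), u_next=np.maximum(u1, floor),
                         frame_dt=t1 - t0, params=cfg.params)
        return pair, v0 - v0.mean()

    raise ValueError(f"unknown fixture kind {kind!r}")
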