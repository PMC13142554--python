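"""Forward integration of the modified chemotaxis reaction-diffusion system.

The system on a zero-flux rectangular grid is

    du/dt = f(u) - b * div(u grad v) + du_ * lap(u)
    dv/dt = c*u - e*v + dv_ * lap(v)

with the bistable cubic ``f`` from :mod:`ksnet.kinetics`.  Time stepping
is classical RK4 with a fixed step; an explicit stability bound
``dt <= h^2 / (4 max(du, dv))`` is enforced (with automatic shrinking).

Depending on the unstable threshold ``gamma`` the long-time state ranges
from spatially homogeneous, through an invading front, to a stable
network-like pattern; :func:`classify_regime` assigns those labels from
the final snapshot and the recorded area-fraction history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid_ops import chemotaxis_div, laplacian
from .kinetics import Params, reaction_f

__all__ = [
    "SimConfig",
    "Trajectory",
    "BlowUpError",
    "make_initial_condition",
    "rhs",
    "simulate",
    "mean_values",
    "classify_regime",
]

# classification thresholds (declared constants; the reference figures are
# qualitative, so these are the operational definitions used throughout)
HOMOGENEOUS_TOL = 0.01     # max deviation from a rest state
LOW_CUT, HIGH_CUT = 0.3, 0.7  # histogram cuts for bimodality
BIMODAL_MIN_FRAC = 0.05    # each mode must exceed this area fraction
DOMINANT_FRAC = 0.80       # invasion leaves one phase dominating
BOUNDARY_BAND = 5          # cells counted as the boundary band
INTERIOR_MINORITY_FRAC = 0.01  # interior share below which a phase is "confined"
STATIONARY_RATE = 1e-3     # max |du/dt| proxy below which state is settled
BLOWUP_LIMIT = 1e3


class BlowUpError(RuntimeError):
    """Raised when the solution exceeds the blow-up guard."""


@dataclass
class SimConfig:
    """Configuration of one forward run."""

    params: Params = field(default_factory=Params)
    nx: int = 100
    ny: int = 100
    t_end: float = 180.0
    dt: float = 0.01
    snapshot_times: Optional[Sequence[float]] = None
    seed: int = 0
    ic_spec: str = "nine-squares"
    background: float = 0.2
    square_value: float = 0.8
    noise_amp: float = 0.2
    v_init: float = 0.5
    flux_form: str = "upwind"
    diag_every: int = 1

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        if self.diag_every < 1:
            raise ValueError("diag_every must be >= 1")
        if self.flux_form not in ("upwind", "centered"):
            raise ValueError(f"unknown flux_form {self.flux_form!r}")

    @property
    def dt_stable(self) -> float:
        """Explicit diffusion stability bound ``h^2 / (4 max(du, dv))``."""
        p = self.params
        dmax = max(p.du, p.dv)
        return np.inf if dmax == 0 else p.h * p.h / (4.0 * dmax)


@dataclass
class Trajectory:
    """Snapshots plus per-step diagnostics of one simulation."""

    config: SimConfig
    times: np.ndarray           # snapshot times actually hit
    u_snapshots: np.ndarray     # (n_snap, ny, nx)
    v_snapshots: np.ndarray
    diag_t: np.ndarray          # diagnostic sample times
    mean_u: np.ndarray          # plain cell averages
    mean_v: np.ndarray
    min_u: np.ndarray
    max_u: np.ndarray
    min_v: np.ndarray
    frac_low: np.ndarray        # area fraction with u < LOW_CUT
    frac_high: np.ndarray       # area fraction with u > HIGH_CUT
    final_label: Optional[str] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        if self.u_snapshots.shape != self.v_snapshots.shape:
            raise ValueError("u/v snapshot shapes differ")
        if len(self.times) != len(self.u_snapshots):
            raise ValueError("times/snapshots length mismatch")


def make_initial_condition(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Nine raised squares on a noisy low background; uniform chemoattractant.

    ``u0`` is ``background`` everywhere except nine squares (side
    ``nx // 10``) centred on the 3x3 lattice at fractions 1/4, 1/2, 3/4
    of each axis, which carry ``square_value``; i.i.d. Uniform[0,
    noise_amp] noise is added per cell.  ``v0`` is the constant
    ``v_init``.
    """
    nx, ny = cfg.nx, cfg.ny
    side = max(1, nx // 10)
    pitch = min(nx, ny) // 4
    if side > pitch:
        raise ValueError(
            f"square side {side} exceeds lattice pitch {pitch}; squares would overlap")
    u0 = np.full((ny, nx), cfg.background)
    if cfg.ic_spec == "nine-squares":
        half = side // 2
        cxs = [round(nx * f) for f in (0.25, 0.5, 0.75)]
        cys = [round(ny * f) for f in (0.25, 0.5, 0.75)]
        for cy in cys:
            for cx in cxs:
                u0[cy - half:cy - half + side, cx - half:cx - half + side] = cfg.square_value
    elif cfg.ic_spec == "uniform":
        pass
    else:
        raise ValueError(f"unknown ic_spec {cfg.ic_spec!r}")
    rng = np.random.default_rng(cfg.seed)
    u0 = u0 + rng.uniform(0.0, cfg.noise_amp, size=(ny, nx))
    v0 = np.full((ny, nx), cfg.v_init)
    return u0, v0


def rhs(u: np.ndarray, v: np.ndarray, p: Params,
        flux_form: str = "upwind") -> tuple[np.ndarray, np.ndarray]:
    """Semi-discrete right-hand side of the coupled system.

    The simulator defaults to the upwind transport flux, which keeps the
    density nonnegative across sharp chemotactic fronts; the centered
    (arithmetic-mean) flux is available for smooth-field studies.
    """
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite values in input fields")
    return _rhs(u, v, p, flux_form)


def _rhs(u, v, p, flux_form="upwind"):
    # validation-free inner kernel used by the stepper
    dudt = (reaction_f(u, p) - p.b * chemotaxis_div(u, v, p.h, flux_form)
            + p.du * laplacian(u, p.h))
    dvdt = p.c * u - p.e * v + p.dv * laplacian(v, p.h)
    return dudt, dvdt


def simulate(cfg: SimConfig,
             u0: Optional[np.ndarray] = None,
             v0: Optional[np.ndarray] = None) -> Trajectory:
    """RK4 time stepping from the configured initial condition.

    Snapshots are recorded at the requested times (rounded to the step
    grid); diagnostics every ``diag_every`` steps.  Exceeding
    ``BLOWUP_LIMIT`` in ``|u|`` aborts with :class:`BlowUpError`.
    """
    p = cfg.params
    dt = cfg.dt
    if dt > cfg.dt_stable:
        warnings.warn(
            f"dt={dt} exceeds explicit stability bound {cfg.dt_stable:.4g}; shrinking",
            stacklevel=2)
        n_sub = int(np.ceil(dt / cfg.dt_stable))
        dt = dt / n_sub
    if u0 is None or v0 is None:
        u0, v0 = make_initial_condition(cfg)
    u = np.array(u0, dtype=float)
    v = np.array(v0, dtype=float)

    n_steps = int(round(cfg.t_end / dt))
    snap_times = (np.asarray(cfg.snapshot_times, dtype=float)
                  if cfg.snapshot_times is not None
                  else np.array([0.0, cfg.t_end]))
    snap_steps = np.unique(np.clip(np.round(snap_times / dt).astype(int), 0, n_steps))
    snap_set = set(snap_steps.tolist())

    us, vs, ts = [], [], []
    diag = {k: [] for k in ("t", "mu", "mv", "mnu", "mxu", "mnv", "fl", "fh")}

    def record_diag(step: int) -> None:
        diag["t"].append(step * dt)
        diag["mu"].append(u.mean())
        diag["mv"].append(v.mean())
        diag["mnu"].append(u.min())
        diag["mxu"].append(u.max())
        diag["mnv"].append(v.min())
        diag["fl"].append(np.count_nonzero(u < LOW_CUT) / u.size)
        diag["fh"].append(np.count_nonzero(u > HIGH_CUT) / u.size)

    half, sixth = 0.5 * dt, dt / 6.0
    for step in range(n_steps + 1):
        if step % cfg.diag_every == 0 or step == n_steps:
            record_diag(step)
            if abs(diag["mxu"][-1]) > BLOWUP_LIMIT or not np.isfinite(diag["mxu"][-1]):
                raise BlowUpError(
                    f"|u| exceeded {BLOWUP_LIMIT} at t={step * dt:.3f} "
                    f"(max_u={diag['mxu'][-1]:.3g})")
        if step in snap_set:
            ts.append(step * dt)
            us.append(u.copy())
            vs.append(v.copy())
        if step == n_steps:
            break
        ff = cfg.flux_form
        ku1, kv1 = _rhs(u, v, p, ff)
        ku2, kv2 = _rhs(u + half * ku1, v + half * kv1, p, ff)
        ku3, kv3 = _rhs(u + half * ku2, v + half * kv2, p, ff)
        ku4, kv4 = _rhs(u + dt * ku3, v + dt * kv3, p, ff)
        u = u + sixth * (ku1 + 2.0 * ku2 + 2.0 * ku3 + ku4)
        v = v + sixth * (kv1 + 2.0 * kv2 + 2.0 * kv3 + kv4)

    traj = Trajectory(
        config=cfg,
        times=np.asarray(ts),
        u_snapshots=np.asarray(us),
        v_snapshots=np.asarray(vs),
        diag_t=np.asarray(diag["t"]),
        mean_u=np.asarray(diag["mu"]),
        mean_v=np.asarray(diag["mv"]),
        min_u=np.asarray(diag["mnu"]),
        max_u=np.asarray(diag["mxu"]),
        min_v=np.asarray(diag["mnv"]),
        frac_low=np.asarray(diag["fl"]),
        frac_high=np.asarray(diag["fh"]),
    )
    return traj


def mean_values(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Domain integrals of u and v and the residual of their balance law.

    Returns ``(ubar, vbar, residual)`` sampled at the diagnostic times;
    ``residual = |d vbar/dt - (c ubar - e vbar)|`` with the time
    derivative taken by central differences (one-sided at the ends).
    """
    if len(traj.diag_t) < 3:
        raise ValueError("need at least 3 diagnostic samples")
    p = traj.config.params
    cell = p.h * p.h
    area = cell * traj.config.nx * traj.config.ny
    ubar = traj.mean_u * area
    vbar = traj.mean_v * area
    dvbar = np.gradient(vbar, traj.diag_t)
    residual = np.abs(dvbar - (p.c * ubar - p.e * vbar))
    return ubar, vbar, residual


def classify_regime(traj: Trajectory) -> str:
    """Label the long-time state of a trajectory.

    Labels: ``homogeneous-high``, ``homogeneous-low``,
    ``traveling-invasion``, ``network``, ``degenerate-network``,
    ``transient``.  Thresholds are the module constants.  An invasion is
    a run whose minority phase is confined to the boundary band after
    the opposite phase first dominated and then collapsed through one
    half of the domain; a network keeps both phases above the bimodal
    cut with the minority threading the interior; a fragmented high
    phase (several disconnected pieces) is a degenerate network.
    """
    u_f = traj.u_snapshots[-1]
    if np.max(np.abs(u_f - 1.0)) < HOMOGENEOUS_TOL:
        label = "homogeneous-high"
    elif np.max(np.abs(u_f)) < HOMOGENEOUS_TOL:
        label = "homogeneous-low"
    else:
        # rate proxy: change in mean u per unit time over the last window
        t, mu = traj.diag_t, traj.mean_u
        if len(t) >= 2 and t[-1] > t[-2]:
            rate = abs(mu[-1] - mu[-2]) / (t[-1] - t[-2])
        else:
            rate = np.inf
        low, high = u_f < LOW_CUT, u_f > HIGH_CUT
        fl, fh = low.mean(), high.mean()
        band = BOUNDARY_BAND
        interior = np.zeros_like(low)
        interior[band:-band, band:-band] = True
        minority = high if fh < fl else low
        minority_interior = (minority & interior).sum() / max(interior.sum(), 1)
        bimodal = fl > BIMODAL_MIN_FRAC and fh > BIMODAL_MIN_FRAC
        if (max(fl, fh) > DOMINANT_FRAC
                and minority_interior < INTERIOR_MINORITY_FRAC
                and _invaded(traj)):
            label = "traveling-invasion"
        elif rate > STATIONARY_RATE:
            label = "transient"
        elif bimodal:
            label = "degenerate-network" if _n_components(high) > 1 else "network"
        else:
            label = "transient"
    traj.final_label = label
    return label


def _n_components(mask: np.ndarray) -> int:
    from scipy.ndimage import label as cc_label
    return int(cc_label(mask)[1])


def _invaded(traj: Trajectory) -> bool:
    # did one phase first dominate, then collapse through half the domain?
    for f in (traj.frac_high, traj.frac_low):
        if len(f) < 3:
            continue
        peak = int(np.argmax(f))
        if f[peak] > 0.5 and f[-1] < 0.5 and f[peak] - f[-1] > 0.3:
            return True
    return False
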