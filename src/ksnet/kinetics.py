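"""Bistable reaction kinetics and the space-free two-variable ODE.

The reaction term is the cubic ``f(u) = a*u*(1-u)*(u-gamma)`` with stable
rest states at ``u=0`` and ``u=1`` and an unstable threshold at
``u=gamma``.  Coupled with a linear production/decay equation for the
chemoattractant this gives the space-free system

    du/dt = f(u)
    dv/dt = c*u - e*v

whose three equilibria, their stability, and their basins of attraction
are computed here in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "Params",
    "Equilibrium2",
    "reaction_f",
    "reaction_f_prime",
    "ode2_rhs",
    "ode2_equilibria",
    "ode2_classify_basin",
    "ode2_integrate",
]

#: eigenvalues with |Re| below this are treated as marginal
HYPERBOLIC_TOL = 1e-10


@dataclass(frozen=True)
class Params:
    """Scalar model constants shared by every module.

    Attributes
    ----------
    a : reaction amplitude (> 0)
    b : chemotactic sensitivity (> 0)
    c : chemoattractant production rate (> 0)
    e : chemoattractant decay rate (> 0)
    du : cell diffusivity (>= 0)
    dv : chemoattractant diffusivity (>= 0)
    gamma : unstable reaction root, strictly inside (0, 1)
    h : grid spacing (> 0)
    """

    a: float = 7.0
    b: float = 10.0
    c: float = 3.0
    e: float = 2.0
    du: float = 1.0
    dv: float = 10.0
    gamma: float = 0.25
    h: float = 1.0

    def __post_init__(self) -> None:
        errors = []
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0, got {getattr(self, name)}")
        if self.e <= 0:
            errors.append(f"e must be > 0 (v-equilibria are c*u/e), got {self.e}")
        for name in ("du", "dv"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 < self.gamma < 1.0:
            errors.append(f"gamma must lie in (0, 1), got {self.gamma}")
        if self.h <= 0:
            errors.append(f"h must be > 0, got {self.h}")
        if errors:
            raise ValueError("invalid Params: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        allowed = {"a", "b", "c", "e", "du", "dv", "gamma", "h"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown Params keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class Equilibrium2:
    """A stationary point of the space-free system with its linearization."""

    u: float
    v: float
    eigenvalues: tuple
    label: str

    @property
    def state(self) -> np.ndarray:
        return np.array([self.u, self.v])


def reaction_f(u, p: Params):
    """Cubic reaction rate ``a*u*(1-u)*(u-gamma)``, elementwise."""
    u = np.asarray(u, dtype=float)
    out = p.a * u * (1.0 - u) * (u - p.gamma)
    return out if out.ndim else float(out)


def reaction_f_prime(u, p: Params):
    """Exact derivative of the cubic: ``a*(-3u^2 + 2(1+gamma)u - gamma)``."""
    u = np.asarray(u, dtype=float)
    out = p.a * (-3.0 * u * u + 2.0 * (1.0 + p.gamma) * u - p.gamma)
    return out if out.ndim else float(out)


def ode2_rhs(state, p: Params) -> np.ndarray:
    """Right-hand side ``(f(u), c*u - e*v)`` of the space-free system."""
    u, v = state
    return np.array([reaction_f(u, p), p.c * u - p.e * v])


def _label_from_eigs(eigs: Sequence[float]) -> str:
    if any(abs(ev) < HYPERBOLIC_TOL for ev in eigs):
        return "non-hyperbolic"
    n_pos = sum(ev > 0 for ev in eigs)
    if n_pos == 0:
        return "stable node"
    if n_pos == len(tuple(eigs)):
        return "unstable node"
    return "saddle"


def ode2_equilibria(p: Params) -> list[Equilibrium2]:
    """The three equilibria ``(0,0)``, ``(gamma, c*gamma/e)``, ``(1, c/e)``.

    The Jacobian is lower triangular, so the eigenvalues at ``(u*, v*)``
    are exactly ``{f'(u*), -e}``.
    """
    out = []
    for u_star in (0.0, p.gamma, 1.0):
        v_star = p.c * u_star / p.e
        eigs = (reaction_f_prime(u_star, p), -p.e)
        out.append(Equilibrium2(u_star, v_star, eigs, _label_from_eigs(eigs)))
    return out


def ode2_classify_basin(u0: float, p: Params) -> Equilibrium2:
    """Predict the limit equilibrium of a trajectory started at ``u = u0``.

    ``u0 < gamma`` falls to the origin, ``u0 > gamma`` rises to the high
    state, and ``u0 == gamma`` sits on the stable manifold of the saddle.
    """
    if u0 < 0:
        raise ValueError(f"u0 must be >= 0, got {u0}")
    low, saddle, high = ode2_equilibria(p)
    if u0 == p.gamma:
        return saddle
    return low if u0 < p.gamma else high


def ode2_integrate(u0: float, v0: float, p: Params, t_end: float,
                   dt: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Classical RK4 integration of the space-free system.

    Returns ``(times, states)`` with ``states`` of shape ``(n, 2)``.
    """
    n = max(1, int(round(t_end / dt)))
    times = np.linspace(0.0, n * dt, n + 1)
    states = np.empty((n + 1, 2))
    y = np.array([u0, v0], dtype=float)
    states[0] = y
    for i in range(n):
        k1 = ode2_rhs(y, p)
        k2 = ode2_rhs(y + 0.5 * dt * k1, p)
        k3 = ode2_rhs(y + 0.5 * dt * k2, p)
        k4 = ode2_rhs(y + dt * k3, p)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        states[i + 1] = y
    return times, states
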