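"""Reduced two-compartment coupled model and its equilibrium structure.

Two (cell, chemoattractant) pairs exchange by discrete diffusion and a
discrete chemotaxis term:

    u1' = f(u1) - b*u1*(v2 - v1) + du*(u2 - u1)
    v1' = c*u1 - e*v1 + dv*(v2 - v1)
    u2' = f(u2) - b*u2*(v1 - v2) + du*(u1 - u2)
    v2' = c*u2 - e*v2 + dv*(v1 - v2)

Stationary states eliminate v through the linear response
``v1 = alpha1*u1 + alpha2*u2`` (and symmetrically), reducing the search
to the scalar fixed-point equation ``u1 = phi(phi(u1))`` with

    phi(u) = u + f(u) / (b*u*(alpha1 - alpha2) - du).

The module enumerates equilibria from that equation (cross-validated by
full 4D Newton), classifies stability from the analytic Jacobian, scans
the chemotactic sensitivity ``b``, and shoots heteroclinic orbits off
the symmetric saddle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .kinetics import Params, reaction_f, reaction_f_prime

__all__ = [
    "AlphaPair",
    "Equilibrium4",
    "ode4_rhs",
    "ode4_jacobian",
    "alphas",
    "phi",
    "find_equilibria",
    "newton_equilibria",
    "classify_stability",
    "bifurcation_scan",
    "heteroclinic_orbits",
    "swap",
]

log = logging.getLogger(__name__)

EIG_TOL = 1e-10        # stable/unstable/marginal separation
RESIDUAL_TOL = 1e-10   # accepted equilibrium residual
DEDUP_TOL = 1e-8
SINGULAR_TOL = 1e-9    # |denominator| below this marks phi singular


@dataclass(frozen=True)
class AlphaPair:
    """Linear response coefficients of stationary v to (own, other) u."""

    alpha1: float
    alpha2: float


@dataclass
class Equilibrium4:
    """A stationary state of the 4D system with spectrum and label."""

    state: np.ndarray            # (u1, v1, u2, v2)
    eigenvalues: Optional[np.ndarray] = None
    label: str = "unclassified"
    residual: float = np.nan

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.state, swap(self.state), atol=1e-9))


def swap(s: np.ndarray) -> np.ndarray:
    """The conjugacy exchanging the two compartments."""
    s = np.asarray(s, dtype=float)
    return s[..., [2, 3, 0, 1]]


def ode4_rhs(s, p: Params, b: Optional[float] = None) -> np.ndarray:
    """Vector field; ``b`` overrides ``p.b`` when given (scan parameter)."""
    b = p.b if b is None else b
    s = np.asarray(s, dtype=float)
    u1, v1, u2, v2 = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    out = np.empty_like(s)
    out[..., 0] = reaction_f(u1, p) - b * u1 * (v2 - v1) + p.du * (u2 - u1)
    out[..., 1] = p.c * u1 - p.e * v1 + p.dv * (v2 - v1)
    out[..., 2] = reaction_f(u2, p) - b * u2 * (v1 - v2) + p.du * (u1 - u2)
    out[..., 3] = p.c * u2 - p.e * v2 + p.dv * (v1 - v2)
    return out


def ode4_jacobian(s, p: Params, b: Optional[float] = None) -> np.ndarray:
    """Analytic 4x4 Jacobian (batched over leading axes of ``s``)."""
    b = p.b if b is None else b
    s = np.asarray(s, dtype=float)
    u1, v1, u2, v2 = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    J = np.zeros(s.shape[:-1] + (4, 4))
    J[..., 0, 0] = reaction_f_prime(u1, p) - b * (v2 - v1) - p.du
    J[..., 0, 1] = b * u1
    J[..., 0, 2] = p.du
    J[..., 0, 3] = -b * u1
    J[..., 1, 0] = p.c
    J[..., 1, 1] = -p.e - p.dv
    J[..., 1, 3] = p.dv
    J[..., 2, 0] = p.du
    J[..., 2, 1] = -b * u2
    J[..., 2, 2] = reaction_f_prime(u2, p) - b * (v1 - v2) - p.du
    J[..., 2, 3] = b * u2
    J[..., 3, 1] = p.dv
    J[..., 3, 2] = p.c
    J[..., 3, 3] = -p.e - p.dv
    return J


def alphas(p: Params) -> AlphaPair:
    """Unique solution of the stationary linear v-system.

    Solving ``(e+dv) v1 - dv v2 = c u1`` and ``-dv v1 + (e+dv) v2 = c u2``
    for ``v1 = alpha1 u1 + alpha2 u2`` gives

        alpha1 = c (e+dv) / ((e+dv)^2 - dv^2)
        alpha2 = c dv / ((e+dv)^2 - dv^2)
    """
    if p.e <= 0:
        raise ValueError("e must be > 0 (singular v-system otherwise)")
    det = (p.e + p.dv) ** 2 - p.dv ** 2
    return AlphaPair(alpha1=p.c * (p.e + p.dv) / det, alpha2=p.c * p.dv / det)


def phi(u1, p: Params, ap: Optional[AlphaPair] = None,
        b: Optional[float] = None):
    """Stationary map ``u2 = phi(u1)`` after v-elimination.

    ``phi(u) = u + f(u) / (b*u*(alpha1-alpha2) - du)``; a near-zero
    denominator raises (scalar input) or yields NaN (array input).
    """
    b = p.b if b is None else b
    ap = ap or alphas(p)
    u = np.asarray(u1, dtype=float)
    denom = b * u * (ap.alpha1 - ap.alpha2) - p.du
    scalar = u.ndim == 0
    if scalar:
        if abs(denom) < SINGULAR_TOL:
            raise ZeroDivisionError(
                f"phi singular at u1={float(u)} (denominator {float(denom):.3g})")
        return float(u + reaction_f(u, p) / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = u + reaction_f(u, p) / denom
    out[np.abs(denom) < SINGULAR_TOL] = np.nan
    return out


def _stationary_v(u1, u2, ap: AlphaPair) -> tuple:
    return ap.alpha1 * u1 + ap.alpha2 * u2, ap.alpha1 * u2 + ap.alpha2 * u1


def find_equilibria(p: Params, b: Optional[float] = None,
                    scan_max: float = 2.0, n_grid: int = 10_000) -> list[Equilibrium4]:
    """Enumerate equilibria via the scalar fixed-point equation.

    Dense scan of ``u1 - phi(phi(u1))`` for sign changes over
    ``[0, scan_max]`` (singular abscissae excluded), each candidate
    polished by full 4D Newton on the vector field, de-duplicated, and
    accepted only below the residual tolerance.
    """
    b = p.b if b is None else b
    if scan_max < 1.5:
        raise ValueError("scan_max must cover the upper branch (>= 1.5)")
    ap = alphas(p)
    grid = np.linspace(0.0, scan_max, n_grid)
    g = grid - phi(phi(grid, p, ap, b), p, ap, b)

    candidates = [0.0, p.gamma, 1.0]  # always-present symmetric roots
    def g_of(u):  # NaN-safe scalar evaluation (poles yield NaN, not raise)
        return float((u - phi(phi(np.atleast_1d(u), p, ap, b), p, ap, b))[0])

    finite = np.isfinite(g)
    for k in range(len(grid) - 1):
        if finite[k] and finite[k + 1] and g[k] * g[k + 1] < 0:
            try:
                u_root = float(brentq(g_of, grid[k], grid[k + 1], xtol=1e-14))
            except ValueError:  # bracket straddles a pole of phi
                t = g[k] / (g[k] - g[k + 1])
                u_root = float(grid[k] + t * (grid[k + 1] - grid[k]))
            candidates.append(u_root)

    found: list[Equilibrium4] = []
    for u1 in candidates:
        try:
            u2 = phi(u1, p, ap, b)
        except ZeroDivisionError:
            continue
        v1, v2 = _stationary_v(u1, u2, ap)
        eq = _polish(np.array([u1, v1, u2, v2]), p, b)
        if eq is not None:
            _add_unique(found, eq)
    # symmetry closure: the swap image of every equilibrium is one too
    for eq in list(found):
        partner = _polish(swap(eq.state), p, b)
        if partner is not None:
            _add_unique(found, partner)
    found.sort(key=lambda e: (round(e.state[0], 9), round(e.state[2], 9)))
    return found


def _polish(s0: np.ndarray, p: Params, b: float) -> Optional[Equilibrium4]:
    sol = root(lambda s: ode4_rhs(s, p, b), s0,
               jac=lambda s: ode4_jacobian(s, p, b), method="hybr",
               options={"xtol": 1e-13})
    res = float(np.max(np.abs(ode4_rhs(sol.x, p, b))))
    if not sol.success or res > RESIDUAL_TOL:
        log.debug("dropping candidate %s (residual %.3g)", s0, res)
        return None
    if np.max(np.abs(sol.x - s0)) > 0.05 * (1 + np.max(np.abs(s0))):
        # Newton wandered to a different root; not the seeded candidate
        log.debug("candidate %s drifted to %s", s0, sol.x)
    return Equilibrium4(state=sol.x, residual=res)


def _add_unique(found: list, eq: Equilibrium4) -> None:
    for other in found:
        if np.max(np.abs(other.state - eq.state)) < DEDUP_TOL:
            return
    found.append(eq)


def newton_equilibria(p: Params, b: Optional[float] = None,
                      n_per_axis: int = 20,
                      lo: float = -0.1, hi: float = 1.6,
                      max_iter: int = 60) -> list[Equilibrium4]:
    """Brute-force equilibrium search: batched Newton from a 4D lattice.

    Independent oracle for :func:`find_equilibria` — it never touches the
    phi machinery.  Damped Newton iterations run vectorized over all
    ``n_per_axis**4`` lattice seeds; converged points are de-duplicated.
    """
    b = p.b if b is None else b
    axis = np.linspace(lo, hi, n_per_axis)
    S = np.stack(np.meshgrid(axis, axis, axis, axis, indexing="ij"),
                 axis=-1).reshape(-1, 4)
    alive = np.ones(len(S), dtype=bool)
    for _ in range(max_iter):
        F = ode4_rhs(S[alive], p, b)
        J = ode4_jacobian(S[alive], p, b)
        try:
            step = np.linalg.solve(J, F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # batched pseudo-inverse tolerates exactly singular Jacobians
            step = (np.linalg.pinv(J) @ F[..., None])[..., 0]
        step = np.clip(step, -0.5, 0.5)  # damping keeps seeds in basin scale
        S[alive] -= step
        diverged = ~np.isfinite(S).all(axis=1) | (np.abs(S).max(axis=1) > 50)
        alive &= ~diverged
        S[~alive] = np.nan
    res = np.full(len(S), np.inf)
    ok = np.isfinite(S).all(axis=1)
    res[ok] = np.abs(ode4_rhs(S[ok], p, b)).max(axis=1)
    found: list[Equilibrium4] = []
    for s, r in zip(S[res < RESIDUAL_TOL], res[res < RESIDUAL_TOL]):
        _add_unique(found, Equilibrium4(state=s, residual=float(r)))
    found.sort(key=lambda e: (round(e.state[0], 9), round(e.state[2], 9)))
    return found


def classify_stability(eq: Equilibrium4, p: Params,
                       b: Optional[float] = None) -> Equilibrium4:
    """Label an equilibrium from the analytic Jacobian spectrum."""
    b = p.b if b is None else b
    eigs = np.linalg.eigvals(ode4_jacobian(eq.state, p, b))
    re = eigs.real
    if np.all(re < -EIG_TOL):
        label = "stable"
    elif np.any(re > EIG_TOL):
        label = "unstable"
    else:
        label = "marginal"
    eq.eigenvalues = eigs
    eq.label = label
    return eq


def bifurcation_scan(p: Params, b_grid: Sequence[float]) -> list[dict]:
    """Equilibrium and stable-equilibrium counts along a grid of b values."""
    rows = []
    for b in b_grid:
        eqs = [classify_stability(e, p, b) for e in find_equilibria(p, b)]
        n_stable = sum(e.label == "stable" for e in eqs)
        n_counted = sum(e.label != "marginal" for e in eqs)
        rows.append({"b": float(b), "n_eq": n_counted, "n_stable": n_stable,
                     "equilibria": eqs})
    return rows


def heteroclinic_orbits(p: Params, b: float = 25.0, delta: float = 1e-6,
                        t_max: float = 1e3) -> list[dict]:
    """Shoot orbits off the symmetric saddle along its unstable directions.

    For every eigendirection with positive real part the trajectory from
    ``saddle +/- delta*w`` is integrated and its omega-limit classified
    by the nearest equilibrium (within 1e-6); unsettled orbits are
    flagged ``resolved=False``.
    """
    saddle = np.array([p.gamma, p.c * p.gamma / p.e,
                       p.gamma, p.c * p.gamma / p.e])
    eigval, eigvec = np.linalg.eig(ode4_jacobian(saddle, p, b))
    eqs = [classify_stability(e, p, b) for e in find_equilibria(p, b)]
    orbits = []
    for k in np.flatnonzero(eigval.real > EIG_TOL):
        w = np.real(eigvec[:, k])
        w = w / np.linalg.norm(w)
        for sign in (+1.0, -1.0):
            y0 = saddle + sign * delta * w
            sol = solve_ivp(lambda t, y: ode4_rhs(y, p, b), (0.0, t_max), y0,
                            method="RK45", rtol=1e-10, atol=1e-12,
                            dense_output=False)
            end = sol.y[:, -1]
            dists = [np.max(np.abs(end - e.state)) for e in eqs]
            j = int(np.argmin(dists))
            resolved = dists[j] < 1e-6
            orbits.append({
                "direction": sign * w,
                "limit": eqs[j] if resolved else None,
                "path_t": sol.t,
                "path": sol.y.T,
                "resolved": resolved,
            })
    return orbits
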