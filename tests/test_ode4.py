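import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ksnet.kinetics import Params, reaction_f
from ksnet.ode4 import (alphas, bifurcation_scan, classify_stability,
                        find_equilibria, heteroclinic_orbits, ode4_jacobian,
                        ode4_rhs, phi, swap)


@pytest.fixture(scope="module")
def p():
    return Params()


class TestRhs:
    def test_trivial_equilibria(self, p):
        assert np.max(np.abs(ode4_rhs(np.zeros(4), p))) == 0.0
        high = np.array([1.0, p.c / p.e, 1.0, p.c / p.e])
        assert np.max(np.abs(ode4_rhs(high, p))) < 1e-14

    def test_swap_equivariance(self, p):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.uniform(-1, 2, 4)
            assert np.array_equal(ode4_rhs(swap(s), p), swap(ode4_rhs(s, p)))

    def test_jacobian_matches_finite_differences(self, p):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 1.5, 4)
        J = ode4_jacobian(s, p)
        eps = 1e-7
        for k in range(4):
            d = np.zeros(4)
            d[k] = eps
            fd = (ode4_rhs(s + d, p) - ode4_rhs(s - d, p)) / (2 * eps)
            assert np.allclose(J[:, k], fd, atol=1e-6)


class TestAlphas:
    def test_printed_parameter_values(self, p):
        ap = alphas(p)
        assert ap.alpha1 == pytest.approx(9 / 11, rel=1e-14)
        assert ap.alpha2 == pytest.approx(15 / 22, rel=1e-14)

    def test_decoupled_limit(self):
        ap = alphas(Params(dv=0.0))
        assert ap.alpha1 == pytest.approx(3 / 2)
        assert ap.alpha2 == 0.0

    def test_defining_identity(self, p):
        """v built from the alphas makes the v-equations stationary."""
        ap = alphas(p)
        rng = np.random.default_rng(2)
        for _ in range(10):
            u1, u2 = rng.uniform(0, 2, 2)
            v1 = ap.alpha1 * u1 + ap.alpha2 * u2
            v2 = ap.alpha1 * u2 + ap.alpha2 * u1
            s = np.array([u1, v1, u2, v2])
            out = ode4_rhs(s, p)
            assert abs(out[1]) < 1e-12 and abs(out[3]) < 1e-12

    def test_ordering(self, p):
        ap = alphas(p)
        assert ap.alpha1 > ap.alpha2 > 0


class TestPhi:
    def test_fixed_points_at_reaction_roots(self, p):
        for u in (0.0, p.gamma, 1.0):
            assert phi(u, p) == pytest.approx(u, abs=1e-14)

    def test_singular_abscissa(self, p):
        # denominator zero at u = du / (b (alpha1-alpha2)) = 22/75 for b=25
        u_sing = 22.0 / 75.0
        with pytest.raises(ZeroDivisionError):
            phi(u_sing, p, b=25.0)
        arr = phi(np.array([u_sing, 0.5]), p, b=25.0)
        assert np.isnan(arr[0]) and np.isfinite(arr[1])

    def test_consistency_with_stationary_equation(self, p):
        """(u1, phi(u1)) with stationary v zeroes the first component."""
        ap = alphas(p)
        rng = np.random.default_rng(3)
        for b in (10.0, 25.0):
            for u1 in rng.uniform(0.05, 1.8, 15):
                try:
                    u2 = phi(u1, p, ap, b)
                except ZeroDivisionError:
                    continue
                v1 = ap.alpha1 * u1 + ap.alpha2 * u2
                v2 = ap.alpha1 * u2 + ap.alpha2 * u1
                out = ode4_rhs(np.array([u1, v1, u2, v2]), p, b)
                assert abs(out[0]) < 1e-9 * max(1.0, abs(u2))


class TestEquilibria:
    def test_count_b10(self, p):
        eqs = find_equilibria(p, 10.0)
        assert len(eqs) == 3
        states = sorted(tuple(np.round(e.state, 8)) for e in eqs)
        assert states[0] == (0.0, 0.0, 0.0, 0.0)
        assert states[1] == (0.25, 0.375, 0.25, 0.375)
        assert states[2] == (1.0, 1.5, 1.0, 1.5)

    def test_count_b15_new_pair_asymmetric(self, p):
        eqs = find_equilibria(p, 15.0)
        assert len(eqs) == 5
        asym = [e for e in eqs if abs(e.state[0] - e.state[2]) > 1e-6]
        assert len(asym) == 2
        labeled = [classify_stability(e, p, 15.0) for e in asym]
        assert all(e.label == "unstable" for e in labeled)

    def test_count_b25_ordering(self, p):
        eqs = [classify_stability(e, p, 25.0) for e in find_equilibria(p, 25.0)]
        assert len(eqs) == 9
        stable_asym = [e for e in eqs if e.label == "stable"
                       and abs(e.state[0] - e.state[2]) > 1e-6]
        assert len(stable_asym) == 2
        hi = max(stable_asym, key=lambda e: e.state[0])
        u1s, u2s = hi.state[0], hi.state[2]
        assert p.gamma < u2s < 1.0 < u1s

    def test_residuals(self, p):
        for b in (10.0, 25.0):
            for eq in find_equilibria(p, b):
                assert np.max(np.abs(ode4_rhs(eq.state, p, b))) < 1e-10

    def test_scan_max_guard(self, p):
        with pytest.raises(ValueError):
            find_equilibria(p, 25.0, scan_max=1.0)

    def test_phi_route_matches_newton_oracle(self, ode4_enumerations):
        for b, (via_phi, via_newton) in ode4_enumerations.items():
            A = sorted(tuple(np.round(e.state, 6)) for e in via_phi)
            B = sorted(tuple(np.round(e.state, 6)) for e in via_newton)
            assert A == B, f"equilibrium sets differ at b={b}"


class TestStability:
    @pytest.mark.parametrize("b", [10.0, 17.5, 25.0])
    def test_origin_stable(self, p, b):
        from ksnet.ode4 import Equilibrium4
        eq = classify_stability(Equilibrium4(state=np.zeros(4)), p, b)
        assert eq.label == "stable"

    @pytest.mark.parametrize("b", [10.0, 25.0])
    def test_symmetric_saddle_unstable(self, p, b):
        from ksnet.ode4 import Equilibrium4
        s = np.array([p.gamma, p.c * p.gamma / p.e, p.gamma, p.c * p.gamma / p.e])
        assert classify_stability(Equilibrium4(state=s), p, b).label == "unstable"

    def test_swap_partners_share_spectra(self, p):
        eqs = [classify_stability(e, p, 25.0) for e in find_equilibria(p, 25.0)]
        for eq in eqs:
            partner = min(eqs, key=lambda o: np.max(np.abs(o.state - swap(eq.state))))
            assert np.max(np.abs(partner.state - swap(eq.state))) < 1e-8
            assert np.allclose(np.sort_complex(partner.eigenvalues),
                               np.sort_complex(eq.eigenvalues), atol=1e-8)


@pytest.fixture(scope="module")
def scan(p):
    return bifurcation_scan(p, [10.0, 12.5, 15.0, 20.0, 25.0])


@pytest.fixture(scope="module")
def orbits(p):
    return heteroclinic_orbits(p, b=25.0)


class TestBifurcationScan:
    def test_counts(self, scan):
        counts = {row["b"]: row["n_eq"] for row in scan}
        assert counts[10.0] == 3
        assert counts[15.0] == 5
        assert counts[25.0] == 9

    def test_stable_counts(self, scan):
        stable = {row["b"]: row["n_stable"] for row in scan}
        assert stable[10.0] == 2
        assert stable[25.0] == 4

    def test_counts_nondecreasing(self, scan):
        ns = [row["n_eq"] for row in scan]
        assert all(a <= b_ for a, b_ in zip(ns, ns[1:]))


class TestHeteroclinics:
    def test_limit_set(self, p, orbits):
        assert all(o["resolved"] for o in orbits)
        limits = [o["limit"].state for o in orbits]
        has = {
            "origin": any(np.max(np.abs(s)) < 1e-6 for s in limits),
            "high": any(np.max(np.abs(s - [1, 1.5, 1, 1.5])) < 1e-6
                        for s in limits),
            "asymmetric": any(abs(s[0] - s[2]) > 0.1 for s in limits),
        }
        assert all(has.values()), has

    def test_swap_image_of_orbit(self, p, orbits):
        asym = [o for o in orbits if abs(o["limit"].state[0] - o["limit"].state[2]) > 0.1]
        states = [tuple(np.round(o["limit"].state, 6)) for o in asym]
        for o in asym:
            assert tuple(np.round(swap(o["limit"].state), 6)) in states

    def test_delta_robustness(self, p, orbits):
        halved = heteroclinic_orbits(p, b=25.0, delta=5e-7)
        lims = sorted(tuple(np.round(o["limit"].state, 6)) for o in orbits)
        lims_h = sorted(tuple(np.round(o["limit"].state, 6)) for o in halved)
        assert lims == lims_h

    def test_opposite_displacements_split(self, p):
        """Opposite nudges inside the unstable plane of the saddle fall to
        the origin and to an asymmetric stable state (the two-trajectory
        picture).  A pure eigendirection cannot show this split (the
        symmetric rate dominates), so a mixed in-plane direction is used."""
        b = 25.0
        saddle = np.array([p.gamma, p.c * p.gamma / p.e,
                           p.gamma, p.c * p.gamma / p.e])
        ev, V = np.linalg.eig(ode4_jacobian(saddle, p, b))
        ks = np.flatnonzero(ev.real > 1e-10)
        assert len(ks) == 2
        # order: symmetric direction first (equal u-components)
        vecs = [np.real(V[:, k]) / np.linalg.norm(np.real(V[:, k])) for k in ks]
        wsym, wasym = sorted(vecs, key=lambda w: abs(w[0] - w[2]))
        if wsym[0] < 0:
            wsym = -wsym
        theta = 0.9
        d = np.cos(theta) * wasym - np.sin(theta) * wsym

        def limit(y0):
            sol = solve_ivp(lambda t, y: ode4_rhs(y, p, b), (0.0, 1000.0), y0,
                            rtol=1e-10, atol=1e-12)
            return sol.y[:, -1]

        plus = limit(saddle + 1e-3 * d)
        minus = limit(saddle - 1e-3 * d)
        assert np.max(np.abs(plus)) < 1e-6               # falls to the origin
        assert abs(minus[0] - minus[2]) > 0.1            # asymmetric state
        assert p.gamma < min(minus[0], minus[2]) < 1.0 < max(minus[0], minus[2])


class TestPositiveInvariance:
    def test_positive_orthant(self, p):
        """100 random positive starts stay (numerically) nonnegative."""
        rng = np.random.default_rng(4)
        starts = rng.uniform(0.01, 1.5, size=(100, 4))

        def batched(t, y):
            return ode4_rhs(y.reshape(-1, 4), p).ravel()

        sol = solve_ivp(batched, (0.0, 100.0), starts.ravel(),
                        method="RK45", rtol=1e-8, atol=1e-10)
        assert sol.success
        assert sol.y.min() >= -1e-9
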