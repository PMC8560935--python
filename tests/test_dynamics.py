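"""Mussel-cover ODE: functional responses, equilibria, bifurcations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marshres import (
    ForagingMode,
    HogMusselModel,
    ModelParams,
    bifurcation_sweep,
    find_equilibria,
    fold_point,
    mussel_rhs,
    per_mussel_pressure,
)


def brute_force_equilibria(params, mode, n_grid=10_000, refine_tol=1e-12):
    """Independent oracle: sign scan on a dense grid + bisection."""
    grid = np.linspace(0.0, 1.0, n_grid)
    f = np.array([mussel_rhs(m, params, mode) for m in grid])
    roots = [0.0]
    for i in range(n_grid - 1):
        if f[i] * f[i + 1] < 0:
            lo, hi = grid[i], grid[i + 1]
            flo = f[i]
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                fm = mussel_rhs(mid, params, mode)
                if flo * fm < 0:
                    hi = mid
                else:
                    lo, flo = mid, fm
            roots.append(0.5 * (lo + hi))
        elif f[i + 1] == 0 and grid[i + 1] > 0:
            roots.append(grid[i + 1])
    return sorted(set(round(r, 9) for r in roots))


class TestPerMusselPressure:
    @pytest.mark.parametrize(
        "M, params, mode, expected",
        [
            (0.3, ModelParams(a=1, H=2), "none", 2.0),
            (0.2, ModelParams(a=1, H=1, h=0.2), "incomplete", 2.5),
            (0.8, ModelParams(a=1, H=1, h=0.2), "complete", 1.0),
            (0.05, ModelParams(a=1, H=1, h=0.2), "complete", 4.0),
        ],
    )
    def test_worked_values(self, M, params, mode, expected):
        assert per_mussel_pressure(M, params, mode) == pytest.approx(expected)

    def test_incomplete_peaks_at_half_saturation(self):
        """M/(M^2+h^2) is maximized at M = h with value 1/(2h)."""
        p = ModelParams(a=1, H=1, h=0.2)
        peak = per_mussel_pressure(0.2, p, "incomplete")
        grid = np.linspace(0.001, 1.0, 500)
        vals = [per_mussel_pressure(m, p, "incomplete") for m in grid]
        assert peak == pytest.approx(1 / (2 * 0.2))
        assert max(vals) <= peak + 1e-12

    def test_complete_pressure_rises_as_cover_falls(self):
        """Depensation: finite differences of the complete response are
        negative in M everywhere on (0, 1)."""
        p = ModelParams(a=1.3, H=0.7, h=0.15)
        grid = np.linspace(0.01, 0.99, 200)
        vals = np.array([per_mussel_pressure(m, p, "complete") for m in grid])
        assert np.all(np.diff(vals) < 0)

    def test_total_predation_is_cover_times_pressure(self):
        p = ModelParams(g=2.0, a=0.5, H=1.1, h=0.3)
        for mode in ForagingMode:
            M = 0.37
            total = p.g * M * (1 - M) - mussel_rhs(M, p, mode)
            assert total == pytest.approx(M * per_mussel_pressure(M, p, mode))

    def test_invalid_inputs(self):
        p = ModelParams()
        with pytest.raises(ValueError, match="mode"):
            per_mussel_pressure(0.5, p, "grazing")
        with pytest.raises(ValueError, match="cover"):
            per_mussel_pressure(1.5, p, "none")
        with pytest.raises(ValueError, match="cover"):
            mussel_rhs(-0.1, p, "none")

    @given(
        M=st.floats(0.0001, 0.0399),
        h=st.floats(0.21, 0.49),
        aH=st.floats(0.1, 3.0),
    )
    @settings(deadline=None, max_examples=80)
    def test_mode_ordering_at_low_cover(self, M, h, aH):
        """When mussels are genuinely scarce (M < h^2) a focusing hog
        exerts the most per-mussel pressure and a depleting one the
        least: complete > none > incomplete."""
        if M >= h * h:
            M = h * h / 2
        p = ModelParams(a=aH, H=1.0, h=h)
        pc = per_mussel_pressure(M, p, "complete")
        pn = per_mussel_pressure(M, p, "none")
        pi = per_mussel_pressure(M, p, "incomplete")
        assert pc > pn > pi


class TestMusselRhs:
    def test_extinction_is_absorbing(self):
        for mode in ForagingMode:
            for p in (ModelParams(), ModelParams(a=2, H=3, h=0.1)):
                assert mussel_rhs(0.0, p, mode) == 0.0

    def test_carrying_capacity_without_predation(self):
        for mode in ForagingMode:
            assert mussel_rhs(1.0, ModelParams(H=0.0), mode) == pytest.approx(0.0)

    def test_interior_root_complete_mode(self, worked_params):
        """(1-M)(M+0.2) = 0.3 has the quadratic root M ~ 0.15505."""
        root = (0.8 - math.sqrt(0.64 - 0.4)) / 2
        assert mussel_rhs(root, worked_params.with_hogs(0.3), "complete") == (
            pytest.approx(0.0, abs=1e-12)
        )


class TestFindEquilibria:
    def test_pure_logistic(self):
        for mode in ForagingMode:
            eqs = find_equilibria(ModelParams(H=0.0), mode)
            states = {round(e.M, 9): e.stable for e in eqs}
            assert states == {0.0: False, 1.0: True}

    def test_linear_response_closed_form(self):
        eqs = find_equilibria(ModelParams(g=1, a=1, H=0.4), "none")
        states = sorted((e.M, e.stable) for e in eqs)
        assert states[0][0] == pytest.approx(0.0)
        assert not states[0][1]
        assert states[1][0] == pytest.approx(0.6, abs=1e-9)
        assert states[1][1]

    def test_bistability_under_complete_focus(self, worked_params):
        eqs = find_equilibria(worked_params.with_hogs(0.3), "complete")
        assert len(eqs) == 3
        (zero, mid, high) = sorted(eqs, key=lambda e: e.M)
        assert zero.M == 0.0 and zero.stable
        assert mid.M == pytest.approx(0.155051, abs=1e-5) and not mid.stable
        assert high.M == pytest.approx(0.644949, abs=1e-5) and high.stable
        assert eqs.is_bistable

    @pytest.mark.parametrize("mode", list(ForagingMode))
    def test_matches_brute_force_oracle(self, mode, rng):
        """Root finder agrees with a dense sign-scan + bisection oracle
        on random parameter draws."""
        for _ in range(25):
            p = ModelParams(
                g=rng.uniform(0.2, 3.0),
                a=rng.uniform(0.1, 3.0),
                H=rng.uniform(0.0, 2.0),
                h=rng.uniform(0.05, 0.8),
            )
            ours = sorted(e.M for e in find_equilibria(p, mode))
            oracle = brute_force_equilibria(p, mode)
            assert len(ours) == len(oracle)
            for a, b in zip(ours, oracle):
                assert abs(a - b) < 1e-6


class TestBifurcation:
    def test_linear_branch_closed_form(self):
        p = ModelParams(g=1, a=1)
        b = bifurcation_sweep(p, "none", [0.0, 0.5, 1.0])
        stars = [es.largest_stable for es in b.branches]
        assert stars == pytest.approx([1.0, 0.5, 0.0], abs=1e-9)

    def test_fold_location_closed_form(self, worked_params):
        """Tangency of g(1-M)(M+h) with aH: closed form vs numeric max."""
        from scipy.optimize import minimize_scalar

        H_fold, M_fold = fold_point(worked_params)
        assert (H_fold, M_fold) == pytest.approx((0.36, 0.4), abs=1e-12)
        # independent oracle: maximize (1-M)(M+h) numerically
        res = minimize_scalar(
            lambda M: -(1 - M) * (M + 0.2), bounds=(0, 1), method="bounded",
            options={"xatol": 1e-12},
        )
        assert -res.fun == pytest.approx(H_fold, abs=1e-8)
        assert res.x == pytest.approx(M_fold, abs=1e-6)

    def test_fold_terminates_stable_branch(self, worked_params):
        H_fold, _ = fold_point(worked_params)
        b = bifurcation_sweep(
            worked_params, "complete", np.linspace(0.0, 1.0, 101)
        )
        assert b.collapse_threshold == pytest.approx(H_fold, abs=0.011)
        # below the fold the vegetated state persists, above it only bare
        for H, es in zip(b.H_grid, b.branches):
            if H < H_fold - 0.011:
                assert es.largest_stable_interior is not None
            if H > H_fold + 0.011:
                assert es.largest_stable_interior is None

    def test_largest_stable_state_non_increasing_in_H(self, rng):
        for mode in ForagingMode:
            for _ in range(10):
                p = ModelParams(
                    g=rng.uniform(0.5, 2.0),
                    a=rng.uniform(0.2, 2.0),
                    h=rng.uniform(0.05, 0.6),
                )
                b = bifurcation_sweep(p, mode, np.linspace(0, 2, 41))
                stars = [es.largest_stable for es in b.branches]
                assert all(
                    s1 >= s2 - 1e-8 for s1, s2 in zip(stars, stars[1:])
                ), f"{mode}: {p}"

    def test_input_validation(self):
        p = ModelParams()
        with pytest.raises(ValueError, match="non-empty"):
            bifurcation_sweep(p, "none", [])
        with pytest.raises(ValueError, match="increasing"):
            bifurcation_sweep(p, "none", [0.5, 0.2])
        b = bifurcation_sweep(p, "incomplete", [0.0])
        assert b.branches[0].largest_stable == pytest.approx(1.0)


class TestHogMusselModel:
    def test_object_front_end_matches_functions(self, worked_params):
        m = HogMusselModel(worked_params.with_hogs(0.3), "complete")
        assert m.rhs(0.5) == mussel_rhs(0.5, worked_params.with_hogs(0.3), "complete")
        assert [e.M for e in m.equilibria()] == [
            e.M for e in find_equilibria(worked_params.with_hogs(0.3), "complete")
        ]

    def test_trajectory_approaches_stable_state(self, worked_params):
        m = HogMusselModel(worked_params.with_hogs(0.3), "complete")
        _, M_hi = m.simulate(M0=0.5, t_max=60.0)
        _, M_lo = m.simulate(M0=0.05, t_max=60.0)
        assert M_hi[-1] == pytest.approx(0.644949, abs=1e-4)
        assert M_lo[-1] == pytest.approx(0.0, abs=1e-4)
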