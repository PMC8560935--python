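"""Nonspatial dynamics of mussel cover under hog predation.

The model is a single ODE on mussel cover M in [0, 1]:

    dM/dt = g M (1 - M/K) - M * f(M)

with logistic regrowth and a per-mussel predation pressure f(M) whose
shape depends on the hog foraging mode:

    none        f(M) = a H                 (trampling; type I)
    incomplete  f(M) = a H M / (M^2 + h^2) (prey depletion; type III)
    complete    f(M) = a H / (M + h)       (depensatory focus; type II)

Under complete focusing the per-mussel pressure grows as cover falls,
which produces bistability (a stable bare state, an unstable interior
threshold, and a stable vegetated state) and a saddle-node fold at
H_fold = g (1 + h)^2 / (4 a), M_fold = (1 - h) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .params import ForagingMode, ModelParams

__all__ = [
    "per_mussel_pressure",
    "mussel_rhs",
    "find_equilibria",
    "bifurcation_sweep",
    "fold_point",
    "Equilibrium",
    "EquilibriumSet",
    "BifurcationBranch",
    "HogMusselModel",
]

#: classification offset for the stability sign test
_STABILITY_EPS = 1e-5
#: grid size for root bracketing
_GRID_N = 2001
#: bisection tolerance for interior roots
_ROOT_TOL = 1e-10
#: roots closer than this are merged
_MERGE_TOL = 1e-6


def _check_cover(M: float) -> None:
    if not (0.0 <= M <= 1.0) or not np.isfinite(M):
        raise ValueError(f"mussel cover must lie in [0, 1], got {M}")


def per_mussel_pressure(
    M: float, params: ModelParams, mode: ForagingMode | str
) -> float:
    """Predation rate per unit mussel cover at cover ``M``.

    ``none`` is constant in M; ``incomplete`` vanishes as M -> 0 and
    peaks at M = h; ``complete`` strictly increases as M decreases
    (depensation). Total predation is ``M * per_mussel_pressure(M)`` in
    every mode.
    """
    mode = ForagingMode.coerce(mode)
    _check_cover(M)
    aH = params.a * params.H
    if mode is ForagingMode.NONE:
        return aH
    if mode is ForagingMode.INCOMPLETE:
        return aH * M / (M * M + params.h * params.h)
    return aH / (M + params.h)


def mussel_rhs(M: float, params: ModelParams, mode: ForagingMode | str) -> float:
    """dM/dt (cover per year): logistic regrowth minus hog predation.

    Exactly zero at M = 0 in every mode (extinction is absorbing).
    """
    mode = ForagingMode.coerce(mode)
    _check_cover(M)
    if M == 0.0:
        return 0.0
    return params.g * M * (1.0 - M / params.K) - M * per_mussel_pressure(
        M, params, mode
    )


@dataclass(frozen=True)
class Equilibrium:
    M: float
    stable: bool

    @property
    def stability(self) -> str:
        return "stable" if self.stable else "unstable"


@dataclass(frozen=True)
class EquilibriumSet:
    """All equilibria of the mussel ODE in [0, 1] with stability labels."""

    equilibria: tuple[Equilibrium, ...]
    params: ModelParams
    mode: ForagingMode

    def __iter__(self):
        return iter(self.equilibria)

    def __len__(self) -> int:
        return len(self.equilibria)

    @property
    def stable_states(self) -> tuple[float, ...]:
        return tuple(e.M for e in self.equilibria if e.stable)

    @property
    def largest_stable(self) -> float | None:
        s = self.stable_states
        return max(s) if s else None

    @property
    def largest_stable_interior(self) -> float | None:
        s = [m for m in self.stable_states if m > 0.0]
        return max(s) if s else None

    @property
    def is_bistable(self) -> bool:
        return len(self.stable_states) >= 2


def _classify(
    M: float, rhs: Callable[[float], float], eps: float = _STABILITY_EPS
) -> bool:
    """Stable iff the flow points toward M from both admissible sides.

    Degenerate (fold) points where the one-sided signs do not both point
    inward are labelled unstable — conservative for resilience claims.
    """
    lo = max(M - eps, 0.0)
    hi = min(M + eps, 1.0)
    left_in = rhs(lo) > 0 if lo < M else True
    right_in = rhs(hi) < 0 if hi > M else True
    return left_in and right_in


def find_equilibria(
    params: ModelParams, mode: ForagingMode | str
) -> EquilibriumSet:
    """All roots of :func:`mussel_rhs` in [0, 1] with stability labels.

    Roots are bracketed on a uniform grid and refined by bisection; the
    boundary state M = 0 is always included. Stability comes from the
    sign of the rate function at M ± 1e-5.
    """
    mode = ForagingMode.coerce(mode)
    rhs = lambda M: mussel_rhs(M, params, mode)  # noqa: E731

    grid = np.linspace(0.0, 1.0, _GRID_N)
    vals = np.array([rhs(m) for m in grid])
    if not np.all(np.isfinite(vals)):
        raise ArithmeticError(
            "non-finite rate values on the root-bracketing grid; "
            f"params={params}, mode={mode.value}"
        )

    roots: list[float] = [0.0]
    for i in range(len(grid) - 1):
        lo, hi = grid[i], grid[i + 1]
        flo, fhi = vals[i], vals[i + 1]
        if flo == 0.0 and lo > 0.0:
            roots.append(float(lo))
            continue
        if flo * fhi < 0.0:
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                fmid = rhs(mid)
                if fmid == 0.0 or hi - lo < _ROOT_TOL:
                    break
                if flo * fmid < 0.0:
                    hi = mid
                else:
                    lo, flo = mid, fmid
            roots.append(0.5 * (lo + hi))
    if vals[-1] == 0.0:
        roots.append(1.0)

    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > _MERGE_TOL:
            merged.append(r)

    eqs = tuple(Equilibrium(M=r, stable=_classify(r, rhs)) for r in merged)
    return EquilibriumSet(equilibria=eqs, params=params, mode=mode)


def fold_point(params: ModelParams) -> tuple[float, float]:
    """Saddle-node (fold) of the complete-focus mode, closed form.

    The interior equilibria solve g (1 - M)(M + h) = a H; the fold is
    where the left side is tangent to the level a H:
    M_fold = (1 - h)/2, H_fold = g (1 + h)^2 / (4 a).
    """
    if params.a == 0:
        raise ValueError("fold undefined for a = 0 (no predation)")
    M_fold = (1.0 - params.h) / 2.0
    H_fold = params.g * (1.0 + params.h) ** 2 / (4.0 * params.a)
    return H_fold, M_fold


#: sentinel for a sweep with no collapse on the grid
NO_COLLAPSE = None


@dataclass(frozen=True)
class BifurcationBranch:
    """Equilibria and stability across an ascending hog-density grid."""

    H_grid: tuple[float, ...]
    branches: tuple[EquilibriumSet, ...]
    collapse_threshold: float | None
    mode: ForagingMode

    def to_frame(self):
        """Tidy (H, M_star, stability, mode) table."""
        import pandas as pd

        rows = [
            {
                "H": H,
                "M_star": eq.M,
                "stability": eq.stability,
                "mode": self.mode.value,
            }
            for H, eqset in zip(self.H_grid, self.branches)
            for eq in eqset
        ]
        return pd.DataFrame(rows)


def bifurcation_sweep(
    params: ModelParams,
    mode: ForagingMode | str,
    H_grid: Sequence[float],
) -> BifurcationBranch:
    """Equilibrium structure across hog densities.

    ``collapse_threshold`` is the smallest grid H at which no stable
    interior equilibrium remains (None if the vegetated state persists
    across the whole grid).
    """
    mode = ForagingMode.coerce(mode)
    H_arr = np.asarray(H_grid, dtype=float)
    if H_arr.size == 0:
        raise ValueError("H_grid must be non-empty")
    if np.any(H_arr < 0):
        raise ValueError("hog densities must be non-negative")
    if H_arr.size > 1 and not np.all(np.diff(H_arr) > 0):
        raise ValueError("H_grid must be strictly increasing")

    branches = tuple(
        find_equilibria(params.with_hogs(float(H)), mode) for H in H_arr
    )
    collapse = NO_COLLAPSE
    for H, eqset in zip(H_arr, branches):
        if eqset.largest_stable_interior is None:
            collapse = float(H)
            break
    return BifurcationBranch(
        H_grid=tuple(float(H) for H in H_arr),
        branches=branches,
        collapse_threshold=collapse,
        mode=mode,
    )


class HogMusselModel:
    """Mussel-cover dynamics under a fixed hog forcing.

    A thin object-oriented front end over the module functions: holds a
    parameter set and foraging mode and exposes the rate function,
    equilibrium analysis, bifurcation sweeps and trajectory simulation.

    Examples
    --------
    >>> m = HogMusselModel(ModelParams(g=1, a=1, h=0.2, H=0.3), "complete")
    >>> [round(e.M, 3) for e in m.equilibria()]
    [0.0, 0.155, 0.645]
    """

    def __init__(
        self, params: ModelParams | None = None, mode: ForagingMode | str = "none"
    ):
        self.params = params if params is not None else ModelParams()
        self.mode = ForagingMode.coerce(mode)

    def pressure(self, M: float) -> float:
        return per_mussel_pressure(M, self.params, self.mode)

    def rhs(self, M: float) -> float:
        return mussel_rhs(M, self.params, self.mode)

    def equilibria(self) -> EquilibriumSet:
        return find_equilibria(self.params, self.mode)

    def bifurcation(self, H_grid: Sequence[float]) -> BifurcationBranch:
        return bifurcation_sweep(self.params, self.mode, H_grid)

    def simulate(
        self, M0: float, t_max: float, n_steps: int = 1000
    ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate the cover ODE from ``M0`` with ``solve_ivp``."""
        from scipy.integrate import solve_ivp

        _check_cover(M0)
        t_eval = np.linspace(0.0, t_max, n_steps)
        sol = solve_ivp(
            lambda t, y: [mussel_rhs(float(np.clip(y[0], 0.0, 1.0)), self.params, self.mode)],
            (0.0, t_max),
            [M0],
            t_eval=t_eval,
            rtol=1e-8,
            atol=1e-10,
        )
        return sol.t, np.clip(sol.y[0], 0.0, 1.0)
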