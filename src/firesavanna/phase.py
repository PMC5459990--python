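"""Phase diagram, Maxwell point and spatial state prediction.

The forest-savanna boundary of the lattice model is mapped in the plane of
distance-to-agriculture (delta, km) and effective rainfall (P, mm/yr): for
every (delta, P) combination a spatially homogeneous lattice is run from
random cover through the natural phase and a human-impact phase, and the
fraction of cells with tree cover above 40% is stored at two sampling times.
Where that fraction has stopped changing but is neither 0 nor 1, the planar
front between forest and savanna is stationary — the Maxwell point (MP).
Above the MP forest invades savanna, below it savanna invades forest; there
is no large-scale hysteresis, only this environmentally set boundary.

The located MP points are summarised by an exponential curve

    P_MP(delta) = P_inf + A * exp(-delta / ell)

whose large-delta asymptote P_inf is the natural Maxwell point.  Together
with the treeless boundary of the local model (the rainfall below which
savanna tree cover vanishes), the curve predicts the vegetation state of
every cell of a landscape from P, M, delta and soil suitability alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .landscape import EnvironmentalFields
from .suitability import SuitabilityModel
from .vegmodel import (
    CoverState,
    Drivers,
    ModelParams,
    StateClass,
    effective_precip,
    local_equilibrium,
    step,
)

__all__ = [
    "PhaseDiagram",
    "MaxwellCurve",
    "run_phase_grid",
    "locate_maxwell",
    "fit_maxwell_curve",
    "treeless_boundary",
    "predict_state_map",
    "front_speed",
]


@dataclass
class PhaseDiagram:
    """Forest fraction over a (delta, P) grid at two sampling times.

    ``forest_frac_t1[i, j]`` is the fraction of lattice cells with tree
    cover > 40% at time t1 for ``delta_values[i]`` and ``P_values[j]``.
    """

    delta_values: np.ndarray  # km
    P_values: np.ndarray  # mm/yr
    forest_frac_t1: np.ndarray  # (n_delta, n_P)
    forest_frac_t2: np.ndarray
    t1: int
    t2: int
    lattice_n: int
    seed: int | None = None

    @property
    def diff(self) -> np.ndarray:
        """Late-minus-early change in forest fraction."""
        return self.forest_frac_t2 - self.forest_frac_t1

    def plot(self, ax=None):
        """Colour map of the final forest fraction with the MP overlay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(self.delta_values, self.P_values,
                             self.forest_frac_t2.T, vmin=0, vmax=1,
                             shading="nearest", cmap="Greens")
        pts = locate_maxwell(self)
        if pts:
            d, p = np.array(pts).T
            ax.plot(d, p, "k-", lw=1.5, label="Maxwell point")
            ax.legend(loc="lower right")
        ax.set_xlabel("distance to agriculture $\\delta$ (km)")
        ax.set_ylabel("effective rainfall $P$ (mm/yr)")
        plt.colorbar(mesh, ax=ax, label="forest fraction")
        return ax


def run_phase_grid(params: ModelParams, delta_values, P_values,
                   lattice_n: int = 32, t1: int = 300, t2: int = 500,
                   seed=None, boundary: str = "periodic",
                   include_grass_init: bool = False) -> PhaseDiagram:
    """Run the lattice model for every (delta, P) combination.

    Each combination is a homogeneous environment: uniform effective
    rainfall P and a uniform logging rate corresponding to distance delta
    (delta = 0 means inside the managed zone, where trees and saplings are
    removed at r0).  Humans are switched on at t1; forest fraction
    (tree cover > 40%) is recorded at t1 and t2.  All combinations advance
    together as one batched lattice, with periodic boundaries and random
    initial cover over (F, T, S, B) by default.
    """
    if t2 <= t1:
        raise ValueError("t2 must be greater than t1")
    delta_values = np.asarray(delta_values, dtype=float)
    P_values = np.asarray(P_values, dtype=float)
    if delta_values.size == 0 or P_values.size == 0:
        raise ValueError("delta and P grids must be non-empty")
    if lattice_n < 16:
        raise ValueError("lattice_n must be at least 16")

    nd, npp = delta_values.size, P_values.size
    B = nd * npp
    dd = np.repeat(delta_values, npp).reshape(B, 1, 1)
    pp = np.tile(P_values, nd).reshape(B, 1, 1)

    rng = np.random.default_rng(seed)
    shape = (B, lattice_n, lattice_n)
    state = CoverState.random(shape, rng, include_grass=include_grass_init)
    drivers = Drivers.build(pp, dd, dd == 0.0, params)

    n1 = int(round(t1 / params.dt))
    n2 = int(round(t2 / params.dt))

    def forest_frac(s):
        return (s.tree_cover() > 40.0).mean(axis=(-2, -1))

    for i in range(n2):
        state, _ = step(state, drivers, params, rng,
                        humans_active=(i >= n1), boundary=boundary)
        if i + 1 == n1:
            frac1 = forest_frac(state)
    frac2 = forest_frac(state)

    return PhaseDiagram(
        delta_values=delta_values, P_values=P_values,
        forest_frac_t1=frac1.reshape(nd, npp),
        forest_frac_t2=frac2.reshape(nd, npp),
        t1=t1, t2=t2, lattice_n=lattice_n, seed=seed,
    )


def locate_maxwell(diagram: PhaseDiagram, tol_diff: float | None = None,
                   tol_frac: float = 0.05) -> list[tuple[float, float]]:
    """Per-delta-column Maxwell points.

    In each column the MP is where the forest-fraction change between the
    two sampling times crosses zero while the final fraction is neither ~0
    nor ~1.  The crossing P is linearly interpolated between grid rows; a
    column with no eligible crossing contributes nothing (an empty result is
    valid).  ``tol_diff`` defaults to 2/lattice_n + 0.01, reflecting the
    one-front resolution of the lattice and the slow convergence near the MP.
    """
    if tol_diff is None:
        tol_diff = 2.0 / diagram.lattice_n + 0.01
    points: list[tuple[float, float]] = []
    P = diagram.P_values
    for i, delta in enumerate(diagram.delta_values):
        frac = diagram.forest_frac_t2[i]
        diff = diagram.diff[i]
        ok = (frac > tol_frac) & (frac < 1.0 - tol_frac)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            continue
        # zero crossings of diff between consecutive eligible rows
        best = None
        for a, b in zip(idx[:-1], idx[1:]):
            if b != a + 1:
                continue
            if diff[a] == 0.0:
                best = (0.0, P[a])
            elif diff[a] * diff[b] < 0:
                w = diff[a] / (diff[a] - diff[b])
                best = (0.0, P[a] + w * (P[b] - P[a]))
            if best is not None:
                break
        if best is None:
            j = idx[np.argmin(np.abs(diff[idx]))]
            if abs(diff[j]) <= tol_diff:
                best = (abs(diff[j]), P[j])
        if best is not None:
            points.append((float(delta), float(best[1])))
    return points


@dataclass
class MaxwellCurve:
    """Exponential summary of the Maxwell point versus distance,
    P_MP(delta) = P_inf + A * exp(-delta / ell)."""

    P_inf: float  # natural Maxwell point, mm/yr
    A: float  # amplitude, mm/yr
    ell: float  # decay length, km
    rms_residual: float = np.nan
    n_points: int = 0

    def __call__(self, delta):
        delta = np.asarray(delta, dtype=float)
        with np.errstate(over="ignore"):
            return self.P_inf + self.A * np.exp(-delta / self.ell)

    def to_dict(self) -> dict:
        return {"P_inf": self.P_inf, "A": self.A, "ell": self.ell,
                "rms_residual": self.rms_residual, "n_points": self.n_points}

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaxwellCurve":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


def fit_maxwell_curve(points) -> MaxwellCurve:
    """Least-squares exponential fit to located (delta, P_MP) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (delta, P) points")
    d, p = pts[:, 0], pts[:, 1]
    span = np.ptp(d)
    if span <= 0:
        raise ValueError("degenerate delta spread: all points at one distance")

    def f(x, P_inf, A, ell):
        return P_inf + A * np.exp(-x / ell)

    p0 = (float(p[np.argmax(d)]), max(float(np.ptp(p)), 1.0), max(span / 3.0, 0.1))
    popt, _ = curve_fit(f, d, p, p0=p0, maxfev=20000,
                        bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, np.inf]))
    resid = p - f(d, *popt)
    return MaxwellCurve(float(popt[0]), float(popt[1]), float(popt[2]),
                        float(np.sqrt(np.mean(resid ** 2))), len(d))


def treeless_boundary(params: ModelParams, P_range=(200.0, 1600.0),
                      T_tol: float = 1e-3, xtol: float = 2.0) -> float:
    """Largest effective rainfall at which the local model's steady-state
    savanna tree cover is zero (no humans, no noise, mean-field fire).

    Below the returned value the landscape is treeless (grass/bare); above
    it savanna trees can persist.  Found by bisection on the steady state of
    the deterministic local model.
    """

    def t_star(P):
        eq = local_equilibrium(float(P), params, init="savanna")
        return float(eq.T[0, 0])

    lo, hi = map(float, P_range)
    f_lo, f_hi = t_star(lo) - T_tol, t_star(hi) - T_tol
    if f_lo >= 0 or f_hi <= 0:
        raise ValueError(
            f"no treeless transition in bracket {P_range}: "
            f"T*({lo})={f_lo + T_tol:.4f}, T*({hi})={f_hi + T_tol:.4f}"
        )
    return float(brentq(lambda P: t_star(P) - T_tol, lo, hi, xtol=xtol))


def predict_state_map(fields: EnvironmentalFields, curve: MaxwellCurve,
                      suitability: SuitabilityModel, params: ModelParams,
                      P_treeless: float) -> np.ndarray:
    """Vegetation state of every cell from P, M, delta and soil suitability.

    Forest where effective rainfall exceeds the Maxwell curve at the cell's
    distance to agriculture, savanna below it, treeless below the treeless
    boundary; agricultural cells carry their own class.
    """
    pi = suitability.soil_pi(fields.sand, fields.clay, fields.density)
    P_eff = effective_precip(fields.P, fields.M, pi, suitability,
                             M_ref=params.M_ref)
    cls = np.full(fields.shape, StateClass.SAVANNA, dtype=np.int8)
    cls[P_eff > curve(fields.delta)] = StateClass.FOREST
    cls[P_eff < P_treeless] = StateClass.TREELESS
    cls[fields.agri_mask] = StateClass.AGRICULTURAL
    return cls


def front_speed(params: ModelParams, P_eff: float, *, delta: float = np.inf,
                shape=(24, 64), n_steps: int = 500, burn_in: int = 100,
                seeds=(0, 1, 2), boundary: str = "noflux") -> float:
    """Mean signed speed (cells per year) of a planar forest-savanna front.

    The lattice starts half in the local forest state and half in the local
    savanna state; positive speed means the forest advances.  The front is
    stationary at the Maxwell point.  Averaged over seeds because fire is
    stochastic.
    """
    ef = local_equilibrium(P_eff, params, "forest")
    es = local_equilibrium(P_eff, params, "savanna")
    ny, nx = shape
    half = nx // 2
    dvals = np.full(shape, float(delta))
    speeds = []
    for seed in seeds:
        st = CoverState(*(np.empty(shape) for _ in range(5)))
        for k in CoverState._TYPES:
            g = getattr(st, k)
            g[:, :half] = getattr(ef, k)[0, 0]
            g[:, half:] = getattr(es, k)[0, 0]
        drv = Drivers.build(np.full(shape, float(P_eff)), dvals,
                            np.zeros(shape, dtype=bool), params)
        rng = np.random.default_rng(seed)
        f_ref = None
        for i in range(n_steps):
            st, _ = step(st, drv, params, rng,
                         humans_active=np.isfinite(delta),
                         boundary=boundary)
            if i == burn_in:
                f_ref = st.F.mean()
        speeds.append((st.F.mean() - f_ref) * nx / ((n_steps - burn_in - 1) * params.dt))
    return float(np.mean(speeds))
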