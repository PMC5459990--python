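"""Stochastic lattice fire-vegetation dynamics.

Five cover fractions per cell — forest tree F, savanna tree T, savanna
sapling S, grass G and bare soil B — live on the unit simplex and follow a
competitive-colonisation hierarchy: F colonises space held by S, T and G;
S colonises G; G colonises B.  G is the default cover type (non-competitive
mortality converts to grass), and bare soil only forms from grass in dry
cells, with a continuous grass-bare transition.

Fire is a per-cell, per-year Bernoulli event whose probability is a
sigmoidal function of the fire-prone cover C = G + S, saturating at 1/I
(I = minimum fire return interval) above a climate-dependent critical cover
C_c.  Burning spreads to the four nearest neighbours through a discrete
Laplacian with strength D, removes a fraction b of forest cover, and cuts
sapling-to-adult recruitment by a factor d.  Human impact is a removal rate
r0 of trees and saplings in managed cells and an exponentially
distance-decaying removal of forest near edges (decay length lambda_r),
active only during the human-impact time window.

The deterministic skeleton advanced by one Euler step of size dt (noise is
added afterwards, Euler–Maruyama style):

    dF = g_F*F*(S+T+G) - m_F*F - b*f*F - r_F*F
    dT = q*S - m_T*T - g_F*F*T - r_TS*T        q = q0*(1 - d*f)
    dS = g_T*T*G - q*S - m_S*S - g_F*F*S - r_TS*S
    dB = m_GB*G - g_G*G*B
    dG = -(dF + dT + dS + dB)

Growth saturates with effective rainfall, g_i = g_max_i * P/(P + h_i);
mortality rises below a drought threshold, m_i = m0_i + md_i * sigmoid
(k_m*(P_crit_i - P)); savanna trees are the more drought-resistant type
(h_T < h_F, P_crit_T < P_crit_F).  Gaussian noise sigma*sqrt(dt)*xi is
added to F, T, S and B, each scaled by the relative availability of space
that type can colonise, with G absorbing the complement; negative
components are clipped and the cell renormalised, so the simplex is
conserved to machine precision.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .suitability import SuitabilityModel

__all__ = [
    "ModelParams",
    "CoverState",
    "Drivers",
    "StateClass",
    "SimulationResult",
    "FireVegetationModel",
    "effective_precip",
    "critical_cover",
    "local_fire_probability",
    "spread_fire",
    "demographic_rates",
    "logging_rate",
    "step",
    "simulate",
    "summarize_state",
    "classify_tree_cover",
    "local_equilibrium",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


@dataclass(frozen=True)
class ModelParams:
    """All demographic, fire, logging, noise and numerical parameters.

    Rates are per year; rainfall-like quantities in mm/yr; distances in km.
    The shipped defaults are calibrated so the nonspatial (local) model is
    bistable over a rainfall window overlapping 1400-1900 mm/yr, the maximum
    fire probability is 1/I with I = 5 yr, and edge logging is negligible
    beyond the 3 km transition zone (lambda_r = 0.4 km: logging alone
    clears only a sub-kilometre fringe; fire spread carries the damage).
    """

    # growth: g_i = g_max_i * P_eff / (P_eff + h_i)
    g_max_F: float = 0.35
    h_F: float = 900.0
    g_max_T: float = 0.45
    h_T: float = 500.0
    g_max_G: float = 0.50
    h_G: float = 600.0
    # mortality: m_i = m0_i + md_i / (1 + exp(k_m * (P_eff - P_crit_i)))
    m0_F: float = 0.05
    md_F: float = 0.40
    P_crit_F: float = 900.0
    m0_T: float = 0.15
    md_T: float = 0.40
    P_crit_T: float = 400.0
    m_S: float = 0.05
    k_m: float = 0.01
    # grass -> bare conversion, increasing with dryness (continuous)
    m_B0: float = 0.30
    P_crit_B: float = 700.0
    k_B: float = 0.01
    # recruitment and fire
    q0: float = 0.10
    d: float = 0.90  # recruitment reduction in fully burnt cells
    b: float = 0.90  # fraction of forest removed per burn
    I: float = 5.0  # minimum fire return interval, yr
    k_f: float = 20.0  # fire sigmoid steepness (per unit cover)
    C0: float = 0.59  # critical fire-prone cover at reference climate
    s_C: float = 1.0e-4  # dC_c/dP_eff (>0: drier cells burn at lower cover)
    C_lo: float = 0.40
    C_hi: float = 0.80
    P_ref: float = 1700.0
    M_ref: float = 0.50
    D: float = 0.10  # fire-spread strength (4-neighbour Laplacian)
    # human impact
    r0: float = 0.30  # managed-zone removal rate of trees and saplings
    lambda_r: float = 0.40  # edge-logging decay length, km
    # noise and numerics
    sigma: float = 0.04
    dt: float = 1.0  # yr
    dx: float = 1.0  # km
    fire_event_threshold: float = 0.5  # f_eff level that counts as a burn

    def __post_init__(self) -> None:
        if self.I <= 0:
            raise ValueError("fire return interval I must be positive")
        if not (0.0 <= self.b <= 1.0 and 0.0 <= self.d <= 1.0):
            raise ValueError("b and d must lie in [0, 1]")
        if self.D < 0:
            raise ValueError("fire-spread strength D must be non-negative")
        if 4.0 * self.D > 1.0:
            raise ValueError("stability requires 4*D <= 1")
        for name in ("g_max_F", "g_max_T", "g_max_G", "m0_F", "md_F", "m0_T",
                     "md_T", "m_S", "m_B0", "q0", "r0", "sigma", "s_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")

    def stability_check(self, include_humans: bool = True) -> None:
        """Warn when dt times the worst-case total outflow of any compartment
        exceeds 1 (the projection then clips; results remain valid but the
        step is outside the guaranteed-positive regime)."""
        r = self.r0 if include_humans else 0.0
        out = {
            "F": self.m0_F + self.md_F + self.b + r,
            "T": self.m0_T + self.md_T + self.g_max_F + r,
            "S": self.q0 + self.m_S + self.g_max_F + r,
            "G": self.g_max_F + self.g_max_T + self.m_B0,
            "B": self.g_max_G,
        }
        worst = max(out, key=out.get)
        if self.dt * out[worst] > 1.0:
            warnings.warn(
                f"dt * worst-case outflow of {worst} = {self.dt * out[worst]:.2f} > 1; "
                "negative excursions will be clipped by the simplex projection",
                RuntimeWarning, stacklevel=2,
            )

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    @classmethod
    def from_toml(cls, path) -> "ModelParams":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_toml(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k} = {v!r}\n")


class StateClass(enum.IntEnum):
    """Vegetation state classes by total tree cover."""

    TREELESS = 0  # < 5 %
    SAVANNA = 1  # 5-40 % (both bounds inclusive)
    FOREST = 2  # > 40 %
    AGRICULTURAL = 3


@dataclass
class CoverState:
    """Per-cell cover fractions on the simplex (arrays share one shape;
    leading batch dimensions are allowed ahead of the two lattice axes)."""

    F: np.ndarray
    T: np.ndarray
    S: np.ndarray
    G: np.ndarray
    B: np.ndarray

    _TYPES = ("F", "T", "S", "G", "B")

    @property
    def shape(self):
        return self.F.shape

    def stack(self) -> np.ndarray:
        return np.stack([self.F, self.T, self.S, self.G, self.B])

    def copy(self) -> "CoverState":
        return CoverState(*(getattr(self, k).copy() for k in self._TYPES))

    def validate(self, tol: float = 1e-9) -> None:
        total = self.F + self.T + self.S + self.G + self.B
        if np.max(np.abs(total - 1.0)) > tol:
            raise ValueError("cover fractions do not sum to 1")
        for k in self._TYPES:
            if np.any(getattr(self, k) < 0):
                raise ValueError(f"negative cover fraction in {k}")

    def tree_cover(self) -> np.ndarray:
        """Total tree cover in percent, 100*(F+T)."""
        return 100.0 * (self.F + self.T)

    def fire_prone_cover(self) -> np.ndarray:
        return self.G + self.S

    @classmethod
    def random(cls, shape, rng, include_grass: bool = True) -> "CoverState":
        """Uniform Dirichlet initial cover.  With ``include_grass=False`` the
        draw is over (F, T, S, B) only with G = 0, matching the
        phase-diagram initialisation protocol."""
        if include_grass:
            w = rng.dirichlet(np.ones(5), size=shape)
            w = np.moveaxis(w, -1, 0)
            return cls(*(w[i].copy() for i in range(5)))
        w = rng.dirichlet(np.ones(4), size=shape)
        w = np.moveaxis(w, -1, 0)
        return cls(w[0].copy(), w[1].copy(), w[2].copy(),
                   np.zeros(shape), w[3].copy())

    @classmethod
    def uniform(cls, shape, fractions) -> "CoverState":
        f = np.asarray(fractions, dtype=float)
        if f.shape != (5,) or abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
            raise ValueError("fractions must be 5 non-negative values summing to 1")
        return cls(*(np.full(shape, fi) for fi in f))


def classify_tree_cover(tc_percent, agri_mask=None) -> np.ndarray:
    """Class map from percent tree cover: forest > 40, savanna 5-40
    (inclusive at both cuts), treeless < 5; agricultural cells override."""
    tc = np.asarray(tc_percent, dtype=float)
    cls = np.full(tc.shape, StateClass.SAVANNA, dtype=np.int8)
    cls[tc > 40.0] = StateClass.FOREST
    cls[tc < 5.0] = StateClass.TREELESS
    if agri_mask is not None:
        cls[np.asarray(agri_mask, dtype=bool)] = StateClass.AGRICULTURAL
    return cls


def summarize_state(state: CoverState, agri_mask=None):
    """Tree-cover grid (percent) and its class map."""
    tc = state.tree_cover()
    return tc, classify_tree_cover(tc, agri_mask)


# ---------------------------------------------------------------------------
# Climate aggregation and rates


def effective_precip(P, M, pi, model: SuitabilityModel, M_ref: float = 0.50):
    """Collapse rainfall, seasonality and soil suitability into a single
    rainfall-equivalent using the suitability-coefficient ratios:

        P_eff = P + (th5/th6)*(M - M_ref) + pi/th6

    With M = M_ref and pi = 0, P_eff = P.
    """
    th5, th6 = model.theta[5], model.theta[6]
    if th6 == 0:
        raise ValueError("rainfall coefficient theta6 is zero; cannot convert")
    return (np.asarray(P, dtype=float)
            + (th5 / th6) * (np.asarray(M, dtype=float) - M_ref)
            + np.asarray(pi, dtype=float) / th6)


def critical_cover(P_eff, params: ModelParams):
    """Climate-dependent critical fire-prone cover C_c, a clipped linear
    function of effective rainfall (drier cells burn at lower cover)."""
    c = params.C0 + params.s_C * (np.asarray(P_eff, dtype=float) - params.P_ref)
    return np.clip(c, params.C_lo, params.C_hi)


def local_fire_probability(C, C_c, params: ModelParams):
    """Per-year local fire probability: (1/I) * sigmoid(k_f * (C - C_c))."""
    if params.I <= 0:
        raise ValueError("fire return interval I must be positive")
    return (1.0 / params.I) * _sigmoid(params.k_f * (np.asarray(C, dtype=float) - C_c))


def spread_fire(f_local, D, boundary: str = "noflux"):
    """Fire after nearest-neighbour spread:

        f_eff_i = f_i + D * sum_{j in N(i)} (f_j - f_i),  clipped to [0, 1].

    Operates on the last two axes; under no-flux boundaries a missing
    neighbour contributes zero difference.
    """
    f = np.asarray(f_local, dtype=float)
    if D == 0:
        return f.copy()
    if boundary == "periodic":
        neigh = (np.roll(f, 1, -1) + np.roll(f, -1, -1)
                 + np.roll(f, 1, -2) + np.roll(f, -1, -2))
        lap = neigh - 4.0 * f
    elif boundary == "noflux":
        lap = np.zeros_like(f)
        lap[..., :, 1:] += f[..., :, :-1] - f[..., :, 1:]
        lap[..., :, :-1] += f[..., :, 1:] - f[..., :, :-1]
        lap[..., 1:, :] += f[..., :-1, :] - f[..., 1:, :]
        lap[..., :-1, :] += f[..., 1:, :] - f[..., :-1, :]
    else:
        raise ValueError(f"unknown boundary condition: {boundary!r}")
    return np.clip(f + D * lap, 0.0, 1.0)


def demographic_rates(P_eff, params: ModelParams) -> dict:
    """Per-type growth/mortality rate grids at the given effective rainfall.

    Saturating growth, drought-threshold mortality; savanna trees retain low
    mortality and high growth for drier conditions than forest trees
    (h_T < h_F, P_crit_T < P_crit_F); m_GB is the continuous grass-to-bare
    conversion rate, increasing with dryness.
    """
    P = np.asarray(P_eff, dtype=float)
    Pp = np.clip(P, 0.0, None)
    k = params.k_m
    return {
        "g_F": params.g_max_F * Pp / (Pp + params.h_F),
        "g_T": params.g_max_T * Pp / (Pp + params.h_T),
        "g_G": params.g_max_G * Pp / (Pp + params.h_G),
        "m_F": params.m0_F + params.md_F * _sigmoid(k * (params.P_crit_F - P)),
        "m_T": params.m0_T + params.md_T * _sigmoid(k * (params.P_crit_T - P)),
        "m_S": np.full_like(P, params.m_S),
        "m_GB": params.m_B0 * _sigmoid(params.k_B * (params.P_crit_B - P)),
    }


def logging_rate(delta, agri_mask, active: bool, params: ModelParams):
    """Forest and tree/sapling removal rates (r_F, r_TS).

    Outside the human-impact time window both are zero.  In managed
    (agricultural) cells both equal r0; elsewhere edge logging removes
    forest only, at r0 * exp(-delta / lambda_r).
    """
    delta = np.asarray(delta, dtype=float)
    agri = np.asarray(agri_mask, dtype=bool)
    if not active:
        return np.zeros(delta.shape), np.zeros(delta.shape)
    with np.errstate(over="ignore"):
        r_F = params.r0 * np.exp(-delta / params.lambda_r)
    r_F = np.where(agri, params.r0, r_F)
    r_TS = np.where(agri, params.r0, 0.0)
    return r_F, r_TS


@dataclass
class Drivers:
    """Precomputed per-cell driver grids for the simulator."""

    P_eff: np.ndarray
    C_c: np.ndarray
    rates: dict
    r_F_natural: np.ndarray
    r_TS_natural: np.ndarray
    r_F_active: np.ndarray
    r_TS_active: np.ndarray

    @classmethod
    def build(cls, P_eff, delta, agri_mask, params: ModelParams) -> "Drivers":
        P_eff = np.asarray(P_eff, dtype=float)
        rF0, rTS0 = logging_rate(delta, agri_mask, False, params)
        rF1, rTS1 = logging_rate(delta, agri_mask, True, params)
        return cls(
            P_eff=P_eff,
            C_c=critical_cover(P_eff, params),
            rates=demographic_rates(P_eff, params),
            r_F_natural=rF0, r_TS_natural=rTS0,
            r_F_active=rF1, r_TS_active=rTS1,
        )

    def removal(self, active: bool):
        if active:
            return self.r_F_active, self.r_TS_active
        return self.r_F_natural, self.r_TS_natural


def deterministic_increments(state: CoverState, f_eff, rates: dict,
                             r_F, r_TS, params: ModelParams):
    """The five deterministic increments for one step of size dt.

    Their sum is exactly zero by construction (grass is the slack type)."""
    F, T, S, G, B = state.F, state.T, state.S, state.G, state.B
    q = params.q0 * (1.0 - params.d * f_eff)
    dt = params.dt
    dF = (rates["g_F"] * F * (S + T + G) - rates["m_F"] * F
          - params.b * f_eff * F - r_F * F) * dt
    dT = (q * S - rates["m_T"] * T - rates["g_F"] * F * T - r_TS * T) * dt
    dS = (rates["g_T"] * T * G - q * S - rates["m_S"] * S
          - rates["g_F"] * F * S - r_TS * S) * dt
    dB = (rates["m_GB"] * G - rates["g_G"] * G * B) * dt
    dG = -(dF + dT + dS + dB)
    return dF, dT, dS, dG, dB


def _project_simplex(F, T, S, G, B):
    """Clip negatives and renormalise each cell to total 1."""
    F = np.clip(F, 0.0, None)
    T = np.clip(T, 0.0, None)
    S = np.clip(S, 0.0, None)
    G = np.clip(G, 0.0, None)
    B = np.clip(B, 0.0, None)
    total = F + T + S + G + B
    total = np.where(total <= 0, 1.0, total)  # all-clipped cell -> bare
    return CoverState(F / total, T / total, S / total, G / total, B / total)


def step(state: CoverState, drivers: Drivers, params: ModelParams,
         rng=None, *, humans_active: bool = False,
         deterministic_fire: bool = False,
         boundary: str = "noflux") -> tuple[CoverState, np.ndarray]:
    """Advance the lattice by one time step (dt years).

    Returns the new state and the effective fire field f_eff.  With
    ``deterministic_fire`` the Bernoulli draw is replaced by its expectation
    (the mean-field local model); with sigma = 0, D = 0 and no removal the
    update reduces to an Euler step of the deterministic local ODEs.
    """
    C = state.fire_prone_cover()
    p = local_fire_probability(C, drivers.C_c, params)
    if deterministic_fire:
        f_local = p
    else:
        if rng is None:
            raise ValueError("stochastic fire requires an rng")
        f_local = (rng.random(state.shape) < p).astype(float)
    f_eff = spread_fire(f_local, params.D, boundary)

    r_F, r_TS = drivers.removal(humans_active)
    dF, dT, dS, dG, dB = deterministic_increments(
        state, f_eff, drivers.rates, r_F, r_TS, params)

    F = state.F + dF
    T = state.T + dT
    S = state.S + dS
    G = state.G + dG
    B = state.B + dB

    if params.sigma > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        amp = params.sigma * np.sqrt(params.dt)
        # availability of colonisable space per noisy type; G absorbs the rest
        avail = (state.S + state.T + state.G, state.S, state.G, state.G)
        bump = 0.0
        for target, a in zip("FTSB", avail):
            xi = amp * rng.standard_normal(state.shape) * a
            bump = bump + xi
            if target == "F":
                F = F + xi
            elif target == "T":
                T = T + xi
            elif target == "S":
                S = S + xi
            else:
                B = B + xi
        G = G - bump

    new = _project_simplex(F, T, S, G, B)
    if not np.all(np.isfinite(new.F)):
        raise FloatingPointError("non-finite cover state")
    return new, f_eff


@dataclass
class SimulationResult:
    """Output of a lattice run: final state, recorded snapshots, traces and
    fire-event counts (cells with f_eff above the event threshold)."""

    final: CoverState
    params: ModelParams
    times: np.ndarray
    mean_tree_cover: np.ndarray  # percent, per step
    burned_fraction: np.ndarray  # fraction of cells burning, per step
    fire_events: np.ndarray  # per-cell count of burn steps
    n_steps: int
    snapshots: list = field(default_factory=list)
    snapshot_times: list = field(default_factory=list)
    agri_mask: np.ndarray | None = None

    def tree_cover(self) -> np.ndarray:
        return self.final.tree_cover()

    def classify(self) -> np.ndarray:
        return classify_tree_cover(self.tree_cover(), self.agri_mask)


def simulate(P_eff, params: ModelParams, *, delta=None, agri_mask=None,
             seed=None, rng=None, t_pre: int = 300, t_end: int = 500,
             boundary: str = "noflux", include_grass_init: bool = True,
             deterministic_fire: bool = False, snapshot_every: int = 0,
             initial: CoverState | None = None, fire_record_start: int = 0,
             log_every: int = 0) -> SimulationResult:
    """Run the lattice model.

    The run starts from random cover, evolves ``t_pre`` steps without human
    impact (steady state is reached well within 300 steps at the defaults),
    then switches deforestation on until ``t_end``.  Same seed, same
    configuration => bit-identical trajectory.
    """
    if t_end < t_pre:
        raise ValueError("t_end must be >= t_pre")
    P_eff = np.asarray(P_eff, dtype=float)
    shape = P_eff.shape if P_eff.ndim >= 2 else None
    if rng is None:
        rng = np.random.default_rng(seed)
    if initial is not None:
        state = initial.copy()
    else:
        if shape is None:
            raise ValueError("scalar P_eff requires an explicit initial state")
        state = CoverState.random(shape, rng, include_grass=include_grass_init)
    if delta is None:
        delta = np.full(state.shape, np.inf)
    if agri_mask is None:
        agri_mask = np.zeros(state.shape, dtype=bool)
    params.stability_check(include_humans=bool(np.isfinite(np.min(delta))))
    drivers = Drivers.build(np.broadcast_to(P_eff, state.shape), delta, agri_mask, params)

    n_steps = int(round(t_end / params.dt))
    onset = int(round(t_pre / params.dt))
    mean_tc = np.empty(n_steps)
    burned = np.empty(n_steps)
    fire_events = np.zeros(state.shape, dtype=np.int32)
    snapshots, snap_times = [], []

    for i in range(n_steps):
        t = (i + 1) * params.dt
        state, f_eff = step(state, drivers, params, rng,
                            humans_active=(i >= onset),
                            deterministic_fire=deterministic_fire,
                            boundary=boundary)
        events = f_eff > params.fire_event_threshold
        if i >= fire_record_start:
            fire_events += events
        mean_tc[i] = state.tree_cover().mean()
        burned[i] = events.mean()
        if snapshot_every and (i + 1) % snapshot_every == 0:
            snapshots.append(state.copy())
            snap_times.append(t)
        if log_every and (i + 1) % log_every == 0:
            print(f"step {i + 1:5d}  mean tree cover {mean_tc[i]:6.2f}%  "
                  f"burned {burned[i]:.3f}")

    return SimulationResult(
        final=state, params=params,
        times=np.arange(1, n_steps + 1) * params.dt,
        mean_tree_cover=mean_tc, burned_fraction=burned,
        fire_events=fire_events, n_steps=n_steps - fire_record_start,
        snapshots=snapshots, snapshot_times=snap_times,
        agri_mask=np.asarray(agri_mask, dtype=bool),
    )


def local_equilibrium(P_eff: float, params: ModelParams, init: str = "savanna",
                      t_max: float = 3000.0, dt: float = 0.25) -> CoverState:
    """Steady state of the deterministic local (nonspatial, mean-field fire)
    model from a forest-heavy or grass-heavy start.

    Integrated with a small internal Euler step for robustness; used for the
    bistability window, the treeless boundary and front initialisation.
    """
    inits = {
        "forest": (0.9, 0.02, 0.02, 0.05, 0.01),
        "savanna": (0.01, 0.05, 0.05, 0.85, 0.04),
        "grass": (0.0, 0.0, 0.0, 0.95, 0.05),
    }
    if init not in inits:
        raise ValueError(f"unknown init {init!r}")
    p = params.replace(sigma=0.0, D=0.0, dt=dt)
    state = CoverState.uniform((1, 1), inits[init])
    drivers = Drivers.build(np.full((1, 1), float(P_eff)),
                            np.full((1, 1), np.inf),
                            np.zeros((1, 1), dtype=bool), p)
    n = int(round(t_max / dt))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n):
            state, _ = step(state, drivers, p, deterministic_fire=True)
    return state


class FireVegetationModel:
    """Model object binding an environment to the simulator.

    Built from an :class:`~firesavanna.landscape.EnvironmentalFields` plus a
    suitability model (to convert seasonality and soils into effective
    rainfall); ``simulate`` returns a :class:`SimulationResult`.
    """

    def __init__(self, fields, suitability: SuitabilityModel | None = None,
                 params: ModelParams | None = None):
        self.fields = fields
        self.params = params if params is not None else ModelParams()
        if suitability is None:
            suitability = SuitabilityModel.reference().with_soil_reference(
                fields.sand, fields.clay, fields.density)
        self.suitability = suitability
        pi = suitability.soil_pi(fields.sand, fields.clay, fields.density)
        self.P_eff = effective_precip(fields.P, fields.M, pi, suitability,
                                      M_ref=self.params.M_ref)

    def simulate(self, seed=None, **kw) -> SimulationResult:
        return simulate(self.P_eff, self.params,
                        delta=self.fields.delta,
                        agri_mask=self.fields.agri_mask,
                        seed=seed, **kw)
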