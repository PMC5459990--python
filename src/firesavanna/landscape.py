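"""Synthetic environmental fields and climatological indices.

This module generates gridded landscapes with the statistical structure the
downstream analyses assume: a mean-annual-rainfall (MAR) gradient with
spatially correlated noise, an opposing rainfall-seasonality (MSI) gradient,
topsoil texture/bulk-density fields, an agricultural/urban mask placed
preferentially in drier cells, the Euclidean distance-to-agriculture field,
and the three-class human-impact map (agricultural / transition / natural,
with the transition zone extending 3 km from agriculture).

It also implements the two climatological indices used throughout:

* MAR — mean annual rainfall, the mean over years of the annual sums of a
  monthly climatology (mm/yr).
* MSI — Markham's seasonality index: each month m is represented as a vector
  with magnitude the multi-year mean rainfall of that month and phase m*pi/6;
  MSI is the magnitude of the resultant divided by total mean rainfall. It
  lies in [0, 1]; 0 for perfectly even rainfall, 1 when all rain falls in a
  single month.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import ndimage

__all__ = [
    "MonthlyRainfall",
    "LandscapeConfig",
    "EnvironmentalFields",
    "ImpactClass",
    "NO_AGRICULTURE",
    "compute_mar",
    "compute_msi",
    "generate_environment",
    "distance_to_agriculture",
    "classify_impact",
    "correlated_noise",
]

#: Sentinel distance (km) used when the landscape contains no agriculture at
#: all: every cell is then "infinitely far" from human impact.  Documented as
#: np.inf, never silently 0.
NO_AGRICULTURE = np.inf

#: Width of the transition zone around agricultural/urban areas (km).  Cells
#: with 0 < delta <= 3 km are "transition" (inclusive upper bound), beyond
#: that "natural".
TRANSITION_DISTANCE_KM = 3.0


class ImpactClass(enum.IntEnum):
    """Human-impact classes, ordered by decreasing impact."""

    AGRICULTURAL = 0
    TRANSITION = 1
    NATURAL = 2


@dataclass(frozen=True)
class MonthlyRainfall:
    """A monthly rainfall climatology: ``values[y, m]`` in mm for month ``m``
    (0-based column = calendar month 1..12) of year ``y``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.ndim != 2 or v.shape[1] != 12:
            raise ValueError(
                f"monthly rainfall must have exactly 12 columns, got shape {v.shape}"
            )
        if v.shape[0] < 1:
            raise ValueError("need at least one year of monthly rainfall")
        if np.any(v < 0):
            raise ValueError("monthly rainfall must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    def monthly_means(self) -> np.ndarray:
        """Multi-year mean rainfall per calendar month (length 12)."""
        return self.values.mean(axis=0)


def _as_rainfall(rain) -> MonthlyRainfall:
    if isinstance(rain, MonthlyRainfall):
        return rain
    return MonthlyRainfall(np.asarray(rain, dtype=float))


def compute_mar(rain) -> float:
    """Mean annual rainfall (mm/yr): mean over years of the annual sums."""
    r = _as_rainfall(rain)
    return float(r.values.sum(axis=1).mean())


def compute_msi(rain) -> float:
    """Markham seasonality index in [0, 1].

    Months are unit phases m*pi/6 (m = 1..12) weighted by the multi-year mean
    monthly rainfall; MSI is the resultant magnitude over the total.  Raises
    if MAR is zero (the index is undefined, not silently 0/0).
    """
    r = _as_rainfall(rain)
    pbar = r.monthly_means()
    total = pbar.sum()
    if total <= 0:
        raise ValueError("MSI is undefined for zero mean annual rainfall")
    months = np.arange(1, 13)
    phase = months * np.pi / 6.0
    resultant = np.hypot((pbar * np.cos(phase)).sum(), (pbar * np.sin(phase)).sum())
    # Guard float round-off right at the attained bound.
    return float(min(resultant / total, 1.0))


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    The defaults emulate a subcontinental moist-tropics study region: rainfall
    running from a dry edge (~800 mm/yr) to a wet edge (~2600 mm/yr) across
    the grid, seasonality opposing it (dry side more seasonal), spatially
    correlated perturbations on every field, and agriculture biased toward
    the dry side.
    """

    shape: tuple[int, int] = (96, 96)
    cell_size: float = 1.0  # km
    rainfall_range: tuple[float, float] = (800.0, 2600.0)  # mm/yr, axis-1 gradient
    seasonality_range: tuple[float, float] = (0.65, 0.10)  # MSI, same axis
    correlation_length: float = 5.0  # km, e-folding lag of the noise fields
    rainfall_noise: float = 150.0  # mm/yr (1 SD)
    seasonality_noise: float = 0.04
    sand_mean: float = 40.0  # %
    sand_noise: float = 12.0
    clay_mean: float = 30.0  # %
    clay_noise: float = 8.0
    density_mean: float = 1.3  # g/cm^3
    density_noise: float = 0.10
    agri_fraction: float = 0.07  # fraction of cells converted
    dryness_bias: float = 1.0  # weight of (-rainfall) in the placement score

    def __post_init__(self) -> None:
        if not (0.0 <= self.agri_fraction < 1.0):
            raise ValueError("agri_fraction must lie in [0, 1)")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if min(self.shape) < 2:
            raise ValueError("grid must be at least 2x2")


@dataclass
class EnvironmentalFields:
    """Co-registered environmental grids (row-major, distances in km)."""

    P: np.ndarray  # mean annual rainfall, mm/yr
    M: np.ndarray  # Markham seasonality index, [0, 1]
    sand: np.ndarray  # topsoil sand fraction, %
    clay: np.ndarray  # topsoil clay fraction, %
    density: np.ndarray  # topsoil bulk density, g/cm^3
    agri_mask: np.ndarray  # bool
    delta: np.ndarray  # distance to agriculture, km (NO_AGRICULTURE if none)
    impact_class: np.ndarray  # ImpactClass codes
    cell_size: float = 1.0

    _GRIDS = ("P", "M", "sand", "clay", "density", "agri_mask", "delta", "impact_class")

    def validate(self) -> None:
        shapes = {getattr(self, g).shape for g in self._GRIDS}
        if len(shapes) != 1:
            raise ValueError(f"field grids disagree in shape: {shapes}")
        if np.any((self.M < 0) | (self.M > 1)):
            raise ValueError("M must lie in [0, 1]")
        if np.any(self.delta[self.agri_mask] != 0):
            raise ValueError("delta must be exactly 0 on agricultural cells")
        if np.any(self.delta < 0):
            raise ValueError("distances must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.P.shape

    def to_dataset(self) -> xr.Dataset:
        ny, nx = self.shape
        coords = {
            "y": ("y", np.arange(ny) * self.cell_size, {"units": "km"}),
            "x": ("x", np.arange(nx) * self.cell_size, {"units": "km"}),
        }
        data = {
            "P": (("y", "x"), self.P, {"units": "mm yr-1", "long_name": "mean annual rainfall"}),
            "M": (("y", "x"), self.M, {"units": "1", "long_name": "Markham seasonality index"}),
            "sand": (("y", "x"), self.sand, {"units": "percent"}),
            "clay": (("y", "x"), self.clay, {"units": "percent"}),
            "density": (("y", "x"), self.density, {"units": "g cm-3"}),
            "agri_mask": (("y", "x"), self.agri_mask.astype(np.int8)),
            "delta": (("y", "x"), self.delta, {"units": "km"}),
            "impact_class": (("y", "x"), self.impact_class.astype(np.int8),
                             {"flag_values": "0 1 2",
                              "flag_meanings": "agricultural transition natural"}),
        }
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["cell_size_km"] = self.cell_size
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EnvironmentalFields":
        return cls(
            P=ds["P"].values.astype(float),
            M=ds["M"].values.astype(float),
            sand=ds["sand"].values.astype(float),
            clay=ds["clay"].values.astype(float),
            density=ds["density"].values.astype(float),
            agri_mask=ds["agri_mask"].values.astype(bool),
            delta=ds["delta"].values.astype(float),
            impact_class=ds["impact_class"].values.astype(np.int8),
            cell_size=float(ds.attrs.get("cell_size_km", 1.0)),
        )

    def to_netcdf(self, path) -> None:
        # NetCDF3 via the scipy backend; inf sentinels survive as inf.
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvironmentalFields":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def correlated_noise(shape, correlation_length, cell_size, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with autocorrelation exp(-1) at a
    lag of one correlation length.

    Built by Gaussian-kernel smoothing of white noise (wrap mode, so the
    field is statistically stationary); a Gaussian kernel of width sigma
    yields autocorrelation exp(-r^2 / (4 sigma^2)), hence sigma = L/2.
    """
    sigma_px = correlation_length / (2.0 * cell_size)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_px, mode="wrap")
    sd = smooth.std()
    if sd == 0:  # degenerate tiny grid
        return np.zeros(shape)
    return smooth / sd


def distance_to_agriculture(agri_mask: np.ndarray, cell_size: float = 1.0) -> np.ndarray:
    """Per-cell Euclidean distance (km) to the nearest agricultural cell.

    Zero on agricultural cells; ``NO_AGRICULTURE`` (inf) everywhere when the
    mask is empty.
    """
    agri_mask = np.asarray(agri_mask, dtype=bool)
    if not agri_mask.any():
        return np.full(agri_mask.shape, NO_AGRICULTURE)
    return ndimage.distance_transform_edt(~agri_mask, sampling=cell_size)


def classify_impact(delta: np.ndarray, agri_mask: np.ndarray) -> np.ndarray:
    """Three-class human-impact map from the distance field.

    Agricultural cells keep their own class; non-agricultural cells within
    3 km (inclusive) are "transition", beyond 3 km "natural".
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("negative distance in delta grid")
    cls = np.full(delta.shape, ImpactClass.NATURAL, dtype=np.int8)
    cls[delta <= TRANSITION_DISTANCE_KM] = ImpactClass.TRANSITION
    cls[np.asarray(agri_mask, dtype=bool)] = ImpactClass.AGRICULTURAL
    return cls


def generate_environment(cfg: LandscapeConfig, seed=None) -> EnvironmentalFields:
    """Generate a full synthetic landscape; bit-identical for a fixed seed."""
    rng = np.random.default_rng(seed)
    ny, nx = cfg.shape

    # Gradient axis: columns (x).  Rainfall rises left->right; seasonality
    # opposes it (the dry side is the seasonal side).
    ramp = np.linspace(0.0, 1.0, nx)[None, :] * np.ones((ny, 1))

    def noisy(lo_hi, amplitude):
        lo, hi = lo_hi
        base = lo + (hi - lo) * ramp
        if amplitude > 0:
            base = base + amplitude * correlated_noise(
                cfg.shape, cfg.correlation_length, cfg.cell_size, rng
            )
        else:
            # keep the RNG stream aligned regardless of amplitude
            rng.standard_normal(cfg.shape)
        return base

    P = np.clip(noisy(cfg.rainfall_range, cfg.rainfall_noise), 0.0, None)
    M = np.clip(noisy(cfg.seasonality_range, cfg.seasonality_noise), 0.0, 1.0)

    def soil(mean, amplitude, lo, hi):
        f = mean + amplitude * correlated_noise(
            cfg.shape, cfg.correlation_length, cfg.cell_size, rng
        )
        return np.clip(f, lo, hi)

    sand = soil(cfg.sand_mean, cfg.sand_noise, 0.0, 100.0)
    clay = soil(cfg.clay_mean, cfg.clay_noise, 0.0, 100.0)
    density = soil(cfg.density_mean, cfg.density_noise, 0.5, 2.2)

    # Agriculture: threshold a monotone score favouring dry cells.
    agri_mask = np.zeros(cfg.shape, dtype=bool)
    placement_noise = correlated_noise(cfg.shape, cfg.correlation_length, cfg.cell_size, rng)
    if cfg.agri_fraction > 0:
        p_sd = P.std()
        z_dry = -(P - P.mean()) / (p_sd if p_sd > 0 else 1.0)
        score = cfg.dryness_bias * z_dry + placement_noise
        n_agri = int(round(cfg.agri_fraction * P.size))
        if n_agri > 0:
            cut = np.partition(score.ravel(), -n_agri)[-n_agri]
            agri_mask = score >= cut

    delta = distance_to_agriculture(agri_mask, cfg.cell_size)
    impact = classify_impact(delta, agri_mask)

    fields = EnvironmentalFields(
        P=P, M=M, sand=sand, clay=clay, density=density,
        agri_mask=agri_mask, delta=delta, impact_class=impact,
        cell_size=cfg.cell_size,
    )
    fields.validate()
    return fields
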