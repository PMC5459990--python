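"""Tree-cover bimodality, fire-frequency and percolation analyses.

These are the raster-analysis procedures applied to simulated landscapes
(or, with identical code paths, to any co-registered grids): stratified
sampling of tree cover along the climatic-edaphic forest suitability (CEFS)
axis, 2-D binned median tree-cover change, quantification of the CEFS range
over which forest and savanna states overlap per human-impact class,
fire frequency as a function of tree cover, and a Monte-Carlo estimator of
the 2-D site-percolation threshold that motivates the 40% forest/savanna
tree-cover cut (fire percolates through the grass layer; the spanning
threshold of ~59% grass cover corresponds to ~41% tree cover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .landscape import ImpactClass

__all__ = [
    "stratified_sample",
    "BinnedChange",
    "binned_median_change",
    "overlap_range",
    "fire_frequency_by_cover",
    "PercolationEstimate",
    "spanning_probability",
    "estimate_percolation_threshold",
    "tree_cover_fire_threshold",
]

_CLASS_NAMES = {int(c): c.name.lower() for c in ImpactClass}


def stratified_sample(cefs, tree_cover, impact_class, rng=None, *,
                      n_per_bin: int = 100, n_bins: int = 50,
                      cefs_range=(-7.5, 5.0), extra=None) -> pd.DataFrame:
    """Random spatial sample stratified on CEFS, separately per impact class.

    Up to ``n_per_bin`` cells are drawn uniformly without replacement from
    each of ``n_bins`` consecutive CEFS intervals within ``cefs_range``, for
    each impact class present; bins with fewer eligible cells contribute all
    of them.  ``extra`` maps column names to additional co-registered grids
    (e.g. tree-cover change).  Deterministic for a fixed rng state.
    """
    lo, hi = map(float, cefs_range)
    if not hi > lo:
        raise ValueError("empty CEFS range")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cefs = np.asarray(cefs, dtype=float).ravel()
    tc = np.asarray(tree_cover, dtype=float).ravel()
    cls = np.asarray(impact_class).ravel()
    extra = {k: np.asarray(v).ravel() for k, v in (extra or {}).items()}

    edges = np.linspace(lo, hi, n_bins + 1)
    bin_of = np.digitize(cefs, edges) - 1  # -1 and n_bins mark out-of-range
    rows = []
    for c in np.unique(cls):
        in_class = cls == c
        for b in range(n_bins):
            pool = np.flatnonzero(in_class & (bin_of == b))
            if pool.size == 0:
                continue
            if pool.size > n_per_bin:
                pool = rng.choice(pool, size=n_per_bin, replace=False)
            rows.append(pool)
    if not rows:
        return pd.DataFrame(columns=["cell_index", "cefs", "tree_cover",
                                     "impact_class", *extra])
    idx = np.concatenate(rows)
    out = pd.DataFrame({
        "cell_index": idx,
        "cefs": cefs[idx],
        "tree_cover": tc[idx],
        "impact_class": cls[idx],
    })
    for k, v in extra.items():
        out[k] = v[idx]
    return out


@dataclass
class BinnedChange:
    """Median tree-cover change on a 2-D (CEFS, initial tree cover) grid.

    Medians are only reported where a bin holds at least ``min_count``
    cells (the validity mask); sparser bins are NaN."""

    cefs_edges: np.ndarray
    tc_edges: np.ndarray
    median_change: np.ndarray  # (n_cefs_bins, n_tc_bins), NaN where invalid
    count: np.ndarray
    min_count: int

    @property
    def valid(self) -> np.ndarray:
        return self.count >= self.min_count

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lim = np.nanmax(np.abs(self.median_change)) if self.valid.any() else 1.0
        mesh = ax.pcolormesh(self.cefs_edges, self.tc_edges,
                             self.median_change.T, cmap="RdYlGn",
                             vmin=-lim, vmax=lim, shading="flat")
        ax.set_xlabel("CEFS")
        ax.set_ylabel("tree cover (%)")
        plt.colorbar(mesh, ax=ax, label="median change (% points)")
        return ax


def binned_median_change(tc_t0, tc_t1, cefs, *, cefs_bin: float = 0.25,
                         tc_bin: float = 3.0, min_count: int = 200,
                         cefs_range=(-7.5, 5.0),
                         tc_range=(0.0, 100.0)) -> BinnedChange:
    """Median of (tc_t1 - tc_t0), in percentage points, per 2-D bin of
    (CEFS, initial tree cover)."""
    tc0 = np.asarray(tc_t0, dtype=float).ravel()
    tc1 = np.asarray(tc_t1, dtype=float).ravel()
    cf = np.asarray(cefs, dtype=float).ravel()
    change = tc1 - tc0
    cefs_edges = np.arange(cefs_range[0], cefs_range[1] + cefs_bin / 2, cefs_bin)
    tc_edges = np.arange(tc_range[0], tc_range[1] + tc_bin / 2, tc_bin)
    ni, nj = cefs_edges.size - 1, tc_edges.size - 1
    bi = np.digitize(cf, cefs_edges) - 1
    bj = np.digitize(tc0, tc_edges) - 1
    ok = (bi >= 0) & (bi < ni) & (bj >= 0) & (bj < nj)
    med = np.full((ni, nj), np.nan)
    cnt = np.zeros((ni, nj), dtype=int)
    flat = bi[ok] * nj + bj[ok]
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    change_sorted = change[ok][order]
    starts = np.flatnonzero(np.r_[True, np.diff(flat_sorted) > 0])
    bounds = np.r_[starts, flat_sorted.size]
    for s, e in zip(bounds[:-1], bounds[1:]):
        cell = flat_sorted[s]
        i, j = divmod(int(cell), nj)
        cnt[i, j] = e - s
        if e - s >= min_count:
            med[i, j] = np.median(change_sorted[s:e])
    return BinnedChange(cefs_edges, tc_edges, med, cnt, min_count)


def overlap_range(sample: pd.DataFrame, *, min_frac: float = 0.1,
                  bin_width: float = 0.25,
                  cefs_range=(-7.5, 5.0)) -> dict:
    """Per impact class, the maximal contiguous CEFS interval in which both
    forest (tree cover > 40%) and savanna (5-40%) each exceed ``min_frac``
    of the bin's samples.  Classes with no such bin map to None.

    The minimum-frequency rule operationalises reading state coexistence
    off a scatterplot; sensitivity to ``min_frac`` is discussed in the docs.
    """
    edges = np.arange(cefs_range[0], cefs_range[1] + bin_width / 2, bin_width)
    out: dict = {}
    for c, grp in sample.groupby("impact_class"):
        tc = grp["tree_cover"].to_numpy(dtype=float)
        b = np.digitize(grp["cefs"].to_numpy(dtype=float), edges) - 1
        nb = edges.size - 1
        both = np.zeros(nb, dtype=bool)
        for k in range(nb):
            sel = b == k
            n = sel.sum()
            if n == 0:
                continue
            f_forest = (tc[sel] > 40.0).mean()
            f_savanna = ((tc[sel] >= 5.0) & (tc[sel] <= 40.0)).mean()
            both[k] = (f_forest >= min_frac) and (f_savanna >= min_frac)
        key = _CLASS_NAMES.get(int(c), c)
        if not both.any():
            out[key] = None
            continue
        # longest contiguous run of coexistence bins
        best_len, best_start, run, start = 0, 0, 0, 0
        for k in range(nb):
            if both[k]:
                if run == 0:
                    start = k
                run += 1
                if run > best_len:
                    best_len, best_start = run, start
            else:
                run = 0
        out[key] = (float(edges[best_start]), float(edges[best_start + best_len]))
    return out


def overlap_width(interval) -> float:
    """Width of an overlap interval; 0 for None."""
    return 0.0 if interval is None else interval[1] - interval[0]


def fire_frequency_by_cover(fire_events, n_steps: int, tree_cover, *,
                            tc_bin: float = 3.0) -> pd.DataFrame:
    """Mean fraction of cell-years with a burn, per tree-cover bin.

    ``fire_events`` counts, per cell, the steps whose effective fire
    exceeded the event threshold; ``n_steps`` is the number of recorded
    steps (at least 10)."""
    if n_steps < 10:
        raise ValueError("need at least 10 recorded steps")
    ev = np.asarray(fire_events, dtype=float).ravel() / n_steps
    tc = np.asarray(tree_cover, dtype=float).ravel()
    edges = np.arange(0.0, 100.0 + tc_bin / 2, tc_bin)
    b = np.digitize(tc, edges) - 1
    b = np.clip(b, 0, edges.size - 2)
    rows = []
    for k in range(edges.size - 1):
        sel = b == k
        rows.append({
            "tc_mid": 0.5 * (edges[k] + edges[k + 1]),
            "frequency": ev[sel].mean() if sel.any() else np.nan,
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Site percolation


@dataclass
class PercolationEstimate:
    """Estimated occupation density with spanning probability 0.5."""

    density: float
    se: float
    lattice_n: int
    reps: int
    warning: str | None = None


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def spanning_probability(density: float, shape, rng, reps: int) -> float:
    """Monte-Carlo probability that random occupancy at the given density
    spans top-to-bottom (4-neighbour connectivity, open boundaries)."""
    if len(shape) == 1:
        # 1-D chain: spanning iff every site is occupied
        occ = rng.random((reps,) + tuple(shape)) < density
        return float(occ.all(axis=1).mean())
    hits = 0
    for _ in range(reps):
        occ = rng.random(shape) < density
        labels, n = ndimage.label(occ, structure=_STRUCT4)
        if n == 0:
            continue
        top = np.unique(labels[0])
        bottom = np.unique(labels[-1])
        if np.intersect1d(top[top > 0], bottom[bottom > 0]).size:
            hits += 1
    return hits / reps


def estimate_percolation_threshold(lattice_n: int = 256, reps: int = 200,
                                   rng=None, *, bracket=(0.45, 0.75),
                                   n_sweep: int = 9) -> PercolationEstimate:
    """Occupation density at which the spanning probability is 0.5 on an
    n x n square lattice (site percolation, nearest neighbours).

    A short bisection with half the replicates narrows the bracket, then the
    spanning probability is swept on a local density grid and a logistic
    curve is fitted; the estimate is its 0.5 crossing, the standard error
    comes from the fit covariance.  The literature value for the infinite
    lattice is ~0.5927.
    """
    if lattice_n < 64:
        raise ValueError("lattice_n must be at least 64")
    warning = None
    if reps < 20:
        warning = f"reps={reps} is small; the estimate will be imprecise"
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    shape = (lattice_n, lattice_n)

    lo, hi = map(float, bracket)
    for _ in range(5):
        mid = 0.5 * (lo + hi)
        if spanning_probability(mid, shape, rng, max(reps // 2, 10)) < 0.5:
            lo = mid
        else:
            hi = mid

    centre = 0.5 * (lo + hi)
    width = max(hi - lo, 0.02)
    grid = np.linspace(centre - width, centre + width, n_sweep)
    probs = np.array([spanning_probability(p, shape, rng, reps) for p in grid])

    def f(x, x0, k):
        return 1.0 / (1.0 + np.exp(-k * (x - x0)))

    try:
        popt, pcov = curve_fit(f, grid, probs, p0=(centre, 100.0), maxfev=10000)
        density = float(popt[0])
        se = float(np.sqrt(pcov[0, 0]))
    except RuntimeError:
        density = float(np.interp(0.5, probs, grid))
        se = width / np.sqrt(n_sweep)
        warning = (warning or "") + " logistic fit failed; linear interpolation used"
    return PercolationEstimate(density, se, lattice_n, reps, warning)


def tree_cover_fire_threshold(percolation_density: float,
                              rounded: bool = True):
    """Tree-cover percentage complementary to the grass-layer percolation
    density: fire stops percolating once tree cover exceeds
    100*(1 - density) percent."""
    if not 0.0 < percolation_density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    value = 100.0 * (1.0 - percolation_density)
    return int(round(value)) if rounded else value
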