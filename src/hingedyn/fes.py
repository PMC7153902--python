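"""Free-energy-surface estimation from CV time series.

Pipeline: a Gaussian-kernel (binned KDE) histogram of the samples in CV
space, optional reweighting of metadynamics bias (w_i proportional to
exp(+V(s_i)/k_B T) with V the final accumulated bias), then
F = -k_B T ln(rho), min-shifted so the lowest visited cell is 0.
Unvisited cells are masked, never reported as zero.  Convergence is
assessed by recomputing the surface on truncated series (checkpoints),
statistical errors per basin by block averaging, and barriers between
basins by a minimax grid path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .hinge_model import KB
from .model_io import CVSeries, HingedynError

__all__ = [
    "FreeEnergySurface",
    "ReweightResult",
    "BasinEstimate",
    "DisconnectedBasinsError",
    "grid_edges",
    "kde_histogram",
    "reweight_biased",
    "density_to_fes",
    "fes_checkpoints",
    "basin_errors",
    "barrier_between",
    "find_minimum",
    "write_fes_dat",
]


class DisconnectedBasinsError(HingedynError):
    """No path through visited cells connects the two basins."""


@dataclass
class FreeEnergySurface:
    """Gridded free energy (kJ/mol) over 1-2 CVs, min-shifted.

    ``mask`` flags unvisited cells (True = unvisited); the minimum over
    visited cells is shifted to exactly 0 on construction.
    """

    names: list[str]
    units: list[str]
    edges: list[np.ndarray]
    values: np.ndarray
    temperature: float
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != len(self.edges):
            raise ValueError("one edge array per FES dimension")
        for d, e in enumerate(self.edges):
            if len(e) != self.values.shape[d] + 1:
                raise ValueError(f"edges[{d}] must have n_cells+1 entries")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if self.mask.all():
            raise ValueError("free energy surface has no visited cells")
        vis = self.values[~self.mask]
        self.values = self.values - vis.min()
        self.values[self.mask] = np.nan

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def centers(self, dim: int = 0) -> np.ndarray:
        e = self.edges[dim]
        return 0.5 * (e[1:] + e[:-1])

    def minimum_location(self, window=None) -> tuple[tuple[float, ...], float]:
        """Grid location and value of the lowest visited cell.

        ``window`` optionally restricts the search to per-CV (lo, hi)
        ranges.
        """
        return find_minimum(self, window)


@dataclass(frozen=True)
class ReweightResult:
    """Unbiasing weights (normalized to mean 1) and effective sample size."""

    weights: np.ndarray
    n_eff: float


@dataclass(frozen=True)
class BasinEstimate:
    """Free energy of a basin with its block-averaged standard error."""

    free_energy: float   # kJ/mol, -kT ln (weighted occupancy), min over data
    error: float         # kJ/mol, standard error over blocks
    n_blocks_used: int
    n_blocks_total: int


def grid_edges(ranges: Sequence[tuple[float, float]], bins) -> list[np.ndarray]:
    """Per-CV bin edge arrays; ``bins`` is an int (shared) or per-CV list."""
    if isinstance(bins, int):
        bins = [bins] * len(ranges)
    return [np.linspace(lo, hi, b + 1) for (lo, hi), b in zip(ranges, bins)]


def _series_points(series: CVSeries, cv_names: Sequence[str] | None) -> tuple[np.ndarray, list[str], list[str]]:
    if cv_names is None:
        cv_names = [n for n in series.names if n != "bias"]
    cols = [series.column(n) for n in cv_names]
    units = [series.units[series.names.index(n)] for n in cv_names]
    return np.stack(cols, axis=1), list(cv_names), units


def kde_histogram(
    series: CVSeries,
    weights: np.ndarray | None = None,
    edges: list[np.ndarray] | None = None,
    bandwidth: Sequence[float] | float | None = None,
    cv_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Gaussian-kernel density of the samples on a grid.

    A weighted histogram on ``edges`` smoothed with a Gaussian kernel of
    per-CV ``bandwidth`` (same units as the CV; default: one grid spacing).
    The result is normalized so the cell masses sum to 1.
    """
    from scipy.ndimage import gaussian_filter

    if series.n_rows == 0:
        raise ValueError("cannot build a density from an empty series")
    pts, names, _ = _series_points(series, cv_names)
    if edges is None:
        raise ValueError("grid edges are required")
    if len(edges) != pts.shape[1]:
        raise ValueError("one edge array per CV")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape[0] != series.n_rows:
            raise ValueError("weights length must equal the series length")
    hist, _ = np.histogramdd(pts, bins=edges, weights=weights)
    spacing = [e[1] - e[0] for e in edges]
    if bandwidth is None:
        bandwidth = spacing
    elif np.isscalar(bandwidth):
        bandwidth = [float(bandwidth)] * len(edges)
    sigma_bins = [b / s for b, s in zip(bandwidth, spacing)]
    dens = gaussian_filter(hist, sigma=sigma_bins, mode="constant")
    total = dens.sum()
    if total <= 0:
        raise ValueError("no samples fell inside the grid")
    return dens / total


def reweight_biased(
    series: CVSeries,
    temperature: float,
    mode: str = "final-bias",
    bias=None,
    cv_names: Sequence[str] | None = None,
) -> ReweightResult:
    """Unbiasing weights w_i ~ exp(+V(s_i)/k_B T) for a biased series.

    ``mode="final-bias"`` evaluates the *final* accumulated bias (a
    :class:`~hingedyn.metadynamics.BiasState`) at each sample -- the
    standard static-bias estimator for a converged well-tempered run.
    ``mode="instantaneous"`` uses the recorded per-frame bias column
    instead.  Weights are normalized to mean 1; the effective sample size
    (sum w)^2 / sum w^2 is reported alongside.
    """
    kt = KB * temperature
    if mode == "final-bias":
        if bias is None:
            raise ValueError("mode='final-bias' needs the final BiasState")
        bias_names = {
            "theta_rad": "theta",  # recorded in degrees; CV is radians
        }
        cols = []
        for name in bias.cv_names:
            src = bias_names.get(name, name)
            col = series.column(src)
            if name == "theta_rad":
                col = np.radians(col)
            cols.append(col)
        pts = np.stack(cols, axis=1)
        v = bias.value_at(pts)
    elif mode == "instantaneous":
        v = series.column("bias")
    else:
        raise ValueError(f"unknown reweighting mode {mode!r}")
    v = v - v.max()          # numerical guard; weights are normalized anyway
    w = np.exp(v / kt)
    w = w / w.mean()
    n_eff = float(w.sum() ** 2 / (w ** 2).sum())
    return ReweightResult(weights=w, n_eff=n_eff)


def density_to_fes(
    density: np.ndarray,
    edges: list[np.ndarray],
    temperature: float,
    names: Sequence[str] | None = None,
    units: Sequence[str] | None = None,
    min_mass: float = 0.0,
) -> FreeEnergySurface:
    """F = -k_B T ln(rho) on visited cells, min-shifted; unvisited masked."""
    density = np.asarray(density, dtype=float)
    if density.sum() <= 0:
        raise ValueError("density is identically zero")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    thresh = max(min_mass, 0.0)
    mask = density <= thresh
    if mask.all():
        raise ValueError("no cell exceeds the visitation threshold")
    values = np.full(density.shape, np.nan)
    with np.errstate(divide="ignore"):
        values[~mask] = -KB * temperature * np.log(density[~mask])
    ndim = density.ndim
    names = list(names) if names is not None else [f"cv{i+1}" for i in range(ndim)]
    units = list(units) if units is not None else ["dimensionless"] * ndim
    return FreeEnergySurface(names=names, units=units, edges=list(edges),
                             values=values, temperature=temperature,
                             mask=mask)


def fes_checkpoints(
    series: CVSeries,
    times: Sequence[float],
    fes_builder: Callable[[CVSeries], FreeEnergySurface],
) -> tuple[list[FreeEnergySurface], np.ndarray | None]:
    """FES on the series truncated at each checkpoint time.

    ``fes_builder`` maps a (truncated) CVSeries to a FreeEnergySurface so
    the caller controls reweighting and gridding.  Returns the surfaces and
    the matrix of max |Delta F| over cells visited in *all* checkpoints
    (None for a single checkpoint).
    """
    times = list(times)
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("checkpoint times must be increasing")
    if times and times[0] < series.times[0]:
        raise ValueError("checkpoint before the first sample")
    surfaces = []
    for t in times:
        n = int(np.searchsorted(series.times, t, side="right"))
        if n == 0:
            raise ValueError(f"no samples at or before checkpoint t={t}")
        sub = CVSeries(names=list(series.names), units=list(series.units),
                       times=series.times[:n], values=series.values[:n])
        surfaces.append(fes_builder(sub))
    if len(surfaces) < 2:
        return surfaces, None
    common = ~surfaces[0].mask
    for s in surfaces[1:]:
        common &= ~s.mask
    k = len(surfaces)
    dev = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if common.any():
                d = np.nanmax(np.abs(surfaces[i].values[common]
                                     - surfaces[j].values[common]))
            else:
                d = np.nan
            dev[i, j] = dev[j, i] = d
    return surfaces, dev


def basin_errors(
    series: CVSeries,
    weights: np.ndarray | None,
    basins: dict[str, Sequence[tuple[float, float]]],
    n_blocks: int = 5,
    temperature: float = 300.0,
    cv_names: Sequence[str] | None = None,
) -> dict[str, BasinEstimate]:
    """Per-basin free energy with block-averaged standard errors.

    Basins are rectangular CV ranges.  The series is split into
    ``n_blocks`` contiguous blocks; each block's basin free energy is
    -k_B T ln of its weighted occupancy, and the reported error is the
    standard error over blocks (blocks that never visit the basin are
    excluded and counted).  The central value uses the full series.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    pts, names, _ = _series_points(series, cv_names)
    n = pts.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    kt = KB * temperature
    bounds = np.array_split(np.arange(n), n_blocks)
    out: dict[str, BasinEstimate] = {}
    for name, ranges in basins.items():
        ranges = list(ranges)
        if len(ranges) != pts.shape[1]:
            raise ValueError(
                f"basin {name!r}: need one (lo, hi) range per CV"
            )
        inside = np.ones(n, dtype=bool)
        for d, (lo, hi) in enumerate(ranges):
            inside &= (pts[:, d] >= lo) & (pts[:, d] <= hi)
        occ_total = weights[inside].sum() / weights.sum()
        if occ_total <= 0:
            raise ValueError(f"basin {name!r} is never visited")
        f_total = -kt * math.log(occ_total)
        block_f = []
        for idx in bounds:
            wsum = weights[idx].sum()
            occ = weights[idx][inside[idx]].sum() / wsum if wsum > 0 else 0.0
            if occ > 0:
                block_f.append(-kt * math.log(occ))
        used = len(block_f)
        if used >= 2:
            err = float(np.std(block_f, ddof=1) / math.sqrt(used))
        else:
            err = float("nan")
        out[name] = BasinEstimate(free_energy=f_total, error=err,
                                  n_blocks_used=used,
                                  n_blocks_total=n_blocks)
    return out


# ---------------------------------------------------------------------------
# barriers: minimax path over the grid
# ---------------------------------------------------------------------------

def find_minimum(fes: FreeEnergySurface, window=None) -> tuple[tuple[float, ...], float]:
    """(CV coordinates, F) of the lowest visited cell, optionally windowed."""
    values = np.where(fes.mask, np.inf, np.nan_to_num(fes.values, nan=np.inf))
    if window is not None:
        sel = np.ones(values.shape, dtype=bool)
        grids = np.meshgrid(*[fes.centers(d) for d in range(fes.ndim)],
                            indexing="ij")
        for d, rng in enumerate(window):
            if rng is None:
                continue
            lo, hi = rng
            sel &= (grids[d] >= lo) & (grids[d] <= hi)
        values = np.where(sel, values, np.inf)
    if not np.isfinite(values).any():
        raise ValueError("no visited cells in the requested window")
    flat = int(np.argmin(values))
    idx = np.unravel_index(flat, values.shape)
    coords = tuple(float(fes.centers(d)[idx[d]]) for d in range(fes.ndim))
    return coords, float(values[idx])


def _cell_index(fes: FreeEnergySurface, window) -> tuple[int, ...]:
    values = np.where(fes.mask, np.inf, np.nan_to_num(fes.values, nan=np.inf))
    sel = np.ones(values.shape, dtype=bool)
    grids = np.meshgrid(*[fes.centers(d) for d in range(fes.ndim)],
                        indexing="ij")
    for d, (lo, hi) in enumerate(window):
        sel &= (grids[d] >= lo) & (grids[d] <= hi)
    values = np.where(sel, values, np.inf)
    if not np.isfinite(values).any():
        raise ValueError(f"basin window {window} contains no visited cells")
    return tuple(int(i) for i in
                 np.unravel_index(int(np.argmin(values)), values.shape))


def barrier_between(
    fes: FreeEnergySurface,
    basin_a: Sequence[tuple[float, float]],
    basin_b: Sequence[tuple[float, float]],
) -> float:
    """Minimax-path barrier (kJ/mol) between two basins.

    The minimum over all 4-connected grid paths between the basin minima of
    the maximum F along the path, minus the lower of the two basin minima.
    Deterministic Kruskal/union-find construction: cells are activated in
    order of increasing F until the two minima become connected; the F of
    the activating cell is the pass height.  Invariant to adding a
    constant to F.
    """
    a_idx = _cell_index(fes, basin_a)
    b_idx = _cell_index(fes, basin_b)
    values = np.nan_to_num(fes.values, nan=np.inf)
    values = np.where(fes.mask, np.inf, values)
    shape = values.shape
    flat = values.reshape(-1)
    order = np.argsort(flat, kind="stable")

    parent = np.full(flat.shape[0], -1, dtype=np.int64)  # -1 = inactive

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    a_flat = int(np.ravel_multi_index(a_idx, shape))
    b_flat = int(np.ravel_multi_index(b_idx, shape))
    lower_min = min(float(flat[a_flat]), float(flat[b_flat]))

    if fes.ndim == 1:
        neighbor_steps = [(-1,), (1,)]
    else:
        neighbor_steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    for flat_i in order:
        fval = flat[flat_i]
        if not np.isfinite(fval):
            break
        parent[flat_i] = flat_i
        idx = np.unravel_index(int(flat_i), shape)
        for step in neighbor_steps:
            nb = tuple(i + s for i, s in zip(idx, step))
            if any(not 0 <= i < n for i, n in zip(nb, shape)):
                continue
            nb_flat = int(np.ravel_multi_index(nb, shape))
            if parent[nb_flat] != -1:
                ra, rb = find(int(flat_i)), find(nb_flat)
                if ra != rb:
                    parent[ra] = rb
        if parent[a_flat] != -1 and parent[b_flat] != -1 \
                and find(a_flat) == find(b_flat):
            return float(fval) - lower_min
    raise DisconnectedBasinsError(
        "the two basins are not connected through visited cells"
    )


def write_fes_dat(fes: FreeEnergySurface, path: str) -> None:
    """PLUMED fes.dat-like gridded text: cv columns then F, first CV fastest."""
    from .model_io import NUMERIC_FMT

    centers = [fes.centers(d) for d in range(fes.ndim)]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fes.names) + " free_energy\n")
        for n, u in zip(fes.names, fes.units):
            fh.write(f"#! SET unit_{n} {u}\n")
        if fes.ndim == 1:
            for x, f in zip(centers[0], fes.values):
                fh.write((NUMERIC_FMT % x) + " " + (NUMERIC_FMT % f) + "\n")
        else:
            for j, y in enumerate(centers[1]):
                for i, x in enumerate(centers[0]):
                    fh.write(" ".join(NUMERIC_FMT % v
                                      for v in (x, y, fes.values[i, j]))
                             + "\n")
                fh.write("\n")
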