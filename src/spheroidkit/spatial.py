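"""Radial structure of spheroids and the random-cell-position null model.

Local cell density (PCG degree) is profiled against the normalized distance
to the surface (NDS) in equal-width bins.  Medium and large spheroids show
two concentric layers: a thin *surface* band (NDS below ~0.1) where density
rises, a dense *outer* region, and a sparser *core*; the outer/core boundary
sits near NDS 0.75 (medium) or 0.5 (large).  The outer-region thickness is
the depth of that boundary from the surface, ``core_cut * mean_radius``.

The random-cell-position (RCP) model places the same number of cells as the
real dataset uniformly inside the dataset's alpha shape as non-overlapping
spheres (radius = median nucleus radius, ~6 voxels).  Its density profile is
flat in the interior, so a real profile deviating from the RCP ensemble by
more than the ensemble spread demonstrates non-random cell arrangement.

Dataset-level analyses: partitioning-around-medoids clustering of
(cell number, spheroid volume) into size groups, and the ordinary
least-squares volume-per-cell fit.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import stats

from .geometry import SurfaceModel, depth_from_surface
from .graphs import build_pcg

__all__ = [
    "RadialProfile",
    "RegionAssignment",
    "RcpSpec",
    "radial_profile",
    "summarize_regions",
    "rcp_sample",
    "rcp_profile_ensemble",
    "cluster_datasets",
    "pam",
    "fit_volume_cell_line",
    "round_half_away",
    "suggest_core_cut",
]


@dataclasses.dataclass
class RadialProfile:
    """Binned feature-vs-NDS profile with standard errors.

    ``mean``/``se`` are NaN for empty bins; ``n`` sums to the number of
    observations.
    """

    bin_edges: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclasses.dataclass
class RegionAssignment:
    """Surface/outer/core partition of nuclei by NDS and derived sizes."""

    surface_cut: float
    core_cut: float
    labels: np.ndarray  # strings: surface | outer | core
    mean_density: dict
    mean_radius_um: float
    outer_thickness_um: float


@dataclasses.dataclass
class RcpSpec:
    """Random-cell-position model parameters.

    ``sphere_radius`` defaults to the median nucleus radius (~6 voxels);
    ``n_reps`` to the customary ten Monte Carlo replicates.
    """

    n_cells: int
    sphere_radius: float = 6.0
    n_reps: int = 10
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (reporting convention for um values)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def radial_profile(values: np.ndarray, nds: np.ndarray, n_bins: int = 20) -> RadialProfile:
    """Mean and standard error of a per-nucleus feature in equal NDS bins."""
    values = np.asarray(values, dtype=np.float64)
    nds = np.asarray(nds, dtype=np.float64)
    if values.shape != nds.shape:
        raise ValueError("values and nds must align")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(nds, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = values[idx == b]
        n[b] = len(sel)
        if len(sel):
            mean[b] = sel.mean()
            se[b] = sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else 0.0
    return RadialProfile(edges, mean, se, n)


def summarize_regions(
    nds: np.ndarray,
    density: np.ndarray,
    max_depth_um: float,
    surface_cut: float = 0.1,
    core_cut: float = 0.75,
) -> RegionAssignment:
    """Partition nuclei into surface/outer/core regions by NDS.

    Regions are the intervals [0, surface_cut), [surface_cut, core_cut) and
    [core_cut, 1].  ``max_depth_um`` is the dataset's maximum depth (the
    NDS normalizer) in micrometres, read as the mean spheroid radius; the
    outer-region thickness is ``core_cut * mean_radius`` — the depth of the
    outer/core boundary below the surface.
    """
    if core_cut <= surface_cut:
        raise ValueError("core_cut must exceed surface_cut")
    nds = np.asarray(nds, dtype=np.float64)
    density = np.asarray(density, dtype=np.float64)
    labels = np.where(nds < surface_cut, "surface", np.where(nds < core_cut, "outer", "core"))
    mean_density = {
        region: (density[labels == region].mean() if (labels == region).any() else np.nan)
        for region in ("surface", "outer", "core")
    }
    return RegionAssignment(
        surface_cut=surface_cut,
        core_cut=core_cut,
        labels=labels,
        mean_density=mean_density,
        mean_radius_um=max_depth_um,
        outer_thickness_um=core_cut * max_depth_um,
    )


def suggest_core_cut(profile: RadialProfile, min_nds: float = 0.2) -> float:
    """Heuristic outer/core transition point of a density profile.

    Returns the bin centre with the largest absolute second difference of
    the lightly smoothed bin means, restricted to NDS >= ``min_nds`` (the
    surface rise is excluded).  A convenience only — the published region
    cuts were chosen manually from the curves and remain user-supplied.
    """
    mean = np.asarray(profile.mean, dtype=np.float64)
    centers = profile.bin_centers
    valid = ~np.isnan(mean)
    if valid.sum() < 5:
        raise ValueError("profile too sparse for a change-point suggestion")
    m = mean.copy()
    m[~valid] = np.interp(centers[~valid], centers[valid], mean[valid])
    smooth = np.convolve(m, [0.25, 0.5, 0.25], mode="same")
    d2 = np.abs(np.diff(smooth, 2))
    inner = centers[1:-1]
    ok = inner >= min_nds
    return float(inner[ok][int(np.argmax(d2[ok]))])


def rcp_sample(surface: SurfaceModel, spec: RcpSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """One replicate of the RCP model: uniform non-overlapping spheres.

    Points are drawn uniformly in the alpha shape's bounding box, accepted
    if inside the shape and at least ``2 * sphere_radius`` from all accepted
    points (rejection sampling).  Raises if packing stalls for
    ``max_attempts`` consecutive rejections.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo = surface.points.min(axis=0)
    hi = surface.points.max(axis=0)
    min_dist2 = (2.0 * spec.sphere_radius) ** 2
    accepted: list[np.ndarray] = []
    rejections = 0
    # vectorized proposals in batches for speed
    while len(accepted) < spec.n_cells:
        batch = rng.uniform(lo, hi, size=(256, 3))
        inside = surface.contains(batch)
        for p, ok in zip(batch, inside):
            if len(accepted) >= spec.n_cells:
                break
            if not ok:
                rejections += 1
            else:
                arr = np.asarray(accepted)
                if len(arr) and (np.sum((arr - p) ** 2, axis=1) < min_dist2).any():
                    rejections += 1
                else:
                    accepted.append(p)
                    rejections = 0
                    continue
            if rejections >= spec.max_attempts:
                raise RuntimeError(
                    f"packing infeasible: placed {len(accepted)} of {spec.n_cells} spheres"
                )
    return np.asarray(accepted)


def rcp_profile_ensemble(
    surface: SurfaceModel,
    spec: RcpSpec,
    edge_distance_threshold: float = 40.0,
    n_bins: int = 20,
) -> tuple[RadialProfile, list[np.ndarray]]:
    """Pooled density-vs-NDS profile over RCP replicates.

    Each replicate is sampled, its proximity graph built, the vertex degrees
    (local density) profiled against the replicate's NDS; per-bin means are
    pooled over replicates (mean of replicate means, SE across replicates).
    Returns the pooled profile and the list of replicate point sets.
    """
    rng = np.random.default_rng(spec.seed)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    per_rep = np.full((spec.n_reps, n_bins), np.nan)
    samples = []
    for rep in range(spec.n_reps):
        pts = rcp_sample(surface, spec, rng=rng)
        samples.append(pts)
        g = build_pcg(pts, threshold=edge_distance_threshold)
        degrees = np.array([g.graph.degree[i] for i in range(len(pts))], dtype=float)
        _, nds = depth_from_surface(pts, surface)
        prof = radial_profile(degrees, nds, n_bins=n_bins)
        per_rep[rep] = prof.mean
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(per_rep, axis=0)
        n_valid = np.sum(~np.isnan(per_rep), axis=0)
        sd = np.nanstd(per_rep, axis=0, ddof=1)
        se = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), np.nan)
    n = np.sum(~np.isnan(per_rep), axis=0)
    return RadialProfile(edges, mean, se, n), samples


def _pam_cost(d2: np.ndarray, medoids: tuple[int, ...]) -> float:
    return float(d2[:, list(medoids)].min(axis=1).sum())


def pam(features: np.ndarray, k: int, standardize: bool = True, seed: int = 0) -> np.ndarray:
    """Partitioning around medoids with squared Euclidean dissimilarity.

    Features are z-scored by default (raw cell counts and volumes differ by
    orders of magnitude).  For n <= 20 the optimal medoid set is found by
    exhaustive search, making the result deterministic; larger instances use
    the classic BUILD + SWAP heuristic.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if k > n:
        raise ValueError("k must not exceed the number of datasets")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.sum(diff**2, axis=2)

    if n <= 20:
        best = min(itertools.combinations(range(n), k), key=lambda m: (_pam_cost(d2, m), m))
    else:
        medoids = [int(np.argmin(d2.sum(axis=1)))]
        while len(medoids) < k:
            cur = d2[:, medoids].min(axis=1)
            gains = [np.maximum(cur - d2[:, c], 0).sum() if c not in medoids else -1
                     for c in range(n)]
            medoids.append(int(np.argmax(gains)))
        improved = True
        while improved:
            improved = False
            cost = _pam_cost(d2, tuple(medoids))
            for i, m in enumerate(medoids):
                for c in range(n):
                    if c in medoids:
                        continue
                    trial = medoids.copy()
                    trial[i] = c
                    if _pam_cost(d2, tuple(trial)) < cost - 1e-12:
                        medoids, cost, improved = trial, _pam_cost(d2, tuple(trial)), True
        best = tuple(sorted(medoids))

    return np.argmin(d2[:, list(best)], axis=1)


def cluster_datasets(cell_numbers: np.ndarray, volumes: np.ndarray, k: int = 3) -> np.ndarray:
    """PAM grouping of datasets by (cell number, spheroid volume).

    Returns integer labels 0..k-1 ordered so that group 0 has the smallest
    mean cell number (small spheroids first).
    """
    X = np.column_stack([np.asarray(cell_numbers, float), np.asarray(volumes, float)])
    raw = pam(X, k)
    order = np.argsort([X[raw == g, 0].mean() for g in range(k)])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def fit_volume_cell_line(cell_numbers: np.ndarray, volumes: np.ndarray):
    """OLS fit of spheroid volume (um^3) against cell number.

    Returns ``(slope, intercept, pearson_r)``; the slope is the volume
    added per cell in um^3/cell.
    """
    x = np.asarray(cell_numbers, dtype=np.float64)
    y = np.asarray(volumes, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least two datasets")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in cell numbers")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
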