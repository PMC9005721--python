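"""Synthetic study systems with known truth for exercising the pipeline.

Real occurrence/climate inputs for a large-scale invasion study cannot ship
with a package, so every stage here is exercised against generated worlds:
a rectangular lon/lat domain carrying spatially autocorrelated covariate
rasters (19 bioclim-like ``BIO*`` layers plus 5 soil-like layers) with
engineered correlated pairs, a known logistic true-suitability surface, and
presence records sampled with an accessibility bias field that emulates
population-density driven recording effort in citizen-science data.

The generator's defaults mimic the shape of a mid/high-latitude continental
study at toy scale: a 30 deg x 30 deg box at 0.5 deg resolution (60 x 60
cells), a cold northern strip where the species cannot establish, and bias
decaying over ~50 km from a handful of "city" centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geo import PointLL, haversine_km
from .grid_io import EnvStack, Grid, GridHeader, write_ascii_grid

__all__ = [
    "SyntheticWorld",
    "default_variable_names",
    "make_env_stack",
    "true_suitability",
    "make_bias_field",
    "sample_presences",
    "make_world",
    "make_future_stack",
    "write_world",
    "DEFAULT_EXTENT",
    "DEFAULT_CELLSIZE",
    "DEFAULT_COEFFICIENTS",
    "TEMPERATURE_LIKE",
]

#: (lon_min, lat_min, lon_max, lat_max) of the default toy domain.
DEFAULT_EXTENT = (30.0, 40.0, 60.0, 70.0)
DEFAULT_CELLSIZE = 0.5

#: Default informative variables of the planted niche: two bioclim-like
#: layers (one temperature-like with a positive effect — the species is
#: limited at its cold range edge — one precipitation-like) and one
#: soil-like layer.  Magnitudes are chosen so the niche signal clearly
#: dominates sampling noise: a benchmark world must carry recoverable
#: signal for pipeline validation to be informative.
DEFAULT_COEFFICIENTS = {"BIO1": 2.0, "BIO13": -1.5, "SOC": 1.2}
DEFAULT_INTERCEPT = -0.3
DEFAULT_BLUR_CELLS = 3.0
#: Diffuse recording effort as a fraction of the peak city effort: even far
#: from population centres, roads and villages produce occasional records.
DEFAULT_EFFORT_FLOOR = 0.01

#: Variables treated as "temperature-like" by the future-scenario
#: perturbation (WorldClim convention: BIO1-BIO11 are temperature derived).
TEMPERATURE_LIKE = tuple(f"BIO{i}" for i in range(1, 12))

SOIL_NAMES = ("Silt", "Sand", "CF", "CEC", "SOC")


def default_variable_names(n_bio: int = 19, n_soil: int = 5) -> list[str]:
    """BIO1..BIOn plus soil property names."""
    if n_soil > len(SOIL_NAMES):
        raise ValueError(f"at most {len(SOIL_NAMES)} soil-like variables supported")
    return [f"BIO{i}" for i in range(1, n_bio + 1)] + list(SOIL_NAMES[:n_soil])


@dataclass
class SyntheticWorld:
    """A generated study system: covariates, truth, bias and provenance."""

    stack: EnvStack
    truth: Grid
    bias: Grid
    coefficients: dict[str, float]
    intercept: float
    seed: int
    bias_centers: list[PointLL] = field(default_factory=list)

    @property
    def informative(self) -> list[str]:
        return [k for k, v in self.coefficients.items() if v != 0.0]


def _header_for_extent(extent: Sequence[float], cellsize: float) -> GridHeader:
    lon0, lat0, lon1, lat1 = extent
    if not (lon1 > lon0 and lat1 > lat0):
        raise ValueError("extent must be a non-degenerate lon/lat box")
    ncols = int(round((lon1 - lon0) / cellsize))
    nrows = int(round((lat1 - lat0) / cellsize))
    return GridHeader(ncols=ncols, nrows=nrows, xllcorner=lon0, yllcorner=lat0, cellsize=cellsize)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], blur_cells: float) -> np.ndarray:
    """Standardised Gaussian-blurred white noise (mean 0, sd 1)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=blur_cells, mode="reflect")
    return (z - z.mean()) / z.std()


def make_env_stack(
    extent: Sequence[float] = DEFAULT_EXTENT,
    cellsize: float = DEFAULT_CELLSIZE,
    n_vars: int = 24,
    corr_groups: Iterable[Iterable[int]] = (),
    seed: int = 0,
    blur_cells: float = 2.0,
    names: Sequence[str] | None = None,
    min_group_r: float = 0.85,
) -> EnvStack:
    """Generate spatially autocorrelated standardised covariate rasters.

    Each base variable is Gaussian-blurred white noise standardised to mean 0
    and sd 1.  Within each ``corr_groups`` index set the lowest index is the
    leader; other members are the leader plus scaled independent smooth noise,
    with the scale shrunk until the empirical Pearson |r| with the leader is
    at least ``min_group_r``.

    Groups must be disjoint; indices must be < ``n_vars``.
    """
    header = _header_for_extent(extent, cellsize)
    groups = [sorted(set(g)) for g in corr_groups]
    seen: set[int] = set()
    for g in groups:
        if g and g[-1] >= n_vars:
            raise ValueError(f"corr_group index {g[-1]} >= n_vars {n_vars}")
        if seen & set(g):
            raise ValueError("corr_groups must be disjoint")
        seen |= set(g)
    if names is None:
        names = default_variable_names()[:n_vars] if n_vars <= 24 else [f"V{i}" for i in range(n_vars)]
    if len(names) != n_vars:
        raise ValueError("names length must equal n_vars")

    rng = np.random.default_rng(seed)
    shape = (header.nrows, header.ncols)
    fields = [_smooth_field(rng, shape, blur_cells) for _ in range(n_vars)]
    for g in groups:
        leader = fields[g[0]]
        for idx in g[1:]:
            eps = 0.4
            for _ in range(20):
                mixed = leader + eps * fields[idx]
                mixed = (mixed - mixed.mean()) / mixed.std()
                r = float(np.corrcoef(leader.ravel(), mixed.ravel())[0, 1])
                if abs(r) >= min_group_r:
                    break
                eps *= 0.7
            fields[idx] = mixed
    return EnvStack({name: Grid(header, f) for name, f in zip(names, fields)})


def true_suitability(
    stack: EnvStack,
    coefficients: Mapping[str, float],
    intercept: float = 0.0,
) -> Grid:
    """Cellwise logistic(intercept + sum coef * value) over the stack."""
    missing = [k for k in coefficients if k not in stack]
    if missing:
        raise KeyError(f"coefficients reference variables not in stack: {missing}")
    eta = np.full((stack.header.nrows, stack.header.ncols), float(intercept))
    for name, coef in coefficients.items():
        eta = eta + coef * stack[name].values
    p = 1.0 / (1.0 + np.exp(-eta))
    return Grid(stack.header, p, stack.union_mask.copy())


def make_bias_field(
    stack_header: GridHeader,
    centers: Sequence[PointLL],
    decay_km: float,
) -> Grid:
    """Accessibility field: cell weight = sum_centers exp(-d_km / decay_km).

    Emulates recording effort concentrated around population centres; strictly
    positive everywhere so no cell is unreachable, merely unlikely.
    """
    if decay_km <= 0:
        raise ValueError("decay_km must be > 0")
    if len(centers) == 0:
        raise ValueError("at least one center required")
    rows, cols = np.meshgrid(
        np.arange(stack_header.nrows), np.arange(stack_header.ncols), indexing="ij"
    )
    lon, lat = stack_header.cell_center(rows.ravel(), cols.ravel())
    cells = np.column_stack([lon, lat])
    weights = np.zeros(cells.shape[0])
    for c in centers:
        d = haversine_km(cells, np.array([c.lon, c.lat]))
        weights += np.exp(-np.asarray(d) / decay_km)
    return Grid(stack_header, weights.reshape(stack_header.nrows, stack_header.ncols))


def sample_presences(truth: Grid, bias: Grid, n: int, seed: int = 0) -> np.ndarray:
    """Sample n presence records with effort-biased detection.

    Cells are drawn with probability proportional to truth * bias (masked
    cells excluded); each record is jittered uniformly within its cell, so
    coordinates are not cell-centred.  Returns an (n, 2) lon/lat array.
    """
    if not truth.header.aligned_with(bias.header):
        raise ValueError("truth and bias grids are not aligned")
    h = truth.header
    weight = truth.values * bias.values
    weight = np.where(truth.mask | bias.mask, 0.0, weight).ravel()
    total = weight.sum()
    if n > 0 and total <= 0:
        raise ValueError("truth * bias is zero everywhere; cannot sample presences")
    if n == 0:
        return np.zeros((0, 2))
    rng = np.random.default_rng(seed)
    flat = rng.choice(weight.size, size=n, p=weight / total)
    row, col = np.unravel_index(flat, (h.nrows, h.ncols))
    lon = h.xllcorner + (col + rng.uniform(0.0, 1.0, size=n)) * h.cellsize
    lat = h.ytop - (row + rng.uniform(0.0, 1.0, size=n)) * h.cellsize
    return np.column_stack([lon, lat])


DEFAULT_BIAS_CENTER_FRACTIONS = ((0.30, 0.30), (0.62, 0.22), (0.45, 0.50), (0.72, 0.58), (0.22, 0.55))


def make_world(
    seed: int = 0,
    extent: Sequence[float] = DEFAULT_EXTENT,
    cellsize: float = DEFAULT_CELLSIZE,
    n_bio: int = 19,
    n_soil: int = 5,
    corr_pairs: Sequence[tuple[str, str]] = (("BIO1", "BIO11"),),
    coefficients: Mapping[str, float] | None = None,
    intercept: float = DEFAULT_INTERCEPT,
    bias_decay_km: float = 50.0,
    effort_floor: float = DEFAULT_EFFORT_FLOOR,
    cold_strip_fraction: float = 0.2,
    blur_cells: float = DEFAULT_BLUR_CELLS,
) -> SyntheticWorld:
    """Generate a complete synthetic study system.

    ``corr_pairs`` plants highly correlated variable pairs (leader first),
    emulating the redundancy among bioclimatic layers.  The northern
    ``cold_strip_fraction`` of rows has the true suitability forced near
    zero, emulating a tundra zone beyond the species' physiological limit.
    The sampling-effort field is a sum of exponential kernels around five
    population centres plus ``effort_floor`` of the peak as diffuse
    background effort.
    """
    names = default_variable_names(n_bio, n_soil)
    index = {n: i for i, n in enumerate(names)}
    groups = [sorted((index[a], index[b])) for a, b in corr_pairs]
    stack = make_env_stack(
        extent=extent,
        cellsize=cellsize,
        n_vars=len(names),
        corr_groups=groups,
        seed=seed,
        blur_cells=blur_cells,
        names=names,
    )
    coefficients = dict(DEFAULT_COEFFICIENTS if coefficients is None else coefficients)
    truth = true_suitability(stack, coefficients, intercept)
    n_strip = int(round(cold_strip_fraction * truth.header.nrows))
    if n_strip > 0:
        truth.values[:n_strip, :] *= 0.02  # rows 0.. are the northernmost

    lon0, lat0, lon1, lat1 = extent
    centers = [
        PointLL(lon0 + fx * (lon1 - lon0), lat0 + fy * (lat1 - lat0))
        for fx, fy in DEFAULT_BIAS_CENTER_FRACTIONS
    ]
    bias = make_bias_field(stack.header, centers, decay_km=bias_decay_km)
    if effort_floor:
        bias.values = bias.values + effort_floor * bias.values.max()
    return SyntheticWorld(
        stack=stack,
        truth=truth,
        bias=bias,
        coefficients=coefficients,
        intercept=intercept,
        seed=seed,
        bias_centers=centers,
    )


def make_future_stack(
    stack: EnvStack,
    temp_shift_sd: float = 1.0,
    temperature_like: Sequence[str] = TEMPERATURE_LIKE,
    region_rows: slice | None = None,
) -> EnvStack:
    """Future-scenario stack: warm the temperature-like layers.

    Adds ``temp_shift_sd`` (in units of each layer's sd over unmasked cells)
    to every temperature-like layer, optionally only within ``region_rows``.
    All other layers — in particular the soil properties — are carried over
    unchanged, mirroring the assumption that soil is stable on the forecast
    horizon.
    """
    out: dict[str, Grid] = {}
    for name, grid in stack.items():
        if name in temperature_like:
            g = grid.copy()
            sd = float(g.unmasked.std())
            if region_rows is None:
                g.values = g.values + temp_shift_sd * sd
            else:
                g.values[region_rows, :] += temp_shift_sd * sd
            out[name] = g
        else:
            out[name] = grid
    return EnvStack(out)


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world to disk: one .asc per layer plus truth and bias.

    Returns a manifest of written paths.  Presences are not written here —
    sample them with :func:`sample_presences` and save with pandas.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, grid in world.stack.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(grid, p)
        paths[name] = p
    for extra, grid in (("truth", world.truth), ("bias", world.bias)):
        p = directory / f"{extra}.asc"
        write_ascii_grid(grid, p)
        paths[extra] = p
    return paths
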