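"""Synthetic landscape and virtual species generation.

Builds a seeded, fully reproducible stand-in for a mountainous study region:
smooth and spatially autocorrelated climate surfaces, elevation with derived
slope, categorical land cover, human-pressure layers in [0, 1] correlated
with anthropogenic land cover, river/road polylines with distance rasters,
and habitat layers (NDVI, tree canopy, forest type). A ``TruthModel`` defines
a known logistic suitability surface over a subset of layers so that model
recovery can be scored against ground truth, and ``sample_occurrences`` draws
biased presence-only records from it. ``make_future`` perturbs the stack into
a warming/land-conversion scenario analogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.special import expit
from shapely.geometry import LineString, box

from .grid import GridSpec, PredictorStack, Raster
from .predictors import distance_raster


class SamplingError(RuntimeError):
    """Requested more samples than there are eligible cells."""


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the generated landscape.

    The defaults describe a 200×200 grid of 1 km cells (40,000 km², the scale
    of a large regional study area), five bioclim-style layers, and a
    spatial autocorrelation range of 15 cells for the Gaussian-field layers.
    """

    seed: int = 0
    n_rows: int = 200
    n_cols: int = 200
    cell_size_km: float = 1.0
    n_climate_layers: int = 5
    autocorrelation_range_cells: float = 15.0
    landcover_classes: int = 5
    river_count: int = 3
    road_count: int = 4

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows * self.n_cols < 100:
            raise ValueError("landscape needs at least 100 cells")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.n_climate_layers < 4:
            raise ValueError("need >= 4 climate layers (2 gradient + 2 autocorrelated)")
        if self.autocorrelation_range_cells <= 0:
            raise ValueError("autocorrelation range must be positive")
        if self.landcover_classes < 3:
            raise ValueError("need >= 3 land-cover classes")
        if self.river_count < 0 or self.road_count < 0:
            raise ValueError("feature counts must be non-negative")

    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size_km, crs="synthetic-km")


@dataclass(frozen=True)
class TruthModel:
    """Known logistic suitability: expit(intercept + Σ coef_i · z_i).

    Layers are standardized (z-scored over valid cells) before entering the
    linear predictor, so coefficients are on a per-SD scale. The defaults
    describe a sharply contrasted habitat specialist — steep responses
    (±4 per SD) and low regional prevalence (mean suitability ≈ 0.18) — the
    niche structure of a rare large vertebrate whose suitable habitat is a
    small fraction of the region.
    """

    active_predictors: tuple[str, ...] = ("bio18", "elevation", "human_footprint")
    coefficients: tuple[float, ...] = (4.0, -4.0, -2.5)
    intercept: float = -4.0

    def __post_init__(self) -> None:
        if len(self.active_predictors) != len(self.coefficients):
            raise ValueError("one coefficient per active predictor")


def gaussian_random_field(
    shape: tuple[int, int], range_cells: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized autocorrelated field: filtered white noise, unit variance."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=range_cells, mode="reflect")
    s = f.std()
    return (f - f.mean()) / (s if s > 0 else 1.0)


def _random_polyline(grid: GridSpec, rng: np.random.Generator, north_south: bool) -> LineString:
    """A meandering polyline crossing the extent (rivers run N→S, roads any way)."""
    xmin, ymin, xmax, ymax = grid.extent_km
    n_pts = 20
    if north_south:
        ys = np.linspace(ymax, ymin, n_pts)
        x = rng.uniform(xmin, xmax)
        xs = x + np.cumsum(rng.normal(0, 0.04 * (xmax - xmin), n_pts))
        xs = np.clip(xs, xmin, xmax)
    else:
        p0 = np.array([rng.uniform(xmin, xmax), rng.choice([ymin, ymax])])
        p1 = np.array([rng.choice([xmin, xmax]), rng.uniform(ymin, ymax)])
        t = np.linspace(0, 1, n_pts)
        base = p0[None, :] * (1 - t)[:, None] + p1[None, :] * t[:, None]
        jitter = rng.normal(0, 0.02 * (xmax - xmin), (n_pts, 2))
        jitter[0] = jitter[-1] = 0
        pts = np.clip(base + jitter, [xmin, ymin], [xmax, ymax])
        xs, ys = pts[:, 0], pts[:, 1]
    return LineString(np.column_stack([xs, ys]))


def make_landscape(spec: LandscapeSpec) -> PredictorStack:
    """Generate the full aligned predictor stack for a landscape spec.

    Layers: ``bio18``/``bio19`` (smooth N–S / E–W gradients with gentle
    curvature), ``bio15``/``bio2``/``bio3``/… (autocorrelated Gaussian
    fields), ``elevation`` (m), ``slope`` (degrees), ``landcover`` (codes,
    0 = anthropogenic), ``human_footprint``/``human_modification`` in [0, 1]
    correlated with anthropogenic land cover, ``dist_river``/``dist_road``
    (km), ``ndvi`` in [0, 1], ``tree_canopy`` (%), ``forest_type``
    (elevation-band codes). Identical specs yield bit-identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    shape = grid.shape
    xs, ys = grid.cell_centers()
    xmin, ymin, xmax, ymax = grid.extent_km
    u = (xs - xmin) / (xmax - xmin)  # 0 west → 1 east
    v = (ys - ymin) / (ymax - ymin)  # 0 south → 1 north
    rc = spec.autocorrelation_range_cells

    stack = PredictorStack(grid=grid)
    stack.meta["spec"] = spec

    # --- climate: two smooth gradients, the rest autocorrelated fields
    gradient_names = ["bio18", "bio19"]
    grf_names = ["bio15", "bio2", "bio3"] + [
        f"climate{i}" for i in range(6, spec.n_climate_layers + 1)
    ]
    grf_names = grf_names[: spec.n_climate_layers - 2]
    stack.add("bio18", 120.0 + 80.0 * v + 15.0 * np.sin(2 * np.pi * u))
    stack.add("bio19", 40.0 + 60.0 * u + 10.0 * np.cos(2 * np.pi * v))
    for name in grf_names:
        f = gaussian_random_field(shape, rc, rng)
        stack.add(name, 50.0 + 20.0 * f)

    # --- topography: broad ridge plus autocorrelated relief, metres
    relief = gaussian_random_field(shape, rc * 1.5, rng)
    ridge = 1800.0 * v**1.5  # mountains to the north
    elevation = np.clip(ridge + 600.0 * relief + 400.0, 0.0, None)
    stack.add("elevation", elevation)
    dzdy, dzdx = np.gradient(elevation, grid.cell_size_km * 1000.0)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    stack.add("slope", slope)

    # --- rivers / roads and distance layers
    rivers = [_random_polyline(grid, rng, north_south=True) for _ in range(spec.river_count)]
    roads = [_random_polyline(grid, rng, north_south=False) for _ in range(spec.road_count)]
    r_river = distance_raster(rivers, grid, "dist_river")
    r_road = distance_raster(roads, grid, "dist_road")
    stack.add("dist_river", r_river.values)
    stack.add("dist_road", r_road.values)
    stack.meta["rivers"] = rivers
    stack.meta["roads"] = roads
    stack.meta["degenerate_layers"] = [
        n for n, r in (("dist_river", r_river), ("dist_road", r_road)) if r.degenerate
    ]

    # --- human pressure: latent field drawn toward roads and lowlands
    latent = gaussian_random_field(shape, rc, rng)
    road_pull = np.exp(-stack["dist_road"] / 10.0)
    lowland = 1.0 - (elevation - elevation.min()) / np.ptp(elevation)
    pressure = 0.5 * latent + 1.2 * road_pull + 0.8 * lowland

    # --- land cover: class 0 anthropogenic where pressure is highest,
    #     natural classes from an independent latent field elsewhere
    anthro_frac = 0.2
    thr = np.quantile(pressure, 1.0 - anthro_frac)
    anthro = pressure > thr
    lc_latent = gaussian_random_field(shape, rc, rng)
    n_nat = spec.landcover_classes - 1
    edges = np.quantile(lc_latent, np.linspace(0, 1, n_nat + 1)[1:-1])
    landcover = np.digitize(lc_latent, edges) + 1  # 1..n_nat
    landcover[anthro] = 0
    stack.add("landcover", landcover.astype(float), categorical=True)

    # --- human layers in [0,1]: pressure plus anthropogenic-cover smoothing
    def _unit(a: np.ndarray) -> np.ndarray:
        return (a - a.min()) / (np.ptp(a) if np.ptp(a) > 0 else 1.0)

    anthro_smooth = gaussian_filter(anthro.astype(float), sigma=rc / 3.0)
    stack.add("human_footprint", _unit(pressure + 1.5 * anthro_smooth))
    stack.add(
        "human_modification",
        _unit(0.8 * pressure + 1.5 * anthro_smooth + 0.3 * gaussian_random_field(shape, rc, rng)),
    )

    # --- habitat layers: greener away from people, canopy tied to NDVI
    ndvi = _unit(
        0.8 * (1.0 - stack["human_footprint"]) + 0.4 * gaussian_random_field(shape, rc, rng)
    )
    stack.add("ndvi", ndvi)
    stack.add("tree_canopy", np.clip(100.0 * ndvi + rng.normal(0, 5.0, shape), 0, 100))
    forest_type = np.digitize(elevation, [1000.0, 2000.0, 3500.0, 4500.0]).astype(float)
    stack.add("forest_type", forest_type, categorical=True)

    return stack


def true_suitability(
    stack: PredictorStack, truth: TruthModel, reference: PredictorStack | None = None
) -> Raster:
    """Cellwise logistic suitability of the standardized active layers.

    Standardization statistics come from ``reference`` when given (project a
    fixed niche onto a perturbed scenario stack) and from ``stack`` itself
    otherwise.
    """
    stats = reference if reference is not None else stack
    eta = np.full(stack.grid.shape, truth.intercept, dtype=float)
    for name, coef in zip(truth.active_predictors, truth.coefficients):
        layer = stack[name]  # raises KeyError when missing
        v = stats[name][stats.mask]
        mu, sd = v.mean(), v.std()
        z = (layer - mu) / (sd if sd > 0 else 1.0)
        eta += coef * z
    suit = expit(eta)
    return Raster(suit, stack.grid, stack.mask.copy(), "true_suitability")


def sample_occurrences(
    suit: Raster, n: int, bias: Raster | None = None, seed: int = 0
):
    """Draw ``n`` presence cells with probability ∝ suitability (× bias).

    Sampling is without replacement at cell level; records carry cell-center
    coordinates and source ``"synthetic"``.
    """
    from .occurrences import OccurrenceSet
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.where(suit.mask, np.clip(suit.values, 0.0, None), 0.0)
    if bias is not None:
        suit.require_aligned(bias)
        p = p * np.clip(bias.values, 0.0, None)
    flat = p.ravel()
    positive = flat > 0
    if positive.sum() < n:
        raise SamplingError(
            f"requested {n} cells but only {int(positive.sum())} have positive probability"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    row, col = np.unravel_index(idx, suit.grid.shape)
    x, y = suit.grid.xy(row, col)
    df = pd.DataFrame(
        {"id": [f"occ{i}" for i in range(n)], "x": x, "y": y, "source": "synthetic"}
    )
    return OccurrenceSet(df, crs=suit.grid.crs)


def road_bias(stack: PredictorStack, scale_km: float = 10.0) -> Raster:
    """Detectability bias hook: sampling effort decaying with road distance."""
    return Raster(np.exp(-stack["dist_road"] / scale_km), stack.grid, stack.mask.copy(), "road_bias")


@dataclass(frozen=True)
class FutureScenario:
    """Perturbation of a baseline stack into a scenario analogue.

    ``offsets``/``scales`` act cellwise on named (climate) layers;
    ``landcover_conversion`` flips that fraction of natural land-cover cells
    to the anthropogenic class, frontier-first (cells adjacent to existing
    anthropogenic cover convert before interior cells — expansion, not
    scattered conversion). Human-pressure layers stay constant by default.
    """

    name: str = "rcp45"
    offsets: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    landcover_conversion: float = 0.0


def make_future(stack: PredictorStack, scenario: FutureScenario, seed: int = 0) -> PredictorStack:
    """Apply a ``FutureScenario`` to a baseline stack; returns a new stack."""
    for name in list(scenario.offsets) + list(scenario.scales):
        if name not in stack:
            raise KeyError(f"delta refers to missing layer {name!r}")
    out = stack.copy()
    out.meta["scenario"] = scenario.name
    for name, off in scenario.offsets.items():
        out.layers[name] = out.layers[name] + off
    for name, sc in scenario.scales.items():
        out.layers[name] = out.layers[name] * sc

    frac = scenario.landcover_conversion
    if frac > 0 and "landcover" in out:
        rng = np.random.default_rng(seed)
        lc = out.layers["landcover"].copy()
        natural = lc != 0
        n_target = int(round(frac * natural.sum()))
        converted = 0
        anthro = lc == 0
        if not anthro.any():  # no expansion nucleus: seed one random cell
            r = rng.integers(lc.shape[0])
            c = rng.integers(lc.shape[1])
            lc[r, c] = 0
            anthro = lc == 0
        while converted < n_target:
            frontier = natural & (lc != 0) & binary_dilation(lc == 0)
            cand = np.flatnonzero(frontier.ravel())
            if cand.size == 0:
                break
            take = min(cand.size, n_target - converted)
            chosen = rng.choice(cand, size=take, replace=False)
            lc.ravel()[chosen] = 0
            converted += take
        out.layers["landcover"] = lc
    return out


@dataclass
class PolygonSet:
    """Labelled polygons (protected areas, admin zones, or range categories)."""

    kind: str  # protected_area | zone | range_category
    geometries: list = field(default_factory=list)
    properties: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self):
        return iter(zip(self.geometries, self.properties))


RANGE_LABELS = ("extant", "uncertain", "extinct")
PA_CATEGORIES = ("national_park", "wildlife_sanctuary", "tiger_reserve", "other")


def make_polygons(spec: LandscapeSpec, kind: str, seed: int = 0, count: int = 6) -> PolygonSet:
    """Non-overlapping rectangles within the extent.

    ``protected_area``: ``count`` rectangles with id/name/category;
    ``zone``: vertical bands partitioning the extent (admin analogue);
    ``range_category``: three rectangles labelled extant / uncertain / extinct.
    Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid()
    xmin, ymin, xmax, ymax = grid.extent_km
    geoms, props = [], []

    if kind == "zone":
        n = max(1, count)
        cuts = np.sort(rng.uniform(xmin, xmax, n - 1)) if n > 1 else np.array([])
        edges = np.concatenate([[xmin], cuts, [xmax]])
        for i in range(n):
            geoms.append(box(edges[i], ymin, edges[i + 1], ymax))
            props.append({"id": f"zone{i}", "name": f"Zone {i}"})
    elif kind in ("protected_area", "range_category"):
        if kind == "range_category":
            count = len(RANGE_LABELS)
        # shuffled slot grid guarantees non-overlap
        n_slots = int(np.ceil(np.sqrt(count)))
        slot_w = (xmax - xmin) / n_slots
        slot_h = (ymax - ymin) / n_slots
        slots = [(i, j) for i in range(n_slots) for j in range(n_slots)]
        order = rng.permutation(len(slots))[:count]
        for k, s in enumerate(order):
            i, j = slots[s]
            sx, sy = xmin + i * slot_w, ymin + j * slot_h
            w = rng.uniform(0.4, 0.9) * slot_w
            h = rng.uniform(0.4, 0.9) * slot_h
            ox = rng.uniform(0, slot_w - w)
            oy = rng.uniform(0, slot_h - h)
            geoms.append(box(sx + ox, sy + oy, sx + ox + w, sy + oy + h))
            if kind == "protected_area":
                props.append(
                    {
                        "id": f"pa{k}",
                        "name": f"PA {k}",
                        "category": PA_CATEGORIES[int(rng.integers(len(PA_CATEGORIES)))],
                    }
                )
            else:
                props.append({"label": RANGE_LABELS[k]})
    else:
        raise ValueError(f"unknown polygon kind {kind!r}")
    return PolygonSet(kind=kind, geometries=geoms, properties=props)
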