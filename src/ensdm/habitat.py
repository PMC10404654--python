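"""Suitability post-processing: class maps, disturbance masking, area
accounting, conservation-priority ranking, and range-shift summaries.

Suitability surfaces in [0, 1] are reclassified into four ordinal classes at
fixed thresholds (0.2 / 0.4 / 0.6). A binary human-disturbance mask (mean of
human footprint and human modification, cut at 0.3) removes cells unusable
for conservation. Priorities come from intersecting the three models'
current class maps — high suitability in the baseline model where both
reduced models agree at least on medium suitability — plus a
"possible future" category for cells suitable under every projected
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .grid import AlignmentError, GridSpec, Raster, polygon_cell_mask

CLASS_NAMES = {0: "unsuitable", 1: "low", 2: "medium", 3: "high"}
PRIORITY_NAMES = {0: "none", 1: "possible_future", 2: "high", 3: "very_high"}
DEFAULT_CLASS_BOUNDS = (0.2, 0.4, 0.6)


class ConfigurationError(ValueError):
    pass


@dataclass
class SuitabilityClassMap:
    """Ordinal 4-class raster: 0 unsuitable, 1 low, 2 medium, 3 high."""

    codes: np.ndarray
    grid: GridSpec
    mask: np.ndarray
    model: str = ""
    scenario: str = "current"

    def __post_init__(self) -> None:
        bad = np.setdiff1d(np.unique(self.codes[self.mask]), list(CLASS_NAMES))
        if bad.size:
            raise ValueError(f"invalid class codes {bad.tolist()}")

    def require_aligned(self, other) -> None:
        if self.grid != other.grid:
            raise AlignmentError("class maps are not grid-aligned")

    def copy(self) -> "SuitabilityClassMap":
        return SuitabilityClassMap(
            self.codes.copy(), self.grid, self.mask.copy(), self.model, self.scenario
        )


def reclassify(
    surface: Raster,
    bounds: tuple[float, float, float] = DEFAULT_CLASS_BOUNDS,
    model: str = "",
    scenario: str = "current",
) -> SuitabilityClassMap:
    """Threshold a [0, 1] suitability surface into the four ordinal classes.

    Intervals are half-open at the lower edge — [0, 0.2) unsuitable,
    [0.2, 0.4) low, [0.4, 0.6) medium — with the top class closed at 1.0.
    Values outside [0, 1] (beyond float fuzz) raise a range error.
    """
    vals = surface.values
    valid = surface.mask & np.isfinite(vals)
    v = vals[valid]
    if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
        raise ValueError(f"suitability outside [0,1]: range [{v.min()}, {v.max()}]")
    codes = np.zeros(surface.grid.shape, dtype=int)
    codes[valid] = np.digitize(np.clip(vals[valid], 0, 1), bounds, right=False)
    return SuitabilityClassMap(codes, surface.grid, valid, model=model, scenario=scenario)


def _normalize_unit(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min–max rescale only when values leave [0, 1]; identity otherwise."""
    v = values[mask]
    lo, hi = float(v.min()), float(v.max())
    if lo >= 0.0 and hi <= 1.0:
        return values
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def disturbance_mask(hfp: Raster, hmod: Raster, threshold: float = 0.3) -> Raster:
    """Binary high-disturbance mask from the human-pressure ensemble.

    The ensemble is the arithmetic mean of the unit-normalized layers; cells
    with ensemble pressure > ``threshold`` are high disturbance (1).
    """
    hfp.require_aligned(hmod)
    mask = hfp.mask & hmod.mask
    ens = 0.5 * (_normalize_unit(hfp.values, mask) + _normalize_unit(hmod.values, mask))
    high = np.zeros(hfp.grid.shape, dtype=int)
    high[mask] = (ens[mask] > threshold).astype(int)
    return Raster(high, hfp.grid, mask, "disturbance")


def apply_mask(classmap: SuitabilityClassMap, mask: Raster) -> SuitabilityClassMap:
    """Zero out (→ unsuitable) every cell flagged high-disturbance."""
    classmap.require_aligned(mask)
    out = classmap.copy()
    out.codes[mask.values.astype(bool)] = 0
    return out


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal round-half-up (spreadsheet convention used in reports)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def class_percentages(areas_km2: dict[int, float], total_km2: float) -> dict:
    """Percent-of-total per class, rounded half-up to 2 dp, plus the
    "suitable percent" = rounded medium% + rounded high% convention.

    The rounded-components-then-sum arithmetic matches how suitable shares
    are conventionally reported from class-area tables; raw percents are
    returned alongside.
    """
    pct = {c: round_half_up(100.0 * a / total_km2) for c, a in areas_km2.items()}
    raw = {c: 100.0 * a / total_km2 for c, a in areas_km2.items()}
    suitable = round_half_up(pct.get(2, 0.0) + pct.get(3, 0.0))
    return {"percent": pct, "percent_raw": raw, "suitable_percent": suitable}


def area_report(
    classmaps: list[SuitabilityClassMap],
    zones=None,
    total_area_km2: float | None = None,
) -> pd.DataFrame:
    """Class-area accounting per (zone, model, scenario).

    Areas are cell counts × cell area; percents are of the zone area (or of
    ``total_area_km2`` when supplied), rounded half-up to 2 dp, with the raw
    unrounded percent alongside. Zones default to the full grid.
    """
    rows = []
    zone_list = list(zones) if zones is not None else [(None, {"id": "all", "name": "all"})]
    for cm in classmaps:
        cell_area = cm.grid.cell_area_km2
        for geom, props in zone_list:
            zmask = cm.mask if geom is None else (polygon_cell_mask(cm.grid, geom) & cm.mask)
            zone_area = float(zmask.sum()) * cell_area
            areas = {
                c: float(((cm.codes == c) & zmask).sum()) * cell_area for c in CLASS_NAMES
            }
            denom = total_area_km2 if total_area_km2 is not None else zone_area
            for c in CLASS_NAMES:
                pct = 100.0 * areas[c] / denom if denom > 0 else 0.0
                rows.append(
                    {
                        "zone": props.get("id", props.get("name", "all")),
                        "model": cm.model,
                        "scenario": cm.scenario,
                        "class": CLASS_NAMES[c],
                        "area_km2": areas[c],
                        "percent_of_zone": round_half_up(pct) if denom > 0 else 0.0,
                        "percent_raw": pct,
                    }
                )
            if denom > 0:
                suit = class_percentages(areas, denom)["suitable_percent"]
            else:
                suit = 0.0
            rows.append(
                {
                    "zone": props.get("id", props.get("name", "all")),
                    "model": cm.model,
                    "scenario": cm.scenario,
                    "class": "suitable",
                    "area_km2": areas[2] + areas[3],
                    "percent_of_zone": suit,
                    "percent_raw": 100.0 * (areas[2] + areas[3]) / denom if denom > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PriorityMap:
    """Categorical conservation-priority raster with per-category provenance."""

    codes: np.ndarray
    grid: GridSpec
    mask: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            name: int(((self.codes == code) & self.mask).sum())
            for code, name in PRIORITY_NAMES.items()
        }


def rank_priorities(
    hlcam: SuitabilityClassMap,
    lcam_now: SuitabilityClassMap,
    cm_now: SuitabilityClassMap,
    lcam_future: list[SuitabilityClassMap],
    cm_future: list[SuitabilityClassMap],
    mask: Raster,
    require_all_scenarios: bool = True,
) -> PriorityMap:
    """Intersect the three models' class maps into priority categories.

    On low-disturbance cells only: ``very_high`` where the baseline model is
    high AND both reduced models are at least medium now; ``high`` where the
    baseline is medium under the same agreement; ``possible_future`` where a
    cell not already ranked is at least medium in every future map of both
    scenarios (any single scenario suffices when
    ``require_all_scenarios=False``); ``none`` otherwise. High-disturbance
    cells are always ``none``.
    """
    for other in [lcam_now, cm_now, *lcam_future, *cm_future]:
        hlcam.require_aligned(other)
    hlcam.require_aligned(mask)
    if not lcam_future or not cm_future:
        raise ConfigurationError("future class maps required for both reduced models")
    scenarios = {m.scenario for m in lcam_future} | {m.scenario for m in cm_future}
    if require_all_scenarios and len(scenarios) < 2:
        raise ConfigurationError(
            f"future maps must cover both scenarios, got {sorted(scenarios)}"
        )

    low_dist = ~mask.values.astype(bool)
    agree_now = (lcam_now.codes >= 2) & (cm_now.codes >= 2)
    very_high = low_dist & (hlcam.codes == 3) & agree_now
    high = low_dist & (hlcam.codes == 2) & agree_now
    futures = [m.codes >= 2 for m in [*lcam_future, *cm_future]]
    fut_all = np.logical_and.reduce(futures)
    possible = low_dist & fut_all & ~(very_high | high)

    codes = np.zeros(hlcam.grid.shape, dtype=int)
    codes[possible] = 1
    codes[high] = 2
    codes[very_high] = 3
    provenance = {
        "very_high": "HLCAm high ∩ LCAm≥medium ∩ Cm≥medium, low disturbance",
        "high": "HLCAm medium ∩ LCAm≥medium ∩ Cm≥medium, low disturbance",
        "possible_future": (
            "≥medium in every future map of "
            + ("both scenarios" if require_all_scenarios else "any scenario")
            + ", low disturbance, not already ranked"
        ),
    }
    return PriorityMap(codes, hlcam.grid, hlcam.mask & mask.mask, provenance)


def range_shift(current: SuitabilityClassMap, future: SuitabilityClassMap) -> dict:
    """Gain/loss/stable areas of suitable habitat (≥ medium) plus the shift
    vector between area-weighted suitable centroids (km; +y is north)."""
    current.require_aligned(future)
    cell_area = current.grid.cell_area_km2
    cur = (current.codes >= 2) & current.mask
    fut = (future.codes >= 2) & future.mask
    gain = float((fut & ~cur).sum()) * cell_area
    loss = float((cur & ~fut).sum()) * cell_area
    stable = float((cur & fut).sum()) * cell_area

    def _centroid(sel: np.ndarray):
        if not sel.any():
            return None
        row, col = np.nonzero(sel)
        x, y = current.grid.xy(row, col)
        return float(x.mean()), float(y.mean())

    c0, c1 = _centroid(cur), _centroid(fut)
    if c0 is None or c1 is None:
        vec = (float("nan"), float("nan"))
    else:
        vec = (c1[0] - c0[0], c1[1] - c0[1])
    return {
        "gain_km2": gain,
        "loss_km2": loss,
        "stable_km2": stable,
        "centroid_shift_km": vec,
    }
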