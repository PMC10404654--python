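"""Protected-area assessment: eco-sensitive-zone rings, anthropogenic threat
scoring, and suitability overlap with labelled range polygons.

The eco-sensitive zone (ESZ) is operationalized as a 1 km ring around each
protected area. Threat is the fraction of high-pressure cells — human
footprint / human modification ensemble above the disturbance threshold, or
within 3 km of a road — inside the PA polygon and inside its ESZ ring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from shapely import BufferCapStyle, BufferJoinStyle

from .grid import Raster, polygon_cell_mask
from .habitat import CLASS_NAMES, SuitabilityClassMap, disturbance_mask
from .synth import RANGE_LABELS, PolygonSet

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    pass


class LabelError(ValueError):
    pass


def esz_buffer(polygon, width_km: float = 1.0, join_style: str = "mitre"):
    """Eco-sensitive-zone ring: buffer minus the polygon itself.

    Mitre (square) joins by default so ring areas on the planar grid are
    closed-form (a W×H rectangle with width w gives (W+2w)(H+2w) − WH);
    round joins are available for real geographies.
    """
    if width_km <= 0:
        raise ValueError("buffer width must be positive")
    if polygon is None or polygon.is_empty or not polygon.is_valid:
        raise GeometryError("invalid or empty protected-area polygon")
    js = BufferJoinStyle.mitre if join_style == "mitre" else BufferJoinStyle.round
    buffered = polygon.buffer(width_km, join_style=js, cap_style=BufferCapStyle.square)
    return buffered.difference(polygon)


def pressure_mask(
    hfp: Raster,
    hmod: Raster,
    road_distance: Raster | None = None,
    disturbance_threshold: float = 0.3,
    road_km: float = 3.0,
) -> Raster:
    """Binary anthropogenic-pressure mask: disturbance ensemble > threshold
    OR within ``road_km`` of a road."""
    dist = disturbance_mask(hfp, hmod, threshold=disturbance_threshold)
    pressure = dist.values.astype(bool)
    if road_distance is not None:
        dist.require_aligned(road_distance)
        pressure = pressure | (road_distance.values < road_km)
    return Raster(pressure.astype(int), dist.grid, dist.mask, "pressure")


@dataclass
class ThreatRow:
    pa_id: str
    inside_threat_fraction: float
    esz_threat_fraction: float
    threatened_inside: bool
    threatened_outside: bool


def threat_assess(
    pas: PolygonSet,
    hfp: Raster,
    hmod: Raster,
    road_distance: Raster | None = None,
    esz_width_km: float = 1.0,
    disturbance_threshold: float = 0.3,
    road_km: float = 3.0,
    flag_threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-PA high-pressure fractions inside the polygon and its ESZ ring.

    A PA is flagged threatened inside (resp. outside) when the corresponding
    fraction exceeds ``flag_threshold``. PAs with no cells on the raster are
    excluded with a warning. The flag threshold parallels the disturbance
    cut-off; it is a package convention, not an established standard.
    """
    mask = pressure_mask(hfp, hmod, road_distance, disturbance_threshold, road_km)
    pressure = mask.values.astype(bool)
    rows = []
    for geom, props in pas:
        pa_id = props.get("id", props.get("name", "pa"))
        inside = polygon_cell_mask(mask.grid, geom) & mask.mask
        if not inside.any():
            logger.warning("PA %s has no cells on the raster; excluded", pa_id)
            continue
        ring = esz_buffer(geom, esz_width_km)
        ring_cells = polygon_cell_mask(mask.grid, ring) & mask.mask
        f_in = float(pressure[inside].mean())
        f_esz = float(pressure[ring_cells].mean()) if ring_cells.any() else 0.0
        rows.append(
            ThreatRow(
                pa_id=pa_id,
                inside_threat_fraction=f_in,
                esz_threat_fraction=f_esz,
                threatened_inside=f_in > flag_threshold,
                threatened_outside=f_esz > flag_threshold,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def range_overlap(classmap: SuitabilityClassMap, ranges: PolygonSet) -> pd.DataFrame:
    """Suitability-class areas and within-label percentages per range label
    (extant / uncertain / extinct)."""
    cell_area = classmap.grid.cell_area_km2
    rows = []
    for geom, props in ranges:
        label = props.get("label")
        if label not in RANGE_LABELS:
            raise LabelError(f"unknown range label {label!r}; expected one of {RANGE_LABELS}")
        sel = polygon_cell_mask(classmap.grid, geom) & classmap.mask
        total = float(sel.sum()) * cell_area
        for c, cname in CLASS_NAMES.items():
            area = float(((classmap.codes == c) & sel).sum()) * cell_area
            rows.append(
                {
                    "label": label,
                    "class": cname,
                    "area_km2": area,
                    "percent_of_label": 100.0 * area / total if total > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)
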