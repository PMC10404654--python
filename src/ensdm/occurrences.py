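"""Occurrence records: ingestion, de-duplication, and spatial thinning.

Presence-only records cluster along survey routes and around camera-trap
grids; fitting on raw records overweights those neighbourhoods. Spatial
thinning enforces a minimum pairwise separation (5 km by default, a
home-range-scale figure for large territorial carnivores) while retaining as
many records as possible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

_XY_ALIASES = {"x": ("x", "lon", "longitude"), "y": ("y", "lat", "latitude")}
SOURCES = ("field", "camera", "literature", "synthetic")


class FormatError(ValueError):
    """Input table lacks required coordinate columns."""


@dataclass
class OccurrenceSet:
    """Ordered presence records with planar-km or lon/lat coordinates."""

    records: pd.DataFrame  # columns: id, x, y, source
    crs: str = "synthetic-km"

    def __post_init__(self) -> None:
        required = {"id", "x", "y"}
        if not required.issubset(self.records.columns):
            raise FormatError(f"records need columns {sorted(required)}")
        if "source" not in self.records.columns:
            self.records = self.records.assign(source="synthetic")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)

    def subset(self, index) -> "OccurrenceSet":
        return OccurrenceSet(self.records.iloc[np.asarray(index)].copy(), self.crs)

    def to_csv(self, path) -> None:
        out = self.records.rename(columns={"x": "lon", "y": "lat"})
        out[["id", "lon", "lat", "source"]].to_csv(path, index=False)


def load_occurrences(path, crs: str = "synthetic-km") -> OccurrenceSet:
    """Parse a CSV of presence records; x/y or lon/lat column names accepted.

    Rows whose coordinates fail to parse are dropped and counted in the log.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    cols = {}
    for canon, aliases in _XY_ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is None:
            raise FormatError(f"no column for {canon!r} (accepted: {aliases})")
        cols[canon] = found
    if df.empty:
        logger.warning("occurrence file %s is empty", path)
    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    ok = x.notna() & y.notna() & np.isfinite(x.fillna(np.inf)) & np.isfinite(y.fillna(np.inf))
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropped %d rows with unparseable coordinates", n_bad)
    out = pd.DataFrame(
        {
            "id": df["id"].astype(str) if "id" in df.columns else [f"occ{i}" for i in range(len(df))],
            "x": x,
            "y": y,
            "source": df["source"] if "source" in df.columns else "synthetic",
        }
    )[ok.to_numpy()]
    return OccurrenceSet(out, crs=crs)


def dedupe(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop exact coordinate duplicates, keeping the first occurrence."""
    keep = ~occ.records.duplicated(subset=["x", "y"], keep="first")
    return OccurrenceSet(occ.records[keep.to_numpy()].copy(), occ.crs)


def pairwise_distances_km(xy: np.ndarray, crs: str) -> np.ndarray:
    """Dense pairwise distance matrix; Euclidean for planar, haversine for lon/lat."""
    if crs in ("lonlat", "EPSG:4326"):
        lon = np.radians(xy[:, 0])[:, None]
        lat = np.radians(xy[:, 1])[:, None]
        dlat = lat - lat.T
        dlon = lon - lon.T
        a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def thin_occurrences(
    occ: OccurrenceSet,
    min_dist_km: float = 5.0,
    n_restarts: int = 100,
    seed: int = 0,
    method: str = "distance",
    cell_area_km2: float = 5.0,
) -> OccurrenceSet:
    """Spatially thin records so retained points are mutually separated.

    ``method="distance"`` (default) enforces a minimum pairwise distance of
    ``min_dist_km`` and maximizes retention by randomized greedy selection
    over ``n_restarts`` shuffles of the visiting order — the spThin strategy.
    Ties between equal-size solutions are broken by the lexicographically
    smallest retained-id set, so the result is deterministic given ``seed``.

    ``method="grid"`` instead keeps one record per square grid cell of area
    ``cell_area_km2`` (first record wins), the cell-membership reading of
    one-point-per-cell rarefaction.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    n = len(occ)
    if n == 0:
        return occ

    if method == "grid":
        side = float(np.sqrt(cell_area_km2))
        cells = np.floor(occ.xy / side).astype(int)
        keys = pd.DataFrame(cells, columns=["cx", "cy"])
        keep = ~keys.duplicated(keep="first")
        result = occ.subset(np.flatnonzero(keep.to_numpy()))
    elif method == "distance":
        dist = pairwise_distances_km(occ.xy, occ.crs)
        conflict = dist < min_dist_km
        np.fill_diagonal(conflict, False)
        ids = occ.records["id"].to_numpy()
        rng = np.random.default_rng(seed)
        best_idx: np.ndarray | None = None
        best_key: tuple | None = None
        for _ in range(max(1, n_restarts)):
            order = rng.permutation(n)
            taken = np.zeros(n, dtype=bool)
            blocked = np.zeros(n, dtype=bool)
            for i in order:
                if not blocked[i]:
                    taken[i] = True
                    blocked |= conflict[i]
            idx = np.flatnonzero(taken)
            key = (-idx.size, tuple(sorted(ids[idx])))
            if best_key is None or key < best_key:
                best_key, best_idx = key, idx
        result = occ.subset(np.sort(best_idx))
    else:
        raise ValueError(f"unknown thinning method {method!r}")

    pct = 100.0 * len(result) / n
    logger.info(
        "thinning retained %d of %d records (%.0f%%) at %s",
        len(result), n, pct,
        f"{min_dist_km} km" if method == "distance" else f"{cell_area_km2} km^2 cells",
    )
    return result


def max_retention_bruteforce(xy: np.ndarray, min_dist_km: float, crs: str = "synthetic-km") -> int:
    """Exhaustive maximum-retention count for small instances (oracle; ≤ ~15 pts)."""
    n = len(xy)
    dist = pairwise_distances_km(np.asarray(xy, float), crs)
    best = 0
    for k in range(n, 0, -1):
        for combo in itertools.combinations(range(n), k):
            sub = dist[np.ix_(combo, combo)]
            iu = np.triu_indices(k, 1)
            if k == 1 or (sub[iu] >= min_dist_km).all():
                return k
    return best
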