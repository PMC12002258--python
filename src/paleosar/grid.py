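"""Equal-area gridding of paleocoordinates and great-circle geometry.

Cells come from an equal-area latitude-band tessellation: the sphere is cut
into latitude rings of ~``spacing_km`` height, and each ring is divided into
cells of ~``spacing_km`` arc width at the ring's central latitude, so every
cell has approximately equal area.  Only cell *midpoints* feed the rest of
the pipeline, so the exact tessellation is a convenience, not a commitment.

All distances are great-circle kilometers on a sphere of radius 6371.0088 km
(ellipsoidal precision is meaningless at the >100 km uncertainty of
paleocoordinates).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["EARTH_RADIUS_KM", "KM_PER_DEG", "great_circle_km",
           "pairwise_great_circle_km", "EqualAreaGrid", "bin_to_cells"]

EARTH_RADIUS_KM = 6371.0088
#: Kilometers per degree of arc along a great circle.
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def _check_bounds(lon, lat):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise ValueError("coordinate out of bounds: |lon|<=180, |lat|<=90 required")
    return lon, lat


def great_circle_km(a, b) -> float:
    """Haversine great-circle distance between ``a=(lon, lat)`` and
    ``b=(lon, lat)`` in kilometers."""
    lon1, lat1 = _check_bounds(*a)
    lon2, lat2 = _check_bounds(*b)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def pairwise_great_circle_km(lons, lats) -> np.ndarray:
    """Dense symmetric matrix of great-circle distances (km)."""
    lons, lats = _check_bounds(lons, lats)
    p = np.radians(lats)[:, None]
    lam = np.radians(lons)[:, None]
    h = (np.sin((p - p.T) / 2.0) ** 2
         + np.cos(p) * np.cos(p.T) * np.sin((lam - lam.T) / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


class EqualAreaGrid:
    """Equal-area latitude-band grid with ~``spacing_km`` cell pitch."""

    def __init__(self, spacing_km: float = 100.0):
        if not (25.0 <= spacing_km <= 500.0):
            raise ValueError(f"grid spacing {spacing_km} km outside [25, 500]")
        self.spacing_km = float(spacing_km)
        self.n_rings = max(1, int(round(np.pi * EARTH_RADIUS_KM / spacing_km)))
        edges = np.linspace(-90.0, 90.0, self.n_rings + 1)
        self._ring_mid_lat = 0.5 * (edges[:-1] + edges[1:])
        circumference = 2.0 * np.pi * EARTH_RADIUS_KM * np.cos(np.radians(self._ring_mid_lat))
        self._ring_n_cells = np.maximum(1, np.round(circumference / spacing_km)).astype(int)

    def cell_of(self, lon, lat):
        """Map coordinates to string cell ids ``"r<ring>c<index>"``."""
        lon, lat = _check_bounds(lon, lat)
        ring = np.clip(((np.asarray(lat) + 90.0) / 180.0 * self.n_rings).astype(int),
                       0, self.n_rings - 1)
        n = self._ring_n_cells[ring]
        frac = np.mod(np.asarray(lon) + 180.0, 360.0) / 360.0
        ix = np.minimum((frac * n).astype(int), n - 1)
        if np.isscalar(lon) or np.ndim(lon) == 0:
            return f"r{int(ring)}c{int(ix)}"
        return np.array([f"r{r}c{i}" for r, i in zip(np.atleast_1d(ring), np.atleast_1d(ix))])

    def midpoint(self, cell_id: str):
        """Cell midpoint ``(lon, lat)`` in degrees."""
        ring, ix = cell_id[1:].split("c")
        ring, ix = int(ring), int(ix)
        n = self._ring_n_cells[ring]
        lon = -180.0 + (ix + 0.5) * 360.0 / n
        return lon, float(self._ring_mid_lat[ring])


def bin_to_cells(table: pd.DataFrame, spacing_km: float = 100.0,
                 by=("bin", "group")) -> pd.DataFrame:
    """Aggregate occurrences into equal-area grid cells per bin x group.

    Returns one row per occupied cell with columns ``cell_id``, ``lon``,
    ``lat`` (cell midpoint), ``n_collections``, ``n_occurrences``, plus the
    grouping columns.  Occurrence totals are conserved: the summed
    ``n_occurrences`` equals the input row count.
    """
    grid = EqualAreaGrid(spacing_km)
    df = table.copy()
    df["cell_id"] = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    keys = [k for k in by if k in df.columns]
    grouped = df.groupby(keys + ["cell_id"], observed=True, sort=True).agg(
        n_collections=("collection", "nunique"),
        n_occurrences=("species", "size"),
    ).reset_index()
    if len(grouped):
        mids = np.array([grid.midpoint(c) for c in grouped["cell_id"]])
        grouped["lon"] = mids[:, 0]
        grouped["lat"] = mids[:, 1]
    else:
        grouped["lon"] = np.array([], dtype=float)
        grouped["lat"] = np.array([], dtype=float)
    return grouped
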