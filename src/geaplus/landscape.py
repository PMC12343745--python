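"""Spatial landscape: collection sites, adjacency graph and migration rates.

Sites mimic crop collection sites scattered over a region; a greedy spatial
thinning enforces a minimum spacing, each retained site receives the local
environmental optimum from a raster, and migration follows a stepping-stone
graph (Gabriel graph over great-circle distances) with inverse-distance
rates, row-normalized so the total emigration probability per site stays
below a cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._geo import haversine_km, pairwise_haversine_km
from .env import EnvRaster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Site:
    id: int
    lon: float
    lat: float
    y_opt: float  # local optimum phenotype, environment units
    K: int  # carrying capacity

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"site {self.id}: coordinates out of range")
        if self.K < 0:
            raise ValueError(f"site {self.id}: negative carrying capacity")


@dataclass
class Landscape:
    sites: list[Site]
    min_spacing_km: float
    adjacency: set[tuple[int, int]] = field(default_factory=set)  # symmetric, stored i<j
    migration_rates: dict[tuple[int, int], float] = field(default_factory=dict)  # directed (src, dst)

    def __post_init__(self):
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site ids must be unique")
        self._index = {s.id: k for k, s in enumerate(self.sites)}

    def __len__(self):
        return len(self.sites)

    @property
    def lon(self) -> np.ndarray:
        return np.array([s.lon for s in self.sites])

    @property
    def lat(self) -> np.ndarray:
        return np.array([s.lat for s in self.sites])

    @property
    def y_opt(self) -> np.ndarray:
        return np.array([s.y_opt for s in self.sites])

    @property
    def K(self) -> np.ndarray:
        return np.array([s.K for s in self.sites], dtype=int)

    def site_index(self, site_id: int) -> int:
        return self._index[site_id]

    def neighbors(self, site_id: int) -> list[tuple[int, float]]:
        """(destination id, per-generation migration probability) pairs."""
        return [(dst, m) for (src, dst), m in self.migration_rates.items() if src == site_id]

    def total_carrying_capacity(self) -> int:
        return int(self.K.sum())

    def validate(self) -> None:
        d = pairwise_haversine_km(self.lon, self.lat)
        np.fill_diagonal(d, np.inf)
        if d.min() < self.min_spacing_km - 1e-9:
            raise ValueError("sites closer than min_spacing_km")
        out = {}
        for (src, _dst), m in self.migration_rates.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError("migration rate outside [0, 1]")
            out[src] = out.get(src, 0.0) + m
        if out and max(out.values()) > 1.0 + 1e-12:
            raise ValueError("total emigration probability exceeds 1")


def thin_sites(coords: np.ndarray, min_spacing_km: float) -> np.ndarray:
    """Greedy spatial thinning: keep a site iff it is >= min_spacing_km from
    every previously kept site (first-come order). Returns kept row indices."""
    coords = np.asarray(coords, dtype=float)
    kept: list[int] = []
    for i in range(coords.shape[0]):
        if all(
            haversine_km(coords[i, 0], coords[i, 1], coords[j, 0], coords[j, 1]) >= min_spacing_km
            for j in kept
        ):
            kept.append(i)
    return np.asarray(kept, dtype=int)


def gabriel_graph(lon: np.ndarray, lat: np.ndarray) -> set[tuple[int, int]]:
    """Gabriel graph on great-circle distances: edge (i, j) iff no third site
    falls inside the circle having ij as diameter (d_ik^2 + d_jk^2 <= d_ij^2)."""
    d = pairwise_haversine_km(lon, lat)
    n = d.shape[0]
    edges: set[tuple[int, int]] = set()
    d2 = d**2
    for i in range(n):
        for j in range(i + 1, n):
            others = np.ones(n, dtype=bool)
            others[[i, j]] = False
            if not np.any(d2[i, others] + d2[j, others] <= d2[i, j] + 1e-9):
                edges.add((i, j))
    return edges


def generate_site_coords(
    n_candidates: int,
    extent: tuple[float, float, float, float],
    seed: int | None = None,
) -> np.ndarray:
    """Uniform random candidate collection sites inside a lon/lat extent."""
    rng = np.random.default_rng(seed)
    lon_min, lon_max, lat_min, lat_max = extent
    lon = rng.uniform(lon_min, lon_max, n_candidates)
    lat = rng.uniform(lat_min, lat_max, n_candidates)
    return np.column_stack([lon, lat])


def build_landscape(
    site_coords,
    min_spacing_km: float,
    k_site: int,
    env_raster: EnvRaster,
    *,
    m0_km: float = 1.0,
    m_total: float = 0.05,
    extraction_mode: str = "bilinear",
) -> Landscape:
    """Thin candidate sites, attach environmental optima and build the
    stepping-stone migration graph.

    Migration rate along Gabriel edge (i, j) is m0_km / d_ij (km), then each
    site's outgoing rates are rescaled, if needed, so they sum to at most
    ``m_total``.
    """
    coords = np.asarray(site_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("site_coords must be (n, 2) lon/lat")
    kept = thin_sites(coords, min_spacing_km)
    coords = coords[kept]

    y_opt = env_raster.extract(coords[:, 0], coords[:, 1], mode=extraction_mode)
    ok = np.isfinite(y_opt)
    if not np.all(ok):
        logger.warning("rejecting %d site(s) on masked raster cells", int((~ok).sum()))
        coords, y_opt = coords[ok], y_opt[ok]
    if coords.shape[0] < 2:
        raise ValueError("fewer than 2 sites survive thinning / raster masking")

    sites = [
        Site(id=i, lon=float(coords[i, 0]), lat=float(coords[i, 1]), y_opt=float(y_opt[i]), K=k_site)
        for i in range(coords.shape[0])
    ]
    edges = gabriel_graph(coords[:, 0], coords[:, 1])

    rates: dict[tuple[int, int], float] = {}
    for i, j in edges:
        d = float(haversine_km(coords[i, 0], coords[i, 1], coords[j, 0], coords[j, 1]))
        m = m0_km / d
        rates[(i, j)] = m
        rates[(j, i)] = m
    totals: dict[int, float] = {}
    for (src, _), m in rates.items():
        totals[src] = totals.get(src, 0.0) + m
    for key in list(rates):
        tot = totals[key[0]]
        if tot > m_total:
            rates[key] *= m_total / tot

    land = Landscape(sites=sites, min_spacing_km=min_spacing_km, adjacency=edges, migration_rates=rates)
    land.validate()
    return land


def nearest_site(landscape: Landscape, lon: float, lat: float) -> int:
    """Id of the landscape site closest to a coordinate (used to place refugia)."""
    d = haversine_km(landscape.lon, landscape.lat, lon, lat)
    return landscape.sites[int(np.argmin(d))].id
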