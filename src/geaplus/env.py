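"""Synthetic environment rasters, point extraction and environmental PCA.

The raster is a stand-in for a gridded bioclimatic layer (e.g. mean
temperature of the warmest quarter): a deterministic large-scale gradient
plus smooth, seed-controlled Gaussian bumps, optionally with a no-data mask
(e.g. sea).  Values are in standardized environment units centered near 0 so
they can double as the locally optimal phenotype in the simulator.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class EnvRaster:
    """Regular lon/lat grid of one or more named scalar layers.

    ``lon`` and ``lat`` are strictly increasing cell-center axes; each layer
    is a (nlat, nlon) array; ``mask`` is True on no-data cells.
    """

    lon: np.ndarray
    lat: np.ndarray
    layers: dict[str, np.ndarray]
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if np.any(np.diff(self.lon) <= 0) or np.any(np.diff(self.lat) <= 0):
            raise ValueError("raster axes must be strictly increasing")
        shape = (self.lat.size, self.lon.size)
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} has shape {arr.shape}, expected {shape}")
        if self.mask is None:
            self.mask = np.zeros(shape, dtype=bool)
        elif self.mask.shape != shape:
            raise ValueError("mask shape does not match grid")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def values(self, name: str | None = None) -> np.ndarray:
        if name is None:
            name = next(iter(self.layers))
        return self.layers[name]

    # -- extraction ---------------------------------------------------------
    def extract(self, lon, lat, layer: str | None = None, mode: str = "bilinear") -> np.ndarray:
        """Sample the raster at points; NaN marks missing (outside or masked).

        ``mode='bilinear'`` interpolates from the 4 surrounding cell centers;
        a masked corner triggers a nearest-unmasked fallback within one cell,
        otherwise the point is missing.  ``mode='nearest'`` mirrors typical
        WorldClim-style cell lookup.
        """
        return extract_env(self, np.column_stack([np.atleast_1d(lon), np.atleast_1d(lat)]), layer=layer, mode=mode)

    # -- plain-text persistence --------------------------------------------
    def save(self, path) -> None:
        header = {
            "lon": self.lon.tolist(),
            "lat": self.lat.tolist(),
            "layers": self.layer_names,
            "nodata": "nan",
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for name in self.layer_names:
                vals = self.layers[name].astype(float).copy()
                vals[self.mask] = np.nan
                for row in vals:
                    fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "EnvRaster":
        with open(path) as fh:
            header = json.loads(fh.readline())
            nlat, nlon = len(header["lat"]), len(header["lon"])
            layers = {}
            for name in header["layers"]:
                rows = [np.fromstring(fh.readline(), sep=" ") for _ in range(nlat)]
                layers[name] = np.vstack(rows)
        mask = np.isnan(next(iter(layers.values())))
        for name in layers:
            layers[name] = np.nan_to_num(layers[name])
        return cls(np.asarray(header["lon"]), np.asarray(header["lat"]), layers, mask)


def make_raster(
    extent: tuple[float, float, float, float],
    resolution: float,
    *,
    gradient: tuple[float, float, float] = (0.0, 0.25, 0.15),
    n_bumps: int = 6,
    bump_amplitude: float = 0.5,
    bump_scale_deg: float = 3.0,
    mask_box: tuple[float, float, float, float] | None = None,
    layer: str = "env",
    seed: int | None = None,
) -> EnvRaster:
    """Build a smooth synthetic environment raster.

    value = c + a*(lat - lat0) + b*(lon - lon0) + sum of Gaussian bumps,
    with ``gradient = (c, a, b)`` and centers (lon0, lat0) at the extent
    midpoint.  Bumps are seed-controlled; the gradient is not, so two seeds
    share the same large-scale trend.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lon = np.arange(lon_min, lon_max + resolution / 2, resolution)
    lat = np.arange(lat_min, lat_max + resolution / 2, resolution)
    lon0, lat0 = (lon_min + lon_max) / 2.0, (lat_min + lat_max) / 2.0
    c, a, b = gradient
    LON, LAT = np.meshgrid(lon, lat)
    vals = c + a * (LAT - lat0) + b * (LON - lon0)
    if n_bumps > 0 and bump_amplitude != 0.0:
        rng = np.random.default_rng(seed)
        cx = rng.uniform(lon_min, lon_max, n_bumps)
        cy = rng.uniform(lat_min, lat_max, n_bumps)
        amp = rng.normal(0.0, bump_amplitude, n_bumps)
        for x0, y0, h in zip(cx, cy, amp):
            vals += h * np.exp(-(((LON - x0) ** 2 + (LAT - y0) ** 2) / (2.0 * bump_scale_deg**2)))
    mask = np.zeros_like(vals, dtype=bool)
    if mask_box is not None:
        mlo, mhi, plo, phi = mask_box
        mask |= (LON >= mlo) & (LON <= mhi) & (LAT >= plo) & (LAT <= phi)
    return EnvRaster(lon, lat, {layer: vals}, mask)


def extract_env(raster: EnvRaster, coords, *, layer: str | None = None, mode: str = "bilinear") -> np.ndarray:
    """Extract environment values at (lon, lat) points; NaN where missing.

    Out-of-extent points and points whose interpolation neighbourhood is
    fully masked come back as NaN and are counted in a log message; callers
    exclude them downstream.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2) lon/lat")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    vals2d = raster.values(layer)
    lon_ax, lat_ax = raster.lon, raster.lat
    n = coords.shape[0]
    out = np.full(n, np.nan)

    x, y = coords[:, 0], coords[:, 1]
    inside = (x >= lon_ax[0]) & (x <= lon_ax[-1]) & (y >= lat_ax[0]) & (y <= lat_ax[-1])

    if mode == "nearest":
        ix = np.abs(x[:, None] - lon_ax[None, :]).argmin(axis=1)
        iy = np.abs(y[:, None] - lat_ax[None, :]).argmin(axis=1)
        ok = inside & ~raster.mask[iy, ix]
        out[ok] = vals2d[iy[ok], ix[ok]]
    elif mode == "bilinear":
        ix1 = np.clip(np.searchsorted(lon_ax, x), 1, lon_ax.size - 1)
        iy1 = np.clip(np.searchsorted(lat_ax, y), 1, lat_ax.size - 1)
        ix0, iy0 = ix1 - 1, iy1 - 1
        tx = (x - lon_ax[ix0]) / (lon_ax[ix1] - lon_ax[ix0])
        ty = (y - lat_ax[iy0]) / (lat_ax[iy1] - lat_ax[iy0])
        corners = np.stack(
            [vals2d[iy0, ix0], vals2d[iy0, ix1], vals2d[iy1, ix0], vals2d[iy1, ix1]]
        )
        cmask = np.stack(
            [raster.mask[iy0, ix0], raster.mask[iy0, ix1], raster.mask[iy1, ix0], raster.mask[iy1, ix1]]
        )
        w = np.stack([(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty])
        clean = inside & ~cmask.any(axis=0)
        out[clean] = (w[:, clean] * corners[:, clean]).sum(axis=0)
        # masked-corner fallback: nearest unmasked corner of the enclosing cell
        dirty = inside & cmask.any(axis=0) & ~cmask.all(axis=0)
        if np.any(dirty):
            wd = np.where(cmask[:, dirty], -np.inf, w[:, dirty])
            pick = wd.argmax(axis=0)
            out[np.flatnonzero(dirty)] = corners[pick, np.flatnonzero(dirty)]
    else:
        raise ValueError(f"unknown extraction mode {mode!r}")

    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.info("extract_env: %d/%d points missing (outside extent or masked)", n_missing, n)
    return out


@dataclass
class EnvPCA:
    """PCA of multivariate environmental variables on the correlation matrix."""

    loadings: np.ndarray  # (n_vars_kept, k)
    scores: np.ndarray  # (n, k)
    variance_explained: np.ndarray  # (k,), fractions of total variance
    kept_variables: list[int] = field(default_factory=list)


def env_pca(env_matrix, k: int = 3) -> EnvPCA:
    """First ``k`` principal components of unit-scaled environmental variables.

    Constant variables are dropped with a warning.  Sign convention: the
    largest-magnitude entry of each loading vector is positive.
    """
    X = np.asarray(env_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("env matrix must be 2-D (individuals x variables)")
    if np.isnan(X).any():
        raise ValueError("env matrix contains missing rows; exclude them first")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} constant environmental variable(s)")
    X = X[:, keep]
    if X.shape[1] < k:
        raise ValueError(f"need at least k={k} non-constant variables, have {X.shape[1]}")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    p = PCA(n_components=k, svd_solver="full")
    scores = p.fit_transform(Z)
    loadings = p.components_.T.copy()
    for j in range(k):
        i_max = np.abs(loadings[:, j]).argmax()
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return EnvPCA(
        loadings=loadings,
        scores=scores,
        variance_explained=p.explained_variance_ratio_.copy(),
        kept_variables=list(np.flatnonzero(keep)),
    )
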