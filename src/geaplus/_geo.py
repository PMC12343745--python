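"""Great-circle geometry helpers.

All distances in the package go through :func:`haversine_km` with a single
Earth radius so that simulator, clustering and accuracy metrics agree.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lon, lat):
    """Full symmetric distance matrix (km) for coordinate vectors."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
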