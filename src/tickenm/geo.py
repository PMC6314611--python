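"""Great-circle geometry on the WGS84 sphere approximation.

All distances in this package go through :func:`haversine_km`, with the
Earth radius fixed at 6371.0088 km (IUGG mean radius) so results are
reproducible to the meter across modules.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: km per degree of great-circle arc on the mean-radius sphere
KM_PER_ARC_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Broadcasts over array inputs; the haversine form is numerically
    stable for small separations, unlike the spherical law of cosines.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distance_km(lons, lats):
    """Full symmetric matrix of great-circle distances (km) for a point set."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def arc_degrees(lon1, lat1, lon2, lat2):
    """Central angle between points, in degrees of great-circle arc."""
    return haversine_km(lon1, lat1, lon2, lat2) / KM_PER_ARC_DEGREE
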