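"""Spherical geometry and the local planar projection used throughout.

All spatial computation in this package happens on an azimuthal-equidistant
(AEQ) plane centered on the breeding colony, in kilometres.  At colony scale
(< 100 km) the AEQ plane preserves distances from the center exactly and
distorts pairwise distances negligibly, which keeps kernel-density and
step-kinematics code free of spherical bookkeeping.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6371.0 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def aeq_forward(lat, lon, lat0, lon0):
    """Project lat/lon (degrees) to (x, y) km on the AEQ plane centered at (lat0, lon0).

    x points east, y points north; the center maps to (0, 0).
    """
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    lat0 = np.radians(float(lat0))
    lon0 = np.radians(float(lon0))
    dlon = lon - lon0
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))  # angular distance
    az = np.arctan2(
        np.sin(dlon) * np.cos(lat),
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon),
    )
    d = EARTH_RADIUS_KM * c
    return d * np.sin(az), d * np.cos(az)


def aeq_inverse(x, y, lat0, lon0):
    """Inverse of :func:`aeq_forward`: (x, y) km back to (lat, lon) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lat0 = np.radians(float(lat0))
    lon0 = np.radians(float(lon0))
    d = np.hypot(x, y)
    delta = d / EARTH_RADIUS_KM
    az = np.arctan2(x, y)
    sin_lat = np.sin(lat0) * np.cos(delta) + np.cos(lat0) * np.sin(delta) * np.cos(az)
    lat = np.arcsin(np.clip(sin_lat, -1.0, 1.0))
    lon = lon0 + np.arctan2(
        np.sin(az) * np.sin(delta) * np.cos(lat0),
        np.cos(delta) - np.sin(lat0) * sin_lat,
    )
    return np.degrees(lat), np.degrees(lon)
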