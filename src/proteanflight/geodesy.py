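"""Geodesic distance and azimuth on the WGS84 ellipsoid.

Consecutive GPS fixes are a few tens of metres apart, but track endpoints
(release to loft) are several kilometres apart, so a proper ellipsoidal
solution is used throughout rather than a flat-earth approximation.  The
inverse problem is solved with Vincenty's iterative method, vectorized over
numpy arrays; for the short, non-antipodal baselines of homing-flight data
it converges in a handful of iterations to sub-millimetre accuracy.
"""

from __future__ import annotations

import numpy as np

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)

_MAX_ITER = 50
_TOL = 1e-12


def geodesic_inverse(lat1, lon1, lat2, lon2):
    """Distance (m) and initial azimuth (degrees clockwise from north).

    All arguments in decimal degrees; scalars or broadcastable arrays.
    Coincident points return distance 0 and azimuth 0.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    )
    phi1 = np.radians(lat1)
    phi2 = np.radians(lat2)
    L = np.radians(lon2 - lon1)

    U1 = np.arctan((1.0 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    coincident = (lat1 == lat2) & (lon1 == lon2)

    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos_2sigma_m = np.ones_like(lam)

    active = ~coincident
    for _ in range(_MAX_ITER):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma_n = np.sqrt(
            (cosU2 * sin_lam) ** 2
            + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        cos_sigma_n = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma_n = np.arctan2(sin_sigma_n, cos_sigma_n)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(
                sin_sigma_n != 0, cosU1 * cosU2 * sin_lam / np.where(sin_sigma_n == 0, 1, sin_sigma_n), 0.0
            )
        cos_sq_alpha_n = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_2sigma_m_n = np.where(
                cos_sq_alpha_n != 0,
                cos_sigma_n - 2.0 * sinU1 * sinU2 / np.where(cos_sq_alpha_n == 0, 1, cos_sq_alpha_n),
                0.0,  # equatorial line
            )
        C = WGS84_F / 16.0 * cos_sq_alpha_n * (4.0 + WGS84_F * (4.0 - 3.0 * cos_sq_alpha_n))
        lam_new = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma_n
            + C
            * sin_sigma_n
            * (cos_2sigma_m_n + C * cos_sigma_n * (-1.0 + 2.0 * cos_2sigma_m_n**2))
        )

        sin_sigma = np.where(active, sin_sigma_n, sin_sigma)
        cos_sigma = np.where(active, cos_sigma_n, cos_sigma)
        sigma = np.where(active, sigma_n, sigma)
        cos_sq_alpha = np.where(active, cos_sq_alpha_n, cos_sq_alpha)
        cos_2sigma_m = np.where(active, cos_2sigma_m_n, cos_2sigma_m)

        delta = np.abs(lam_new - lam)
        lam = np.where(active, lam_new, lam)
        active = active & (delta > _TOL)
        if not np.any(active):
            break

    u_sq = cos_sq_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - B
                / 6.0
                * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
    )
    distance = WGS84_B * A * (sigma - delta_sigma)

    sin_lam, cos_lam = np.sin(lam), np.cos(lam)
    azimuth = np.degrees(
        np.arctan2(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    )
    azimuth = np.mod(azimuth, 360.0)

    distance = np.where(coincident, 0.0, distance)
    azimuth = np.where(coincident, 0.0, azimuth)
    if distance.ndim == 0:
        return float(distance), float(azimuth)
    return distance, azimuth


def geodesic_distance(lat1, lon1, lat2, lon2):
    """Geodesic distance only (m)."""
    return geodesic_inverse(lat1, lon1, lat2, lon2)[0]


def step_distances(lat, lon):
    """Distances between consecutive fixes of a track (length n-1)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    d, _ = geodesic_inverse(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return np.atleast_1d(d)


def path_length(lat, lon):
    """Total along-track geodesic length of a fix sequence (m)."""
    if len(np.asarray(lat)) < 2:
        return 0.0
    return float(np.sum(step_distances(lat, lon)))


def local_scale(lat0, lon0):
    """Metres per degree of latitude and longitude near a reference point.

    Computed from the geodesic solver itself so that a local tangent-plane
    construction round-trips through `geodesic_inverse` consistently.
    """
    d_lat = geodesic_distance(lat0, lon0, lat0 + 0.01, lon0) / 0.01
    d_lon = geodesic_distance(lat0, lon0, lat0, lon0 + 0.01) / 0.01
    return d_lat, d_lon
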