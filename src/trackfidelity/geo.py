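"""Geodesic and projection primitives on the WGS84 ellipsoid.

All public distance functions accept scalars or numpy arrays of
longitudes/latitudes in decimal degrees (WGS84) and return metres.

The inverse geodesic uses Vincenty's iterative method, which is accurate to
well under a millimetre for the regional (< 10,000 km) distances handled
here; nearly-antipodal pairs, where Vincenty fails to converge, fall back to
the spherical great-circle formula.  A haversine implementation on the
authalic sphere is provided as a faster alternative behind the ``method``
switch used by the speed filter.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
# mean Earth radius (IUGG R1), used for haversine and great-circle fallback
EARTH_RADIUS_M = 6371008.8


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres on a sphere of mean Earth radius."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def vincenty_m(lon1, lat1, lon2, lat2, *, max_iter: int = 200, tol: float = 1e-12):
    """WGS84 inverse geodesic distance in metres (Vincenty's formulae).

    Vectorised; non-converged (nearly antipodal) elements fall back to the
    spherical great-circle distance.
    """
    lon1, lat1, lon2, lat2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2)))
    scalar = lon1.ndim == 0
    shape = lon1.shape
    lon1, lat1, lon2, lat2 = (np.atleast_1d(x).ravel()
                              for x in (lon1, lat1, lon2, lat2))

    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - WGS84_F) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1 - WGS84_F) * np.tan(np.radians(lat2)))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    active = np.ones(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(max_iter):
        if not active.any():
            break
        sl, cl = np.sin(lam[active]), np.cos(lam[active])
        su1, cu1 = sinU1[active], cosU1[active]
        su2, cu2 = sinU2[active], cosU2[active]
        ss = np.sqrt((cu2 * sl) ** 2 + (cu1 * su2 - su1 * cu2 * cl) ** 2)
        cs = su1 * su2 + cu1 * cu2 * cl
        sig = np.arctan2(ss, cs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(ss > 0, cu1 * cu2 * sl / np.where(ss == 0, 1, ss), 0.0)
        csa = 1.0 - sin_alpha ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2sm = np.where(csa != 0, cs - 2.0 * su1 * su2 / np.where(csa == 0, 1, csa), 0.0)
        C = WGS84_F / 16.0 * csa * (4.0 + WGS84_F * (4.0 - 3.0 * csa))
        lam_new = L[active] + (1.0 - C) * WGS84_F * sin_alpha * (
            sig + C * ss * (c2sm + C * cs * (-1.0 + 2.0 * c2sm ** 2)))

        sin_sigma[active] = ss
        cos_sigma[active] = cs
        sigma[active] = sig
        cos_sq_alpha[active] = csa
        cos2sm[active] = c2sm

        conv = np.abs(lam_new - lam[active]) < tol
        lam[active] = lam_new
        idx = np.flatnonzero(active)
        active[idx[conv]] = False

    u_sq = cos_sq_alpha * (WGS84_A ** 2 - WGS84_B ** 2) / WGS84_B ** 2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    dsig = B * sin_sigma * (cos2sm + B / 4.0 * (
        cos_sigma * (-1.0 + 2.0 * cos2sm ** 2)
        - B / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma ** 2) * (-3.0 + 4.0 * cos2sm ** 2)))
    dist = WGS84_B * A * (sigma - dsig)

    if active.any():  # antipodal fallback
        dist[active] = haversine_m(lon1[active], lat1[active], lon2[active], lat2[active])
    coincident = (lon1 == lon2) & (lat1 == lat2)
    dist[coincident] = 0.0
    return float(dist[0]) if scalar else dist.reshape(shape)


def geodesic_m(lon1, lat1, lon2, lat2, method: str = "ellipsoidal"):
    """Distance in metres; ``method`` is ``"ellipsoidal"`` (default) or ``"haversine"``."""
    if method == "ellipsoidal":
        return vincenty_m(lon1, lat1, lon2, lat2)
    if method == "haversine":
        return haversine_m(lon1, lat1, lon2, lat2)
    raise ValueError(f"unknown distance method: {method!r}")


def geodesic_km(lon1, lat1, lon2, lat2, method: str = "ellipsoidal"):
    return geodesic_m(lon1, lat1, lon2, lat2, method) / 1000.0


class LocalEqualArea:
    """Lambert azimuthal equal-area projection centred on (lon0, lat0).

    Spherical form on the authalic radius: area-true everywhere, which is
    what kernel home-range estimation and contour areas require at cluster
    scale.  Coordinates are metres east/north of the centre.
    """

    # authalic radius for WGS84
    R = 6371007.1809

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._l0 = np.radians(lon0)
        self._p0 = np.radians(lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float)) - self._l0
        phi = np.radians(np.asarray(lat, dtype=float))
        c = 1.0 + np.sin(self._p0) * np.sin(phi) + np.cos(self._p0) * np.cos(phi) * np.cos(lam)
        c = np.clip(c, 1e-12, None)
        k = np.sqrt(2.0 / c)
        x = self.R * k * np.cos(phi) * np.sin(lam)
        y = self.R * k * (np.cos(self._p0) * np.sin(phi) - np.sin(self._p0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.R
        y = np.asarray(y, dtype=float) / self.R
        rho = np.sqrt(x ** 2 + y ** 2)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho == 0, self._p0,
                np.arcsin(np.clip(np.cos(c) * np.sin(self._p0)
                                  + np.where(rho == 0, 0, y * np.sin(c) * np.cos(self._p0) / np.where(rho == 0, 1, rho)),
                                  -1.0, 1.0)))
            lam = np.where(
                rho == 0, 0.0,
                np.arctan2(x * np.sin(c),
                           rho * np.cos(self._p0) * np.cos(c) - y * np.sin(self._p0) * np.sin(c)))
        return np.degrees(lam + self._l0), np.degrees(phi)


def gc_interpolate(lon1: float, lat1: float, lon2: float, lat2: float, frac):
    """Points along the great circle from p1 to p2 at fractions ``frac`` in [0, 1]."""
    frac = np.asarray(frac, dtype=float)
    p1 = _unit_vector(lon1, lat1)
    p2 = _unit_vector(lon2, lat2)
    dot = float(np.clip(np.dot(p1, p2), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-12:
        v = np.outer(np.ones_like(frac), p1)
    else:
        v = (np.sin((1.0 - frac)[:, None] * omega) * p1[None, :]
             + np.sin(frac[:, None] * omega) * p2[None, :]) / np.sin(omega)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(v[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return lon, lat


def gc_destination(lon: float, lat: float, bearing_deg: float, dist_m: float):
    """Destination point on the sphere from a start point, initial bearing and distance."""
    delta = dist_m / EARTH_RADIUS_M
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    return float(np.degrees(lam2)), float(np.degrees(phi2))


def offset_m(lon, lat, dx_m, dy_m):
    """Shift points east by dx and north by dy metres (local tangent plane)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = np.degrees(np.asarray(dy_m, dtype=float) / EARTH_RADIUS_M)
    dlon = np.degrees(np.asarray(dx_m, dtype=float) / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    return lon + dlon, lat + dlat


def _unit_vector(lon, lat):
    lam, phi = np.radians(lon), np.radians(lat)
    return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])
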