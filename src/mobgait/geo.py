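"""Geodesic distances and a local planar projection on the WGS84 ellipsoid.

All distance computations in the package funnel through :func:`geodesic_km`
(Vincenty's inverse formula, accurate to well under a millimetre at the
sub-100 km scales handled here). Planar geometry (hull areas, ellipses,
turning angles) uses :func:`LocalProjection`, an equirectangular projection
about a reference point scaled by the local meridional and transverse radii
of curvature, so that projected separations agree with geodesic distances to
first order.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
WGS84_A = 6378137.0          # semi-major axis, m
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)

__all__ = ["geodesic_km", "LocalProjection", "WGS84_A", "WGS84_B", "WGS84_F"]


def geodesic_km(lat1, lon1, lat2, lon2, *, tol: float = 1e-12, max_iter: int = 200):
    """WGS84 geodesic distance in kilometres (Vincenty inverse, vectorized).

    Parameters broadcast against each other; scalars in → scalar out.
    Convergence is unconditional for the short (< a few hundred km) lines
    this package works with; near-antipodal pairs fall back to the last
    iterate, which is still metre-accurate and irrelevant at our scales.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    )
    scalar = lat1.ndim == 0
    phi1 = np.atleast_1d(np.radians(lat1))
    phi2 = np.atleast_1d(np.radians(lat2))
    L = np.atleast_1d(np.radians(lon2 - lon1))

    U1 = np.arctan((1 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)
    active = np.ones(lam.shape, dtype=bool)

    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        sin_sigma_new = np.hypot(t1, t2)
        cos_sigma_new = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma_new = np.arctan2(sin_sigma_new, cos_sigma_new)

        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(
                sin_sigma_new > 0, cosU1 * cosU2 * sin_lam / sin_sigma_new, 0.0
            )
        cos_sq_alpha_new = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2sm_new = np.where(
                cos_sq_alpha_new > 0,
                cos_sigma_new - 2.0 * sinU1 * sinU2 / np.where(
                    cos_sq_alpha_new > 0, cos_sq_alpha_new, 1.0
                ),
                0.0,  # equatorial line
            )
        C = WGS84_F / 16.0 * cos_sq_alpha_new * (
            4.0 + WGS84_F * (4.0 - 3.0 * cos_sq_alpha_new)
        )
        lam_new = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma_new
            + C * sin_sigma_new * (
                cos2sm_new + C * cos_sigma_new * (-1.0 + 2.0 * cos2sm_new**2)
            )
        )

        upd = active
        sin_sigma = np.where(upd, sin_sigma_new, sin_sigma)
        cos_sigma = np.where(upd, cos_sigma_new, cos_sigma)
        sigma = np.where(upd, sigma_new, sigma)
        cos_sq_alpha = np.where(upd, cos_sq_alpha_new, cos_sq_alpha)
        cos2sm = np.where(upd, cos2sm_new, cos2sm)
        converged = np.abs(lam_new - lam) < tol
        lam = np.where(upd, lam_new, lam)
        active = active & ~converged
        if not active.any():
            break

    u_sq = cos_sq_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = B * sin_sigma * (
        cos2sm
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - B / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    s = WGS84_B * A * (sigma - delta_sigma) / 1000.0

    # coincident points short-circuit (sigma -> 0 handles it, but be exact)
    coincident = (phi1 == phi2) & (L == 0.0)
    s = np.where(coincident, 0.0, s)
    return float(s[0]) if scalar else s.reshape(lat1.shape)


def _curvature_radii_km(lat0_deg: float) -> tuple[float, float]:
    """Meridional (M) and transverse (N) radii of curvature at lat0, in km."""
    e2 = WGS84_F * (2.0 - WGS84_F)
    s = np.sin(np.radians(lat0_deg))
    w = np.sqrt(1.0 - e2 * s * s)
    M = WGS84_A * (1.0 - e2) / w**3
    N = WGS84_A / w
    return M / 1000.0, N / 1000.0


class LocalProjection:
    """Invertible equirectangular projection about a reference point, in km.

    x runs east, y runs north. Scale factors are the WGS84 curvature radii at
    the reference latitude, which keeps planar distances within ~1e-4 of
    geodesic ones for extents below a few tens of kilometres.
    """

    MAX_EXTENT_KM = 100.0

    def __init__(self, lat0: float, lon0: float):
        if not (-90.0 <= lat0 <= 90.0):
            raise ValueError(f"reference latitude {lat0} outside [-90, 90]")
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        M, N = _curvature_radii_km(lat0)
        self._ky = M * np.pi / 180.0                       # km per degree latitude
        self._kx = N * np.cos(np.radians(lat0)) * np.pi / 180.0  # km per degree longitude

    @classmethod
    def around_centroid(cls, lats, lons) -> "LocalProjection":
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        if lats.size == 0:
            raise ValueError("cannot build a projection from zero points")
        if np.ptp(lons) > 180.0:
            raise ValueError("trajectory crosses the antimeridian; unsupported")
        return cls(float(np.mean(lats)), float(np.mean(lons)))

    def forward(self, lats, lons):
        """Degrees -> planar (x, y) km. Raises if the extent exceeds 100 km."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        dlon = lons - self.lon0
        if np.any(np.abs(dlon) > 180.0):
            raise ValueError("longitude span crosses the antimeridian; unsupported")
        x = dlon * self._kx
        y = (lats - self.lat0) * self._ky
        if x.size and max(np.max(np.abs(x)), np.max(np.abs(y))) > self.MAX_EXTENT_KM:
            raise ValueError("extent exceeds the 100 km local-projection limit")
        return x, y

    def inverse(self, x, y):
        """Planar (x, y) km -> (lat, lon) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.lat0 + y / self._ky, self.lon0 + x / self._kx
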