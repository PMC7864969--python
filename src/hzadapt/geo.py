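"""Geodesic distances between populations on the WGS84 ellipsoid.

Distances use Vincenty's inverse formula. The iteration can fail to
converge for nearly antipodal points; such pairs (which do not occur for
populations within one hybrid zone) fall back to the great-circle
distance on the ellipsoid's mean radius and are logged.
"""

from __future__ import annotations

import math

import numpy as np

from .core import PopulationMap, logger

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)


def vincenty_inverse(
    lat1: float, lon1: float, lat2: float, lon2: float,
    tol: float = 1e-12, max_iter: int = 200,
) -> float:
    """Geodesic distance in metres between two WGS84 points.

    Raises ``ArithmeticError`` on non-convergence (nearly antipodal
    points); callers may fall back to a spherical distance.
    """
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1.0 - WGS84_F) * math.tan(phi1))
    U2 = math.atan((1.0 - WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sigma_m = (
            cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        )
        C = WGS84_F / 16.0 * cos2_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
            )
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise ArithmeticError("Vincenty iteration did not converge")

    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
            - B / 6.0 * cos_2sigma_m
            * (-3.0 + 4.0 * sin_sigma**2)
            * (-3.0 + 4.0 * cos_2sigma_m**2)
        )
    )
    return WGS84_B * A * (sigma - delta_sigma)


def _spherical_fallback(lat1, lon1, lat2, lon2) -> float:
    R = (2.0 * WGS84_A + WGS84_B) / 3.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    h = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2.0 * R * math.asin(math.sqrt(h))


def geographic_distance_matrix(pmap: PopulationMap) -> "pd.DataFrame":
    """Symmetric population x population geodesic distance matrix (km)."""
    import pandas as pd

    pops = pmap.populations
    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        la1, lo1, _ = pmap.pop_coords[pops[i]]
        if not (-90 <= la1 <= 90 and -180 <= lo1 <= 360):
            raise ValueError(f"invalid coordinates for population {pops[i]!r}")
        for j in range(i + 1, n):
            la2, lo2, _ = pmap.pop_coords[pops[j]]
            try:
                d = vincenty_inverse(la1, lo1, la2, lo2)
            except ArithmeticError:
                d = _spherical_fallback(la1, lo1, la2, lo2)
                logger.warning(
                    "Vincenty non-convergence for %s-%s; spherical fallback used",
                    pops[i], pops[j],
                )
            D[i, j] = D[j, i] = d / 1000.0
    return pd.DataFrame(D, index=pops, columns=pops)
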