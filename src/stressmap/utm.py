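"""WGS84 <-> UTM conversion (transverse Mercator, Krüger series).

Forward and inverse projection using the 6th-order series in the third
flattening, accurate to well under a millimetre within a UTM zone — far below
GPS error, which dominates at walking scale. Only the pieces the grid
aggregation needs are exposed: zone selection from a lon/lat centroid, and
vectorised forward/inverse transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E = math.sqrt(_F * (2.0 - _F))
_N = _F / (2.0 - _F)

_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

# Rectifying radius
_A1 = _A / (1 + _N) * (1 + _N**2 / 4 + _N**4 / 64 + _N**6 / 256)

# Krüger series coefficients (forward: alpha, inverse: beta), order n^6.
_ALPHA = (
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
    - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440 + 281 * _N**5 / 630
    - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
    + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
)
_BETA = (
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
    - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
    - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
    + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
)


def utm_zone(lon: float, lat: float) -> tuple[int, bool]:
    """UTM zone number and hemisphere flag (northern=True) for a point."""
    zone = int((lon + 180.0) // 6.0) + 1
    zone = min(max(zone, 1), 60)
    return zone, lat >= 0


def zone_central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def to_utm(lon, lat, zone: int, northern: bool = True):
    """Project lon/lat (degrees, scalars or arrays) to UTM easting/northing (m)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam0 = math.radians(zone_central_meridian(zone))
    phi = np.radians(lat)
    lam = np.radians(lon) - lam0

    sphi = np.sin(phi)
    # conformal latitude via tau' = sinh(asinh(tan) adjusted for e)
    t = np.sinh(np.arctanh(sphi) - _E * np.arctanh(_E * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.sqrt(t * t + np.cos(lam) ** 2))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _A1 * eta
    northing = _K0 * _A1 * xi
    if not northern:
        northing = northing + _FALSE_NORTHING_SOUTH
    return easting, northing


def from_utm(easting, northing, zone: int, northern: bool = True):
    """Inverse projection: UTM easting/northing (m) back to lon/lat degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not northern:
        northing = northing - _FALSE_NORTHING_SOUTH
    xi = northing / (_K0 * _A1)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A1)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    sinh_eta = np.sinh(eta_p)
    cos_xi = np.cos(xi_p)
    lam = np.arctan2(sinh_eta, cos_xi)
    tau_p = np.sin(xi_p) / np.sqrt(sinh_eta * sinh_eta + cos_xi * cos_xi)

    # Newton inversion of the conformal-latitude map tau'(phi)
    tau = tau_p.copy()
    for _ in range(6):
        sphi = tau / np.sqrt(1 + tau * tau)
        sigma = np.sinh(_E * np.arctanh(_E * sphi))
        f = tau * np.sqrt(1 + sigma * sigma) - sigma * np.sqrt(1 + tau * tau) - tau_p
        dtau = (
            (np.sqrt((1 + sigma * sigma) * (1 + tau * tau)) - sigma * tau)
            * (1 - _E * _E)
            * np.sqrt(1 + tau * tau)
            / (1 + (1 - _E * _E) * tau * tau)
        )
        tau = tau - f / dtau

    lat = np.degrees(np.arctan(tau))
    lon = np.degrees(lam + math.radians(zone_central_meridian(zone)))
    return lon, lat


@dataclass(frozen=True)
class UtmCrs:
    """A concrete metric CRS: one UTM zone + hemisphere."""

    zone: int
    northern: bool = True

    @classmethod
    def for_points(cls, lon, lat) -> "UtmCrs":
        """Zone auto-selected from the centroid of the given points."""
        zone, northern = utm_zone(float(np.mean(lon)), float(np.mean(lat)))
        return cls(zone=zone, northern=northern)

    @property
    def name(self) -> str:
        return f"UTM{self.zone}{'N' if self.northern else 'S'}"

    def project(self, lon, lat):
        return to_utm(lon, lat, self.zone, self.northern)

    def unproject(self, easting, northing):
        return from_utm(easting, northing, self.zone, self.northern)
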