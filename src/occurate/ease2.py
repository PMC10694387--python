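"""EASE-Grid 2.0 Global projection (EPSG:6933).

Ellipsoidal Lambert cylindrical equal-area projection on WGS 84 with
standard parallel 30° N — the projection underlying the 100-km equal-area
analysis grid. Forward and inverse transforms follow the standard
closed-form equations (Snyder, *Map Projections: A Working Manual*,
eqs. 3-12, 10-1/10-2 and the authalic-latitude series 3-18).

All functions accept scalars or numpy arrays of degrees / metres.
"""

from __future__ import annotations

import numpy as np

#: WGS 84 semi-major axis (m) and squared first eccentricity.
A = 6378137.0
F = 1.0 / 298.257223563
E2 = F * (2.0 - F)
E = np.sqrt(E2)

_LAT_TS = np.deg2rad(30.0)
#: Scale factor along the standard parallel.
K0 = np.cos(_LAT_TS) / np.sqrt(1.0 - E2 * np.sin(_LAT_TS) ** 2)


def _q(sin_phi):
    """Authalic function q(φ) from sin φ (Snyder eq. 3-12)."""
    es = E * sin_phi
    return (1.0 - E2) * (
        sin_phi / (1.0 - es * es) - np.log((1.0 - es) / (1.0 + es)) / (2.0 * E)
    )


Q_POLE = float(_q(1.0))

#: Full map extent: |x| ≤ X_MAX, |y| ≤ Y_MAX.
X_MAX = A * K0 * np.pi
Y_MAX = A * Q_POLE / (2.0 * K0)


def forward(lon_deg, lat_deg):
    """Project geographic coordinates (degrees) to EASE-2 metres (x, y)."""
    lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    x = A * K0 * lon
    y = A * _q(np.sin(lat)) / (2.0 * K0)
    return x, y


def inverse(x, y):
    """Back-project EASE-2 metres to (longitude, latitude) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = x / (A * K0)
    q = 2.0 * K0 * y / A
    beta = np.arcsin(np.clip(q / Q_POLE, -1.0, 1.0))
    # Authalic→geodetic latitude series (Snyder eq. 3-18).
    e4 = E2 * E2
    e6 = e4 * E2
    phi = (
        beta
        + (E2 / 3.0 + 31.0 * e4 / 180.0 + 517.0 * e6 / 5040.0) * np.sin(2.0 * beta)
        + (23.0 * e4 / 360.0 + 251.0 * e6 / 3780.0) * np.sin(4.0 * beta)
        + (761.0 * e6 / 45360.0) * np.sin(6.0 * beta)
    )
    return np.rad2deg(lon), np.rad2deg(phi)
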