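"""Great-circle distances between society centroids and the Gaussian kernel.

Societies in geographic proximity share environment, demography and cultural
contact; the residual covariance of a cross-cultural regression therefore
carries a spatial component.  Distances are haversine great-circle distances
on a sphere of radius 6371.0 km; spatial similarity decays as
``S_ij = exp(-(d_ij / sigma_s)**2)`` with length-scale ``sigma_s`` in km.

A Gaussian kernel of geodesic (rather than chordal) distance is not
guaranteed positive semi-definite on the sphere, so matrices are repaired by
flooring eigenvalues before entering likelihood computations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("phylospatial")

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance",
    "distance_matrix",
    "gaussian_similarity",
    "repair_psd",
]

EARTH_RADIUS_KM = 6371.0
_EIG_FLOOR = 1e-8


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.isnan(lat)) or np.any(np.isnan(lon)):
        raise ValueError("missing coordinates")
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValueError(f"latitude out of [-90, 90]: {lat[(lat < -90) | (lat > 90)]}")
    if np.any((lon <= -180.0) | (lon > 180.0)):
        raise ValueError(
            f"longitude out of (-180, 180]: {lon[(lon <= -180) | (lon > 180)]}"
        )


def great_circle_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between two (lat, lon) points in degrees."""
    _check_coords([a[0], b[0]], [a[1], b[1]])
    lat1, lon1, lat2, lon2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """All-pairs haversine distances (km) from a society coordinate table.

    ``coords`` must have one row per society (index = society_id) and columns
    ``lat``, ``lon`` in signed decimal degrees.
    """
    if coords.index.duplicated().any():
        dupes = coords.index[coords.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate society_id(s): {dupes}")
    lat = np.radians(coords["lat"].to_numpy(dtype=float))
    lon = np.radians(coords["lon"].to_numpy(dtype=float))
    _check_coords(coords["lat"], coords["lon"])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    s = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    D = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=coords.index, columns=coords.index)


def gaussian_similarity(
    D: pd.DataFrame | np.ndarray, sigma_s: float, repair: bool = True
) -> pd.DataFrame | np.ndarray:
    """Gaussian spatial kernel ``S_ij = exp(-(d_ij / sigma_s)**2)``.

    ``sigma_s`` is the spatial length-scale in km.  With ``repair`` the kernel
    matrix has its eigenvalues floored to keep it usable as a correlation
    structure.
    """
    if sigma_s <= 0:
        raise ValueError(f"sigma_s must be > 0, got {sigma_s}")
    arr = np.asarray(D, dtype=float)
    S = np.exp(-((arr / sigma_s) ** 2))
    if repair:
        S = repair_psd(S)
    if isinstance(D, pd.DataFrame):
        return pd.DataFrame(S, index=D.index, columns=D.columns)
    return S


def repair_psd(M: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Floor the eigenvalues of a symmetric matrix and restore the unit diagonal.

    Cheap path: if a Cholesky factorization succeeds the matrix is already
    positive definite and is returned untouched.  Otherwise eigenvalues below
    ``floor`` are raised to ``floor`` and the diagonal is renormalized to 1
    (the input is a correlation-structure matrix), which preserves PSD.
    """
    M = np.asarray(M, dtype=float)
    M = (M + M.T) / 2.0
    try:
        np.linalg.cholesky(M)
        return M
    except np.linalg.LinAlgError:
        pass
    w, Q = np.linalg.eigh(M)
    log.info(
        "PSD repair: flooring %d eigenvalue(s), min was %.3e",
        int((w < floor).sum()),
        float(w.min()),
    )
    w = np.maximum(w, floor)
    R = (Q * w) @ Q.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    return (R + R.T) / 2.0
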