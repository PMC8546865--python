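"""Linking hit abundance to geolocated pollution measurements.

Surveys measured on heterogeneous scales are pooled by per-survey Box-Cox
standardization (profile-likelihood lambda, bounded search on [-5, 5])
followed by within-survey z-scoring. Each sample is matched to its nearest
pooled measurement by great-circle (haversine) distance within a maximum
radius (400 km in the reference analysis; a sensitivity table over radii is
provided). Matched samples' hit counts are correlated with the pooled
z-scores (Spearman), and a Siegel repeated-median line — median over points
of the median pairwise slope, 50% breakdown — summarizes the trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import CorrelationResult, spearman

#: IUGG mean Earth radius
EARTH_RADIUS_KM = 6371.0088


@dataclass
class TrendFit:
    slope: float
    intercept: float


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of [-180, 180]")


def haversine_km(a: Sequence[float], b: Sequence[float]) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = float(a[0]), float(a[1])
    lat2, lon2 = float(b[0]), float(b[1])
    _check_coords(np.array([lat1, lat2]), np.array([lon1, lon2]))
    return float(
        _haversine_matrix(np.array([lat1]), np.array([lon1]), np.array([lat2]), np.array([lon2]))[
            0, 0
        ]
    )


def _haversine_matrix(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Pairwise great-circle distances (km), rows = first set."""
    p1 = np.radians(lat1)[:, None]
    p2 = np.radians(lat2)[None, :]
    dphi = p2 - p1
    dlmb = np.radians(lon2)[None, :] - np.radians(lon1)[:, None]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def boxcox_lambda(x: Sequence[float]) -> float:
    """Profile-likelihood Box-Cox lambda, bounded search on [-5, 5]."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    res = optimize.minimize_scalar(
        lambda lmb: -sps.boxcox_llf(lmb, x),
        bounds=(-5.0, 5.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def pool_surveys(surveys: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool heterogeneous surveys onto one standardized scale.

    Per survey, independently: shift by 1 - min if any value is
    non-positive, Box-Cox with the fitted lambda, then z-score (mean 0, sd 1
    within the survey). Returns all points concatenated, ordered by
    (survey_id, point index), with columns survey_id, point_index, lat, lon,
    value, pooled_z.
    """
    pooled = []
    for survey in surveys:
        if len(survey) < 3:
            raise ValueError("each survey needs at least 3 points")
        vals = survey["value"].to_numpy(dtype=float)
        shift = 0.0
        if vals.min() <= 0:
            shift = 1.0 - vals.min()
        lam = boxcox_lambda(vals + shift)
        transformed = sps.boxcox(vals + shift, lam)
        sd = transformed.std()
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(
                f"survey {survey['survey_id'].iat[0]!r} has zero variance after transform"
            )
        z = (transformed - transformed.mean()) / sd
        out = survey.copy()
        out["point_index"] = np.arange(len(survey))
        out["boxcox_lambda"] = lam
        out["shift"] = shift
        out["pooled_z"] = z
        pooled.append(out)
    result = pd.concat(pooled, ignore_index=True)
    return result.sort_values(["survey_id", "point_index"], ignore_index=True)


def match_pollution(
    samples: pd.DataFrame, points: pd.DataFrame, radius_km: float
) -> pd.DataFrame:
    """Nearest pooled measurement per sample within the radius.

    Ties in distance are broken by (survey_id, point_index) lexicographic
    order; unmatched samples carry NaN distance and pooled_z.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    pts = points.sort_values(["survey_id", "point_index"], ignore_index=True)
    s_lat = samples["lat"].to_numpy(dtype=float)
    s_lon = samples["lon"].to_numpy(dtype=float)
    p_lat = pts["lat"].to_numpy(dtype=float)
    p_lon = pts["lon"].to_numpy(dtype=float)
    _check_coords(s_lat, np.clip(s_lon, -180, 180))
    d = _haversine_matrix(s_lat, s_lon, p_lat, p_lon)
    nearest = d.argmin(axis=1)  # first occurrence wins -> lexicographic tie-break
    dist = d[np.arange(len(samples)), nearest]
    matched = dist <= radius_km
    return pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "survey_id": np.where(matched, pts["survey_id"].to_numpy()[nearest], None),
            "point_index": np.where(matched, pts["point_index"].to_numpy()[nearest], -1),
            "distance_km": np.where(matched, dist, np.nan),
            "pooled_z": np.where(matched, pts["pooled_z"].to_numpy()[nearest], np.nan),
        }
    )


def repeated_median_fit(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """Siegel repeated-median line: slope = median over i of the median over
    j != i of pairwise slopes (pairs at equal x excluded from the inner
    median); intercept = median of y - slope*x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching x/y with at least 2 points")
    if np.unique(x).size < 2:
        raise ValueError("all x values equal")
    slope, intercept = sps.siegelslopes(y, x, method="hierarchical")
    return TrendFit(float(slope), float(intercept))


def correlate_pollution(
    matched: pd.DataFrame, hit_counts: Mapping[str, float] | pd.Series
) -> tuple[CorrelationResult, TrendFit]:
    """Spearman of matched samples' hit counts vs pooled z-scores, plus the
    repeated-median trend of counts on pooled_z for plotting."""
    counts = pd.Series(hit_counts)
    sub = matched.dropna(subset=["pooled_z"])
    sub = sub[sub["sample_id"].isin(counts.index)]
    if len(sub) < 3:
        raise ValueError("need at least 3 matched samples")
    y = counts.loc[sub["sample_id"]].to_numpy(dtype=float)
    z = sub["pooled_z"].to_numpy(dtype=float)
    corr = spearman(z, y)
    trend = repeated_median_fit(z, y)
    return corr, trend


def radius_sensitivity(
    samples: pd.DataFrame,
    points: pd.DataFrame,
    hit_counts: Mapping[str, float] | pd.Series,
    radii: Sequence[float],
) -> pd.DataFrame:
    """Coverage and correlation at each matching radius.

    Radii with fewer than 3 matched samples report NaN rho with a note.
    """
    if len(radii) < 2:
        raise ValueError("need at least 2 radii")
    counts = pd.Series(hit_counts)
    rows = []
    for r in radii:
        matched = match_pollution(samples, points, r)
        ok = matched.dropna(subset=["pooled_z"])
        n_matched = len(ok)
        coverage = n_matched / len(samples) if len(samples) else float("nan")
        if n_matched < 3:
            rows.append((r, n_matched, coverage, np.nan, np.nan, "fewer than 3 matches"))
            continue
        corr, _ = correlate_pollution(matched, counts)
        rows.append((r, n_matched, coverage, corr.rho, corr.p_value, ""))
    return pd.DataFrame(
        rows, columns=["radius_km", "n_matched", "coverage", "rho", "p_value", "note"]
    )


def country_join(
    samples: pd.DataFrame, country_waste: pd.DataFrame
) -> pd.DataFrame:
    """Exact-key join of samples to country-level mismanaged-waste shares
    (columns: country, share). Samples without a country row are dropped."""
    return samples.merge(country_waste, on="country", how="inner", validate="many_to_one")
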