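"""Growing-season climate covariates from monthly climatologies.

Builds the three site-level covariates used by the path models and the
hierarchical Bayesian model: growing-season daylight hours ``L`` (mean hours
per day), total growing-season precipitation ``P`` (mm) and mean
growing-season temperature ``T`` (degrees C).  The growing season is a fixed
8-month window — January through August in the northern hemisphere, July
through February in the southern hemisphere (the equator takes the northern
window).  Monthly values are climatological normals, so the southern window
simply names 8 months of the same 12-month climatology; no cross-year
bookkeeping is attempted.

Daylight hours are supplied on an integer longitude/latitude lattice and
interpolated to site coordinates by inverse-distance weighting over the four
surrounding lattice corners.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from divstab.data_core import ValidationError

NORTHERN_WINDOW = list(range(1, 9))
SOUTHERN_WINDOW = [7, 8, 9, 10, 11, 12, 1, 2]


def growing_season_window(latitude: float) -> list[int]:
    """Ordered growing-season months (8) for a site latitude."""
    if not -90 <= latitude <= 90:
        raise ValueError(f"latitude out of range: {latitude}")
    return list(NORTHERN_WINDOW) if latitude >= 0 else list(SOUTHERN_WINDOW)


def season_aggregate(monthly: pd.DataFrame, window: list[int]) -> tuple[float, float]:
    """(mean temperature, total precipitation) over a month window.

    ``monthly`` has columns ``month, temperature, precipitation`` for one
    site.  Temperature is averaged, precipitation summed, over the window.
    """
    sub = monthly.set_index("month")
    missing = [m for m in window if m not in sub.index]
    if missing:
        raise ValidationError(f"months missing from climatology: {missing}")
    sel = sub.loc[window]
    return float(sel["temperature"].mean()), float(sel["precipitation"].sum())


def interpolate_daylight(lon: float, lat: float, daylight: pd.DataFrame,
                         window: list[int]) -> float:
    """Inverse-distance-weighted daylight hours at a site, averaged over a window.

    ``daylight`` has columns ``lon, lat, month, hours`` at integer lon/lat
    points.  For each month the value at the site is the weighted mean of
    the four surrounding integer corners with weights proportional to
    1/distance (Euclidean, degree coordinates); a site coinciding with a
    lattice node takes that node's value.  The returned covariate is the
    mean over the window months.
    """
    lon0, lat0 = np.floor(lon), np.floor(lat)
    corners = [(lon0, lat0), (lon0 + 1, lat0), (lon0, lat0 + 1), (lon0 + 1, lat0 + 1)]
    # a site on a lattice line has redundant corners; keep unique ones
    corners = [(x, y) for x, y in dict.fromkeys(corners)]
    d = np.array([np.hypot(lon - x, lat - y) for x, y in corners])

    idx = daylight.set_index(["lon", "lat", "month"])["hours"]
    monthly_vals = []
    for m in window:
        vals = []
        for x, y in corners:
            key = (x, y, m)
            if key not in idx.index:
                raise ValidationError(
                    f"daylight lattice point missing: lon={x} lat={y} month={m}")
            vals.append(float(idx.loc[key]))
        vals = np.asarray(vals)
        if np.any(d == 0):
            monthly_vals.append(vals[np.argmin(d)])
        else:
            w = 1.0 / d
            monthly_vals.append(float(np.sum(w * vals) / np.sum(w)))
    return float(np.mean(monthly_vals))


def build_covariates(sites: pd.DataFrame, monthly_climate: pd.DataFrame,
                     daylight: pd.DataFrame | None = None,
                     grids: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-site (optionally per-grid) growing-season covariates L, P, T.

    Parameters
    ----------
    sites
        ``site_id, longitude, latitude`` rows.
    monthly_climate
        ``site_id, month, temperature, precipitation`` — 12 months per site.
    daylight
        Integer-lattice table ``lon, lat, month, hours``; if None, the L
        column is NaN (tables without a daylight product remain usable for
        temperature/precipitation work).
    grids
        Optional grid summary frame (``grid_id, site_id``): the returned
        frame then has one row per grid inheriting its site's covariates.
    """
    rows = []
    for _, s in sites.iterrows():
        window = growing_season_window(float(s["latitude"]))
        mc = monthly_climate[monthly_climate["site_id"] == s["site_id"]]
        if mc["month"].nunique() != 12:
            raise ValidationError(
                f"site {s['site_id']}: expected 12 months, got {mc['month'].nunique()}")
        t_mean, p_total = season_aggregate(mc, window)
        light = (interpolate_daylight(float(s["longitude"]), float(s["latitude"]),
                                      daylight, window)
                 if daylight is not None else np.nan)
        rows.append({"site_id": s["site_id"], "daylight": light,
                     "precipitation": p_total, "temperature": t_mean})
    cov = pd.DataFrame(rows)
    if cov["precipitation"].lt(0).any():
        raise ValidationError("negative growing-season precipitation")
    if grids is not None:
        cov = grids[["grid_id", "site_id"]].merge(cov, on="site_id", how="left")
    return cov


def write_covariates(cov: pd.DataFrame, path, delimiter: str = ",") -> None:
    cov.to_csv(path, sep=delimiter, index=False)
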