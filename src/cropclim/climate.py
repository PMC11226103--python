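"""Monthly-to-yearly climate covariates and descriptive trend fits.

Monthly climate variables (TerraClimate layout: long rows of municipality,
year, month, variable, value) are collapsed to the eleven yearly covariates
used by the production model: yearly minimum of monthly minimum temperature,
yearly maximum of monthly maximum temperature, and yearly means of everything
else, with average temperature defined as the yearly mean of the monthly
midpoint (tmin + tmax) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MONTHLY_COLUMNS = ("municipality_code", "year", "month", "variable", "value")

#: monthly variable name -> (yearly covariate name, aggregation)
MONTHLY_TO_YEARLY = {
    "tmin": ("min_temperature", "min"),
    "tmax": ("max_temperature", "max"),
    "aet": ("actual_evapotranspiration", "mean"),
    "pet": ("reference_evapotranspiration", "mean"),
    "ppt": ("precipitation", "mean"),
    "runoff": ("runoff", "mean"),
    "soil": ("soil_moisture", "mean"),
    "vap": ("vapor_pressure", "mean"),
    "srad": ("radiation", "mean"),
    "ws": ("wind_speed", "mean"),
}


def _validate_monthly(monthly: pd.DataFrame) -> pd.DataFrame:
    missing = set(MONTHLY_COLUMNS) - set(monthly.columns)
    if missing:
        raise ValueError(f"monthly table is missing columns: {sorted(missing)}")
    monthly = monthly.loc[:, list(MONTHLY_COLUMNS)]
    if not monthly["month"].between(1, 12).all():
        raise ValueError("month must be in 1..12")
    key = ["municipality_code", "year", "month", "variable"]
    if monthly.duplicated(key).any():
        raise ValueError("duplicate (municipality, year, month, variable) rows")
    unknown = set(monthly["variable"]) - set(MONTHLY_TO_YEARLY)
    if unknown:
        raise ValueError(f"unknown monthly variables: {sorted(unknown)}")
    return monthly


def aggregate_yearly(monthly: pd.DataFrame) -> pd.DataFrame:
    """Collapse monthly climate rows to one row per municipality-year.

    Yearly min of tmin, yearly max of tmax, yearly mean of (tmin+tmax)/2 for
    average temperature (only months where both are present), yearly mean for
    every other variable.  Partial years are averaged over the months that
    are present; the boolean ``complete`` column is True only when every
    variable present for that municipality-year covers all 12 months.
    A variable entirely absent for a municipality-year is a missing (NaN)
    cell, never a silent zero.
    """
    monthly = _validate_monthly(monthly)
    wide = monthly.pivot_table(
        index=["municipality_code", "year", "month"],
        columns="variable",
        values="value",
        aggfunc="first",
    )
    if {"tmin", "tmax"} <= set(wide.columns):
        wide["_tmid"] = (wide["tmin"] + wide["tmax"]) / 2.0

    grouped = wide.groupby(level=["municipality_code", "year"])
    out = {}
    for mvar, (yvar, how) in MONTHLY_TO_YEARLY.items():
        if mvar in wide.columns:
            out[yvar] = getattr(grouped[mvar], how)()
    if "_tmid" in wide.columns:
        out["avg_temperature"] = grouped["_tmid"].mean()

    yearly = pd.DataFrame(out)
    counts = grouped.count().drop(columns="_tmid", errors="ignore")
    # complete = every variable that has any data this year has all 12 months
    yearly["complete"] = ((counts == 12) | (counts == 0)).all(axis=1) & (
        counts.max(axis=1) == 12
    )
    return yearly.reset_index()


@dataclass
class NationalSeries:
    """Cross-municipality yearly means of one variable, with extreme years."""

    variable: str
    values: pd.Series  # indexed by year
    year_max: int
    year_min: int


def national_series(yearly: pd.DataFrame, variable: str) -> NationalSeries:
    """Unweighted mean across municipalities per year, plus argmax/argmin."""
    if variable not in yearly.columns:
        raise ValueError(f"variable {variable!r} not in yearly table")
    sub = yearly[yearly[variable].notna()]
    if sub.empty:
        raise ValueError(f"no data for variable {variable!r}")
    means = sub.groupby("year")[variable].mean().sort_index()
    return NationalSeries(
        variable=variable,
        values=means,
        year_max=int(means.idxmax()),
        year_min=int(means.idxmin()),
    )


@dataclass
class TrendFit:
    """Best of four polynomial trend fits (degree 1-4) selected by AIC."""

    degree: int
    coefficients: np.ndarray  # ascending powers, original x units
    aic: float
    fitted_values: np.ndarray
    candidate_aic: dict


def fit_trend_smoother(x, y=None) -> TrendFit:
    """Fit OLS polynomials of degree 1..4 and keep the AIC-minimizing one.

    AIC = n*ln(RSS/n) + 2*(degree+2), counting the intercept, the polynomial
    coefficients and the residual variance as parameters.  Accepts either a
    pandas Series (index used as x) or two arrays.
    """
    if y is None:
        series = pd.Series(x)
        xv = np.asarray(series.index, dtype=float)
        yv = series.to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    n = len(xv)
    if n <= 5:
        raise ValueError("need more than 5 points to compare degrees 1-4")

    # center/scale x for conditioning; convert coefficients back afterwards
    mu, sd = xv.mean(), xv.std() or 1.0
    z = (xv - mu) / sd

    best = None
    cand = {}
    for degree in (1, 2, 3, 4):
        V = np.vander(z, degree + 1, increasing=True)
        coef_z, *_ = np.linalg.lstsq(V, yv, rcond=None)
        fitted = V @ coef_z
        rss = float(np.sum((yv - fitted) ** 2))
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * (degree + 2)
        cand[degree] = aic
        if best is None or aic < best[0]:
            # back-transform: p(z) with z = (x - mu)/sd -> coefficients in x
            poly = np.polynomial.Polynomial(coef_z)(
                np.polynomial.Polynomial([-mu / sd, 1.0 / sd])
            )
            best = (aic, degree, poly.coef, fitted)
    aic, degree, coef, fitted = best
    coef = np.pad(coef, (0, degree + 1 - len(coef)))
    return TrendFit(
        degree=degree,
        coefficients=coef,
        aic=float(aic),
        fitted_values=fitted,
        candidate_aic=cand,
    )


def read_monthly_csv(path) -> pd.DataFrame:
    """Read a long-format monthly climate CSV."""
    return _validate_monthly(pd.read_csv(path, dtype={"municipality_code": str}))


def read_monthly_netcdf(path, centroids: pd.DataFrame) -> pd.DataFrame:
    """Sample a CF-style monthly climate raster at municipality centroids.

    ``centroids`` needs columns municipality_code, lat, lon.  Each data
    variable in the file must be dimensioned (time, lat, lon) with a monthly
    time axis; the nearest grid cell to each centroid is taken.  Requires
    xarray.
    """
    import xarray as xr

    ds = xr.open_dataset(path)
    records = []
    time = pd.DatetimeIndex(ds["time"].values)
    for _, row in centroids.iterrows():
        cell = ds.sel(lat=row["lat"], lon=row["lon"], method="nearest")
        for var in ds.data_vars:
            vals = np.asarray(cell[var].values, dtype=float)
            for t, v in zip(time, vals):
                records.append(
                    (row["municipality_code"], int(t.year), int(t.month), var, v)
                )
    ds.close()
    return pd.DataFrame(records, columns=list(MONTHLY_COLUMNS))


def write_yearly_csv(yearly: pd.DataFrame, path) -> None:
    yearly.to_csv(path, index=False)
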