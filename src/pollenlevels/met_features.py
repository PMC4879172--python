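"""Predictor construction from gridded daily meteorology.

The feature set for the pollen-level classifier is 30 predictors per
(location, date):

* 12 monthly mean temperatures of the preceding calendar year
  (``TAVG_JANUARY_PREVYEAR`` ... ``TAVG_DECEMBER_PREVYEAR``),
* 4- and 16-day averages of the seven daily meteorological fields, each
  lagged by one day (``TMAX_4DAYS_AVG_1DAYLAG`` etc.),
* cumulative growing degree days lagged by one day (``GDD_1DAYLAG``),
* the static grid-cell coordinates ``LONGITUDE``, ``LATITUDE``, ``ALTITUDE``.

Growing degree days use base temperature 5 degC, the standard growth
threshold for temperate tree species, accumulated from January 1 and reset
at every year boundary.  If the daily maximum does not exceed the base
temperature no degree days accumulate, and negative daily values are
clamped to zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

MET_VARIABLES = ("tmax", "tmin", "vap", "wind", "prec", "evap", "rad")

_VAR_ABBREV = {
    "tmax": "TMAX",
    "tmin": "TMIN",
    "vap": "VAPORPRESSURE",
    "wind": "WINDSPEED",
    "prec": "PRECIPITATION",
    "evap": "EVAPORATION",
    "rad": "RADIATION",
}

_MONTHS = (
    "JANUARY", "FEBRUARY", "MARCH", "APRIL", "MAY", "JUNE",
    "JULY", "AUGUST", "SEPTEMBER", "OCTOBER", "NOVEMBER", "DECEMBER",
)

TAVG_COLUMNS = tuple(f"TAVG_{m}_PREVYEAR" for m in _MONTHS)
LAGGED_COLUMNS = tuple(
    f"{_VAR_ABBREV[v]}_{k}DAYS_AVG_1DAYLAG" for v in MET_VARIABLES for k in (4, 16)
)
STATIC_COLUMNS = ("LONGITUDE", "LATITUDE", "ALTITUDE")

#: the 30 predictor columns, in canonical order
PREDICTOR_COLUMNS = TAVG_COLUMNS + LAGGED_COLUMNS + ("GDD_1DAYLAG",) + STATIC_COLUMNS

GDD_BASE_TEMPERATURE = 5.0


def daily_gdd(tmax, tmin, tbase: float = GDD_BASE_TEMPERATURE):
    """Daily growing degree days: ``(tmax + tmin)/2 - tbase``, clamped.

    Zero when ``tmax <= tbase`` (no accumulation below the growth
    threshold) and never negative.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any ``tmax < tmin``.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("daily_gdd: tmax < tmin encountered")
    gdd = np.clip((tmax + tmin) / 2.0 - tbase, 0.0, None)
    gdd = np.where(tmax <= tbase, 0.0, gdd)
    return gdd if gdd.ndim else float(gdd)


def _check_contiguous_daily(index: pd.DatetimeIndex) -> None:
    if len(index) > 1:
        deltas = np.diff(index.values).astype("timedelta64[D]").astype(int)
        if not np.all(deltas == 1):
            raise ValueError("time axis is not contiguous daily")


def accumulate_gdd(
    tmax: pd.Series, tmin: pd.Series, tbase: float = GDD_BASE_TEMPERATURE
) -> pd.Series:
    """Cumulative GDD lagged by one day, reset each January 1.

    ``tmax``/``tmin`` must share a contiguous daily DatetimeIndex.  The
    value for day *t* is the sum of daily GDD through day *t - 1* of the
    same calendar year; the feature is 0 on January 1.
    """
    if not tmax.index.equals(tmin.index):
        raise ValueError("tmax and tmin must share one index")
    idx = pd.DatetimeIndex(tmax.index)
    _check_contiguous_daily(idx)
    daily = pd.Series(daily_gdd(tmax.to_numpy(), tmin.to_numpy(), tbase), index=idx)
    cum = daily.groupby(idx.year).cumsum()
    lagged = cum.groupby(idx.year).shift(1).fillna(0.0)
    lagged.name = "GDD_1DAYLAG"
    return lagged


def rolling_mean_lagged(values: pd.Series, k: int) -> pd.Series:
    """Mean of the ``k`` days strictly before each day.

    Missing (NaN) where fewer than ``k`` prior days exist; NaNs in the
    source propagate into every window containing them.
    """
    if k <= 0:
        raise ValueError(f"window length must be positive, got {k}")
    _check_contiguous_daily(pd.DatetimeIndex(values.index))
    return values.rolling(k).mean().shift(1)


def prevyear_monthly_tavg(cell: pd.DataFrame, year: int) -> pd.Series:
    """The 12 monthly mean temperatures of ``year - 1`` for one cell.

    ``cell`` holds daily ``tmax``/``tmin`` on a DatetimeIndex.  The daily
    mean temperature is ``(tmax + tmin)/2``.  All 12 values are NaN when
    the preceding year is not fully present.
    """
    table = _prevyear_tavg_table(cell)
    if year in table.index:
        return table.loc[year]
    return pd.Series(np.nan, index=list(TAVG_COLUMNS), name=year)


def _prevyear_tavg_table(cell: pd.DataFrame) -> pd.DataFrame:
    """Rows indexed by feature year; columns TAVG_*_PREVYEAR."""
    idx = pd.DatetimeIndex(cell.index)
    tavg = (cell["tmax"] + cell["tmin"]) / 2.0
    monthly = tavg.groupby([idx.year, idx.month]).mean().unstack()
    # only years with all 12 months qualify as a complete preceding year
    counts = tavg.groupby([idx.year, idx.month]).size().unstack()
    complete = counts.notna().all(axis=1)
    monthly = monthly.loc[complete[complete].index]
    monthly.columns = [TAVG_COLUMNS[m - 1] for m in monthly.columns]
    monthly = monthly[list(TAVG_COLUMNS)]
    monthly.index = monthly.index + 1  # year y uses means of year y-1
    return monthly


def cell_feature_table(cell: pd.DataFrame, lon: float, lat: float, alt: float) -> pd.DataFrame:
    """All 30 predictors for every day of one grid cell's daily series.

    ``cell`` holds the seven meteorological variables on a contiguous daily
    DatetimeIndex.  Rows whose lookback (16-day window or preceding year)
    is unavailable carry NaNs and are dropped later by
    :func:`assemble_features`.
    """
    missing = set(MET_VARIABLES) - set(cell.columns)
    if missing:
        raise ValueError(f"met series lacks variables: {sorted(missing)}")
    idx = pd.DatetimeIndex(cell.index)
    _check_contiguous_daily(idx)

    out = pd.DataFrame(index=idx)
    tavg_table = _prevyear_tavg_table(cell)
    years = pd.Series(idx.year, index=idx)
    for col in TAVG_COLUMNS:
        mapping = tavg_table[col] if col in tavg_table else pd.Series(dtype=float)
        out[col] = years.map(mapping)
    for var in MET_VARIABLES:
        for k in (4, 16):
            out[f"{_VAR_ABBREV[var]}_{k}DAYS_AVG_1DAYLAG"] = rolling_mean_lagged(
                cell[var], k
            )
    out["GDD_1DAYLAG"] = accumulate_gdd(cell["tmax"], cell["tmin"])
    out["LONGITUDE"] = lon
    out["LATITUDE"] = lat
    out["ALTITUDE"] = alt
    return out[list(PREDICTOR_COLUMNS)]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (broadcasts over arrays)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 6371.0088 * 2 * np.arcsin(np.sqrt(a))


def cell_series(met: xr.Dataset, iy: int, ix: int) -> pd.DataFrame:
    """Extract one cell's daily meteorology as a DataFrame."""
    sub = met.isel(cell_y=iy, cell_x=ix)
    frame = pd.DataFrame(
        {v: sub[v].to_numpy() for v in MET_VARIABLES},
        index=pd.DatetimeIndex(met["time"].to_numpy()),
    )
    return frame


def nearest_cell(met: xr.Dataset, lon: float, lat: float, name: str = "?") -> tuple[int, int]:
    """Index of the grid cell whose center is nearest (haversine).

    Ties break toward the lowest flat (row-major) cell index.  Raises if the
    point lies outside the grid hull (beyond half a cell spacing from the
    outermost centers).
    """
    lons = met["lon"].to_numpy()
    lats = met["lat"].to_numpy()
    dlon = np.max(np.abs(np.diff(np.unique(lons)))) if lons.size > 1 else 1.0
    dlat = np.max(np.abs(np.diff(np.unique(lats)))) if lats.size > 1 else 1.0
    if not (
        lons.min() - dlon / 2 <= lon <= lons.max() + dlon / 2
        and lats.min() - dlat / 2 <= lat <= lats.max() + dlat / 2
    ):
        raise ValueError(f"location {name!r} ({lon:.3f}, {lat:.3f}) is outside the grid")
    dist = haversine_km(lon, lat, lons, lats)
    flat = int(np.argmin(dist))  # argmin takes the first (lowest) index on ties
    iy, ix = np.unravel_index(flat, lons.shape)
    return int(iy), int(ix)


def assemble_features(
    met: xr.Dataset,
    locations: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Join locations to grid cells and build the 30-predictor table.

    Parameters
    ----------
    met
        Gridded meteorology with dims ``(time, cell_y, cell_x)`` and
        coordinates ``lon``, ``lat``, ``alt``.
    locations
        One row per location with columns ``site``, ``lon``, ``lat``.
    labels
        Optional labeled pollen series with columns ``site``, ``date``,
        ``level`` (``"low"``/``"high"``) for a single taxon.
    window
        Optional inclusive ``(min_doy, max_doy)`` analysis window.

    Returns
    -------
    DataFrame with columns ``site``, ``date``, the 30 predictors, and
    ``level`` when labels were supplied.  Rows with any missing predictor
    are dropped (counted in the log); complete cases only enter modeling.
    """
    cells: dict[tuple[int, int], pd.DataFrame] = {}
    pieces = []
    for row in locations.itertuples(index=False):
        iy, ix = nearest_cell(met, row.lon, row.lat, name=str(row.site))
        if (iy, ix) not in cells:
            cells[(iy, ix)] = cell_feature_table(
                cell_series(met, iy, ix),
                lon=float(met["lon"].values[iy, ix]),
                lat=float(met["lat"].values[iy, ix]),
                alt=float(met["alt"].values[iy, ix]),
            )
        feats = cells[(iy, ix)].copy()
        feats.insert(0, "site", row.site)
        pieces.append(feats.reset_index(names="date"))
    table = pd.concat(pieces, ignore_index=True)
    table = table[["site", "date"] + list(PREDICTOR_COLUMNS)]

    if window is not None:
        doy = pd.DatetimeIndex(table["date"]).dayofyear
        table = table[(doy >= window[0]) & (doy <= window[1])].reset_index(drop=True)

    if labels is not None:
        lab = labels[["site", "date", "level"]].copy()
        lab["date"] = pd.to_datetime(lab["date"])
        table = table.merge(lab, on=["site", "date"], how="left")
        n_unlabeled = int(table["level"].isna().sum())
        if n_unlabeled:
            logger.info("assemble_features: dropping %d unlabeled rows", n_unlabeled)
            table = table.dropna(subset=["level"]).reset_index(drop=True)

    n_incomplete = int(table[list(PREDICTOR_COLUMNS)].isna().any(axis=1).sum())
    if n_incomplete:
        logger.info(
            "assemble_features: dropping %d rows with incomplete predictors",
            n_incomplete,
        )
    table = table.dropna(subset=list(PREDICTOR_COLUMNS)).reset_index(drop=True)
    return table


def load_met(path) -> xr.Dataset:
    """Read gridded meteorology from NetCDF or long-format CSV.

    The CSV layout is one row per (cell_y, cell_x, date) with columns
    ``cell_y, cell_x, date, lon, lat, alt`` plus the seven variables.
    """
    path = str(path)
    if path.endswith(".csv"):
        long = pd.read_csv(path, parse_dates=["date"])
        ys = np.sort(long["cell_y"].unique())
        xs = np.sort(long["cell_x"].unique())
        times = np.sort(long["date"].unique())
        long = long.set_index(["date", "cell_y", "cell_x"]).sort_index()
        shape = (len(times), len(ys), len(xs))
        data = {
            v: long[v].to_numpy().reshape(shape) for v in MET_VARIABLES
        }
        static = long.xs(times[0], level="date")
        coords = {
            "time": times,
            "lon": (("cell_y", "cell_x"), static["lon"].to_numpy().reshape(shape[1:])),
            "lat": (("cell_y", "cell_x"), static["lat"].to_numpy().reshape(shape[1:])),
            "alt": (("cell_y", "cell_x"), static["alt"].to_numpy().reshape(shape[1:])),
        }
        return xr.Dataset(
            {v: (("time", "cell_y", "cell_x"), a) for v, a in data.items()},
            coords=coords,
        )
    return xr.open_dataset(path, engine="scipy").load()
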