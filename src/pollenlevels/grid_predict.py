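"""Grid-wide prediction: probability and level maps for chosen dates.

Applies a trained classifier to every grid cell, assembling the same 30
predictors used at the monitoring sites, so the map value at a monitored
site's cell equals the point prediction for that site on the same date.
Cells whose lookback (16-day window or preceding calendar year) is
unavailable are masked as no-data (NaN).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .met_features import PREDICTOR_COLUMNS, cell_feature_table, cell_series
from .model import TrainedClassifier


def predict_grid(
    model: TrainedClassifier, met: xr.Dataset, dates
) -> xr.Dataset:
    """Probability-of-high and binary-level layers for each requested date.

    Parameters
    ----------
    model
        A classifier with an optimized threshold.
    met
        Gridded meteorology with dims ``(time, cell_y, cell_x)``.
    dates
        Iterable of date-likes; every date must have a fully present
        preceding calendar year in ``met`` (needed by the monthly
        temperature predictors).

    Returns
    -------
    ``xr.Dataset`` with variables ``probability`` ([0, 1], NaN = no data)
    and ``level`` (1.0 high / 0.0 low / NaN masked) over
    ``(time, cell_y, cell_x)``.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    if len(dates) == 0:
        raise ValueError("no dates requested")
    times = pd.DatetimeIndex(met["time"].to_numpy())
    years = np.unique(times.year)
    earliest_valid = pd.Timestamp(f"{years.min() + 1}-01-01")
    bad = dates[(dates < earliest_valid) | (dates > times.max())]
    if len(bad):
        raise ValueError(
            f"dates {[str(d.date()) for d in bad]} lack feature history; "
            f"earliest valid date is {earliest_valid.date()}"
        )
    ny = met.sizes["cell_y"]
    nx = met.sizes["cell_x"]
    prob = np.full((len(dates), ny, nx), np.nan)
    for iy in range(ny):
        for ix in range(nx):
            feats = cell_feature_table(
                cell_series(met, iy, ix),
                lon=float(met["lon"].values[iy, ix]),
                lat=float(met["lat"].values[iy, ix]),
                alt=float(met["alt"].values[iy, ix]),
            ).loc[dates]
            ok = ~feats[list(PREDICTOR_COLUMNS)].isna().any(axis=1).to_numpy()
            if ok.any():
                prob[ok, iy, ix] = model.predict_proba_high(feats[ok])
    if model.threshold is None:
        raise ValueError("classifier has no optimized threshold")
    level = np.where(np.isnan(prob), np.nan, (prob >= model.threshold).astype(float))
    return xr.Dataset(
        {
            "probability": (("time", "cell_y", "cell_x"), prob),
            "level": (("time", "cell_y", "cell_x"), level),
        },
        coords={
            "time": dates,
            "lon": met["lon"],
            "lat": met["lat"],
            "alt": met["alt"],
        },
        attrs={"threshold": float(model.threshold)},
    )


def export_raster(raster: xr.Dataset, path, format: str = "netcdf") -> None:
    """Write the prediction raster to disk.

    NetCDF (CF-style ``time``/``cell_y``/``cell_x`` dimensions with
    ``lon``/``lat`` coordinate variables, NaN as no-data) round-trips
    losslessly via :func:`load_raster`.
    """
    if raster["time"].size == 0:
        raise ValueError("raster has no dates")
    if format == "netcdf":
        raster.to_netcdf(path, engine="scipy")
    elif format == "geotiff":
        raise NotImplementedError(
            "GeoTIFF export is not supported in this build; use format='netcdf'"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def load_raster(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def quicklook_png(raster: xr.Dataset, path) -> None:
    """Optional quick-look panel of the probability layers (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = raster["time"].size
    ncols = min(3, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for i in range(nrows * ncols):
        ax = axes[i // ncols][i % ncols]
        if i < n:
            im = ax.pcolormesh(
                raster["lon"], raster["lat"],
                raster["probability"].isel(time=i),
                vmin=0, vmax=1, shading="auto",
            )
            ax.set_title(str(pd.Timestamp(raster["time"].values[i]).date()))
            fig.colorbar(im, ax=ax)
        else:
            ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
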