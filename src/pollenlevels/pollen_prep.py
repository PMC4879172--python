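"""Pollen season delimitation and concentration-level assignment.

The pollen season of one site-year is delimited by the 99 % method: it
starts on the day the cumulative count reaches 0.5 % of the annual total
and ends on the day it reaches 99.5 %.  Per taxon, the union of all
site-year seasons (minimum onset to maximum end, day-of-year) fixes the
analysis window used everywhere downstream.

Daily concentrations are dichotomized at taxon-specific limits tied to
first allergy symptoms: 35 grains/m3 for Corylus, 45 for Alnus, 20 for
Betula; a day at or above its limit is *high*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: symptom-based level limits (grains/m3)
DEFAULT_THRESHOLDS = {"Corylus": 35.0, "Alnus": 45.0, "Betula": 20.0}


class NoSeasonError(ValueError):
    """Raised when a site-year has zero total pollen (no season exists)."""


@dataclass(frozen=True)
class SeasonWindow:
    site: str
    taxon: str
    year: int
    onset_doy: int
    end_doy: int

    def __post_init__(self):
        if not 1 <= self.onset_doy <= self.end_doy <= 366:
            raise ValueError("invalid season bounds")


def delimit_season_99(
    series: pd.DataFrame, start_pct: float = 0.5, end_pct: float = 99.5
) -> SeasonWindow:
    """Delimit one site/taxon/year season by cumulative percentages.

    ``series`` holds columns ``site, taxon, date, count`` for a single
    site, taxon and calendar year.  Onset is the first day whose cumulative
    count reaches ``start_pct`` % of the annual total (ties inclusive);
    the end is the first day reaching ``end_pct`` %.  Days absent from the
    series count as zero (and are logged).

    Raises
    ------
    NoSeasonError
        If the annual total is zero.
    """
    sites = series["site"].unique()
    taxa = series["taxon"].unique()
    dates = pd.to_datetime(series["date"])
    years = dates.dt.year.unique()
    if len(sites) != 1 or len(taxa) != 1 or len(years) != 1:
        raise ValueError("delimit_season_99 expects one site/taxon/year")
    n_days = pd.Timestamp(f"{years[0]}-12-31").dayofyear
    if len(series) < n_days:
        logger.info(
            "site %s year %s: %d days missing, treated as zero counts",
            sites[0], years[0], n_days - len(series),
        )
    ordered = series.assign(date=dates).sort_values("date")
    counts = ordered["count"].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative pollen counts")
    total = counts.sum()
    if total <= 0:
        raise NoSeasonError(f"site {sites[0]} year {years[0]}: all-zero year")
    cum = np.cumsum(counts)
    onset_i = int(np.searchsorted(cum, start_pct / 100.0 * total))
    end_i = int(np.searchsorted(cum, end_pct / 100.0 * total))
    doys = pd.DatetimeIndex(ordered["date"]).dayofyear.to_numpy()
    return SeasonWindow(
        site=str(sites[0]),
        taxon=str(taxa[0]),
        year=int(years[0]),
        onset_doy=int(doys[onset_i]),
        end_doy=int(doys[end_i]),
    )


def delimit_all_seasons(pollen: pd.DataFrame) -> pd.DataFrame:
    """Season table for every (site, taxon, year); all-zero years excluded.

    Returns a DataFrame with columns site, taxon, year, onset_doy, end_doy.
    """
    pollen = pollen.assign(date=pd.to_datetime(pollen["date"]))
    rows = []
    for (site, taxon, year), grp in pollen.groupby(
        ["site", "taxon", pollen["date"].dt.year]
    ):
        try:
            w = delimit_season_99(grp)
        except NoSeasonError as exc:
            logger.warning("excluded: %s", exc)
            continue
        rows.append((w.site, w.taxon, w.year, w.onset_doy, w.end_doy))
    return pd.DataFrame(
        rows, columns=["site", "taxon", "year", "onset_doy", "end_doy"]
    )


def taxon_analysis_window(seasons: pd.DataFrame) -> tuple[int, int]:
    """Maximum range of a taxon's seasons: (min onset, max end) day-of-year."""
    if len(seasons) == 0:
        raise ValueError("no seasons supplied")
    return int(seasons["onset_doy"].min()), int(seasons["end_doy"].max())


def assign_levels(
    series: pd.DataFrame, thresholds: dict[str, float] | None = None
) -> pd.DataFrame:
    """Attach the binary concentration level: high iff count >= limit."""
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    unknown = set(series["taxon"].unique()) - set(thresholds)
    if unknown:
        raise KeyError(f"no level limit for taxa: {sorted(unknown)}")
    limits = series["taxon"].map(thresholds)
    out = series.copy()
    out["level"] = np.where(series["count"] >= limits, "high", "low")
    return out
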