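"""Bioclimatic covariates from monthly county climate series.

Three of the standard WorldClim-style bioclimatic variables are derived per
county and year from 12 monthly values each of minimum temperature, mean
temperature and precipitation:

* **Bio6** — minimum temperature of the coldest month (°C): overwintering
  severity for diapausing larvae/pupae.
* **Bio10** — mean temperature of the warmest quarter (°C): conditions for
  adult flight activity.
* **Bio18** — precipitation of the warmest quarter (mm): summer moisture.

A *quarter* is a window of three consecutive calendar months within one year
(January–March … October–December; no December–February wrap).  The warmest
quarter is chosen on mean temperature and the same window is used for Bio18.
Ties are broken toward the earliest start month.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12
QUARTER = 3

__all__ = [
    "bio6",
    "warmest_quarter",
    "bio10_bio18",
    "county_year_covariates",
    "attach_covariates",
]


def _validate_monthly(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (MONTHS_PER_YEAR,):
        raise ValueError(
            f"{name}: expected exactly {MONTHS_PER_YEAR} monthly values, got shape {arr.shape}"
        )
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        months = ", ".join(str(m + 1) for m in bad)
        raise ValueError(f"{name}: missing or non-finite value for month(s) {months}")
    return arr


def bio6(monthly_tmin) -> float:
    """Minimum temperature of the coldest month (°C)."""
    return float(_validate_monthly(monthly_tmin, "monthly_tmin").min())


def warmest_quarter(monthly_tmean) -> int:
    """Start month (1-based) of the warmest 3-consecutive-month window.

    Scans the ten windows Jan–Mar … Oct–Dec and returns the start month of the
    one with the highest mean of monthly mean temperatures.  Ties go to the
    earliest start month (logged at DEBUG level).
    """
    tmean = _validate_monthly(monthly_tmean, "monthly_tmean")
    # compare window *sums* (slice sums, left to right): no division noise,
    # so equal windows compare exactly equal
    window_sums = np.array(
        [tmean[s : s + QUARTER].sum() for s in range(MONTHS_PER_YEAR - QUARTER + 1)]
    )
    best = int(np.argmax(window_sums))  # argmax takes the first maximum
    if np.count_nonzero(window_sums == window_sums[best]) > 1:
        logger.debug("warmest_quarter tie; using earliest start month %d", best + 1)
    return best + 1


def bio10_bio18(monthly_tmean, monthly_prcp) -> tuple[float, float]:
    """(Bio10, Bio18): warmest-quarter mean temperature (°C) and precipitation sum (mm)."""
    tmean = _validate_monthly(monthly_tmean, "monthly_tmean")
    prcp = _validate_monthly(monthly_prcp, "monthly_prcp")
    start = warmest_quarter(tmean) - 1
    window = slice(start, start + QUARTER)
    return float(tmean[window].mean()), float(prcp[window].sum())


def county_year_covariates(climate: pd.DataFrame) -> pd.DataFrame:
    """Derive one (bio6, bio10, bio18) row per (county, year).

    Parameters
    ----------
    climate : DataFrame
        Long monthly series with columns ``county, year, month, tmin_C,
        tmean_C, prcp_mm`` — one row per county-year-month, months 1..12
        complete for every county-year.

    Returns
    -------
    DataFrame with columns ``county, year, bio6, bio10, bio18``, sorted by
    (county, year).
    """
    required = {"county", "year", "month", "tmin_C", "tmean_C", "prcp_mm"}
    missing = required - set(climate.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")

    df = climate.sort_values(["county", "year", "month"], kind="stable")
    sizes = df.groupby(["county", "year"], sort=False)["month"].agg(["size", "nunique"])
    complete = (sizes["size"] == MONTHS_PER_YEAR) & (sizes["nunique"] == MONTHS_PER_YEAR)
    if not complete.all():
        county, year = complete.idxmin()
        months = sorted(
            df[(df["county"] == county) & (df["year"] == year)]["month"].unique()
        )
        raise ValueError(
            f"incomplete monthly series for county={county!r}, year={year}: "
            f"months present {months}"
        )
    n_cy = len(sizes)
    months = df["month"].to_numpy().reshape(n_cy, MONTHS_PER_YEAR)
    if not np.array_equal(months, np.tile(np.arange(1, 13), (n_cy, 1))):
        raise ValueError("monthly series must hold months 1..12 per county-year")

    tmin = df["tmin_C"].to_numpy(dtype=float).reshape(n_cy, MONTHS_PER_YEAR)
    tmean = df["tmean_C"].to_numpy(dtype=float).reshape(n_cy, MONTHS_PER_YEAR)
    prcp = df["prcp_mm"].to_numpy(dtype=float).reshape(n_cy, MONTHS_PER_YEAR)
    for name, arr in (("tmin_C", tmin), ("tmean_C", tmean), ("prcp_mm", prcp)):
        if not np.isfinite(arr).all():
            bad = np.flatnonzero(~np.isfinite(arr).all(axis=1))[0]
            raise ValueError(f"{name}: non-finite value for {sizes.index[bad]}")

    n_windows = MONTHS_PER_YEAR - QUARTER + 1
    # window sums month-by-month, matching the scalar warmest_quarter arithmetic
    window_sums = np.stack(
        [tmean[:, s : s + QUARTER].sum(axis=1) for s in range(n_windows)], axis=1
    )
    start = np.argmax(window_sums, axis=1)  # first maximum, earliest window
    b10 = np.take_along_axis(window_sums, start[:, None], axis=1)[:, 0] / QUARTER
    prcp_windows = np.stack(
        [prcp[:, s : s + QUARTER].sum(axis=1) for s in range(n_windows)], axis=1
    )
    b18 = np.take_along_axis(prcp_windows, start[:, None], axis=1)[:, 0]

    out = pd.DataFrame(
        {
            "county": sizes.index.get_level_values("county"),
            "year": sizes.index.get_level_values("year").astype(int),
            "bio6": tmin.min(axis=1),
            "bio10": b10,
            "bio18": b18,
        }
    )
    return out.sort_values(["county", "year"], ignore_index=True)


def attach_covariates(events: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Left-join bioclim covariates onto an event table by (county, year).

    Raises if any event's (county, year) has no covariate row, listing the
    offending pairs.
    """
    merged = events.merge(covariates, on=["county", "year"], how="left", validate="m:1")
    unmatched = merged["bio6"].isna()
    if unmatched.any():
        offenders = (
            merged.loc[unmatched, ["county", "year"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        listing = ", ".join(f"({c!r}, {y})" for c, y in offenders)
        raise ValueError(f"no climate covariates for (county, year): {listing}")
    return merged
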