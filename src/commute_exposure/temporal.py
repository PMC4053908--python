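"""Temporal adjustment factors from monitoring-station time series.

Hour-of-day ratios are computed between the annual weekday hourly means
and the annual (weekday) mean at each station: the street site provides
the main-street factors, the background site the side-street factors.
"""

from __future__ import annotations

import numpy as np

from .models import RatioTable, StationSeries


def _hourly_ratios(series: StationSeries, weekdays_only: bool = True) -> np.ndarray:
    ts = series.timestamps
    vals = np.asarray(series.values, dtype=float)
    if weekdays_only:
        mask = ts.dayofweek < 5
        ts, vals = ts[mask], vals[mask]
    if len(vals) == 0:
        raise ValueError("no weekday observations in series")
    hours = ts.hour.to_numpy()
    overall = vals.mean()
    ratios = np.empty(24)
    for h in range(24):
        sel = vals[hours == h]
        if sel.size == 0:
            raise ValueError(f"empty hour bin: no observations for hour {h}")
        ratios[h] = sel.mean() / overall
    return ratios


def compute_hourly_ratios(
    street: StationSeries, background: StationSeries, weekdays_only: bool = True
) -> RatioTable:
    """RatioTable with ratio_m from the street and ratio_s from the background site.

    Each entry is the mean of that clock hour's values across weekdays
    divided by the overall weekday mean.  ``weekdays_only=False`` includes
    weekends in both the numerator and the denominator.
    """
    if street.site_type != "street" or background.site_type != "background":
        raise ValueError(
            f"expected (street, background) series, got "
            f"({street.site_type!r}, {background.site_type!r})"
        )
    return RatioTable(
        ratio_m=_hourly_ratios(street, weekdays_only),
        ratio_s=_hourly_ratios(background, weekdays_only),
    )


def lookup_ratio(table: RatioTable, road_class: str, hour: int) -> float:
    """Adjustment factor for a leg from its road class and start hour."""
    if not 0 <= hour <= 23:
        raise ValueError(f"hour must be in 0-23, got {hour}")
    if road_class == "main":
        return float(table.ratio_m[hour])
    if road_class == "side":
        return float(table.ratio_s[hour])
    raise ValueError(f"road class is {road_class!r}; classify the leg first")
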