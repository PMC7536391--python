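"""Compute the weather exposures used by the yield model for one county-season.

Builds a 60-day synthetic daily weather series, then accumulates growing
degree-days (beneficial heat between the crop's base and ceiling),
extreme degree-days (harmful heat above the damage threshold), and the
seasonal crop water deficit index (unmet evaporative demand).
"""

import numpy as np
import pandas as pd

from cropshift.predictors import (
    DEFAULT_CALENDARS,
    crop_water_deficit_index,
    seasonal_degree_days,
)

rng = np.random.default_rng(0)
cal = DEFAULT_CALENDARS["corn"]

dates = pd.date_range("2005-01-01", "2005-12-31", freq="D")
doy = dates.dayofyear
tmean = 12 + 14 * np.sin((doy - 110) / 365 * 2 * np.pi) + rng.normal(0, 2, len(dates))
weather = pd.DataFrame(
    {
        "county_id": "C001",
        "date": dates,
        "tmin": tmean - 5,
        "tmax": tmean + 5,
        "precip": rng.gamma(0.6, 5.0, len(dates)),
        "pet": np.clip(1.5 + 0.2 * tmean, 0, None),
    }
)

gdd, edd = seasonal_degree_days(weather, cal)
cdi = crop_water_deficit_index(weather, cal)

print(f"corn season (day {cal.season_start}-{cal.season_end}, "
      f"base {cal.gdd_base} C, damage threshold {cal.edd_threshold} C)")
print(f"  GDD = {gdd:8.1f} degree-days   (accumulated beneficial heat)")
print(f"  EDD = {edd:8.1f} degree-days   (accumulated heat above {cal.edd_threshold} C)")
print(f"  CDI = {cdi:8.3f}               (0 = demand fully met, 1 = no rain at all)")
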