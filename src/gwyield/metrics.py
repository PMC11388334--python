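"""Deterministic building blocks: water deficit, weather classes, CV, agreement.

Weather classes partition the July water-deficit axis (mm, precipitation
minus PET) at 0, -50 and -150 mm.  Boundary convention (documented and
fixed): a deficit of exactly 0 is *normal*, exactly -50 is *normal*,
exactly -150 is *dry*; "very dry" means strictly more negative than
-150 mm.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


class WeatherClass(str, Enum):
    WET = "wet"
    NORMAL = "normal"
    DRY = "dry"
    VERY_DRY = "very_dry"


#: Class boundaries on the deficit axis (mm).
WET_BOUND = 0.0
DRY_BOUND = -50.0
VERY_DRY_BOUND = -150.0

#: Categorical order used for tabular output.
CLASS_ORDER = [w.value for w in (WeatherClass.WET, WeatherClass.NORMAL,
                                 WeatherClass.DRY, WeatherClass.VERY_DRY)]


def water_deficit(precip, pet):
    """July water deficit: precipitation minus potential evapotranspiration (mm).

    Negative values indicate a deficit.  Inputs must be finite and PET
    non-negative.
    """
    p = np.asarray(precip, dtype=float)
    e = np.asarray(pet, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(e))):
        raise ValueError("precip and pet must be finite")
    if np.any(e < 0):
        raise ValueError("pet must be non-negative")
    out = p - e
    return float(out) if out.ndim == 0 else out


def classify_weather(deficit):
    """Map water deficits (mm) to weather classes.

    wet iff deficit > 0; normal iff -50 <= deficit <= 0; dry iff
    -150 <= deficit < -50; very_dry iff deficit < -150.
    """
    d = np.asarray(deficit, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("deficit must be finite")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.empty(d.shape, dtype=object)
    out[d > WET_BOUND] = WeatherClass.WET
    out[(d <= WET_BOUND) & (d >= DRY_BOUND)] = WeatherClass.NORMAL
    out[(d < DRY_BOUND) & (d >= VERY_DRY_BOUND)] = WeatherClass.DRY
    out[d < VERY_DRY_BOUND] = WeatherClass.VERY_DRY
    if scalar:
        return out[0]
    return out


def coefficient_of_variation(values) -> float:
    """CV in percent: sample SD (n-1 denominator) / mean * 100.

    Undefined (raises ValueError) for fewer than two values or a
    non-positive mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least two values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m * 100.0)


def agreement(observed, predicted, weather_class=None) -> pd.DataFrame:
    """Agreement between paired series: squared Pearson correlation and RMSE.

    R² here is the squared correlation coefficient, not 1 - SSE/SST, so a
    constant bias leaves it at 1 while inflating RMSE.  When
    ``weather_class`` is supplied, one row per class is returned in
    addition to the overall row ("all").

    Returns a DataFrame with columns ``group, n, r2, rmse``.  Zero variance
    in either series makes R² undefined; it is reported as NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be the same length")
    if obs.size < 3:
        raise ValueError("agreement requires at least 3 pairs")

    def _one(o, p):
        rmse = float(np.sqrt(np.mean((o - p) ** 2)))
        if o.size < 3 or np.std(o) == 0 or np.std(p) == 0:
            return np.nan, rmse
        r = stats.pearsonr(o, p).statistic
        return float(r * r), rmse

    rows = []
    r2, rmse = _one(obs, pred)
    rows.append({"group": "all", "n": obs.size, "r2": r2, "rmse": rmse})
    if weather_class is not None:
        wc = np.asarray(
            [w.value if isinstance(w, WeatherClass) else str(w) for w in weather_class]
        )
        if wc.shape != obs.shape:
            raise ValueError("weather_class must match the series length")
        for cls in CLASS_ORDER:
            mask = wc == cls
            if not mask.any():
                rows.append({"group": cls, "n": 0, "r2": np.nan, "rmse": np.nan})
                continue
            r2c, rmsec = _one(obs[mask], pred[mask])
            rows.append({"group": cls, "n": int(mask.sum()), "r2": r2c, "rmse": rmsec})
    return pd.DataFrame(rows)
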