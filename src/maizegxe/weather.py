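"""Daily weather series, file I/O, and astronomical day length.

The canonical on-disk form is a CSV with header ``DATE,SRAD,TMAX,TMIN,RAIN``
(ISO dates, MJ m^-2 d^-1, degC, degC, mm).  A reader for the fixed-width
DSSAT-style ``.WTH`` layout (``yyddd`` dates) is also provided.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WeatherSeries", "day_length", "read_weather_csv", "write_weather_csv",
           "read_wth"]


@dataclass
class WeatherSeries:
    """Contiguous daily weather for one site.

    Attributes
    ----------
    dates : np.ndarray of datetime64[D], strictly consecutive days
    tmax, tmin : degC
    srad : MJ m^-2 d^-1 global solar radiation
    rain : mm d^-1
    latitude : site latitude in decimal degrees (needed for day length)
    """

    dates: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    srad: np.ndarray
    rain: np.ndarray
    latitude: float = 11.5

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        for name in ("tmax", "tmin", "srad", "rain"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.dates)
        if not all(len(getattr(self, a)) == n for a in ("tmax", "tmin", "srad", "rain")):
            raise ValueError("weather columns must all have the same length")
        if n == 0:
            raise ValueError("empty weather series")
        if n > 1:
            gaps = np.diff(self.dates).astype("timedelta64[D]").astype(int)
            if np.any(gaps != 1):
                raise ValueError("weather series must be contiguous daily records")
        if np.any(self.tmax < self.tmin):
            bad = int(np.argmax(self.tmax < self.tmin))
            raise ValueError(f"Tmax < Tmin on {self.dates[bad]}")
        if np.any(self.rain < 0) or np.any(self.srad < 0):
            raise ValueError("rain and srad must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def doy(self) -> np.ndarray:
        """1-based day of year for every record."""
        years = self.dates.astype("datetime64[Y]")
        return (self.dates - years.astype("datetime64[D]")).astype(int) + 1

    def index_of(self, date: dt.date | str | np.datetime64) -> int:
        d = np.datetime64(date, "D")
        i = int((d - self.dates[0]).astype(int))
        if i < 0 or i >= len(self):
            raise KeyError(f"{d} not in weather series")
        return i

    def slice_years(self, year: int) -> "WeatherSeries":
        mask = self.dates.astype("datetime64[Y]").astype(int) + 1970 == year
        if not mask.any():
            raise KeyError(f"no records for year {year}")
        return WeatherSeries(self.dates[mask], self.tmax[mask], self.tmin[mask],
                             self.srad[mask], self.rain[mask], self.latitude)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"DATE": self.dates, "SRAD": self.srad, "TMAX": self.tmax,
                             "TMIN": self.tmin, "RAIN": self.rain})


def day_length(latitude: float, doy: int | np.ndarray) -> float | np.ndarray:
    """Astronomical day length in hours (sunrise to sunset).

    Standard solar-declination geometry: declination
    ``delta = -23.45 cos(2 pi (doy + 10) / 365)`` and half-day angle
    ``arccos(-tan(lat) tan(delta))``.  Valid for |latitude| < 66 degrees
    (no polar day/night).
    """
    if abs(latitude) >= 66:
        raise ValueError("day_length is only defined for |latitude| < 66 degrees")
    lat = math.radians(latitude)
    doy_arr = np.asarray(doy, dtype=float)
    decl = np.radians(-23.45 * np.cos(2.0 * np.pi * (doy_arr + 10.0) / 365.0))
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_h)
    if np.isscalar(doy) or getattr(doy, "ndim", 1) == 0:
        return float(hours)
    return hours


def read_weather_csv(path: str | Path, latitude: float = 11.5) -> WeatherSeries:
    """Read the ``DATE,SRAD,TMAX,TMIN,RAIN`` CSV dialect."""
    df = pd.read_csv(path)
    missing = {"DATE", "SRAD", "TMAX", "TMIN", "RAIN"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    dates = pd.to_datetime(df["DATE"]).values.astype("datetime64[D]")
    return WeatherSeries(dates, df["TMAX"].values, df["TMIN"].values,
                         df["SRAD"].values, df["RAIN"].values, latitude)


def write_weather_csv(wx: WeatherSeries, path: str | Path) -> None:
    wx.to_frame().to_csv(path, index=False, date_format="%Y-%m-%d")


def read_wth(path: str | Path, latitude: float = 11.5) -> WeatherSeries:
    """Read a minimal DSSAT-style .WTH file.

    Expects a ``@DATE  SRAD  TMAX  TMIN  RAIN`` header line followed by
    whitespace-separated rows whose DATE is the 5-digit ``yyddd`` form
    (two-digit year, 3-digit day of year; years < 30 map to 20xx).
    """
    rows: list[tuple[dt.date, float, float, float, float]] = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("*", "!")):
                continue
            if line.startswith("@"):
                header_seen = "DATE" in line.upper()
                continue
            if not header_seen:
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"malformed WTH row: {line!r}")
            code = parts[0]
            if len(code) != 5 or not code.isdigit():
                raise ValueError(f"WTH DATE must be yyddd, got {code!r}")
            yy, ddd = int(code[:2]), int(code[2:])
            year = 2000 + yy if yy < 30 else 1900 + yy
            date = dt.date(year, 1, 1) + dt.timedelta(days=ddd - 1)
            srad, tmax, tmin, rain = map(float, parts[1:5])
            rows.append((date, srad, tmax, tmin, rain))
    if not rows:
        raise ValueError("WTH file contains no data rows")
    dates = np.array([r[0] for r in rows], dtype="datetime64[D]")
    arr = np.array([r[1:] for r in rows], dtype=float)
    return WeatherSeries(dates, arr[:, 1], arr[:, 2], arr[:, 0], arr[:, 3], latitude)
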