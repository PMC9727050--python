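"""Daily-series I/O, hourly aggregation, stratified counts, and logging.

The daily series is the pipeline's canonical input: one row per calendar
day with mean temperature (C), relative humidity (%), PM10 (ug/m3), a
holiday indicator, derived day-of-week (1 = Monday), and one non-negative
integer death-count column per population stratum (``deaths_<label>``).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries", "read_daily_series", "write_daily_series",
    "aggregate_hourly", "build_stratum_counts", "load_holidays", "get_logger",
]

_REQUIRED = ("date", "tmean", "rh", "pm10", "holiday")


def get_logger(name="tvdlnm", level="INFO", logfile=None) -> logging.Logger:
    logger = logging.getLogger(name)
    logger.setLevel(level)
    if not logger.handlers:
        fmt = logging.Formatter(
            "%(asctime)s [%(levelname)s] %(name)s: %(message)s")
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(fmt)
        logger.addHandler(h)
        if logfile:
            fh = logging.FileHandler(logfile)
            fh.setFormatter(fmt)
            logger.addHandler(fh)
    return logger


@dataclass
class DailySeries:
    """Validated container for aligned daily records."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.reset_index(drop=True).copy()
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"daily series missing columns: {missing}")
        df["date"] = pd.to_datetime(df["date"])
        dup = df["date"][df["date"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate date: {dup.iloc[0].date()}")
        diffs = df["date"].diff().dropna()
        bad = diffs[diffs != pd.Timedelta(days=1)]
        if len(bad):
            at = df["date"][bad.index[0]].date()
            raise ValueError(f"dates not consecutive/increasing at {at}")
        rh = df["rh"].to_numpy(dtype=float)
        out = np.where(np.isfinite(rh) & ((rh < 0) | (rh > 100)))[0]
        if out.size:
            raise ValueError(
                f"relative humidity out of [0, 100] at row {out[0]} "
                f"(date {df['date'].iloc[out[0]].date()}, rh={rh[out[0]]})")
        for col in self._death_cols(df):
            v = df[col].to_numpy(dtype=float)
            neg = np.where(np.isfinite(v) & (v < 0))[0]
            if neg.size:
                raise ValueError(f"negative death count in {col} at row {neg[0]}")
            nonint = np.where(np.isfinite(v) & (v != np.round(v)))[0]
            if nonint.size:
                raise ValueError(f"non-integer death count in {col} at row "
                                 f"{nonint[0]}")
        df["holiday"] = df["holiday"].fillna(False).astype(bool)
        df["dow"] = df["date"].dt.dayofweek + 1   # 1 = Monday
        self.frame = df

    @staticmethod
    def _death_cols(df):
        return [c for c in df.columns if c.startswith("deaths_")]

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.Series:
        return self.frame["date"]

    @property
    def death_columns(self) -> list:
        return self._death_cols(self.frame)

    @property
    def strata(self) -> list:
        return [c[len("deaths_"):] for c in self.death_columns]

    def deaths(self, stratum: str) -> np.ndarray:
        col = f"deaths_{stratum}"
        if col not in self.frame.columns:
            raise KeyError(f"no stratum column {col!r}; available: "
                           f"{self.strata}")
        return self.frame[col].to_numpy(dtype=float)

    def missing_report(self) -> dict:
        return {c: int(self.frame[c].isna().sum())
                for c in self.frame.columns if c != "date"}


def read_daily_series(path, config=None) -> DailySeries:
    """Read and validate a daily-series CSV (ISO dates, header row)."""
    df = pd.read_csv(path)
    series = DailySeries(df)
    log = get_logger()
    miss = {k: v for k, v in series.missing_report().items() if v}
    if miss:
        log.info("missing values per column: %s", miss)
    return series


def write_daily_series(series: DailySeries, path) -> None:
    df = series.frame.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df["holiday"] = df["holiday"].astype(int)
    df.to_csv(path, index=False)


def load_holidays(path) -> set:
    """Holiday list file: one ISO date per line, '#' comments allowed."""
    dates = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                dates.add(pd.Timestamp(line))
    return dates


def aggregate_hourly(hourly: pd.DataFrame, min_valid_fraction: float = 0.75,
                     min_hours_per_day: int = 18):
    """Two-stage aggregation of hourly station data to a daily mean series.

    Stations whose overall valid-data fraction (non-missing hours over the
    full day span times 24) falls below ``min_valid_fraction`` are excluded
    entirely.  For retained stations a daily mean is computed when at least
    ``min_hours_per_day`` hourly values are present, else that station-day
    is missing.  The daily value is the unweighted mean across retained
    stations with a value that day.

    Returns ``(daily, n_retained)`` where ``daily`` is a Series indexed by
    date.
    """
    if not 0.0 < min_valid_fraction <= 1.0:
        raise ValueError("min_valid_fraction must be in (0, 1]")
    df = hourly.copy()
    df["datetime"] = pd.to_datetime(df["datetime"])
    df["day"] = df["datetime"].dt.normalize()
    days = pd.date_range(df["day"].min(), df["day"].max(), freq="D")
    expected = len(days) * 24
    valid = df.dropna(subset=["value"]).groupby("station").size()
    keep = sorted(valid[valid / expected >= min_valid_fraction].index)
    if not keep:
        raise ValueError("no station meets the valid-data threshold of "
                         f"{min_valid_fraction:.0%}")
    sub = df[df["station"].isin(keep)]
    g = sub.groupby(["station", "day"])["value"]
    per_station = g.mean().where(g.count() >= min_hours_per_day)
    daily = (per_station.reset_index()
             .groupby("day")["value"].mean()
             .reindex(days))
    daily.index.name = "date"
    return daily, len(keep)


def build_stratum_counts(records: pd.DataFrame, scheme: dict,
                         dates: pd.Series):
    """Daily death counts per stratum from individual death records.

    ``scheme`` maps a stratum label to a predicate dict ``{field: rule}``
    where a rule is either a set/list of allowed values or an inclusive
    ``(lo, hi)`` numeric range; the empty dict matches every record.
    Records missing a field required by a stratum are excluded from that
    column only and tallied (for the missingness bias check).

    Returns ``(counts, tallies)``: a DataFrame of columns
    ``deaths_<label>`` indexed like ``dates``, and a dict of per-stratum
    excluded-for-missingness counts.
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"]).dt.normalize()
    dates = pd.to_datetime(pd.Series(dates)).dt.normalize()
    lo, hi = dates.min(), dates.max()
    outside = rec[(rec["date"] < lo) | (rec["date"] > hi)]
    if len(outside):
        raise ValueError(f"record date {outside['date'].iloc[0].date()} "
                         f"outside series range {lo.date()}..{hi.date()}")
    counts = pd.DataFrame(index=pd.Index(dates, name="date"))
    tallies = {}
    for label, pred in scheme.items():
        mask = np.ones(len(rec), dtype=bool)
        req_missing = np.zeros(len(rec), dtype=bool)
        for fieldname, rule in pred.items():
            col = rec[fieldname]
            isna = col.isna().to_numpy()
            req_missing |= isna
            if isinstance(rule, tuple) and len(rule) == 2 and \
                    all(isinstance(r, (int, float)) for r in rule):
                ok = (col >= rule[0]) & (col <= rule[1])
            else:
                ok = col.isin(list(rule))
            mask &= ok.fillna(False).to_numpy()
        mask &= ~req_missing
        tallies[label] = int(req_missing.sum())
        daily = rec.loc[mask].groupby("date").size()
        counts[f"deaths_{label}"] = (daily.reindex(counts.index)
                                     .fillna(0).astype(int).to_numpy())
    return counts, tallies
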