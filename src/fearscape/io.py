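"""Reading, validating, resampling and annotating tracking tables.

All tables travel as delimited text with documented headers:

* tracks:        individual_id, species, sex, timestamp, x, y
* shooting log:  event_id, timestamp, field_id, centroid_x, centroid_y,
                 n_shots, n_killed   (NatureScot-log style: date, time,
                 shots, kills, field parcel)
* bursts:        burst_id, individual_id, timestamp, label, x, y, z
                 where x/y/z are space-separated acceleration samples

Timestamps are UTC throughout.  Annotation adds winter label, date index
(days since 1 November, 1 Nov = 1), day/night from solar elevation at
the configured site, and farm membership by point-in-polygon (boundary
points count as inside).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fearscape import solar
from fearscape.config import SPECIES
from fearscape.landscape import Landscape

TRACK_SCHEMA = ["individual_id", "species", "sex", "timestamp", "x", "y"]
EVENT_SCHEMA = ["event_id", "timestamp", "field_id", "centroid_x", "centroid_y",
                "n_shots", "n_killed"]
BURST_SCHEMA = ["burst_id", "individual_id", "timestamp", "label", "x", "y", "z"]


class SchemaError(ValueError):
    """A table is missing mandatory columns or violates row invariants."""


def _require_columns(df: pd.DataFrame, schema, what: str) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing mandatory columns: {missing}")


def _parse_timestamps(df: pd.DataFrame, what: str) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True).dt.tz_localize(None)
    bad = df.index[ts.isna() & df["timestamp"].notna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header plus 1-based
        raise SchemaError(f"{what}: unparseable timestamps at file lines {lines}")
    out = df.copy()
    out["timestamp"] = ts
    return out


# -- tracks -----------------------------------------------------------

def read_tracks(path) -> pd.DataFrame:
    """Read and validate a GPS track CSV.

    Raises :class:`SchemaError` for missing columns, unparseable
    timestamps (with file line numbers), unknown species codes or
    duplicated timestamps within an individual.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACK_SCHEMA, "track")
    df = _parse_timestamps(df, "tracks")
    unknown = set(df["species"].unique()) - set(SPECIES)
    if unknown:
        raise SchemaError(f"unknown species codes: {sorted(unknown)}")
    dup = df.duplicated(["individual_id", "timestamp"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["individual_id", "timestamp"]].drop_duplicates()
        raise SchemaError(
            "duplicated timestamps per individual: "
            + "; ".join(f"{r.individual_id}@{r.timestamp}" for r in
                        offenders.head(10).itertuples()))
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    return df.sort_values(["individual_id", "timestamp"], ignore_index=True)


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in df.columns])


# -- shooting log -----------------------------------------------------

def read_shooting_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_SCHEMA, "shooting log")
    df = _parse_timestamps(df, "shooting log")
    bad = df.index[df["n_killed"] > df["n_shots"]]
    if len(bad):
        raise SchemaError(f"n_killed exceeds n_shots at file lines {[int(i) + 2 for i in bad]}")
    return df.sort_values("timestamp", ignore_index=True)


def write_shooting_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# -- accelerometer bursts --------------------------------------------

def read_bursts(path) -> pd.DataFrame:
    """Read a burst CSV; sample columns become float arrays.

    Each burst must have three equal-length axes with at least two
    samples.
    """
    df = pd.read_csv(path)
    _require_columns(df, BURST_SCHEMA, "burst")
    df = _parse_timestamps(df, "bursts")
    for ax in ("x", "y", "z"):
        df[ax] = df[ax].map(lambda s: np.fromstring(str(s), sep=" "))
    lens = df[["x", "y", "z"]].map(len)
    bad = df.index[(lens.nunique(axis=1) > 1) | (lens["x"] < 2)]
    if len(bad):
        raise SchemaError(
            f"bursts with unequal or too-short axes at file lines {[int(i) + 2 for i in bad[:10]]}")
    return df


def write_bursts(df: pd.DataFrame, path, precision: int = 6) -> None:
    out = df.copy()
    for ax in ("x", "y", "z"):
        out[ax] = out[ax].map(
            lambda a: " ".join(f"{v:.{precision}g}" for v in np.asarray(a)))
    cols = [c for c in BURST_SCHEMA if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out.to_csv(path, index=False, columns=cols)


# -- resampling -------------------------------------------------------

def resample_hourly(fixes: pd.DataFrame, tolerance_min: float = 30.0) -> pd.DataFrame:
    """Thin fixes to at most one per clock hour per individual.

    For each hour mark, the nearest fix within ``tolerance_min`` is
    kept (ties go to the earlier fix); hours without a qualifying fix
    stay empty — no interpolation.  Idempotent.
    """
    if fixes.empty:
        return fixes.copy()
    df = fixes.sort_values(["individual_id", "timestamp"])
    nearest_hour = df["timestamp"].dt.round("h")
    offset = (df["timestamp"] - nearest_hour).abs()
    ok = offset <= pd.Timedelta(minutes=tolerance_min)
    df = df[ok].assign(_hour=nearest_hour[ok], _off=offset[ok])
    df = df.sort_values(["individual_id", "_hour", "_off", "timestamp"])
    out = df.groupby(["individual_id", "_hour"], as_index=False, sort=False).head(1)
    return (out.drop(columns=["_hour", "_off"])
               .sort_values(["individual_id", "timestamp"], ignore_index=True))


# -- annotation -------------------------------------------------------

def winter_of(timestamps: pd.Series) -> pd.Series:
    """Winter label "YYYY-YYYY+1" for dates in Oct-Apr, else <NA>."""
    ts = pd.to_datetime(timestamps)
    month = ts.dt.month
    year = ts.dt.year.where(month >= 10, ts.dt.year - 1)
    label = year.astype("Int64").astype(str) + "-" + (year + 1).astype("Int64").astype(str)
    return label.where((month >= 10) | (month <= 4), pd.NA)


def date_index_of(timestamps: pd.Series) -> pd.Series:
    """Integer days since 1 November of the winter (1 Nov = 1).

    October days come out non-positive; the standard winters analysed
    here start on 1 November so indices are >= 1.
    """
    ts = pd.to_datetime(timestamps)
    month = ts.dt.month
    ref_year = ts.dt.year.where(month >= 10, ts.dt.year - 1)
    ref = pd.to_datetime(ref_year.astype(str) + "-11-01")
    return (ts.dt.normalize() - ref).dt.days + 1


def annotate_fixes(
    fixes: pd.DataFrame,
    landscape: Landscape | None = None,
    lat: float = solar.SITE_LAT,
    lon: float = solar.SITE_LON,
) -> pd.DataFrame:
    """Add winter, date_index, is_day and farm_id columns.

    Coordinates and timestamps are never modified.  Fixes outside all
    farm polygons (or with no landscape supplied) get ``farm_id`` NA;
    fixes outside the landscape extent additionally raise a warning.
    """
    out = fixes.copy()
    out["winter"] = winter_of(out["timestamp"])
    out["date_index"] = date_index_of(out["timestamp"])
    out["is_day"] = solar.is_daytime(out["timestamp"], lat=lat, lon=lon)
    if landscape is not None:
        inside = landscape.contains(out["x"].to_numpy(), out["y"].to_numpy())
        if not inside.all():
            import warnings

            warnings.warn(f"{(~inside).sum()} fixes outside landscape extent; farm_id set to NA")
        farm = np.full(len(out), None, dtype=object)
        if inside.any():
            farm[inside] = landscape.farms_at(
                out.loc[inside, "x"].to_numpy(), out.loc[inside, "y"].to_numpy())
        out["farm_id"] = farm
    else:
        out["farm_id"] = None
    return out
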