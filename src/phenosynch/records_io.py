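"""Data model, delimited-text I/O, validation and species-inclusion filters.

The central container is :class:`Dataset`: a table of individual flowering
records (one row per individual, with observed onset and end census dates),
per-year census calendars, and a species metadata table.  All dates are
ISO-8601 calendar dates; arithmetic is done in integer days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIFE_FORMS = ("tree", "perennial", "annual")

RECORD_COLUMNS = [
    "species", "genus", "family", "life_form",
    "year", "individual_id", "onset", "end",
]
META_COLUMNS = ["species", "genus", "family", "life_form"]


class ValidationError(ValueError):
    """A record table violates an invariant (dates, life form, referential)."""


class ParseError(ValueError):
    """A field could not be parsed (malformed date, bad header)."""


@dataclass(frozen=True)
class CensusCalendar:
    """Ordered weekly observation dates for one year."""

    year: int
    dates: tuple

    def __post_init__(self):
        dates = tuple(pd.Timestamp(d) for d in self.dates)
        object.__setattr__(self, "dates", dates)
        if len(dates) < 2:
            raise ValidationError("a census calendar needs at least 2 dates")
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValidationError("census dates must be strictly increasing")
        if any(d.year != self.year for d in dates):
            raise ValidationError(
                f"calendar for {self.year} contains dates from another year")

    def __len__(self):
        return len(self.dates)

    def as_index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(list(self.dates))

    def __contains__(self, d) -> bool:
        return pd.Timestamp(d) in set(self.dates)


@dataclass
class Dataset:
    """Flowering records + census calendars + species metadata."""

    records: pd.DataFrame
    calendars: dict
    meta: pd.DataFrame
    dropped_species: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "reason"]))

    def __post_init__(self):
        validate_dataset(self)

    @property
    def species(self) -> list:
        return sorted(self.records["species"].unique())

    @property
    def years(self) -> list:
        return sorted(self.records["year"].unique())


def _parse_dates(s: pd.Series, colname: str, path) -> pd.Series:
    out = pd.to_datetime(s, format="ISO8601", errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: malformed {colname} date {s.iloc[row]!r} in row {row + 2}")
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ValidationError(f"{path}: missing {colname} date in row {row + 2}")
    return out


def validate_dataset(ds: Dataset) -> None:
    """Check every Dataset invariant; raise ValidationError on the first hit."""
    rec, meta = ds.records, ds.meta
    missing = [c for c in RECORD_COLUMNS if c not in rec.columns]
    if missing:
        raise ValidationError(f"records table missing columns {missing}")
    bad_lf = set(rec["life_form"]) - set(LIFE_FORMS)
    if bad_lf:
        raise ValidationError(f"unknown life_form values {sorted(bad_lf)}")
    if (rec["end"] < rec["onset"]).any():
        i = int(np.flatnonzero((rec["end"] < rec["onset"]).to_numpy())[0])
        raise ValidationError(
            f"record row {i}: end {rec['end'].iloc[i].date()} precedes "
            f"onset {rec['onset'].iloc[i].date()}")
    if meta["species"].duplicated().any():
        dup = meta.loc[meta["species"].duplicated(), "species"].iloc[0]
        raise ValidationError(f"duplicate species {dup!r} in metadata")
    unknown = set(rec["species"]) - set(meta["species"])
    if unknown:
        raise ValidationError(
            f"records reference species absent from metadata: {sorted(unknown)}")
    for year, grp in rec.groupby("year"):
        if year not in ds.calendars:
            raise ValidationError(f"no census calendar for year {year}")
        dates = set(ds.calendars[year].dates)
        for col in ("onset", "end"):
            off = ~grp[col].isin(dates)
            if off.any():
                bad = grp.loc[off].iloc[0]
                raise ValidationError(
                    f"{bad['species']} {col} {bad[col].date()} is not a "
                    f"census date of {year}")


def read_calendar(path) -> dict:
    """Read a calendar CSV (columns year,date) into per-year calendars."""
    df = pd.read_csv(path)
    if not {"year", "date"} <= set(df.columns):
        raise ParseError(f"{path}: calendar CSV needs columns year,date")
    df["date"] = _parse_dates(df["date"], "census", path)
    return {int(y): CensusCalendar(int(y), tuple(g["date"].sort_values()))
            for y, g in df.groupby("year")}


def read_dataset(records_path, calendar_path, meta_path) -> Dataset:
    """Read and validate a full dataset from three delimited-text files."""
    rec = pd.read_csv(records_path)
    missing = [c for c in RECORD_COLUMNS if c not in rec.columns]
    if missing:
        raise ParseError(f"{records_path}: missing columns {missing}")
    rec["onset"] = _parse_dates(rec["onset"], "onset", records_path)
    rec["end"] = _parse_dates(rec["end"], "end", records_path)
    rec["year"] = rec["year"].astype(int)
    meta = pd.read_csv(meta_path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{meta_path}: missing columns {missing}")
    calendars = read_calendar(calendar_path)
    return Dataset(records=rec.reset_index(drop=True), calendars=calendars,
                   meta=meta)


def _species_flowering_days(rec: pd.DataFrame, calendars: dict) -> pd.Series:
    """Distinct census dates with >=1 individual in flower, pooled over years."""
    counts = {}
    for (species, year), grp in rec.groupby(["species", "year"]):
        cal = calendars[year]
        dates = [d for d in cal.dates
                 if ((grp["onset"] <= d) & (d <= grp["end"])).any()]
        counts.setdefault(species, set()).update((year, d) for d in dates)
    return pd.Series({s: len(v) for s, v in counts.items()}, dtype=int)


def filter_species(ds: Dataset, min_flowering_days: int = 2,
                   min_individuals: int = 5,
                   require_both_years: bool = False) -> Dataset:
    """Apply the species-inclusion filters.

    Retains species whose pooled set of census dates with flowering has size
    strictly greater than ``min_flowering_days``, and with at least
    ``min_individuals`` individuals — per year in every observed year when
    ``require_both_years``, else pooled over years.  Dropped species are
    reported on ``Dataset.dropped_species`` and logged.
    """
    rec = ds.records
    dropped = []
    keep = set(rec["species"].unique())

    fdays = _species_flowering_days(rec, ds.calendars)
    for sp in sorted(keep):
        if fdays.get(sp, 0) <= min_flowering_days:
            keep.discard(sp)
            dropped.append((sp, f"flowering days {fdays.get(sp, 0)} <= "
                                f"{min_flowering_days}"))

    years = sorted(rec["year"].unique())
    counts = rec.groupby(["species", "year"])["individual_id"].count()
    for sp in sorted(keep):
        if require_both_years:
            per_year = [counts.get((sp, y), 0) for y in years]
            ok = all(c >= min_individuals for c in per_year)
            why = f"individuals per year {per_year} < {min_individuals}"
        else:
            n = int(counts.loc[sp].sum()) if sp in counts.index.levels[0] else 0
            ok = n >= min_individuals
            why = f"individuals {n} < {min_individuals}"
        if not ok:
            keep.discard(sp)
            dropped.append((sp, why))

    if not keep:
        logger.warning("filter_species removed every species")
    for sp, why in dropped:
        logger.info("dropping %s: %s", sp, why)
    out_rec = rec[rec["species"].isin(keep)].reset_index(drop=True)
    out_meta = ds.meta[ds.meta["species"].isin(keep)].reset_index(drop=True)
    report = pd.DataFrame(dropped, columns=["species", "reason"])
    return replace(ds, records=out_rec, meta=out_meta, dropped_species=report)


def write_summary_table(summaries: pd.DataFrame, path) -> None:
    """Write a species-year summary table; round-trips to 12 significant digits."""
    summaries.to_csv(path, index=False, float_format="%.12g")


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
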