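import numpy as np
import pandas as pd
import pytest

from phenosynch.records_io import CensusCalendar, Dataset
from phenosynch import synthetic_data as sd


@pytest.fixture(scope="session")
def cal2016():
    """Weekly census calendar, 1 March - 31 July 2016."""
    return sd.weekly_calendar(2016)


def make_records(rows):
    """Build a records frame from (species, life_form, year, id, onset, end)."""
    df = pd.DataFrame(rows, columns=["species", "life_form", "year",
                                     "individual_id", "onset", "end"])
    df["genus"] = df["species"].str.split("_").str[0]
    df["family"] = df["genus"] + "aceae"
    df["onset"] = pd.to_datetime(df["onset"])
    df["end"] = pd.to_datetime(df["end"])
    return df[["species", "genus", "family", "life_form", "year",
               "individual_id", "onset", "end"]]


def make_dataset(rows, calendars):
    rec = make_records(rows)
    meta = rec[["species", "genus", "family", "life_form"]].drop_duplicates()
    return Dataset(records=rec.reset_index(drop=True), calendars=calendars,
                   meta=meta.reset_index(drop=True))


@pytest.fixture
def toy_dataset(cal2016):
    """Three species on the 2016 weekly calendar (census dates only)."""
    d = cal2016.dates
    rows = [
        ("Acer_alpha", "tree", 2016, "a1", d[2], d[4]),
        ("Acer_alpha", "tree", 2016, "a2", d[3], d[5]),
        ("Acer_alpha", "tree", 2016, "a3", d[2], d[3]),
        ("Acer_alpha", "tree", 2016, "a4", d[3], d[4]),
        ("Acer_alpha", "tree", 2016, "a5", d[2], d[5]),
        ("Viola_beta", "perennial", 2016, "b1", d[5], d[10]),
        ("Viola_beta", "perennial", 2016, "b2", d[6], d[12]),
        ("Viola_beta", "perennial", 2016, "b3", d[4], d[9]),
        ("Stellaria_gamma", "annual", 2016, "c1", d[1], d[1]),
        ("Stellaria_gamma", "annual", 2016, "c2", d[1], d[2]),
    ]
    return make_dataset(rows, {2016: cal2016})


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-condition synthetic community (both years), filtered."""
    from phenosynch.records_io import filter_species
    ds, _ = sd.simulate_records(seed=1)
    return filter_species(ds, 2, 5, False)
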