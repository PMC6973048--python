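"""I/O, validation and species-inclusion filtering."""

import numpy as np
import pandas as pd
import pytest

from phenosynch import records_io as rio
from phenosynch.records_io import (CensusCalendar, ParseError,
                                   ValidationError, filter_species,
                                   read_dataset, write_summary_table,
                                   read_summary_table)

from conftest import make_dataset, make_records


def _write_triplet(tmp_path, rec, calendars, meta=None):
    rp, cp, mp = (tmp_path / n for n in ("r.csv", "c.csv", "m.csv"))
    out = rec.copy()
    out["onset"] = out["onset"].dt.strftime("%Y-%m-%d")
    out["end"] = out["end"].dt.strftime("%Y-%m-%d")
    out.to_csv(rp, index=False)
    rows = [(y, d.strftime("%Y-%m-%d"))
            for y, cal in calendars.items() for d in cal.dates]
    pd.DataFrame(rows, columns=["year", "date"]).to_csv(cp, index=False)
    if meta is None:
        meta = rec[["species", "genus", "family", "life_form"]].drop_duplicates()
    meta.to_csv(mp, index=False)
    return rp, cp, mp


class TestCensusCalendar:
    def test_requires_two_increasing_same_year_dates(self):
        with pytest.raises(ValidationError):
            CensusCalendar(2016, ("2016-03-01",))
        with pytest.raises(ValidationError):
            CensusCalendar(2016, ("2016-03-08", "2016-03-01"))
        with pytest.raises(ValidationError):
            CensusCalendar(2016, ("2016-03-01", "2017-03-08"))

    def test_membership(self, cal2016):
        assert "2016-03-01" in cal2016
        assert "2016-03-02" not in cal2016


class TestReadDataset:
    def test_round_trip_three_rows(self, tmp_path, cal2016):
        d = cal2016.dates
        rec = make_records([
            ("Acer_a", "tree", 2016, "i1", d[0], d[1]),
            ("Acer_a", "tree", 2016, "i2", d[1], d[3]),
            ("Viola_b", "annual", 2016, "i1", d[2], d[2]),
        ])
        ds = read_dataset(*_write_triplet(tmp_path, rec, {2016: cal2016}))
        assert len(ds.records) == 3
        pd.testing.assert_frame_equal(ds.records[rec.columns], rec)

    def test_malformed_date_names_row(self, tmp_path, cal2016):
        d = cal2016.dates
        rec = make_records([("Acer_a", "tree", 2016, "i1", d[0], d[1])])
        rp, cp, mp = _write_triplet(tmp_path, rec, {2016: cal2016})
        txt = rp.read_text().replace("2016-03-01", "01/03/2016")
        rp.write_text(txt)
        with pytest.raises(ParseError, match="row 2"):
            read_dataset(rp, cp, mp)

    def test_end_before_onset_rejected(self, tmp_path, cal2016):
        d = cal2016.dates
        rec = make_records([("Acer_a", "tree", 2016, "i1", d[1], d[0])])
        with pytest.raises(ValidationError, match="precedes"):
            read_dataset(*_write_triplet(tmp_path, rec, {2016: cal2016}))

    def test_species_missing_from_meta_named(self, tmp_path, cal2016):
        d = cal2016.dates
        rec = make_records([("Acer_a", "tree", 2016, "i1", d[0], d[1])])
        meta = pd.DataFrame([("Other_sp", "Other", "Otheraceae", "tree")],
                            columns=["species", "genus", "family", "life_form"])
        with pytest.raises(ValidationError, match="Acer_a"):
            read_dataset(*_write_triplet(tmp_path, rec, {2016: cal2016}, meta))

    def test_unknown_life_form_rejected(self, tmp_path, cal2016):
        d = cal2016.dates
        rec = make_records([("Acer_a", "tree", 2016, "i1", d[0], d[1])])
        rp, cp, mp = _write_triplet(tmp_path, rec, {2016: cal2016})
        rp.write_text(rp.read_text().replace("tree", "shrub"))
        mp.write_text(mp.read_text().replace("tree", "shrub"))
        with pytest.raises(ValidationError, match="life_form"):
            read_dataset(rp, cp, mp)

    def test_non_census_date_rejected(self, tmp_path, cal2016):
        d = cal2016.dates
        rec = make_records([("Acer_a", "tree", 2016, "i1", d[0], d[1])])
        rp, cp, mp = _write_triplet(tmp_path, rec, {2016: cal2016})
        rp.write_text(rp.read_text().replace("2016-03-08", "2016-03-09"))
        with pytest.raises(ValidationError, match="census"):
            read_dataset(rp, cp, mp)


class TestFilterSpecies:
    def test_min_individuals_threshold(self, toy_dataset):
        out = filter_species(toy_dataset, min_flowering_days=0,
                             min_individuals=5)
        assert out.species == ["Acer_alpha"]
        assert set(out.dropped_species["species"]) == {
            "Viola_beta", "Stellaria_gamma"}

    def test_both_years_requirement(self, cal2016):
        cal17 = CensusCalendar(2017, tuple(
            d + pd.DateOffset(years=1) for d in cal2016.dates))
        d16, d17 = cal2016.dates, cal17.dates
        rows = [("Acer_a", "tree", 2016, f"i{k}", d16[k], d16[k + 1])
                for k in range(6)]
        rows += [("Acer_a", "tree", 2017, f"j{k}", d17[k], d17[k + 1])
                 for k in range(3)]
        ds = make_dataset(rows, {2016: cal2016, 2017: cal17})
        pooled = filter_species(ds, 0, 5, require_both_years=False)
        assert pooled.species == ["Acer_a"]
        strict = filter_species(ds, 0, 5, require_both_years=True)
        assert strict.species == []

    def test_identity_when_thresholds_trivial(self, toy_dataset):
        out = filter_species(toy_dataset, min_flowering_days=0,
                             min_individuals=1)
        assert out.species == toy_dataset.species
        assert len(out.records) == len(toy_dataset.records)

    def test_flowering_days_filter_is_strict(self, toy_dataset):
        # Stellaria_gamma flowers on exactly 2 census dates -> dropped at 2
        out = filter_species(toy_dataset, min_flowering_days=2,
                             min_individuals=1)
        assert "Stellaria_gamma" not in out.species
        out2 = filter_species(toy_dataset, min_flowering_days=1,
                              min_individuals=1)
        assert "Stellaria_gamma" in out2.species

    def test_idempotent_and_monotone(self, toy_dataset):
        once = filter_species(toy_dataset, 2, 3)
        twice = filter_species(once, 2, 3)
        assert once.species == twice.species
        for k in range(1, 8):
            hi = filter_species(toy_dataset, 2, k)
            lo = filter_species(toy_dataset, 2, max(k - 1, 1))
            assert set(hi.species) <= set(lo.species)


class TestSummaryTable:
    def test_round_trip_and_order(self, tmp_path):
        df = pd.DataFrame({
            "species": ["a", "b"], "year": [2016, 2016],
            "TFL": [15.0, 1 / 3], "MFL": [7.123456789012, 2.0]})
        path = tmp_path / "s.csv"
        write_summary_table(df, path)
        back = read_summary_table(path)
        assert list(back["species"]) == ["a", "b"]
        np.testing.assert_allclose(back["TFL"], df["TFL"], rtol=1e-12)
        np.testing.assert_allclose(back["MFL"], df["MFL"], rtol=1e-12)

    def test_empty_summaries_header_only(self, tmp_path):
        path = tmp_path / "s.csv"
        write_summary_table(pd.DataFrame(columns=["species", "TFL"]), path)
        assert path.read_text().strip() == "species,TFL"
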