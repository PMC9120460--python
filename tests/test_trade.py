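import io

import pandas as pd
import pytest

from arachnotrade.trade import (
    WHOLE_INDIVIDUAL_CODES,
    classify_purpose,
    classify_source,
    filter_whole_individuals,
    nonnative_wild_exports,
    read_cites,
    read_lemis,
    summarise_lemis,
)


def frame(rows):
    defaults = dict(genus="Pandinus", species="imperator", quantity=1.0,
                    description_code="LIV", disposition="C", purpose="T",
                    source_code="W", country_origin="GH", shipment_year=2015)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestWholeIndividuals:
    def test_admitted_codes_exactly(self):
        assert WHOLE_INDIVIDUAL_CODES == {"BOD", "EGL", "DEA", "LIV", "SPE", "SKI", "TRO"}

    @pytest.mark.parametrize("code, kept", [
        ("LIV", True), ("BOD", True), ("EGL", True), ("DEA", True),
        ("SPE", True), ("SKI", True), ("TRO", True),
        ("SHE", False), ("CAV", False), ("", False),
    ])
    def test_filter(self, code, kept):
        out = filter_whole_individuals(frame([{"description_code": code}]))
        assert len(out) == (1 if kept else 0)

    def test_synthetic_kept_count_matches_truth(self):
        from arachnotrade.synth import gen_lemis, gen_registry
        records, _ = gen_registry(n_species=20, n_genera=5, seed=8)
        rows, truth = gen_lemis(records, n_records=500, seed=8)
        df = read_lemis(io.StringIO(pd.DataFrame(rows).to_csv(index=False)))
        assert len(filter_whole_individuals(df)) == truth.planted_kept_records


@pytest.mark.parametrize("code, cls", [
    ("W", "wild"), ("C", "captive"), ("F", "captive"), ("D", "captive"),
    ("R", "captive"), ("", "other"), ("U", "other"), ("I", "other"),
    ("w", "wild"),
])
def test_classify_source(code, cls):
    assert classify_source(code) == cls


@pytest.mark.parametrize("code, cls", [
    ("M", "non_commercial"), ("S", "non_commercial"), ("Y", "non_commercial"),
    ("T", "commercial_or_other"), ("P", "commercial_or_other"),
    ("", "commercial_or_other"),
])
def test_classify_purpose(code, cls):
    assert classify_purpose(code) == cls


class TestSummarise:
    def test_wild_percentage_quantity_weighted(self):
        df = frame([{"source_code": "W", "quantity": 70.0},
                    {"source_code": "C", "quantity": 30.0}])
        s = summarise_lemis(df)
        assert s["pct_wild"] == 70.0
        assert s["pct_captive"] == 30.0

    def test_seized_share(self):
        rows = [{"disposition": "C"}] * 9 + [{"disposition": "S"}]
        s = summarise_lemis(frame(rows))
        assert s["pct_seized"] == 10.0

    def test_partition_sums_to_total(self):
        from arachnotrade.synth import gen_lemis, gen_registry
        records, _ = gen_registry(n_species=15, n_genera=4, seed=5)
        rows, _ = gen_lemis(records, n_records=800, seed=5)
        df = filter_whole_individuals(
            read_lemis(io.StringIO(pd.DataFrame(rows).to_csv(index=False))))
        s = summarise_lemis(df)
        assert s["pct_wild"] + s["pct_captive"] + s["pct_other"] == pytest.approx(100.0)

    def test_order_and_split_invariance(self):
        df = frame([{"source_code": "W", "quantity": 50.0},
                    {"source_code": "C", "quantity": 30.0}])
        split = frame([{"source_code": "C", "quantity": 30.0},
                       {"source_code": "W", "quantity": 20.0},
                       {"source_code": "W", "quantity": 30.0}])
        a, b = summarise_lemis(df), summarise_lemis(split)
        for key in ("total_individuals", "pct_wild", "pct_captive", "pct_seized"):
            assert a[key] == pytest.approx(b[key])

    def test_placeholder_genera_excluded_and_fractions_bounded(self):
        df = frame([{"genus": "Non-CITES entry"}, {"genus": "Pandinus"},
                    {"genus": ""}])
        per_genus = summarise_lemis(df)["per_genus"]
        assert list(per_genus["genus_norm"]) == ["pandinus"]
        assert ((per_genus["wild_fraction"] >= 0) & (per_genus["wild_fraction"] <= 1)).all()

    def test_per_genus_wild_fraction_planted(self):
        from arachnotrade.synth import gen_lemis, gen_registry
        records, _ = gen_registry(n_species=12, n_genera=3, seed=7)
        genus = records[0].genus
        rows, truth = gen_lemis(
            records, n_records=400,
            per_genus_wild_fractions={g: 0.0 for g in {r.genus for r in records}} |
                                     {genus: 1.0},
            species_coverage=1.0, seed=7)
        df = filter_whole_individuals(
            read_lemis(io.StringIO(pd.DataFrame(rows).to_csv(index=False))))
        per_genus = summarise_lemis(df)["per_genus"].set_index("genus_norm")
        assert per_genus.loc[genus.lower(), "wild_fraction"] == 1.0
        others = per_genus.drop(index=genus.lower())
        # other genera only reach wild via cross-genus synonym listings
        accepted_genera = {r.genus.lower() for r in records}
        assert (others.loc[others.index.isin(accepted_genera) == False, "wild_fraction"] >= 0).all()


class TestNonnative:
    def test_nonnative_and_native_examples(self, micro_index):
        df = frame([
            {"genus": "Cyriopagopus", "species": "lividus", "quantity": 100.0,
             "country_origin": "Vietnam"},
            {"genus": "Grammostola", "species": "rosea", "quantity": 50.0,
             "country_origin": "Chile"},
        ])
        ranges = {"Cyriopagopus lividus": {"Thailand"},
                  "Grammostola rosea": {"Chile"}}
        per_country, per_species = nonnative_wild_exports(df, ranges, micro_index)
        pc = per_country.set_index("country")
        assert pc.loc["Vietnam", "nonnative_individuals"] == 100.0
        assert pc.loc["Chile", "nonnative_individuals"] == 0.0
        assert per_species.set_index("accepted_name").loc[
            "Cyriopagopus lividus", "nonnative_wild_individuals"] == 100.0

    def test_unknown_range_never_counts_as_nonnative(self, micro_index):
        df = frame([{"genus": "Pandinus", "species": "imperator",
                     "quantity": 10.0, "country_origin": "XX"}])
        per_country, per_species = nonnative_wild_exports(df, {}, micro_index)
        row = per_country.iloc[0]
        assert row["unknown_range_individuals"] == 10.0
        assert row["nonnative_individuals"] == 0.0
        assert per_species.empty

    def test_synonym_reaches_accepted_species_range(self, micro_index):
        """A shipment under a junior synonym uses the accepted species' range."""
        df = frame([{"genus": "Haplopelma", "species": "lividum",
                     "quantity": 5.0, "country_origin": "Vietnam"}])
        per_country, _ = nonnative_wild_exports(
            df, {"Cyriopagopus lividus": {"Thailand"}}, micro_index)
        assert per_country.iloc[0]["nonnative_individuals"] == 5.0


class TestReadCites:
    def _csv(self, tmp_path, text):
        p = tmp_path / "cites.csv"
        p.write_text(text, encoding="utf-8")
        return p

    def test_wide_layout_years_filtered_and_resolved(self, micro_index, tmp_path):
        path = self._csv(tmp_path, (
            "Taxon,App.,Term,Unit,1970,2015,2020\n"
            "Haplopelma lividum,II,live,,5,10,3\n"
            "Grammostola pulchra,II,live,,,7,\n"
            "Unknownus taxon,II,live,,,2,\n"))
        species, yearly = read_cites(path, micro_index)
        by_name = species.set_index("name")
        assert by_name.loc["Cyriopagopus lividus", "match_kind"] == "synonym"
        assert bool(by_name.loc["Unknownus taxon", "unresolved"])
        assert set(yearly["year"]) == {2015, 2020}  # 1970 outside 1975-2021

    def test_long_layout(self, micro_index, tmp_path):
        path = self._csv(tmp_path, (
            "taxon,year,quantity\nGrammostola pulchra,2016,4\n"
            "Grammostola pulchra,2016,6\n"))
        species, yearly = read_cites(path, micro_index)
        assert len(species) == 1
        assert yearly.iloc[0]["quantity"] == 10.0


def test_read_lemis_filters_class_and_handles_quantities(tmp_path):
    path = tmp_path / "lemis.csv"
    path.write_text(
        "class,genus,species,quantity,description,disposition,purpose,source,"
        "country_origin,shipment_year\n"
        "Arachnida,Pandinus,imperator,10,LIV,C,T,W,GH,2015\n"
        "Reptilia,Python,regius,99,LIV,C,T,W,GH,2015\n"
        "Arachnida,Pandinus,imperator,,LIV,C,T,W,GH,2015\n"
        "Arachnida,Pandinus,imperator,-5,LIV,C,T,W,GH,2015\n",
        encoding="utf-8")
    df = read_lemis(path)
    assert len(df) == 2  # reptile filtered, negative rejected
    assert df["quantity"].tolist() == [10.0, 0.0]  # missing -> 0
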