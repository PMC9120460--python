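import pytest

from arachnotrade.biogeo import (
    CountryTable,
    RangeAssertion,
    build_country_ranges,
    country_trade_summary,
    endemism_summary,
    expand_region,
    expand_span,
    standardise_country,
)


@pytest.fixture(scope="module")
def world():
    """Four countries forming a triangle with one centroid inside it,
    plus two far-away ones (one across the antimeridian)."""
    rows = [
        {"country_id": "TH", "canonical_name": "Thailand", "aliases": "Siam",
         "lon": "0", "lat": "0"},
        {"country_id": "VN", "canonical_name": "Vietnam", "aliases": "",
         "lon": "10", "lat": "0"},
        {"country_id": "MY", "canonical_name": "Malaysia", "aliases": "",
         "lon": "5", "lat": "10"},
        {"country_id": "KH", "canonical_name": "Cambodia", "aliases": "",
         "lon": "5", "lat": "3"},  # inside the TH-VN-MY triangle
        {"country_id": "CL", "canonical_name": "Chile", "aliases": "",
         "lon": "-70", "lat": "-30"},
        {"country_id": "FJ", "canonical_name": "Fiji", "aliases": "",
         "lon": "178", "lat": "-17"},
    ]
    return CountryTable(rows)


class TestStandardise:
    def test_alias_match(self, world):
        assert standardise_country("Siam", world) == "TH"
        assert standardise_country("thailand", world) == "TH"

    def test_unmatched_goes_to_worklist(self, world):
        worklist = []
        assert standardise_country("Atlantis", world, worklist) is None
        assert worklist == ["Atlantis"]

    def test_empty_worklist_iff_all_mapped(self, world):
        worklist = []
        for name in ("Thailand", "Siam", "Vietnam", "chile"):
            standardise_country(name, world, worklist)
        assert worklist == []


class TestExpandRegion:
    region_map = {"indochina": {"TH", "VN", "KH"}, "lonely": {"CL"}}

    def test_known_region(self):
        assert expand_region("Indochina", self.region_map) == {"TH", "VN", "KH"}

    def test_unknown_region_worklist(self):
        worklist = []
        assert expand_region("Narnia", self.region_map, worklist) == set()
        assert worklist == ["Narnia"]

    def test_singleton_region(self):
        assert expand_region("lonely", self.region_map) == {"CL"}


class TestExpandSpan:
    def test_single_country_degenerate(self, world):
        out, flags = expand_span({"TH"}, world)
        assert out == {"TH"} and flags == []

    def test_hull_includes_interior_centroid(self, world):
        """TH-VN-MY triangle contains Cambodia's centroid (point-in-triangle
        verified by hand: (5,3) inside (0,0),(10,0),(5,10))."""
        out, _ = expand_span({"TH", "VN", "MY"}, world)
        assert out == {"TH", "VN", "MY", "KH"}

    def test_collinear_centroids_listed_only(self, world):
        # TH (0,0), VN (10,0) and a synthetic midpoint country on lat 0
        rows = [
            {"country_id": c, "canonical_name": c, "aliases": "",
             "lon": str(lon), "lat": "0"}
            for c, lon in (("A", 0), ("B", 5), ("C", 10))
        ]
        table = CountryTable(rows)
        out, _ = expand_span({"A", "B", "C"}, table)
        assert out == {"A", "B", "C"}

    def test_hull_never_removes_members(self, world):
        out, _ = expand_span({"TH", "VN", "CL"}, world)
        assert out >= {"TH", "VN", "CL"}

    def test_antimeridian_span_flagged_unexpanded(self, world):
        out, flags = expand_span({"TH", "CL", "FJ"}, world)
        assert "antimeridian_span" in flags
        assert out == {"TH", "CL", "FJ"}


class TestBuildRanges:
    def test_union_and_dedup(self, world):
        assertions = [
            RangeAssertion("Sp a", "country", "Thailand"),
            RangeAssertion("Sp a", "region", "indochina"),
        ]
        ranges, report = build_country_ranges(
            assertions, world, {"indochina": {"TH", "VN", "KH"}})
        assert ranges["Sp a"].countries == {"TH", "VN", "KH"}
        assert report["n_connections"] == 3

    def test_island_replaced_by_sovereign(self, world):
        assertions = [RangeAssertion("Sp b", "island", "Koh Samui")]
        ranges, _ = build_country_ranges(
            assertions, world, {}, island_map={"koh samui": "TH"})
        assert ranges["Sp b"].countries == {"TH"}
        assert ranges["Sp b"].provenance["TH"] == "island"

    def test_span_assertion_parses_to_listed_areas(self, world):
        assertions = [RangeAssertion("Sp c", "span", "Thailand to Vietnam")]
        ranges, _ = build_country_ranges(assertions, world, {})
        assert ranges["Sp c"].countries == {"TH", "VN"}

    def test_unmappable_species_flagged(self, world):
        assertions = [RangeAssertion("Sp d", "country", "Atlantis")]
        ranges, report = build_country_ranges(assertions, world, {})
        assert ranges["Sp d"].unmappable
        assert report["unmappable"] == ["Sp d"]
        assert report["worklist"] == ["Atlantis"]

    def test_planted_ranges_recovered(self, tmp_path):
        from arachnotrade.biogeo import load_assertions_csv, load_region_map
        from arachnotrade.synth import gen_ranges, gen_registry
        import csv
        records, _ = gen_registry(n_species=40, n_genera=8, seed=14)
        _, _, _, _, truth = gen_ranges(records, seed=14, out_dir=tmp_path)
        table = CountryTable.from_csv(tmp_path / "countries.csv")
        region_map = load_region_map(tmp_path / "regions.csv")
        with open(tmp_path / "islands.csv", newline="") as fh:
            island_map = {r["island"]: r["country_id"] for r in csv.DictReader(fh)}
        assertions = load_assertions_csv(tmp_path / "ranges.csv")
        ranges, report = build_country_ranges(assertions, table, region_map,
                                              island_map)
        assert {k: v.countries for k, v in ranges.items()} == truth.planted_ranges
        assert report["n_connections"] == truth.planted_connections
        assert report["worklist"] == []

    def test_full_endemism_when_rate_is_one(self):
        from arachnotrade.synth import gen_ranges, gen_registry
        records, _ = gen_registry(n_species=10, n_genera=3, seed=4)
        *_, truth = gen_ranges(records, endemism_rate=1.0, seed=4)
        assert all(len(v) == 1 for v in truth.planted_ranges.values())


class TestCountrySummary:
    def _ranges(self):
        from arachnotrade.biogeo import CountryRange
        return {
            f"Aa sp{i}": CountryRange(f"Aa sp{i}", countries={"X"})
            for i in range(10)
        }

    def test_percentage_traded(self):
        ranges = self._ranges()
        traded = {f"Aa sp{i}" for i in range(3)}
        df = country_trade_summary(ranges, traded).set_index("country_id")
        assert df.loc["X", "n_species"] == 10
        assert df.loc["X", "pct_traded"] == 30.0

    def test_endemic_counts(self):
        from arachnotrade.biogeo import CountryRange
        ranges = {"Aa bb": CountryRange("Aa bb", countries={"X"}),
                  "Cc dd": CountryRange("Cc dd", countries={"X", "Y"})}
        df = country_trade_summary(ranges, {"Aa bb"}).set_index("country_id")
        assert df.loc["X", "n_endemic"] == 1
        assert df.loc["X", "n_endemic_traded"] == 1
        assert endemism_summary(ranges)["pct_endemic"] == 50.0

    def test_small_genus_filter_variant(self):
        from arachnotrade.biogeo import CountryRange
        ranges = {
            "Big sp1": CountryRange("Big sp1", countries={"X"}),
            "Big sp2": CountryRange("Big sp2", countries={"X"}),
            "Big sp3": CountryRange("Big sp3", countries={"X"}),
            "Tiny sp1": CountryRange("Tiny sp1", countries={"X"}),
        }
        traded = {"Big sp1", "Big sp2", "Big sp3", "Tiny sp1"}
        plain = country_trade_summary(ranges, traded).set_index("country_id")
        filtered = country_trade_summary(
            ranges, traded, min_traded_per_genus=2).set_index("country_id")
        assert plain.loc["X", "n_traded"] == 4
        assert filtered.loc["X", "n_traded"] == 3  # genus Tiny (<=2 traded) dropped

    def test_connection_count_equals_sum_of_range_sizes(self):
        from arachnotrade.biogeo import CountryRange
        ranges = {"Aa bb": CountryRange("Aa bb", countries={"X", "Y"}),
                  "Cc dd": CountryRange("Cc dd", countries={"Z"})}
        df = country_trade_summary(ranges, set())
        assert int(df["n_species"].sum()) == sum(len(r.countries)
                                                 for r in ranges.values())
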