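"""Digitise textual range statements into country sets and endemism.

"Thailand to Vietnam" spans expand through a convex hull over country
centroids; regions expand through an editable table; single-country ranges
flag likely endemics, the species most exposed to collection.
"""

from arachnotrade import (
    CountryTable, RangeAssertion, build_country_ranges, country_trade_summary,
    endemism_summary,
)

table = CountryTable([
    {"country_id": "TH", "canonical_name": "Thailand", "aliases": "Siam",
     "lon": "0", "lat": "0"},
    {"country_id": "VN", "canonical_name": "Vietnam", "aliases": "", "lon": "10", "lat": "0"},
    {"country_id": "MY", "canonical_name": "Malaysia", "aliases": "", "lon": "5", "lat": "10"},
    {"country_id": "KH", "canonical_name": "Cambodia", "aliases": "", "lon": "5", "lat": "3"},
])
region_map = {"indochina": {"TH", "VN", "KH"}}

assertions = [
    RangeAssertion("Cyriopagopus lividus", "country", "Siam"),
    RangeAssertion("Chilobrachys dyscolus", "span", "Thailand to Malaysia to Vietnam"),
    RangeAssertion("Heterometrus laoticus", "region", "indochina"),
]
ranges, report = build_country_ranges(assertions, table, region_map)
for name, rng in sorted(ranges.items()):
    print(f"  {name:24s} -> {sorted(rng.countries)}"
          + ("  (endemic)" if rng.endemic else ""))
print(f"{report['n_connections']} species-country connections")

# The span's hull contains Cambodia's centroid, so KH joins the range even
# though it was never listed -- mirroring how broad textual ranges are read.
print(endemism_summary(ranges))
summary = country_trade_summary(ranges, traded_species={"Cyriopagopus lividus"})
print(summary.to_string(index=False))
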