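"""Country-level range digitisation and trade-exposure summaries.

Checklist range statements come in four kinds — a single country, a named
region ("South America"), a span ("Thailand to Vietnam") and an island —
and are digitised to sets of standardised country identifiers.  Spans are
expanded by building the convex hull of the listed areas' country centroids
and including every country whose centroid falls inside it; regions expand
through an editable region -> country table; dependent islands are replaced
by their sovereign country.  Endemism (single-country range) and per-country
trade exposure are computed from the resulting species x country sets.

The centroid-in-hull test runs on the raw lon/lat plane; at continental
scale that approximates intersecting the hull with country polygons while
keeping the pipeline free of border geometry.  Antimeridian-spanning spans
are flagged, not mapped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import MultiPoint, Point

logger = logging.getLogger(__name__)

ASSERTION_KINDS = ("country", "region", "span", "island")


@dataclass
class RangeAssertion:
    """One textual range statement for a species.

    ``kind`` comes from the source sheet the statement was filed under,
    never inferred from the text.  For spans, ``raw_text`` lists the areas
    separated by ``" to "`` or ``;``.
    """

    accepted_name: str
    kind: str
    raw_text: str

    def __post_init__(self) -> None:
        if self.kind not in ASSERTION_KINDS:
            raise ValueError(f"unknown assertion kind {self.kind!r}")


@dataclass
class CountryRange:
    """Digitised range: species -> standardised country ids with provenance."""

    accepted_name: str
    countries: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)
    unmappable: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def endemic(self) -> bool:
        return len(self.countries) == 1


class CountryTable:
    """Reference countries: id, canonical name, aliases, centroid (lon, lat)."""

    def __init__(self, rows):
        self.by_id: dict[str, dict] = {}
        self._alias: dict[str, str] = {}
        for row in rows:
            cid = row["country_id"]
            if cid in self.by_id:
                raise ValueError(f"duplicate country_id {cid!r}")
            lon, lat = float(row["lon"]), float(row["lat"])
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValueError(f"centroid out of bounds for {cid!r}")
            self.by_id[cid] = {
                "canonical_name": row["canonical_name"],
                "centroid": (lon, lat),
            }
            self._alias[cid.lower()] = cid
            self._alias[row["canonical_name"].strip().lower()] = cid
            for alias in filter(None, (a.strip() for a in row.get("aliases", "").split("|"))):
                self._alias[alias.lower()] = cid

    @classmethod
    def from_csv(cls, path) -> "CountryTable":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls(list(csv.DictReader(fh)))

    def centroid(self, country_id: str) -> tuple[float, float]:
        return self.by_id[country_id]["centroid"]

    def lookup(self, raw_name: str) -> str | None:
        return self._alias.get(raw_name.strip().lower())

    def __iter__(self):
        return iter(self.by_id)

    def __len__(self) -> int:
        return len(self.by_id)


def standardise_country(raw_name: str, table: CountryTable,
                        worklist: list[str] | None = None) -> str | None:
    """Exact/alias match of a raw country name to its standard id.

    Unmatched names are appended to ``worklist`` (the manual-correction
    queue) and ``None`` returned — never silently dropped.
    """
    cid = table.lookup(raw_name)
    if cid is None and worklist is not None:
        worklist.append(raw_name)
    return cid


def load_region_map(path) -> dict[str, set[str]]:
    """Region -> country-id set from a CSV with columns region, country_id."""
    out: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["region"].strip().lower(), set()).add(row["country_id"].strip())
    return out


def expand_region(region_name: str, region_map: dict[str, set[str]],
                  worklist: list[str] | None = None) -> set[str]:
    """Return the configured country set for a region; unknown -> worklist."""
    countries = region_map.get(region_name.strip().lower())
    if countries is None:
        if worklist is not None:
            worklist.append(region_name)
        return set()
    return set(countries)


def expand_span(listed_countries: set[str], table: CountryTable) -> tuple[set[str], list[str]]:
    """Expand a "country A to country B" span via a centroid convex hull.

    The hull of the listed countries' centroids is built on the lon/lat
    plane; every reference country whose centroid lies inside or on the
    hull is included, unioned with the listed countries themselves (the
    hull never removes members).  With fewer than three distinct centroids,
    or collinear ones, the hull degenerates and the listed set is returned.
    Spans whose centroids straddle more than 180 degrees of longitude are
    flagged and left unexpanded.
    """
    listed = {c for c in listed_countries if c in table.by_id}
    flags: list[str] = []
    pts = {table.centroid(c) for c in listed}
    if len(pts) < 3:
        return set(listed), flags
    lons = [p[0] for p in pts]
    if max(lons) - min(lons) > 180.0:
        flags.append("antimeridian_span")
        return set(listed), flags
    hull = MultiPoint([Point(*p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":  # collinear centroids
        return set(listed), flags
    out = set(listed)
    for cid in table:
        if hull.covers(Point(*table.centroid(cid))):
            out.add(cid)
    return out, flags


def _split_span_areas(raw_text: str) -> list[str]:
    parts: list[str] = []
    for chunk in raw_text.split(";"):
        parts.extend(p.strip() for p in chunk.split(" to "))
    return [p for p in parts if p]


def build_country_ranges(
    assertions,
    table: CountryTable,
    region_map: dict[str, set[str]],
    island_map: dict[str, str] | None = None,
) -> tuple[dict[str, CountryRange], dict]:
    """Digitise all range assertions into per-species country sets.

    Per species the country, region-expanded, span-expanded and
    island-resolved sets are unioned and de-duplicated.  "Introduced"
    localities are expected to be excluded upstream.  Returns
    ``(ranges, report)`` where report carries the correction worklist,
    the unmappable species list and the total species-country connection
    count.
    """
    island_map = {k.strip().lower(): v for k, v in (island_map or {}).items()}
    worklist: list[str] = []
    ranges: dict[str, CountryRange] = {}
    for a in assertions:
        rng = ranges.setdefault(a.accepted_name, CountryRange(a.accepted_name))
        if a.kind == "country":
            cid = standardise_country(a.raw_text, table, worklist)
            if cid:
                rng.countries.add(cid)
                rng.provenance.setdefault(cid, "country")
        elif a.kind == "region":
            for cid in expand_region(a.raw_text, region_map, worklist):
                rng.countries.add(cid)
                rng.provenance.setdefault(cid, "region")
        elif a.kind == "span":
            listed: set[str] = set()
            for area in _split_span_areas(a.raw_text):
                cid = table.lookup(area)
                if cid:
                    listed.add(cid)
                else:
                    region = expand_region(area, region_map)
                    if region:
                        listed |= region
                    else:
                        worklist.append(area)
            expanded, flags = expand_span(listed, table)
            rng.flags.extend(flags)
            for cid in expanded:
                rng.countries.add(cid)
                rng.provenance.setdefault(cid, "span")
        elif a.kind == "island":
            key = a.raw_text.strip().lower()
            cid = island_map.get(key) or table.lookup(a.raw_text)
            if cid:
                rng.countries.add(cid)
                rng.provenance.setdefault(cid, "island")
            else:
                worklist.append(a.raw_text)
    unmappable = []
    for rng in ranges.values():
        if not rng.countries:
            rng.unmappable = True
            unmappable.append(rng.accepted_name)
    n_connections = sum(len(r.countries) for r in ranges.values())
    logger.info("digitised %d species-country connections for %d species",
                n_connections, len(ranges))
    report = {
        "worklist": worklist,
        "unmappable": unmappable,
        "n_connections": n_connections,
    }
    return ranges, report


def country_trade_summary(
    ranges: dict[str, CountryRange],
    traded_species: set[str],
    genus_of: dict[str, str] | None = None,
    min_traded_per_genus: int = 0,
) -> pd.DataFrame:
    """Per-country richness, trade exposure and endemism.

    A species contributes to every country in its range.  Endemic means a
    single-country range.  ``min_traded_per_genus`` > 0 drops genera with
    that many or fewer traded species before computing the traded
    percentage (the popular-group variant).
    """
    genus_of = genus_of or {
        name: name.split()[0] for name in ranges
    }
    traded_eff = set(traded_species)
    if min_traded_per_genus > 0:
        per_genus: dict[str, int] = {}
        for sp in traded_species:
            g = genus_of.get(sp, sp.split()[0])
            per_genus[g] = per_genus.get(g, 0) + 1
        traded_eff = {
            sp for sp in traded_species
            if per_genus[genus_of.get(sp, sp.split()[0])] > min_traded_per_genus
        }
    rows: dict[str, dict] = {}
    for name, rng in ranges.items():
        if rng.unmappable:
            continue
        genus = genus_of.get(name, name.split()[0])
        for cid in rng.countries:
            row = rows.setdefault(cid, {
                "country_id": cid, "species": set(), "traded": set(),
                "genera": set(), "genera_traded": set(),
                "endemic": set(), "endemic_traded": set(),
            })
            row["species"].add(name)
            row["genera"].add(genus)
            if name in traded_eff:
                row["traded"].add(name)
                row["genera_traded"].add(genus)
            if rng.endemic:
                row["endemic"].add(name)
                if name in traded_eff:
                    row["endemic_traded"].add(name)
    records = []
    for cid in sorted(rows):
        r = rows[cid]
        n_species = len(r["species"])
        n_traded = len(r["traded"])
        records.append({
            "country_id": cid,
            "n_species": n_species,
            "n_traded": n_traded,
            "pct_traded": 100.0 * n_traded / n_species if n_species else 0.0,
            "n_genera": len(r["genera"]),
            "n_genera_traded": len(r["genera_traded"]),
            "n_endemic": len(r["endemic"]),
            "n_endemic_traded": len(r["endemic_traded"]),
        })
    return pd.DataFrame(records)


def endemism_summary(ranges: dict[str, CountryRange]) -> dict:
    """Fraction of mappable species whose range is a single country."""
    mappable = [r for r in ranges.values() if not r.unmappable]
    n_endemic = sum(r.endemic for r in mappable)
    return {
        "n_species": len(mappable),
        "n_endemic": n_endemic,
        "pct_endemic": 100.0 * n_endemic / len(mappable) if mappable else 0.0,
    }


def load_assertions_csv(path) -> list[RangeAssertion]:
    """Assertion CSV with columns accepted_name, kind, raw_text."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(RangeAssertion(row["accepted_name"], row["kind"].strip(), row["raw_text"]))
    return out


def write_ranges_csv(ranges: dict[str, CountryRange], path) -> None:
    """Species x country long CSV with provenance tags."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accepted_name", "country_id", "provenance"])
        for name in sorted(ranges):
            rng = ranges[name]
            for cid in sorted(rng.countries):
                writer.writerow([name, cid, rng.provenance.get(cid, "")])
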