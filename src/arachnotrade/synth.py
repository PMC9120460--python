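"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage is exercised offline by generating checklists, shop
pages, trade records and range assertions whose expected downstream outputs
are fully determined by a recorded :class:`GroundTruth`.  Token vocabularies
(genus syllables, epithet syllables, decoy words, localities, country names)
are pairwise disjoint by construction so that planted entities can never
collide with the shipped blocklist, the colour lexicon or each other, and
recovery checks can demand exact equality.

All generators are pure functions of their parameters and ``seed`` (numpy
``default_rng``; no reliance on hash ordering), so rerunning one writes
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .taxonomy import TaxonRecord

# Disjoint syllable alphabets: genera, epithets, synonym epithets share no
# syllables with each other or with localities/countries, so no generated
# token is a prefix of an unrelated one (all names are 3 syllables = 9
# chars, and distinctness forbids proper prefixes at equal length).
GENUS_SYLLABLES = ["zyx", "vok", "quw", "jyr", "xel", "wuz", "kyv", "zam", "pyx", "vyn"]
EPITHET_SYLLABLES = ["mur", "tal", "pid", "ros", "ven", "dor", "lim", "bex", "nus", "gat"]
LOCALITY_SYLLABLES = ["kra", "ben", "tor", "mal", "sid", "pon"]
COUNTRY_SYLLABLES = ["hol", "fer", "nac", "tus", "rie", "gom", "lat", "bur"]

DECOY_WORDS = [
    "available", "breeding", "stock", "juvenile", "adult", "captive", "bred",
    "size", "price", "offer", "listing", "shipment", "terrarium", "substrate",
    "molt", "female", "male", "unsexed", "slings", "feeding",
]

#: Colour terms planted next to genus mentions; all present in the packaged
#: lexicon and absent from the ambiguous-exclusion list.
PLANT_COLOURS = ["blue", "red", "electric", "green", "violet", "copper", "golden", "black"]

ARCHIVE_YEARS = list(range(2014, 2020))


def _names_from_syllables(rng, syllables, n, n_syll=3):
    """n distinct pseudo-words built from a syllable alphabet.

    All words from one call share a length, so none is a prefix of another
    (left-boundary prefix matching stays exact).  The length grows when the
    requested count approaches the combinatorial capacity.
    """
    while len(syllables) ** n_syll < 4 * n:
        n_syll += 1
    out = []
    seen = set()
    while len(out) < n:
        word = "".join(syllables[i] for i in rng.integers(0, len(syllables), n_syll))
        if word not in seen:
            seen.add(word)
            out.append(word)
    return out


@dataclass
class GroundTruth:
    """Everything needed to predict the output of every downstream stage."""

    seed: int
    # registry
    name_to_accepted: dict = field(default_factory=dict)
    species_groups: dict = field(default_factory=dict)
    description_years: dict = field(default_factory=dict)
    mean_names_per_species: float = 0.0
    # corpus
    planted_species_per_page: dict = field(default_factory=dict)
    planted_matches: list = field(default_factory=list)
    planted_colour_counts: dict = field(default_factory=dict)
    planted_locality_listings: list = field(default_factory=list)
    online_species_years: dict = field(default_factory=dict)
    snapshot_sites: list = field(default_factory=list)
    # lemis
    planted_source_totals: dict = field(default_factory=dict)
    planted_seized_total: float = 0.0
    planted_commercial_total: float = 0.0
    planted_whole_total: float = 0.0
    planted_kept_records: int = 0
    per_genus_wild: dict = field(default_factory=dict)
    lemis_species: list = field(default_factory=list)
    lemis_species_years: dict = field(default_factory=dict)
    planted_nonnative: dict = field(default_factory=dict)
    # cites
    cites_species: list = field(default_factory=list)
    # ranges
    planted_ranges: dict = field(default_factory=dict)
    planted_connections: int = 0

    def to_json(self, path) -> None:
        def _enc(obj):
            if isinstance(obj, set):
                return sorted(obj)
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(type(obj))
        payload = {k: v for k, v in self.__dict__.items()}
        # tuple-keyed maps -> "a||b" string keys for JSON
        for key in ("planted_species_per_page", "planted_colour_counts"):
            payload[key] = {"||".join(map(str, k)): _enc(v) if isinstance(v, set) else v
                            for k, v in payload[key].items()}
        payload["online_species_years"] = {
            k: sorted(v) for k, v in payload["online_species_years"].items()}
        payload["lemis_species_years"] = {
            k: sorted(v) for k, v in payload["lemis_species_years"].items()}
        payload["planted_ranges"] = {
            k: sorted(v) for k, v in payload["planted_ranges"].items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=_enc)


def gen_registry(
    n_species: int = 60,
    n_genera: int = 12,
    synonym_rate: float = 0.8,
    abbrev_rate: float = 0.1,
    seed: int = 0,
    out_dir=None,
    group: str = "spider",
    truth: GroundTruth | None = None,
):
    """Generate a checklist with synonym histories and known name map.

    ``synonym_rate`` is the mean synonyms per species (names per species is
    1 + synonym_rate, emulating checklist exports where species carry a
    handful of historical names); ``abbrev_rate`` is the probability a
    synonym is written with an abbreviated genus in the file, applied only
    where the loader's first-letter repair provably recovers the full
    genus.  Returns ``(records, truth)`` and, with ``out_dir``, writes
    ``checklist.csv``.
    """
    if not (n_species >= n_genera >= 1):
        raise ValueError("need n_species >= n_genera >= 1")
    if not (0 <= synonym_rate) or not (0 <= abbrev_rate <= 1):
        raise ValueError("invalid synonym_rate/abbrev_rate")
    rng = np.random.default_rng(seed)
    truth = truth or GroundTruth(seed=seed)

    genera = [g.capitalize() for g in _names_from_syllables(rng, GENUS_SYLLABLES, n_genera)]
    families = [f"{g[:6].capitalize()}idae" for g in
                _names_from_syllables(rng, GENUS_SYLLABLES, max(1, n_genera // 3))]
    # enough distinct epithets for accepted names plus all synonyms
    epithet_pool = _names_from_syllables(
        rng, EPITHET_SYLLABLES, n_species * (2 + int(np.ceil(synonym_rate * 3))))
    pool_iter = iter(epithet_pool)

    records: list[TaxonRecord] = []
    rows = []
    total_names = 0
    for i in range(n_species):
        genus = genera[i % n_genera]
        epithet = next(pool_iter)
        accepted = f"{genus} {epithet}"
        year = int(rng.integers(1850, 2021))
        n_syn = int(rng.poisson(synonym_rate))
        synonyms = []
        cell_parts = []
        seen_genera = [genus]  # mirrors the loader's repair candidates
        for _ in range(n_syn):
            if len(genera) > 1 and rng.random() < 0.5:
                syn_genus = genera[int(rng.integers(0, n_genera))]
                while syn_genus == genus and n_genera > 1:
                    syn_genus = genera[int(rng.integers(0, n_genera))]
            else:
                syn_genus = genus
            syn_epithet = next(pool_iter)
            syn = f"{syn_genus} {syn_epithet}"
            synonyms.append(syn)
            # abbreviate only when the loader's repair provably round-trips
            abbreviate = False
            if rng.random() < abbrev_rate:
                match = next(
                    (g for g in seen_genera if g[0].lower() == syn_genus[0].lower()),
                    None)
                abbreviate = match == syn_genus
            cell_parts.append(f"{syn_genus[0]}. {syn_epithet}" if abbreviate else syn)
            if syn_genus not in seen_genera:
                seen_genera.append(syn_genus)
        rec = TaxonRecord(
            accepted_name=accepted, genus=genus, epithet=epithet,
            family=families[i % len(families)], group=group,
            description_year=year, synonyms=synonyms,
        )
        records.append(rec)
        truth.species_groups[accepted] = group
        truth.description_years[accepted] = year
        for name in rec.all_names:
            truth.name_to_accepted[name.lower()] = accepted
        total_names += len(rec.all_names)
        rows.append({
            "genus": genus, "epithet": epithet, "family": rec.family,
            "year": str(year), "synonyms": "|".join(cell_parts),
            "nomen_dubium": "",
        })
    truth.mean_names_per_species = total_names / n_species

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import csv as _csv
        with open(out_dir / "checklist.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.DictWriter(
                fh, fieldnames=["genus", "epithet", "family", "year", "synonyms", "nomen_dubium"])
            writer.writeheader()
            writer.writerows(rows)
    return records, truth


def _listing_tokens(rng, name_tokens, colour):
    """One shop listing: planted name (+ optional colour) with decoy padding."""
    pad = lambda n: [DECOY_WORDS[i] for i in rng.integers(0, len(DECOY_WORDS), n)]
    tokens = pad(4) + list(name_tokens)
    if colour:
        tokens.append(colour)
    tokens += pad(4)
    return tokens


def gen_corpus(
    records,
    n_sites: int = 12,
    pages_per_site: int = 6,
    species_per_page: int = 5,
    colour_prob: float = 0.4,
    locality_prob: float = 0.2,
    adversarial: bool = False,
    seed: int = 0,
    out_dir=None,
    truth: GroundTruth | None = None,
):
    """Generate shop-like HTML pages with planted species mentions.

    Half the sites are "archived" with dated snapshots (2014-2019), half are
    the contemporary snapshot (null year).  Each page embeds
    ``species_per_page`` binomials (accepted name or a synonym, recorded
    which), a colour word directly after the name with probability
    ``colour_prob`` (inside the genus context window), and "sp + locality"
    listings at ``locality_prob``.  Adversarial mode adds genus-prefix traps
    and split binomials that must not be detected as species.

    Returns ``(pages_spec, truth)`` where pages_spec is a list of
    ``(site_id, page_id, snapshot_year, html)``; with ``out_dir`` the pages
    and a ``manifest.csv`` are written.
    """
    rng = np.random.default_rng(seed + 1)
    truth = truth or GroundTruth(seed=seed)
    by_name = {}
    for rec in records:
        for name in rec.all_names:
            by_name[name] = rec

    pages_spec = []
    for s in range(n_sites):
        site_id = f"site{s:03d}"
        archived = s % 2 == 1
        if not archived:
            truth.snapshot_sites.append(site_id)
        for p in range(pages_per_site):
            page_id = f"p{p:02d}"
            year = int(ARCHIVE_YEARS[int(rng.integers(0, len(ARCHIVE_YEARS)))]) if archived else None
            tokens: list[str] = []
            planted: set[str] = set()
            # a species can only be listed once described
            eligible = [i for i, r in enumerate(records)
                        if year is None or (r.description_year or 0) <= year]
            idx = rng.choice(eligible, size=min(species_per_page, len(eligible)),
                             replace=False)
            for ri in idx:
                rec = records[int(ri)]
                names = rec.all_names
                name = names[int(rng.integers(0, len(names)))]
                colour = None
                if rng.random() < colour_prob:
                    colour = PLANT_COLOURS[int(rng.integers(0, len(PLANT_COLOURS)))]
                    genus_token = name.split()[0].lower()
                    key = (genus_token, colour)
                    truth.planted_colour_counts[key] = truth.planted_colour_counts.get(key, 0) + 1
                tokens += _listing_tokens(rng, name.split(), colour)
                planted.add(rec.accepted_name)
                truth.planted_matches.append({
                    "site_id": site_id, "page_id": page_id,
                    "matched_name": name, "accepted_name": rec.accepted_name,
                    "kind": "exact_current" if name == rec.accepted_name else "synonym",
                })
                if year is not None:
                    truth.online_species_years.setdefault(rec.accepted_name, set()).add(year)
                else:
                    truth.online_species_years.setdefault(rec.accepted_name, set())
            if rng.random() < locality_prob:
                rec = records[int(rng.integers(0, len(records)))]
                loc = _names_from_syllables(rng, LOCALITY_SYLLABLES, 1, 2)[0].capitalize()
                tokens += [rec.genus, "sp", loc]
                tokens += [DECOY_WORDS[i] for i in rng.integers(0, len(DECOY_WORDS), 4)]
                truth.planted_locality_listings.append({
                    "site_id": site_id, "page_id": page_id,
                    "genus": rec.genus, "locality": loc,
                })
            if adversarial:
                rec = records[int(rng.integers(0, len(records)))]
                # left-boundary trap: genus as prefix of a longer word
                tokens += [rec.genus + "atus"]
                tokens += [DECOY_WORDS[i] for i in rng.integers(0, len(DECOY_WORDS), 4)]
                # split binomial: genus and epithet not side-by-side
                rec2 = records[int(rng.integers(0, len(records)))]
                tokens += [rec2.genus, DECOY_WORDS[int(rng.integers(0, len(DECOY_WORDS)))],
                           rec2.epithet]
                tokens += [DECOY_WORDS[i] for i in rng.integers(0, len(DECOY_WORDS), 4)]
            truth.planted_species_per_page[(site_id, page_id)] = planted
            body = " ".join(tokens)
            html = f"<html><body><p>{body}</p><script>var x=1;</script></body></html>"
            pages_spec.append((site_id, page_id, year, html))

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "pages").mkdir(parents=True, exist_ok=True)
        import csv as _csv
        with open(out_dir / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["path", "site_id", "page_id", "snapshot_year"])
            for site_id, page_id, year, html in pages_spec:
                rel = f"pages/{site_id}_{page_id}.html"
                (out_dir / rel).write_text(html, encoding="utf-8")
                writer.writerow([rel, site_id, page_id, "" if year is None else year])
    return pages_spec, truth


DEFAULT_CODE_FREQUENCIES = {
    # description: ~92% whole-individual codes, the rest parts/products
    "description": {"LIV": 0.66, "DEA": 0.08, "BOD": 0.05, "SPE": 0.06,
                    "EGL": 0.03, "SKI": 0.02, "TRO": 0.02, "SHE": 0.05, "CAV": 0.03},
    # disposition: seizures are a tiny sliver of declared imports
    "disposition": {"C": 0.9796, "S": 0.0004, "A": 0.012, "R": 0.008},
    # purpose: overwhelmingly commercial; M/S/Y are the non-commercial codes
    "purpose": {"T": 0.9, "P": 0.018, "S": 0.05, "M": 0.02, "Y": 0.012},
}


def gen_lemis(
    records,
    n_records: int = 2000,
    code_frequencies: dict | None = None,
    per_genus_wild_fractions: dict | None = None,
    default_wild_fraction: float = 0.70,
    country_ids=None,
    seed: int = 0,
    out_dir=None,
    truth: GroundTruth | None = None,
    synonym_use_rate: float = 0.25,
    species_coverage: float = 0.25,
    native_origin_rate: float = 0.7,
):
    """Generate a LEMIS-like import ledger with controlled code mixes.

    Only ``species_coverage`` of the registry appears in the ledger at all,
    emulating how import records cover far fewer species than online
    listings do.

    ``per_genus_wild_fractions`` maps genus -> probability a record is
    wild-sourced (default ``default_wild_fraction`` everywhere); non-wild
    records split between captive codes (C/F/D/R) and a small "other"
    residue.  Species names use a junior synonym at ``synonym_use_rate`` to
    exercise name reconciliation.  If ``truth.planted_ranges`` is already
    populated, origin countries are drawn from the country pool and the
    realised non-native wild quantities per origin are recorded.

    Returns ``(rows, truth)``; with ``out_dir`` writes ``lemis.csv``.
    """
    freqs = {**DEFAULT_CODE_FREQUENCIES, **(code_frequencies or {})}
    for family, fmap in freqs.items():
        if abs(sum(fmap.values()) - 1.0) > 1e-9:
            raise ValueError(f"{family} frequencies must sum to 1")
    rng = np.random.default_rng(seed + 2)
    truth = truth or GroundTruth(seed=seed)
    wild_fracs = per_genus_wild_fractions or {}
    countries = list(country_ids) if country_ids else [f"C{i:02d}" for i in range(10)]
    n_cover = max(1, int(round(species_coverage * len(records))))
    covered = sorted(int(i) for i in rng.choice(len(records), size=min(n_cover, len(records)),
                                                replace=False))
    pool = [records[i] for i in covered]

    def draw(fmap):
        keys = sorted(fmap)
        probs = np.array([fmap[k] for k in keys])
        return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]

    rows = []
    source_totals = {"wild": 0.0, "captive": 0.0, "other": 0.0}
    seized = commercial = whole_total = 0.0
    kept = 0
    genus_tot: dict[str, float] = {}
    genus_wild: dict[str, float] = {}
    nonnative: dict[str, dict[str, float]] = {}
    for _ in range(n_records):
        rec = pool[int(rng.integers(0, len(pool)))]
        names = rec.all_names
        use_syn = len(names) > 1 and rng.random() < synonym_use_rate
        name = names[int(rng.integers(1, len(names)))] if use_syn else rec.accepted_name
        genus_raw, species_raw = name.split()
        qty = float(rng.integers(1, 400))
        desc = draw(freqs["description"])
        disp = draw(freqs["disposition"])
        purp = draw(freqs["purpose"])
        # wild probability keys on the genus as listed in the ledger, since
        # per-genus summaries group by the listed genus without synonymisation
        p_wild = wild_fracs.get(genus_raw, wild_fracs.get(rec.genus, default_wild_fraction))
        r = rng.random()
        if r < p_wild:
            source = "W"
        elif r < p_wild + (1 - p_wild) * 0.9:
            source = ["C", "F", "D", "R"][int(rng.integers(0, 4))]
        else:
            source = ["U", "I", ""][int(rng.integers(0, 3))]
        # most shipments leave from a native country; the rest from anywhere
        native_pool = sorted(truth.planted_ranges.get(rec.accepted_name, ()))
        if native_pool and rng.random() < native_origin_rate:
            origin = native_pool[int(rng.integers(0, len(native_pool)))]
        else:
            origin = countries[int(rng.integers(0, len(countries)))]
        # shipments start no earlier than the species' description year
        lo = min(2020, max(2008, rec.description_year or 2008))
        year = int(rng.integers(lo, 2021))
        rows.append({
            "class": "Arachnida", "genus": genus_raw, "species": species_raw,
            "quantity": f"{qty:.0f}", "description": desc, "disposition": disp,
            "purpose": purp, "source": source, "country_origin": origin,
            "shipment_year": str(year),
        })
        if desc in {"BOD", "EGL", "DEA", "LIV", "SPE", "SKI", "TRO"}:
            kept += 1
            whole_total += qty
            cls = ("wild" if source == "W"
                   else "captive" if source in {"C", "F", "D", "R"} else "other")
            source_totals[cls] += qty
            if disp == "S":
                seized += qty
            if purp not in {"M", "S", "Y"}:
                commercial += qty
            gkey = genus_raw.lower()
            genus_tot[gkey] = genus_tot.get(gkey, 0.0) + qty
            if cls == "wild":
                genus_wild[gkey] = genus_wild.get(gkey, 0.0) + qty
        # non-native accounting is over ALL wild records, pre description-filter
        if source == "W" and truth.planted_ranges:
            entry = nonnative.setdefault(origin, {"wild": 0.0, "nonnative": 0.0,
                                                  "unknown": 0.0})
            entry["wild"] += qty
            native = truth.planted_ranges.get(rec.accepted_name)
            if not native:
                entry["unknown"] += qty
            elif origin not in native:
                entry["nonnative"] += qty
        truth.lemis_species_years.setdefault(rec.accepted_name, set()).add(year)
        if rec.accepted_name not in truth.lemis_species:
            truth.lemis_species.append(rec.accepted_name)
    truth.planted_source_totals = source_totals
    truth.planted_seized_total = seized
    truth.planted_commercial_total = commercial
    truth.planted_whole_total = whole_total
    truth.planted_kept_records = kept
    truth.per_genus_wild = {
        g: {"total": genus_tot[g], "wild": genus_wild.get(g, 0.0)}
        for g in sorted(genus_tot)
    }
    truth.planted_nonnative = nonnative
    truth.lemis_species.sort()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import csv as _csv
        with open(out_dir / "lemis.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows, truth


def gen_cites(records, n_species: int = 6, seed: int = 0, out_dir=None,
              truth: GroundTruth | None = None):
    """Small CITES gross-imports style table over a species subset.

    Uses the wide layout (Taxon + year columns).  Returns ``(rows, truth)``;
    with ``out_dir`` writes ``cites.csv``.
    """
    rng = np.random.default_rng(seed + 3)
    truth = truth or GroundTruth(seed=seed)
    idx = rng.choice(len(records), size=min(n_species, len(records)), replace=False)
    years = [2012, 2015, 2018, 2020]
    rows = []
    for ri in sorted(int(i) for i in idx):
        rec = records[ri]
        names = rec.all_names
        name = names[int(rng.integers(0, len(names)))]
        row = {"Taxon": name, "App.": "II", "Term": "live", "Unit": ""}
        for y in years:
            row[str(y)] = str(int(rng.integers(0, 50)))
        rows.append(row)
        if rec.accepted_name not in truth.cites_species:
            truth.cites_species.append(rec.accepted_name)
    truth.cites_species.sort()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import csv as _csv
        fieldnames = ["Taxon", "App.", "Term", "Unit"] + [str(y) for y in years]
        with open(out_dir / "cites.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
    return rows, truth


def gen_country_world(n_countries: int = 24, n_regions: int = 4, seed: int = 0):
    """Synthetic reference world: gridded countries, regions, islands.

    Countries sit on a lon/lat grid (collinear rows, so same-row spans
    degenerate predictably); each belongs to one region; a few dependent
    islands map to sovereign countries.  Returns
    ``(country_rows, region_map, island_map)``.
    """
    rng = np.random.default_rng(seed + 4)
    names = [n.capitalize() for n in _names_from_syllables(rng, COUNTRY_SYLLABLES, n_countries)]
    per_row = 6
    country_rows = []
    for i, name in enumerate(names):
        lon = -150.0 + (i % per_row) * 30.0
        lat = -45.0 + (i // per_row) * 30.0
        country_rows.append({
            "country_id": f"C{i:02d}", "canonical_name": name,
            "aliases": f"{name} Republic|{name[:4].upper()}",
            "lon": f"{lon}", "lat": f"{lat}",
        })
    region_map: dict[str, set[str]] = {}
    for i, row in enumerate(country_rows):
        region_map.setdefault(f"region{i % n_regions}", set()).add(row["country_id"])
    island_map = {
        f"{names[i].lower()} island": f"C{i:02d}" for i in range(0, min(4, n_countries))
    }
    return country_rows, region_map, island_map


def gen_ranges(
    records,
    endemism_rate: float = 0.764,
    region_use_rate: float = 0.15,
    span_use_rate: float = 0.15,
    island_use_rate: float = 0.1,
    n_countries: int = 24,
    seed: int = 0,
    out_dir=None,
    truth: GroundTruth | None = None,
):
    """Generate range assertions of all four kinds with planted country sets.

    Endemic species (probability ``endemism_rate``) get a single country
    assertion; the rest get 2-4 countries, optionally a region, a span of
    collinear same-row countries (so hull expansion provably returns the
    listed set) and an island.  Country names are sometimes written via an
    alias to exercise standardisation.  Planted per-species country sets and
    the total connection count are recorded.

    Returns ``(assertions_rows, country_rows, region_map, island_map, truth)``;
    with ``out_dir`` writes ``ranges.csv``, ``countries.csv``,
    ``regions.csv`` and ``islands.csv``.
    """
    if not (0 <= endemism_rate <= 1):
        raise ValueError("endemism_rate must be in [0, 1]")
    rng = np.random.default_rng(seed + 5)
    truth = truth or GroundTruth(seed=seed)
    country_rows, region_map, island_map = gen_country_world(n_countries, seed=seed)
    cids = [r["country_id"] for r in country_rows]
    name_of = {r["country_id"]: r["canonical_name"] for r in country_rows}
    alias_of = {r["country_id"]: r["aliases"].split("|")[0] for r in country_rows}
    island_names = sorted(island_map)
    per_row = 6
    rows_of = {}
    for i, cid in enumerate(cids):
        rows_of.setdefault(i // per_row, []).append(cid)

    def country_text(cid):
        return alias_of[cid] if rng.random() < 0.3 else name_of[cid]

    assertions = []
    for rec in records:
        planted: set[str] = set()
        if rng.random() < endemism_rate:
            cid = cids[int(rng.integers(0, len(cids)))]
            assertions.append({"accepted_name": rec.accepted_name, "kind": "country",
                               "raw_text": country_text(cid)})
            planted.add(cid)
        else:
            k = int(rng.integers(2, 5))
            chosen = [cids[int(i)] for i in rng.choice(len(cids), size=k, replace=False)]
            for cid in chosen:
                assertions.append({"accepted_name": rec.accepted_name, "kind": "country",
                                   "raw_text": country_text(cid)})
                planted.add(cid)
            if rng.random() < region_use_rate:
                region = f"region{int(rng.integers(0, len(region_map)))}"
                assertions.append({"accepted_name": rec.accepted_name, "kind": "region",
                                   "raw_text": region})
                planted |= region_map[region]
            if rng.random() < span_use_rate:
                row = rows_of[int(rng.integers(0, len(rows_of)))]
                span = [row[int(i)] for i in
                        rng.choice(len(row), size=min(3, len(row)), replace=False)]
                assertions.append({
                    "accepted_name": rec.accepted_name, "kind": "span",
                    "raw_text": " to ".join(name_of[c] for c in span)})
                planted |= set(span)  # collinear row => hull degenerates to listed set
            if rng.random() < island_use_rate and island_names:
                isl = island_names[int(rng.integers(0, len(island_names)))]
                assertions.append({"accepted_name": rec.accepted_name, "kind": "island",
                                   "raw_text": isl})
                planted.add(island_map[isl])
        truth.planted_ranges[rec.accepted_name] = planted
    truth.planted_connections = sum(len(v) for v in truth.planted_ranges.values())

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import csv as _csv
        with open(out_dir / "ranges.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.DictWriter(fh, fieldnames=["accepted_name", "kind", "raw_text"])
            writer.writeheader()
            writer.writerows(assertions)
        with open(out_dir / "countries.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.DictWriter(
                fh, fieldnames=["country_id", "canonical_name", "aliases", "lon", "lat"])
            writer.writeheader()
            writer.writerows(country_rows)
        with open(out_dir / "regions.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["region", "country_id"])
            for region in sorted(region_map):
                for cid in sorted(region_map[region]):
                    writer.writerow([region, cid])
        with open(out_dir / "islands.csv", "w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["island", "country_id"])
            for isl in sorted(island_map):
                writer.writerow([isl, island_map[isl]])
    return assertions, country_rows, region_map, island_map, truth


def generate_all(out_dir, seed: int = 0, config: dict | None = None) -> GroundTruth:
    """Drive all generators from one config; write a full fixture bundle.

    ``config`` keys (all optional) override the per-generator defaults:
    registry, corpus, lemis, cites, ranges — each a kwargs dict.  The
    GroundTruth is serialised next to the fixtures as ``ground_truth.json``.
    """
    cfg = config or {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth(seed=seed)
    records, truth = gen_registry(seed=seed, out_dir=out_dir, truth=truth,
                                  **cfg.get("registry", {}))
    _, truth = gen_corpus(records, seed=seed, out_dir=out_dir, truth=truth,
                          **cfg.get("corpus", {}))
    _, country_rows, _, _, truth = gen_ranges(records, seed=seed, out_dir=out_dir,
                                              truth=truth, **cfg.get("ranges", {}))
    _, truth = gen_lemis(records, seed=seed, out_dir=out_dir, truth=truth,
                         country_ids=[r["country_id"] for r in country_rows],
                         **cfg.get("lemis", {}))
    _, truth = gen_cites(records, seed=seed, out_dir=out_dir, truth=truth,
                         **cfg.get("cites", {}))
    truth.to_json(out_dir / "ground_truth.json")
    return truth
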