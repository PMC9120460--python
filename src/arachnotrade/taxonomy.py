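"""Species/synonym name registry and lookup index.

Online shop listings and import ledgers routinely use junior synonyms or
superseded genus placements, so every downstream matching step runs through a
single name index built from checklist exports (e.g. the World Spider Catalog,
the Scorpion Files, ITIS).  The index maps every name a species has ever
carried to its currently accepted binomial, and groups full names by their
leading genus token so that a genus hit on a page narrows the species search
to names historically housed in that genus.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

GROUPS = ("spider", "scorpion", "uropygi", "amblypygi")

_AUTHORITY_RE = re.compile(r"\([^)]*\)")
_WS_RE = re.compile(r"\s+")
_ABBREV_RE = re.compile(r"^([A-Za-z])\.\s*(\S.*)$")


def normalise_name(name: str) -> str:
    """Normalise a taxon name for matching.

    Lower-cases, strips parenthetical authorities (``"(Smith 1996)"``) and
    collapses internal whitespace.  Diacritics are preserved: matching is
    byte-insensitive lowercase only, never collation-based.
    """
    cleaned = _AUTHORITY_RE.sub(" ", name)
    return _WS_RE.sub(" ", cleaned).strip().lower()


class ChecklistError(ValueError):
    """A checklist file is missing a required column or is unusable."""


@dataclass
class TaxonRecord:
    """One accepted species with its full name history.

    ``synonyms`` holds post-repair historical binomials (abbreviated genera
    already expanded where possible).  ``description_year`` is the year of
    the original description, or ``None`` when the source row was
    unparseable.
    """

    accepted_name: str
    genus: str
    epithet: str
    family: str = ""
    group: str = "spider"
    description_year: int | None = None
    nomen_dubium: bool = False
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genus or not self.epithet:
            raise ValueError("genus and epithet must be non-empty")
        if self.accepted_name != f"{self.genus} {self.epithet}":
            raise ValueError(
                f"accepted_name {self.accepted_name!r} != genus + epithet"
            )
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.description_year is not None and self.description_year < 1750:
            raise ValueError("description_year before 1750")

    @property
    def all_names(self) -> list[str]:
        """Accepted name plus synonyms, accepted first, order preserved."""
        names = [self.accepted_name]
        for syn in self.synonyms:
            if syn not in names:
                names.append(syn)
        return names


@dataclass
class Resolution:
    """Outcome of resolving a raw name against the index."""

    accepted_name: str | None
    match_kind: str  # exact_current | synonym | unknown
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()


@dataclass
class NameIndex:
    """Lookup structures over every name in the registry.

    name_to_accepted
        normalised full name -> accepted name (many-to-one).
    genus_to_names
        normalised leading genus token (any genus ever used) -> set of
        normalised full names whose first token is that genus.
    """

    name_to_accepted: dict[str, str] = field(default_factory=dict)
    genus_to_names: dict[str, set[str]] = field(default_factory=dict)
    accepted_names: set[str] = field(default_factory=set)
    display: dict[str, str] = field(default_factory=dict)
    conflicts: dict[str, list[str]] = field(default_factory=dict)
    nomen_dubium_names: list[str] = field(default_factory=list)
    accepted_group: dict[str, str] = field(default_factory=dict)

    @property
    def genus_list(self) -> list[str]:
        return sorted(self.genus_to_names)

    def __len__(self) -> int:
        return len(self.name_to_accepted)

    def to_json(self, path) -> None:
        payload = {
            "name_to_accepted": self.name_to_accepted,
            "genus_to_names": {g: sorted(v) for g, v in self.genus_to_names.items()},
            "accepted_names": sorted(self.accepted_names),
            "display": self.display,
            "conflicts": self.conflicts,
            "nomen_dubium_names": self.nomen_dubium_names,
            "accepted_group": self.accepted_group,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "NameIndex":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            name_to_accepted=payload["name_to_accepted"],
            genus_to_names={g: set(v) for g, v in payload["genus_to_names"].items()},
            accepted_names=set(payload["accepted_names"]),
            display=payload.get("display", {}),
            conflicts=payload.get("conflicts", {}),
            nomen_dubium_names=payload.get("nomen_dubium_names", []),
            accepted_group=payload.get("accepted_group", {}),
        )


def repair_abbreviated_synonym(
    abbrev_name: str, candidate_genera: Sequence[str]
) -> tuple[str, bool]:
    """Expand an abbreviated-genus synonym like ``"G. rosea"``.

    Returns ``(name, repaired)``.  The abbreviation letter is matched
    case-insensitively against the initial letter of each candidate genus in
    the order given (the order genera were encountered in the source synonym
    listing); the first match wins.  If nothing matches the input is returned
    unchanged with ``repaired=False`` so callers can flag it.
    """
    m = _ABBREV_RE.match(abbrev_name.strip())
    if not m:
        return abbrev_name, False
    letter, epithet = m.group(1).lower(), m.group(2)
    for genus in candidate_genera:
        if genus and genus[0].lower() == letter:
            return f"{genus} {epithet}", True
    return abbrev_name, False


def _parse_year(raw: str | None):
    if raw is None:
        return None
    raw = str(raw).strip()
    m = re.search(r"(1[789]\d\d|20\d\d)", raw)
    return int(m.group(1)) if m else None


def load_checklist(
    checklist_file,
    group: str,
    column_map: dict[str, str] | None = None,
    synonym_delimiter: str = "|",
) -> list[TaxonRecord]:
    """Read a checklist CSV/TSV export into :class:`TaxonRecord` rows.

    Subspecies rows (trinomials) are dropped.  ``column_map`` maps the
    logical fields {genus, epithet, name, family, year, synonyms,
    nomen_dubium} to the file's column headers; sensible defaults cover
    files that already use those names.  The synonyms cell is
    ``synonym_delimiter``-packed; abbreviated-genus entries are repaired
    against the genera already seen in that species' listing.
    """
    cmap = {
        "genus": "genus",
        "epithet": "epithet",
        "name": "name",
        "family": "family",
        "year": "year",
        "synonyms": "synonyms",
        "nomen_dubium": "nomen_dubium",
    }
    if column_map:
        cmap.update(column_map)

    delimiter = "\t" if str(checklist_file).endswith((".tsv", ".tab")) else ","
    records: list[TaxonRecord] = []
    n_trinomial = n_badyear = 0
    with open(checklist_file, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ChecklistError(f"{checklist_file}: empty file")
        cols = set(reader.fieldnames)
        have_parts = cmap["genus"] in cols and cmap["epithet"] in cols
        have_name = cmap["name"] in cols
        if not (have_parts or have_name):
            raise ChecklistError(
                f"{checklist_file}: need columns "
                f"({cmap['genus']!r}, {cmap['epithet']!r}) or {cmap['name']!r}"
            )
        for row in reader:
            if have_parts:
                genus = (row.get(cmap["genus"]) or "").strip()
                epithet = (row.get(cmap["epithet"]) or "").strip()
                if " " in epithet:  # epithet cell holding "epithet subsp"
                    n_trinomial += 1
                    continue
            else:
                tokens = (row.get(cmap["name"]) or "").split()
                if len(tokens) != 2:
                    n_trinomial += 1
                    continue
                genus, epithet = tokens
            if not genus or not epithet:
                continue

            year = _parse_year(row.get(cmap["year"]))
            if row.get(cmap["year"]) not in (None, "") and year is None:
                n_badyear += 1
                logger.warning(
                    "unparseable year %r for %s %s; year set to unknown",
                    row.get(cmap["year"]), genus, epithet,
                )

            raw_syns = (row.get(cmap["synonyms"]) or "").strip()
            seen_genera = [genus]
            synonyms: list[str] = []
            for syn in filter(None, (s.strip() for s in raw_syns.split(synonym_delimiter))):
                repaired, ok = repair_abbreviated_synonym(syn, seen_genera)
                if _ABBREV_RE.match(syn) and not ok:
                    logger.warning("unrepairable abbreviated synonym %r", syn)
                syn = repaired
                tokens = syn.split()
                if len(tokens) >= 2 and tokens[0] not in seen_genera:
                    seen_genera.append(tokens[0])
                if len(tokens) == 2:  # synonym trinomials dropped like rows
                    synonyms.append(syn)

            dubium = str(row.get(cmap["nomen_dubium"], "")).strip().lower() in (
                "1", "true", "yes", "y",
            )
            records.append(
                TaxonRecord(
                    accepted_name=f"{genus} {epithet}",
                    genus=genus,
                    epithet=epithet,
                    family=(row.get(cmap["family"]) or "").strip(),
                    group=group,
                    description_year=year,
                    nomen_dubium=dubium,
                    synonyms=synonyms,
                )
            )
    logger.info(
        "%s: %d species loaded (%d trinomial rows removed, %d bad years)",
        checklist_file, len(records), n_trinomial, n_badyear,
    )
    return records


def build_name_index(
    records: Iterable[TaxonRecord], include_nomen_dubium: bool = True
) -> NameIndex:
    """Build the :class:`NameIndex` over every name in ``records``.

    Every accepted name and every synonym is indexed; genus buckets come from
    the leading token of every name.  Names mapping to two accepted species
    are kept for both targets in ``conflicts`` and excluded from the
    one-to-one ``name_to_accepted`` map.  With ``include_nomen_dubium=False``
    dubious species' names are dropped from the search space but listed in
    ``nomen_dubium_names``.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot index an empty registry")
    index = NameIndex()
    for rec in records:
        if rec.nomen_dubium:
            index.nomen_dubium_names.extend(rec.all_names)
            if not include_nomen_dubium:
                continue
        index.accepted_names.add(rec.accepted_name)
        index.accepted_group[rec.accepted_name] = rec.group
        for name in rec.all_names:
            norm = normalise_name(name)
            if not norm:
                continue
            index.display.setdefault(norm, name)
            current = index.name_to_accepted.get(norm)
            if norm in index.conflicts:
                if rec.accepted_name not in index.conflicts[norm]:
                    index.conflicts[norm].append(rec.accepted_name)
            elif current is not None and current != rec.accepted_name:
                index.conflicts[norm] = [current, rec.accepted_name]
                del index.name_to_accepted[norm]
                logger.warning(
                    "name %r maps to multiple accepted species: %s",
                    name, index.conflicts[norm],
                )
            else:
                index.name_to_accepted[norm] = rec.accepted_name
            genus_token = norm.split()[0]
            index.genus_to_names.setdefault(genus_token, set()).add(norm)
    return index


def resolve_name(name: str, index: NameIndex, group: str | None = None) -> Resolution:
    """Resolve a raw name to its accepted binomial.

    ``exact_current`` when the name is itself an accepted name, ``synonym``
    when it reaches the accepted name through a historical name, ``unknown``
    otherwise.  For homonyms (one name, several accepted species) a unique
    candidate within ``group`` is used when one exists; otherwise the
    resolution is flagged ambiguous with all candidates listed.
    """
    norm = normalise_name(name)
    if norm in index.conflicts:
        candidates = tuple(index.conflicts[norm])
        if group is not None:
            in_group = [c for c in candidates if index.accepted_group.get(c) == group]
            if len(in_group) == 1:
                accepted = in_group[0]
                kind = "exact_current" if norm == normalise_name(accepted) else "synonym"
                return Resolution(accepted, kind, ambiguous=False, candidates=candidates)
        kind = (
            "exact_current"
            if any(norm == normalise_name(c) for c in candidates)
            else "synonym"
        )
        return Resolution(None, kind, ambiguous=True, candidates=candidates)
    accepted = index.name_to_accepted.get(norm)
    if accepted is None:
        return Resolution(None, "unknown")
    if norm == normalise_name(accepted):
        return Resolution(accepted, "exact_current")
    return Resolution(accepted, "synonym")
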