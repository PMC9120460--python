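"""Hierarchical genus-then-species keyword search over cleaned pages.

With tens of thousands of species names, scanning every name against every
page is wasteful; instead each page is scanned for genus tokens first and
only the full names historically housed in a detected genus are then
searched.  The genus pre-filter is purely an optimisation: the species
detection set is identical to a brute-force all-names scan.

Matching is case-insensitive fixed-string with a LEFT word boundary only
(the token must start at a token boundary; the right edge is unconstrained),
so genus "Neon" matches "Neonate spiders" — that one-sided behaviour is what
the spurious-genus blocklist exists to clean up.  Abbreviated genera and
split binomials are deliberately not repaired.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .corpus import CleanPage
from .taxonomy import NameIndex, resolve_name

logger = logging.getLogger(__name__)

#: Genus tokens observed to fire only as prefixes of ordinary words
#: (e.g. "Neon" in "Neonate"); removable because none ever yielded a
#: species-level hit.
DEFAULT_BLOCKLIST = frozenset(
    t.lower() for t in (
        "rufus", "Dia", "Diana", "Mala", "Inca", "Pero", "May", "Janus",
        "Yukon", "Lucia", "Zora", "Beata", "Neon", "Prima", "Meta", "Patri",
        "Enna", "Maso", "Mica", "Perro",
    )
)

CONTEXT_BEFORE = 3
CONTEXT_AFTER = 4


@dataclass
class Detection:
    """One (page, matched name) event.

    ``matched_name`` is None for genus-only hits.  Context windows are the
    tokens around the genus hit (up to 3 before, 4 after), the raw material
    for colour/locality analysis.
    """

    site_id: str
    page_id: str
    snapshot_year: int | None
    genus_token: str
    matched_name: str | None
    accepted_name: str | None
    match_kind: str  # exact_current | synonym | genus_only
    context_before: list[str] = field(default_factory=list)
    context_after: list[str] = field(default_factory=list)
    position: int = 0
    ambiguous: bool = False


def _token_matches(token: str, pattern: str, strict: bool) -> bool:
    token = token.lower()
    return token == pattern if strict else token.startswith(pattern)


def find_genus_mentions(
    page: CleanPage, genus_list, strict_boundaries: bool = False
) -> list[tuple[str, int]]:
    """Locate genus-token hits in a page.

    Returns ``(genus_token, token_position)`` pairs.  Default mode requires
    only the left boundary (genus is a prefix of the token); ``strict``
    requires the whole token to equal the genus.
    """
    genus_set = {g.lower() for g in genus_list}
    hits: list[tuple[str, int]] = []
    tokens = page.tokens
    if strict_boundaries:
        for i, tok in enumerate(tokens):
            low = tok.lower()
            if low in genus_set:
                hits.append((low, i))
    else:
        # Prefix matching: any genus that is a prefix of the token fires.
        for i, tok in enumerate(tokens):
            low = tok.lower()
            for j in range(1, len(low) + 1):
                pref = low[:j]
                if pref in genus_set:
                    hits.append((pref, i))
    return hits


def capture_context(tokens, position: int) -> tuple[list[str], list[str]]:
    """Up to 3 tokens before and 4 after a genus hit, clipped at page edges."""
    before = tokens[max(0, position - CONTEXT_BEFORE):position]
    after = tokens[position + 1:position + 1 + CONTEXT_AFTER]
    return list(before), list(after)


def _name_matches_at(tokens, pos: int, name_tokens, strict: bool) -> bool:
    """Does the full name match at token ``pos`` (left boundary only)?

    All but the last name token must match their page token exactly (the
    fixed-string pattern has a space after them); the last token needs only
    to be a prefix of its page token unless ``strict``.
    """
    k = len(name_tokens)
    if pos + k > len(tokens):
        return False
    for off in range(k - 1):
        if tokens[pos + off].lower() != name_tokens[off]:
            return False
    return _token_matches(tokens[pos + k - 1], name_tokens[-1], strict)


def hierarchical_search(
    page: CleanPage, index: NameIndex, strict_boundaries: bool = False
) -> list[Detection]:
    """Genus-first species search of one page.

    For every genus hit, every full name in that genus bucket (any name the
    species ever carried) is tried at that position.  Species hits become
    detections with the resolution kind of the matched name; a genus hit
    yielding no species hit becomes a genus_only detection.  Output is
    ordered by position for reproducible diffs.
    """
    tokens = page.tokens
    detections: list[Detection] = []
    for genus_token, pos in find_genus_mentions(page, index.genus_to_names, strict_boundaries):
        before, after = capture_context(tokens, pos)
        species_hit = False
        for name in sorted(index.genus_to_names.get(genus_token, ())):
            name_tokens = name.split()
            if _name_matches_at(tokens, pos, name_tokens, strict_boundaries):
                res = resolve_name(name, index)
                detections.append(Detection(
                    site_id=page.site_id,
                    page_id=page.page_id,
                    snapshot_year=page.snapshot_year,
                    genus_token=genus_token,
                    matched_name=index.display.get(name, name),
                    accepted_name=res.accepted_name,
                    match_kind=res.match_kind,
                    context_before=before,
                    context_after=after,
                    position=pos,
                    ambiguous=res.ambiguous,
                ))
                species_hit = True
        if not species_hit:
            detections.append(Detection(
                site_id=page.site_id,
                page_id=page.page_id,
                snapshot_year=page.snapshot_year,
                genus_token=genus_token,
                matched_name=None,
                accepted_name=None,
                match_kind="genus_only",
                context_before=before,
                context_after=after,
                position=pos,
            ))
    detections.sort(key=lambda d: (d.site_id, d.page_id, d.position, d.matched_name or ""))
    return detections


def search_corpus(pages, index: NameIndex, strict_boundaries: bool = False) -> list[Detection]:
    """Run :func:`hierarchical_search` over a whole corpus, in page order."""
    out: list[Detection] = []
    for page in pages:
        out.extend(hierarchical_search(page, index, strict_boundaries))
    return out


def brute_force_species_search(page: CleanPage, index: NameIndex,
                               strict_boundaries: bool = False) -> set[tuple]:
    """Reference scan: every full name against the page, no genus pre-filter.

    Returns {(site, page, position, matched normalised name)}; used as the
    equivalence oracle for :func:`hierarchical_search`.
    """
    tokens = page.tokens
    hits = set()
    for name in index.name_to_accepted:
        name_tokens = name.split()
        for pos in range(len(tokens)):
            if _name_matches_at(tokens, pos, name_tokens, strict_boundaries):
                hits.add((page.site_id, page.page_id, pos, name))
    for name in index.conflicts:
        name_tokens = name.split()
        for pos in range(len(tokens)):
            if _name_matches_at(tokens, pos, name_tokens, strict_boundaries):
                hits.add((page.site_id, page.page_id, pos, name))
    return hits


def filter_spurious(detections, blocklist=DEFAULT_BLOCKLIST):
    """Drop blocklisted genus_only detections; report review candidates.

    Only genus_only hits are removable — a species-level detection inside a
    blocklisted genus is retained with a warning, because the blocklist's
    rationale (no species ever detected in the genus) would be violated.
    The audit report lists every genus with at least one genus_only hit and
    zero species hits corpus-wide, the manual-review candidates.
    """
    blockset = {b.lower() for b in blocklist}
    species_genera = {
        d.matched_name.split()[0].lower()
        for d in detections if d.match_kind != "genus_only" and d.matched_name
    }
    kept: list[Detection] = []
    removed: list[Detection] = []
    warnings: list[str] = []
    genus_only_genera: set[str] = set()
    for d in detections:
        if d.match_kind == "genus_only":
            genus_only_genera.add(d.genus_token)
            if d.genus_token in blockset:
                if d.genus_token in species_genera:
                    warnings.append(
                        f"blocklisted genus {d.genus_token!r} has species "
                        "detections corpus-wide; genus_only hits removed anyway"
                    )
                removed.append(d)
                continue
        kept.append(d)
    review = sorted(genus_only_genera - species_genera - blockset)
    for w in sorted(set(warnings)):
        logger.warning(w)
    report = {
        "removed": len(removed),
        "review_candidates": review,
        "warnings": sorted(set(warnings)),
    }
    return kept, report


def collapse_per_page(detections) -> list[Detection]:
    """One detection per (page, matched name) for species-level summaries.

    Colour counting keeps the full multiplicity; species lists count
    presence, so repeated listings of one name on a page collapse to the
    first occurrence.
    """
    seen = set()
    out = []
    for d in detections:
        key = (d.site_id, d.page_id, d.matched_name, d.match_kind, d.genus_token)
        if key in seen:
            continue
        seen.add(key)
        out.append(d)
    return out


def write_detections_csv(detections, path) -> None:
    """Detections as CSV, context tokens pipe-joined, one row per event."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "site_id", "page_id", "snapshot_year", "genus_token",
            "matched_name", "accepted_name", "match_kind",
            "context_before", "context_after", "position",
        ])
        for d in detections:
            writer.writerow([
                d.site_id, d.page_id,
                "" if d.snapshot_year is None else d.snapshot_year,
                d.genus_token, d.matched_name or "", d.accepted_name or "",
                d.match_kind, "|".join(d.context_before),
                "|".join(d.context_after), d.position,
            ])


def read_detections_csv(path) -> list[Detection]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(Detection(
                site_id=row["site_id"],
                page_id=row["page_id"],
                snapshot_year=int(row["snapshot_year"]) if row["snapshot_year"] else None,
                genus_token=row["genus_token"],
                matched_name=row["matched_name"] or None,
                accepted_name=row["accepted_name"] or None,
                match_kind=row["match_kind"],
                context_before=row["context_before"].split("|") if row["context_before"] else [],
                context_after=row["context_after"].split("|") if row["context_after"] else [],
                position=int(row["position"]),
            ))
    return out
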