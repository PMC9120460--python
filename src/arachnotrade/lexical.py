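"""Colour-term co-occurrence over genus context windows.

Shops frequently advertise undescribed diversity by appending a colour
("Chilobrachys sp Electric Blue") or locality to a genus name instead of a
species epithet.  Counting colour terms inside the 3-before/4-after context
windows around genus mentions quantifies that novelty signal per genus.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources

logger = logging.getLogger(__name__)


def _read_wordlist(path_or_resource) -> list[str]:
    if hasattr(path_or_resource, "read_text"):
        text = path_or_resource.read_text(encoding="utf-8")
    else:
        with open(path_or_resource, encoding="utf-8") as fh:
            text = fh.read()
    return [w.strip().lower() for w in text.splitlines() if w.strip()]


def _packaged(name: str):
    return resources.files("arachnotrade.data").joinpath(name)


def default_stopwords() -> set[str]:
    """Packaged static English stop-word list (configurable by callers)."""
    return set(_read_wordlist(_packaged("stopwords.txt")))


def default_blocklist() -> set[str]:
    """Packaged spurious-genus blocklist (word-prefix false positives)."""
    return set(_read_wordlist(_packaged("genus_blocklist.txt")))


@dataclass
class ColourLexicon:
    """Colour vocabulary = colour list minus ambiguous exclusions."""

    colour_terms: set[str]
    ambiguous_exclusions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.colour_terms = {t.lower() for t in self.colour_terms}
        self.ambiguous_exclusions = {t.lower() for t in self.ambiguous_exclusions}
        self.colour_terms -= self.ambiguous_exclusions

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.colour_terms


def build_colour_lexicon(colour_list_file=None, exclusions_file=None) -> ColourLexicon:
    """Assemble the effective colour lexicon from one-term-per-line files.

    Defaults to the packaged colour list (single-token colour words plus
    descriptors like "electric" and "metallic") and the packaged ambiguity
    exclusions ("space", "jungle", "web", ...).
    """
    colours = _read_wordlist(colour_list_file or _packaged("colours.txt"))
    if not colours:
        raise ValueError("colour list is empty")
    exclusions = _read_wordlist(
        exclusions_file if exclusions_file is not None else _packaged("colour_exclusions.txt")
    )
    missing = [e for e in exclusions if e not in colours]
    if missing:
        logger.warning("exclusions absent from colour list (no-op): %s", missing)
    lex = ColourLexicon(set(colours), set(exclusions))
    logger.info(
        "colour lexicon: %d terms (%d excluded)",
        len(lex.colour_terms), len(exclusions),
    )
    return lex


@dataclass
class GenusColourCount:
    genus_token: str
    colour_term: str
    count: int


def count_colour_cooccurrence(
    detections,
    lexicon: ColourLexicon,
    stopwords: set[str] | None = None,
    per_token_multiplicity: bool = False,
):
    """Count colour terms in genus context windows.

    Per genus mention, stop words are removed from the combined context
    window, the remaining tokens lower-cased and intersected with the
    lexicon; each distinct colour in the window increments (genus, colour)
    by one.  ``per_token_multiplicity=True`` switches to raw token counts
    (a window "red red" then counts red twice).

    Returns ``(rows, summary)`` where rows are :class:`GenusColourCount`
    and summary maps genus -> number of distinct colours, plus the mean
    distinct colours per genus keyword under key ``"__mean__"``.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    stopset = {w.lower() for w in stopwords}
    counts: dict[tuple[str, str], int] = {}
    for d in detections:
        window = [
            t.lower() for t in (*d.context_before, *d.context_after)
            if t and t.lower() not in stopset
        ]
        hits = [t for t in window if t in lexicon]
        if not per_token_multiplicity:
            hits = sorted(set(hits))
        for colour in hits:
            key = (d.genus_token, colour)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        GenusColourCount(g, c, n)
        for (g, c), n in sorted(counts.items())
    ]
    per_genus: dict[str, int] = {}
    for row in rows:
        per_genus[row.genus_token] = per_genus.get(row.genus_token, 0) + 1
    summary: dict[str, float] = dict(per_genus)
    if per_genus:
        summary["__mean__"] = sum(per_genus.values()) / len(per_genus)
    return rows, summary


def write_colour_counts_csv(rows, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["genus", "colour", "count"])
        for r in rows:
            writer.writerow([r.genus_token, r.colour_term, r.count])


def write_colour_summary_csv(summary, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["genus", "n_colours"])
        for genus, n in sorted(summary.items()):
            if genus != "__mean__":
                writer.writerow([genus, n])
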