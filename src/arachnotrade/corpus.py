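"""Saved-web-page ingestion and normalisation.

Pages arrive as saved HTML or plain text plus a manifest giving site, page
and snapshot-year metadata (contemporary scrape pages carry a null year).
Cleaning reduces each page to single-space-separated alphanumeric tokens so
that fixed-string name matching behaves identically regardless of the markup
the shop used.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import lxml.html

logger = logging.getLogger(__name__)

# \w is Unicode-aware (letters, digits, underscore); underscore is excluded
# explicitly so it behaves like punctuation.
_NON_ALNUM_RE = re.compile(r"[\W_]+", re.UNICODE)


@dataclass
class CleanPage:
    """One normalised page: space-separated alphanumeric tokens only."""

    site_id: str
    page_id: str
    snapshot_year: int | None  # None = contemporary snapshot
    text: str
    flagged_empty: bool = False
    flagged_decode: bool = False

    @property
    def n_chars(self) -> int:
        return len(self.text)

    @property
    def tokens(self) -> list[str]:
        return self.text.split(" ") if self.text else []


def _strip_markup(raw: str) -> str:
    """Drop HTML markup, including <script>/<style> content, keep text."""
    if "<" not in raw:
        return raw
    try:
        doc = lxml.html.fromstring(raw)
    except (lxml.etree.ParserError, ValueError):
        return raw
    for el in doc.iter("script", "style"):
        el.drop_tree()
    return doc.text_content()


def clean_html(raw: str | bytes) -> str:
    """Normalise a raw page blob to matching-ready text.

    Markup is stripped, every non-alphanumeric character becomes a space,
    runs of spaces collapse to one and the result is stripped.  Casing is
    preserved (matching is case-insensitive downstream); "alphanumeric"
    means Unicode letters and digits so diacritic names survive.
    Idempotent: cleaning already-clean text is a no-op.
    """
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8", errors="replace")
    text = _strip_markup(raw)
    return _NON_ALNUM_RE.sub(" ", text).strip()


def load_corpus(root, manifest) -> list[CleanPage]:
    """Load and clean every page listed in ``manifest``.

    The manifest CSV has columns ``path`` (relative to ``root``),
    ``site_id``, ``page_id`` and ``snapshot_year`` (empty = contemporary).
    A page that cleans to nothing is retained, flagged empty, so per-site
    page counts stay faithful to the manifest.
    """
    root = Path(root)
    pages: list[CleanPage] = []
    per_site: dict[str, int] = {}
    with open(manifest, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            path = root / row["path"]
            if not path.exists():
                raise FileNotFoundError(f"manifest entry missing on disk: {path}")
            raw = path.read_bytes()
            flagged_decode = False
            try:
                raw_text = raw.decode("utf-8")
            except UnicodeDecodeError:
                raw_text = raw.decode("utf-8", errors="replace")
                flagged_decode = True
            text = clean_html(raw_text)
            year_raw = (row.get("snapshot_year") or "").strip()
            page = CleanPage(
                site_id=row["site_id"],
                page_id=row["page_id"],
                snapshot_year=int(year_raw) if year_raw else None,
                text=text,
                flagged_empty=not text,
                flagged_decode=flagged_decode,
            )
            pages.append(page)
            per_site[page.site_id] = per_site.get(page.site_id, 0) + 1
    for site, n in sorted(per_site.items()):
        logger.info("site %s: %d pages", site, n)
    logger.info("corpus: %d pages from %d sites", len(pages), len(per_site))
    return pages


def write_corpus_store(pages, path) -> None:
    """Persist cleaned pages as JSON-lines (one CleanPage per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in pages:
            fh.write(json.dumps({
                "site_id": p.site_id,
                "page_id": p.page_id,
                "snapshot_year": p.snapshot_year,
                "text": p.text,
                "flagged_empty": p.flagged_empty,
            }) + "\n")


def read_corpus_store(path) -> list[CleanPage]:
    pages = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            pages.append(CleanPage(
                site_id=d["site_id"],
                page_id=d["page_id"],
                snapshot_year=d["snapshot_year"],
                text=d["text"],
                flagged_empty=d.get("flagged_empty", False),
            ))
    return pages
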