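"""Hierarchical genus-then-species search over cleaned shop pages.

Pages are reduced to alphanumeric tokens, genus tokens are located with a
left word boundary only, and only names historically housed in a detected
genus are searched for species hits.
"""

from arachnotrade import (
    TaxonRecord, build_name_index, clean_html, filter_spurious,
    hierarchical_search,
)
from arachnotrade.corpus import CleanPage

registry = [
    TaxonRecord(accepted_name="Cyriopagopus lividus", genus="Cyriopagopus",
                epithet="lividus", synonyms=["Haplopelma lividum"]),
    TaxonRecord(accepted_name="Neon levis", genus="Neon", epithet="levis"),
]
index = build_name_index(registry)

html = "<ul><li>Haplopelma lividum adults!</li><li>Neonate spiders</li></ul>"
page = CleanPage("shop1", "p1", None, clean_html(html))
print("cleaned text:", page.text)

detections = hierarchical_search(page, index)
for d in detections:
    print(f"  {d.match_kind:13s} genus={d.genus_token!r} -> {d.accepted_name}")

# 'Neonate' fires genus 'Neon' because only the left boundary is enforced;
# the packaged blocklist removes exactly such genus-only false positives.
kept, report = filter_spurious(detections)
print(f"after blocklist: {len(kept)} detections ({report['removed']} removed)")
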