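"""Colour co-occurrence around genus mentions: the novelty signal.

Sellers often append a colour ("sp. Electric Blue") instead of an epithet,
hinting at undescribed diversity.  Colour terms are counted inside the
3-before/4-after context window of each genus mention.
"""

from arachnotrade import build_colour_lexicon, count_colour_cooccurrence
from arachnotrade.matcher import Detection

detections = [
    Detection(site_id="s1", page_id="p1", snapshot_year=None,
              genus_token="chilobrachys", matched_name=None, accepted_name=None,
              match_kind="genus_only", context_before=["stunning"],
              context_after=["sp", "Electric", "Blue", "sling"]),
    Detection(site_id="s1", page_id="p2", snapshot_year=None,
              genus_token="chilobrachys", matched_name=None, accepted_name=None,
              match_kind="genus_only", context_before=["the", "blue"],
              context_after=["from", "Thailand"]),
]

lexicon = build_colour_lexicon()  # packaged colour list minus ambiguous terms
rows, summary = count_colour_cooccurrence(detections, lexicon)
for r in rows:
    print(f"  {r.genus_token} + {r.colour_term}: {r.count}")
print(f"mean distinct colours per genus keyword: {summary['__mean__']:.2f}")

# Each window counts a colour once, so repeated adjectives in one listing do
# not inflate the association between a genus and a colour.
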