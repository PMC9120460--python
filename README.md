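# arachnotrade

Monitoring the wildlife trade in arachnids (spiders, scorpions, whip
scorpions) from the text people actually trade with: online shop pages,
import ledgers and treaty databases.

Trade in invertebrates is vast but poorly monitored. Species are advertised
under junior synonyms or superseded genus placements, import ledgers record
genera without reconciling names, and range knowledge is often a sentence
("South America", "Thailand to Vietnam") rather than a map. `arachnotrade`
is a reusable pipeline that

- builds a **name index** from checklist exports with synonym histories, so
  any name a species ever carried resolves to its accepted binomial
  (abbreviated-genus synonyms like `G. rosea` are repaired by first-letter
  matching);
- runs a **hierarchical genus-then-species keyword search** over cleaned
  web pages: case-insensitive fixed-string matching with a left word
  boundary, genus hits first, then only the names historically housed in a
  detected genus — provably equivalent to a brute-force all-names scan;
- captures **context windows** (3 tokens before, 4 after) around genus
  mentions and counts colour-term co-occurrence, a proxy for undescribed
  "colour morph" diversity in trade;
- classifies **LEMIS**-style import records (whole-individual description
  codes `BOD EGL DEA LIV SPE SKI TRO`; sources `W` = wild vs `C F D R` =
  captive; purposes `M S Y` = non-commercial; disposition `S` = seized) and
  reads **CITES** gross-imports exports;
- integrates species across sources into per-species trade profiles with
  UpSet-style overlap counts, per-year trends, description-to-first-trade
  lags and per-website richness;
- digitises textual **range assertions** (country / region / "A to B" span
  / island) into standardised country sets — spans expand via a convex hull
  over country centroids — yielding single-country endemism and per-country
  trade exposure.

A seeded synthetic-data module generates checklists, shop pages, ledgers
and range assertions with recorded ground truth, so the whole pipeline is
testable end-to-end with exact-recovery checks and no downloads.

## Worked example

```python
from arachnotrade import TaxonRecord, build_name_index, clean_html, hierarchical_search
from arachnotrade.corpus import CleanPage

registry = [TaxonRecord(accepted_name="Cyriopagopus lividus", genus="Cyriopagopus",
                        epithet="lividus", synonyms=["Haplopelma lividum"])]
index = build_name_index(registry)
page = CleanPage("shop1", "p1", None, clean_html("<li>Haplopelma lividum adults!</li>"))
for d in hierarchical_search(page, index):
    print(d.match_kind, d.matched_name, "->", d.accepted_name)
```

prints

```
synonym Haplopelma lividum -> Cyriopagopus lividus
```

— the listing used a name superseded by a genus transfer, and the index
still attributes it to the right species. The `examples/` directory holds
one short script per capability (name resolution, page search, colour
signals, ledger classification, range digitisation, full pipeline); each
prints the numbers it computes with a note on what they mean. A thin CLI
(`arachnotrade index|clean|match|colours|lemis|ranges|synth|run`) wraps the
same functions for batch use.

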