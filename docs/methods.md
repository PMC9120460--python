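# Methods

This note documents the models, conventions and numerical choices behind
`arachnotrade`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Name registry and resolution

A checklist export supplies one row per accepted species with a packed list
of historical names. Names are normalised by lower-casing, collapsing
internal whitespace and stripping parenthetical authorities; matching is
byte-insensitive lowercase only — no collation of ligatures or diacritics,
because scientific names rarely carry them and fixed-string matching keeps
the search cheap and auditable. Subspecies (trinomial) rows are dropped:
shop listings and ledgers trade at the binomial level.

Abbreviated-genus synonyms (`G. rosea`) are expanded to the first genus in
that species' own listing whose initial letter matches, accepted genus
first, then genera of earlier-listed synonyms in order. This is a
heuristic: it can mis-expand when two candidate genera share an initial,
which is why unrepairable and repaired names are logged.

Homonyms (one name reaching two accepted species, possible across group
checklists) are never silently collapsed: both targets are kept in a
conflict record, resolution prefers a unique candidate within a supplied
group, and otherwise the lookup is flagged ambiguous. *Nomen dubium* names
stay in the search space by default but are tagged, since doubtful
application is a reason to annotate a detection, not to miss it.

## Page cleaning and matching semantics

Pages are reduced to single-space-separated alphanumeric tokens:
markup (including script/style content) is removed, then every
non-alphanumeric character becomes a space and runs collapse.
"Alphanumeric" means Unicode letters and digits, so diacritic names
survive. Cleaning is idempotent, and the token stream equals the maximal
alphanumeric runs of the input — both property-tested.

Matching is case-insensitive fixed-string with a **left boundary only**:
a genus fires wherever a token *starts with* it, so `Neon` fires inside
`Neonate`. This one-sided rule is deliberate — it mirrors how short genus
names behave as word prefixes in real shop text — and the packaged
blocklist of twenty such genus tokens removes genus-only hits from genera
that never yield a species hit. A strict both-boundary mode exists behind a
flag (default off). Species matching requires the full binomial as a
contiguous string: abbreviated genera and split binomials in page text are
*not* repaired, trading recall for auditability.

The hierarchical search (genus hits first, then only names historically
housed in that genus) is an optimisation with a proof obligation: on every
corpus the species-detection set must equal a brute-force scan of all
names. The suite checks this equivalence on 200 random corpora, adversarial
text included.

Multiple hits of one species on a page collapse to one for species lists
but keep full multiplicity for colour counting, since the colour analysis
counts mention-level co-occurrence.

## Colour co-occurrence

Each genus mention carries a context window of up to 3 tokens before and 4
after. Stop words (packaged static English list, configurable) are removed,
remaining tokens lower-cased and intersected with the colour lexicon — a
packaged single-token colour vocabulary (including descriptors such as
*electric*, *metallic*, *cobalt*) minus an ambiguity exclusion list
(*space*, *jungle*, *web*, ...). A window counts each distinct colour once;
raw token multiplicity is available behind a flag. Multi-word colour names
are matched as unigrams only, because cleaning destroys punctuation but not
adjacency and the descriptor tokens are informative on their own; a bigram
mode is a documented alternative.

## Trade-record classification

Summaries cover only description codes that plausibly represent whole
individuals — `BOD, EGL, DEA, LIV, SPE, SKI, TRO` — and are
quantity-weighted. Sources partition exactly: `W` → wild; `C, F, D, R` →
captive; everything else (including blank) → other. Purposes `M, S, Y`
count as non-commercial; disposition `S` marks seized. Quantities are
summed as given, with missing values treated as 0 (logged) and negative
rows rejected. The whole-individual filter is applied before any
percentage is computed. Per-genus summaries group by the genus **as
listed** in the ledger, with `Non-CITES entry`/missing placeholders
excluded and no synonymisation — ledgers are summarised on their own terms,
while species-level integration resolves names through the index.
Genus-only rows count for individuals but never for species overlap.

CITES gross-imports exports are read in the standard wide layout (taxon +
year columns) or a long fallback, filtered to 1975–2021, with unresolvable
taxa retained under their raw name and flagged.

## Cross-source integration

Species membership per source is computed under two bases: `exact_only`
(current accepted name matched) and `any_name` (any historical name); broad
summaries use `any_name`. Overlap counts are an exact partition over the
seven non-empty source combinations. "Unique to a year" means the species'
dated detection set across all sources is exactly that year; species seen
only in the undated contemporary snapshot are tallied separately and
excluded from lag statistics. Lag = first dated detection year minus
description year, computed for species described after 1999; negative lags
are retained and flagged. Per-site richness reports mean ± SE (sample
SD/√n) over sites with at least one species — the printed range of such
statistics starts at 1 — with the all-sites denominator emitted alongside.

## Range digitisation

Assertions come typed by their source sheet: country, region, span,
island. Countries standardise by exact or alias match against a reference
table; failures go to a correction worklist, never dropped. Regions expand
through a shipped, editable region → country table. Spans expand by
building the convex hull of the listed areas' country centroids on the raw
lon/lat plane and including every reference country whose centroid lies
inside or on it, always unioned with the listed countries. With fewer than
three distinct or collinear centroids the hull degenerates to the listed
set; spans straddling more than 180° of longitude are flagged
(`antimeridian_span`) and left unexpanded rather than mapped through an
ill-posed hull. Centroid-in-hull approximates intersecting the hull with
country polygons; at continental scale the approximation is adequate for an
inclusion test and keeps the pipeline free of border geometry — a polygon
mode can be added where borders are supplied. Dependent islands are
replaced by their sovereign country. Endemic means a single-country range.
The per-country exposure summary optionally drops genera with ≤ k traded
species before computing traded percentages (the popular-group variant).

## Synthetic study world

The generators emulate the study conditions end-to-end with recorded ground
truth. Defaults, chosen once: synonym rate 0.8 (≈1.8 names per species, the
regime of real checklist exports), corpus of 12 sites × 6 pages (half
archived 2014–2019, half contemporary), colour adjacency probability 0.4,
locality listings at 0.2; ledger of 2,000 records with ~92% whole-individual
codes, 70% wild sourcing, ~0.04% seizures and ~92% commercial purpose,
covering 25% of the registry's species (ledgers see far fewer species than
shop pages); 70% of shipments leave from a native country; endemism rate
0.764. Species appear in dated sources only from their description year
onward. Token vocabularies (genus syllables, epithet syllables, decoys,
localities, country names) are pairwise disjoint and uniform-length per
category, so no planted token is a prefix of an unrelated one and recovery
checks can demand exact equality. Generation is a pure function of the
seed (numpy `default_rng`; no hash-order dependence), so fixture bundles
are byte-identical across runs.

What passing these tests shows: the machinery is exact — matching semantics,
classification partitions, hull expansion and integration reproduce planted
truth perfectly. What it does not show: robustness to the messiness of real
data (misspellings, OCR noise, image-only listings, multilingual text,
incomplete synonymies, genuinely ambiguous ranges). The adversarial corpus
mode covers the known fixed-string failure modes (prefix traps, split
binomials) but not fuzzy variation, which the matcher deliberately does not
attempt.

## Problem sizes

The acceptance script uses a 400-species / 30-genus registry, a 30-site ×
8-page corpus, a 10,000-record ledger and a 24-country world; the test
suite uses smaller worlds per test. These sizes give stable percentages
while keeping any run comfortably under a minute on one CPU.

## Known limitations

- Live site discovery, crawling, archive retrieval and external API access
  are out of scope; the corpus contract is a manifest of saved pages.
- The hierarchical matcher cannot find species listed only under
  abbreviations, split names or images.
- The region → country table ships as an editable default; reproducing any
  particular study's connection counts requires that study's own table.
- Colour counting at the keyword level mixes genus tokens with any
  common-name keywords a caller adds; the keyword set is configurable.
- Scorpion-style manual range curation (removing clearly non-native
  occurrences, extinct species) is represented as explicit exclusion lists
  in configuration, not automated inference.
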