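"""Build a name index from a checklist and resolve trade-listing names.

Shops routinely advertise under junior synonyms; the index maps every name a
species ever carried back to its accepted binomial.
"""

from arachnotrade import TaxonRecord, build_name_index, resolve_name

registry = [
    TaxonRecord(accepted_name="Cyriopagopus lividus", genus="Cyriopagopus",
                epithet="lividus", family="Theraphosidae",
                description_year=1996, synonyms=["Haplopelma lividum"]),
    TaxonRecord(accepted_name="Grammostola rosea", genus="Grammostola",
                epithet="rosea", family="Theraphosidae",
                description_year=1837, synonyms=["Grammostola spathulata"]),
]
index = build_name_index(registry)

print(f"index holds {len(index)} names for {len(index.accepted_names)} species")
for raw in ("Haplopelma lividum", "GRAMMOSTOLA ROSEA", "Fakegenus nullus"):
    res = resolve_name(raw, index)
    print(f"  {raw!r:28s} -> {res.accepted_name} ({res.match_kind})")

# 'Haplopelma lividum' resolves as a synonym because the species moved genus;
# matching only the current name would miss such listings entirely.
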