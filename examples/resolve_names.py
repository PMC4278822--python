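"""Resolve deposited taxon names against a checklist.

Builds a small synthetic checklist containing the classic hard cases —
a cluster of one accepted name plus synonyms, a genus name accepted in
two families, and a misspelt species — then shows how parsing,
resolution, clade constraints and curation behave on each.
"""

from biocollate import (
    Checklist,
    ChecklistEntry,
    CladeConstraint,
    TaxonName,
    apply_curation,
    parse_taxon_name,
    resolve_name,
)

spider = {
    "kingdom": "Animalia", "phylum": "Arthropoda", "class": "Arachnida",
    "order": "Araneae", "family": "Salticidae", "genus": "Euophrys",
    "species": "Euophrys frontalis",
}
bee = {
    "kingdom": "Animalia", "phylum": "Arthropoda", "class": "Insecta",
    "order": "Hymenoptera", "family": "Colletidae", "genus": "Diphaglossa",
    "species": "Diphaglossa gayi",
}
beetle = lambda fam: {
    "kingdom": "Animalia", "phylum": "Arthropoda", "class": "Insecta",
    "order": "Coleoptera", "family": fam, "genus": "Notiophilus",
}

checklist = Checklist([
    ChecklistEntry("E1", "Euophrys frontalis", "species", "accepted", "E1", spider),
    ChecklistEntry("E2", "Euophrys frontalis", "species", "synonym", "E1", spider),
    ChecklistEntry("E3", "Euophrys frontalis", "species", "synonym", "E1", spider),
    ChecklistEntry("N1", "Notiophilus", "genus", "accepted", "N1", beetle("Carabidae")),
    ChecklistEntry("N2", "Notiophilus", "genus", "accepted", "N2", beetle("Erirhinidae")),
    ChecklistEntry("D1", "Diphaglossa gayi", "species", "accepted", "D1", bee),
])

# The parser strips authorities; common names parse nonsensically, on purpose.
for entered in ("Euophrys frontalis (Walckenaer, 1802)", "Black and White Casqued Hornbill"):
    print(f"parse {entered!r:45s} -> {parse_taxon_name(entered)!r}")

# One accepted record among synonyms: the accepted record wins.
res = resolve_name(checklist, "Euophrys frontalis")
print(f"\n'Euophrys frontalis' -> {res.mode}, {res.rank} {res.name} ({res.matched_entry})")

# A homonym genus: the lowest classification common to both records.
res = resolve_name(checklist, "Notiophilus")
print(f"'Notiophilus'        -> {res.mode}, {res.rank} {res.name}")

# A clade constraint (the study was of carabids) breaks the tie.
res = resolve_name(checklist, "Notiophilus", CladeConstraint("family", "Carabidae"))
print(f"'Notiophilus'|Carab. -> {res.mode}, family {res.classification['family']}")

# A typo resolves to nothing until a curator fixes the query name; the
# name entered and the parsed name are never touched.
taxon = TaxonName("T1", "ST1", "Diphaglosa gayi")
taxon.resolution = resolve_name(checklist, taxon.query_name)
print(f"\n'Diphaglosa gayi'    -> {taxon.resolution.mode}")
fixed = apply_curation(taxon, "Diphaglossa gayi", "typographical error", checklist)
print(f"after curation       -> {fixed.resolution.mode}, {fixed.resolution.name}; "
      f"log={fixed.curation_log}")
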