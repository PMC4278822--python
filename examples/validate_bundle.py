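"""Validate survey bundles with injected data-entry errors.

Generates a clean set of seeded study bundles, injects the classic
mistakes (impossible dates, negative conversion times, swapped
coordinates, duplicated names), and shows that the validator reports
exactly the injected issues — then asks for coordinate-fix suggestions
for a site that plots in the wrong country.
"""

import biocollate.validation as V
from biocollate.fixtures import FixtureSpec, gen_checklist, gen_regions, gen_survey
from biocollate.model import assemble_database

spec = FixtureSpec(
    seed=42,
    error_injection={
        V.INVALID_DATE: 1,
        V.NEGATIVE_CONVERSION_TIME: 1,
        V.COUNTRY_MISMATCH: 1,
        V.DUPLICATE_SITE_NAME: 1,
    },
)
checklist, _ = gen_checklist(spec)
regions = gen_regions(spec)
bundles, ledger = gen_survey(spec, checklist, regions)

db = assemble_database(bundles)
issues = V.validate_with_gis(db, regions.countries)

print(f"{len(ledger)} errors injected, {len(issues)} issues found:")
for issue in sorted(issues, key=lambda i: i.code):
    print(f"  [{issue.severity}] {issue.code:25s} {issue.record_ref}: {issue.message}")
assert sorted((i.code, i.record_ref) for i in issues) == sorted(ledger)

# For the country mismatch, evaluate the standard coordinate repairs.
mismatch_ref = next(r for c, r in ledger if c == V.COUNTRY_MISMATCH)
study_id, site_id = mismatch_ref.removeprefix("study ").split("/site ")
site = next(s for s in db.sites if s.study_id == study_id and s.site_id == site_id)
declared = db.source(db.study(study_id).source_id).declared_countries
fixes = V.suggest_coordinate_fixes(site, declared, regions.countries)
print(f"\nsuggested repairs for {mismatch_ref} (declared {declared}):")
for name, (lat, lon), dist in fixes:
    print(f"  {name:12s} -> ({lat:.3f}, {lon:.3f}), {dist:.0f} m from declared country")
# A repair at distance 0 lands inside the declared country; the
# suggestions are for human review, nothing is mutated automatically.
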