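"""Shared fixtures: one seeded synthetic world reused across the suite."""

import pytest

from biocollate.fixtures import FixtureSpec, gen_checklist, gen_regions, gen_survey
from biocollate.geo import annotate_sites
from biocollate.model import assemble_database
from biocollate.taxonomy import resolve_database

SEED = 20140331


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=SEED)

@pytest.fixture(scope="session")
def checklist_and_truth(spec):
    return gen_checklist(spec)

@pytest.fixture(scope="session")
def checklist(checklist_and_truth):
    return checklist_and_truth[0]

@pytest.fixture(scope="session")
def regions(spec):
    return gen_regions(spec)

@pytest.fixture()
def clean_bundles(spec, checklist, regions):
    # function-scoped: the underlying records are mutated by resolution
    bundles, ledger = gen_survey(spec, checklist, regions)
    assert ledger == []
    return bundles

@pytest.fixture()
def db(clean_bundles):
    """A freshly assembled database (function-scoped: tests mutate it)."""
    return assemble_database(clean_bundles)

@pytest.fixture()
def resolved_db(db, checklist):
    resolve_database(db, checklist)
    return db

@pytest.fixture()
def annotated_db(resolved_db, regions):
    return annotate_sites(resolved_db, regions.ecoregions, regions.countries, regions.hotspots)
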