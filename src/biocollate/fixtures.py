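"""Deterministic synthetic fixtures.

Every module in this package is exercisable without downloading any
real checklist, GIS layer or productivity raster: the generators here
emit structurally faithful stand-ins — a checklist with synonym
clusters, homonym pairs and cross-kingdom homonyms; survey bundles with
an exact ledger of injected data-entry errors; nested rectangular region
layers whose areas are computable in closed form; and paired ratings
drawn from a known joint distribution with their analytic kappa.

Everything is seeded: identical spec + seed give identical output.  Each
generator draws from its own pseudo-random stream, derived from the
master seed by a stable label, so adding a generator never shifts the
output of existing ones.

These fixtures emulate the *curation machinery's* inputs, not ecological
reality: abundance values are i.i.d. counts with no community structure,
and region polygons are rectangles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import box

from .agreement import PairedRatings
from .geo import NPPRaster, RegionLayer
from .model import PatchArea, SiteRecord, SourceRecord, StudyBundle, StudyRecord
from .siteattrs import (
    LandUse,
    LandUseClass,
    SecondaryStage,
    UseIntensity,
    all_land_uses,
    make_date_interval,
)
from .taxonomy import Checklist, ChecklistEntry, TaxonName


def _rng(seed: int, label: str) -> np.random.Generator:
    """A stream per generator: master seed + CRC32 of a stable label."""
    return np.random.default_rng([zlib.crc32(label.encode()), seed & 0x7FFFFFFF])


@dataclass
class FixtureSpec:
    """Sizes, rates and shapes for all generators."""

    seed: int = 0
    # survey shape
    n_sources: int = 2
    studies_per_source: int = 2
    sites_per_study: int = 6
    taxa_per_study: int = 8
    morphospecies_rate: float = 0.25
    blank_rate: float = 0.2
    #: injected error counts per validation code, e.g. {"INVALID_DATE": 2}
    error_injection: Dict[str, int] = field(default_factory=dict)
    # checklist shape
    n_accepted_species: int = 40
    n_same_name_synonym_clusters: int = 2  # accepted + synonyms sharing one name
    n_alias_synonym_clusters: int = 2  # synonyms under a different name
    n_homonym_pairs: int = 2  # one name accepted in two families
    n_cross_kingdom_homonyms: int = 1
    n_common_names: int = 3
    # region grid (all rectangles; areas closed-form)
    world_lon: Tuple[float, float] = (0.0, 40.0)
    world_lat: Tuple[float, float] = (-20.0, 20.0)
    hotspot_fraction: float = 0.25  # fraction of fixture land inside the hotspot
    npp_cellsize: float = 2.0


# ---------------------------------------------------------------------------
# Checklist

_CLADES = [
    # (kingdom, phylum, class, order, family)
    ("Animalia", "Arthropoda", "Insecta", "Coleoptera", "Carabidae"),
    ("Animalia", "Arthropoda", "Insecta", "Coleoptera", "Staphylinidae"),
    ("Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Apidae"),
    ("Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Formicidae"),
    ("Animalia", "Arthropoda", "Malacostraca", "Decapoda", "Portunidae"),
    ("Animalia", "Chordata", "Aves", "Accipitriformes", "Accipitridae"),
    ("Animalia", "Chordata", "Aves", "Strigiformes", "Strigidae"),
    ("Animalia", "Chordata", "Aves", "Passeriformes", "Muscicapidae"),
    ("Animalia", "Chordata", "Mammalia", "Chiroptera", "Pteropodidae"),
    ("Animalia", "Mollusca", "Gastropoda", "Stylommatophora", "Helicidae"),
    ("Plantae", "Tracheophyta", "Magnoliopsida", "Lamiales", "Orobanchaceae"),
    ("Plantae", "Tracheophyta", "Liliopsida", "Asparagales", "Asparagaceae"),
]

#: Bird species always present so that four-letter code expansion has a
#: realistic pool (includes a deliberate code collision pair).
_BIRD_POOL = [
    ("Accipiter badius", "Accipitriformes", "Accipitridae"),
    ("Accipiter nisus", "Accipitriformes", "Accipitridae"),
    ("Ketupa zeylonensis", "Strigiformes", "Strigidae"),
    ("Ficedula parva", "Passeriformes", "Muscicapidae"),
    ("Ficedula padma", "Passeriformes", "Muscicapidae"),  # FIPA collides with F. parva
]

_EPITHETS = (
    "gracilis", "robustus", "minor", "sylvatica", "montana", "vulgaris",
    "borealis", "australis", "punctata", "nitida", "obscura", "pallida",
)


def _classification(kingdom, phylum, cls, order, family, genus=None, species=None):
    out = {"kingdom": kingdom, "phylum": phylum, "class": cls, "order": order, "family": family}
    if genus:
        out["genus"] = genus
    if species:
        out["species"] = species
    return out


def gen_checklist(spec: FixtureSpec) -> Tuple[Checklist, Dict[str, Dict[str, str]]]:
    """Generate a checklist plus ground truth.

    The checklist contains unique accepted species spread across a fixed
    clade skeleton; clusters of one accepted name plus synonyms (both
    sharing the accepted name and under alias names); homonym pairs (one
    genus name accepted in two families of the same order); cross-kingdom
    homonyms; common-name entries; and a small pool of bird species for
    code expansion.

    Ground truth maps each engineered query name to its expected
    resolution ``{"mode": ..., "rank": ..., "name": ...}``.
    """
    rng = _rng(spec.seed, "checklist")
    entries: List[ChecklistEntry] = []
    truth: Dict[str, Dict[str, str]] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"COL{counter:05d}"

    def add_species(genus: str, epithet: str, clade, status="accepted", accepted_ref=None,
                    common_names=()) -> ChecklistEntry:
        name = f"{genus} {epithet}"
        eid = next_id()
        e = ChecklistEntry(
            entry_id=eid,
            name=name,
            rank="species",
            status=status,
            accepted_ref=accepted_ref or eid,
            classification=_classification(*clade, genus=genus, species=name),
            common_names=tuple(common_names),
        )
        entries.append(e)
        return e

    # plain accepted species; epithets stay purely alphabetic so the
    # name parser round-trips them
    genera_seen: Dict[str, Tuple[str, ...]] = {}
    for i in range(spec.n_accepted_species):
        clade = _CLADES[i % len(_CLADES)]
        genus = f"{clade[4][:-2]}ella{chr(ord('a') + (i // len(_CLADES)) % 26)}"
        epithet = _EPITHETS[i % len(_EPITHETS)] + chr(ord("a") + (i // len(_EPITHETS)) % 26)
        e = add_species(genus, epithet, clade)
        genera_seen[genus] = clade
        truth[e.name] = {"mode": "accepted_direct", "rank": "species", "name": e.name}

    # bird pool (fixed, for code expansion)
    for binom, order, family in _BIRD_POOL:
        genus = binom.split()[0]
        clade = ("Animalia", "Chordata", "Aves", order, family)
        e = add_species(genus, binom.split()[1], clade)
        genera_seen[genus] = clade
        truth[e.name] = {"mode": "accepted_direct", "rank": "species", "name": e.name}

    # genus-rank records, so morphospecies ("Genus sp. 1") resolve to genus
    for genus, clade in sorted(genera_seen.items()):
        eid = next_id()
        entries.append(
            ChecklistEntry(
                entry_id=eid,
                name=genus,
                rank="genus",
                status="accepted",
                accepted_ref=eid,
                classification=_classification(*clade, genus=genus),
            )
        )
        truth[genus] = {"mode": "accepted_direct", "rank": "genus", "name": genus}

    # accepted + synonyms under the same name
    for i in range(spec.n_same_name_synonym_clusters):
        clade = _CLADES[int(rng.integers(len(_CLADES)))]
        genus, epithet = f"Synonycla{i}", "communis"
        acc = add_species(genus, epithet, clade)
        for _ in range(2):
            add_species(genus, epithet, clade, status="synonym", accepted_ref=acc.entry_id)
        truth[acc.name] = {"mode": "accepted_direct", "rank": "species", "name": acc.name}

    # synonyms under an alias name pointing at a differently-named accepted
    for i in range(spec.n_alias_synonym_clusters):
        clade = _CLADES[int(rng.integers(len(_CLADES)))]
        acc = add_species(f"Validonia{i}", "vera", clade)
        alias = f"Obsoletia{i} antiqua"
        eid = next_id()
        entries.append(
            ChecklistEntry(
                entry_id=eid,
                name=alias,
                rank="species",
                status="synonym",
                accepted_ref=acc.entry_id,
                classification=_classification(*clade, genus=alias.split()[0], species=alias),
            )
        )
        truth[alias] = {"mode": "accepted_via_status", "rank": "species", "name": acc.name}

    # homonym pairs: one genus name accepted in two families, same order
    order_families: Dict[Tuple[str, ...], List[Tuple[str, ...]]] = {}
    for clade in _CLADES:
        order_families.setdefault(clade[:4], []).append(clade)
    two_family_orders = [fams for fams in order_families.values() if len(fams) >= 2]
    for i in range(spec.n_homonym_pairs):
        fams = two_family_orders[i % len(two_family_orders)]
        gname = f"Homonymus{i}"
        for clade in fams[:2]:
            eid = next_id()
            entries.append(
                ChecklistEntry(
                    entry_id=eid,
                    name=gname,
                    rank="genus",
                    status="accepted",
                    accepted_ref=eid,
                    classification=_classification(*clade, genus=gname),
                )
            )
        truth[gname] = {"mode": "lowest_common_rank", "rank": "order", "name": fams[0][3]}

    # cross-kingdom homonyms: a genus accepted in Animalia and Plantae
    animal = _CLADES[0]
    plant = _CLADES[-2]
    for i in range(spec.n_cross_kingdom_homonyms):
        gname = f"Ambiregnum{i}"
        for clade in (animal, plant):
            eid = next_id()
            entries.append(
                ChecklistEntry(
                    entry_id=eid,
                    name=gname,
                    rank="genus",
                    status="accepted",
                    accepted_ref=eid,
                    classification=_classification(*clade, genus=gname),
                )
            )
        truth[gname] = {"mode": "unmatched", "rank": "", "name": ""}

    # common names pointing at accepted species
    accepted_species = [e for e in entries if e.status == "accepted" and e.rank == "species"]
    for i in range(spec.n_common_names):
        target = accepted_species[int(rng.integers(len(accepted_species)))]
        cname = f"Common fixturebird {i}"
        eid = next_id()
        entries.append(
            ChecklistEntry(
                entry_id=eid,
                name=cname,
                rank="species",
                status="common_name",
                accepted_ref=target.entry_id,
                classification={},
            )
        )
        truth[cname] = {"mode": "accepted_via_status", "rank": "species", "name": target.name}

    return Checklist(entries), truth


# ---------------------------------------------------------------------------
# Regions and NPP


@dataclass
class RegionSet:
    ecoregions: RegionLayer
    countries: RegionLayer
    hotspots: RegionLayer
    raster: NPPRaster
    world_lon: Tuple[float, float]
    world_lat: Tuple[float, float]
    country_boxes: Dict[str, Tuple[float, float, float, float]]  # (lon0, lat0, lon1, lat1)


def gen_regions(spec: FixtureSpec) -> RegionSet:
    """Nested rectangular region layers and a 12-month NPP raster.

    The fixture world is the rectangle ``world_lon`` x ``world_lat``,
    treated as entirely terrestrial.  It is split into 2 realms (west /
    east), each into 2 biomes (south / north), each into 2 ecoregions
    (west / east), giving 8 ecoregions; a 2x2 grid of countries; and one
    hotspot covering ``hotspot_fraction`` of the land (a full-height
    rectangle, so the fraction is exact on the sphere).  The NPP grids
    have a cosine latitudinal profile with a mild seasonal cycle and no
    randomness.
    """
    lon0, lon1 = spec.world_lon
    lat0, lat1 = spec.world_lat
    lon_mid, lat_mid = (lon0 + lon1) / 2, (lat0 + lat1) / 2

    eco_features = []
    for ri, (rlon0, rlon1) in enumerate([(lon0, lon_mid), (lon_mid, lon1)]):
        realm = ["Western Realm", "Eastern Realm"][ri]
        for bi, (blat0, blat1) in enumerate([(lat0, lat_mid), (lat_mid, lat1)]):
            biome = f"{['Southern', 'Northern'][bi]} {['Forest', 'Savanna'][ri]}"
            bmid = (rlon0 + rlon1) / 2
            for ei, (elon0, elon1) in enumerate([(rlon0, bmid), (bmid, rlon1)]):
                eco_features.append(
                    (
                        box(elon0, blat0, elon1, blat1),
                        {
                            "ecoregion": f"Ecoregion {ri}{bi}{ei}",
                            "biome": biome,
                            "realm": realm,
                        },
                    )
                )
    ecoregions = RegionLayer("ecoregions", eco_features)

    country_features = []
    country_boxes = {}
    names = [["Aland", "Corland"], ["Borland", "Dorland"]]
    for ci, (clon0, clon1) in enumerate([(lon0, lon_mid), (lon_mid, lon1)]):
        for cj, (clat0, clat1) in enumerate([(lat0, lat_mid), (lat_mid, lat1)]):
            name = names[ci][cj]
            country_boxes[name] = (clon0, clat0, clon1, clat1)
            country_features.append(
                (
                    box(clon0, clat0, clon1, clat1),
                    {
                        "country": name,
                        "region": ["Southern Region", "Northern Region"][cj],
                        "subregion": f"{['West', 'East'][ci]} {['South', 'North'][cj]}",
                    },
                )
            )
    countries = RegionLayer("countries", country_features)

    hs_lon1 = lon0 + (lon1 - lon0) * spec.hotspot_fraction
    hotspots = RegionLayer(
        "hotspots", [(box(lon0, lat0, hs_lon1, lat1), {"hotspot": "Hotspot Alpha"})]
    )

    cs = spec.npp_cellsize
    ncols = int(round((lon1 - lon0) / cs))
    nrows = int(round((lat1 - lat0) / cs))
    months = np.empty((12, nrows, ncols))
    lat_span = max(abs(lat0), abs(lat1)) * 2
    for r in range(nrows):
        lat = lat1 - (r + 0.5) * cs  # row 0 northernmost
        base = 1.0 + np.cos(np.pi * lat / lat_span)
        for m in range(12):
            months[m, r, :] = base * (1.0 + 0.1 * np.cos(2 * np.pi * (m - 6) / 12.0))
    raster = NPPRaster(
        months=months,
        mask=np.ones((nrows, ncols)),
        xllcorner=lon0,
        yllcorner=lat0,
        cellsize=cs,
    )
    return RegionSet(ecoregions, countries, hotspots, raster, (lon0, lon1), (lat0, lat1), country_boxes)


# ---------------------------------------------------------------------------
# Survey bundles with injected errors

Ledger = List[Tuple[str, str]]  # (validation code, record ref)


def gen_survey(
    spec: FixtureSpec,
    checklist: Optional[Checklist] = None,
    regions: Optional[RegionSet] = None,
) -> Tuple[List[StudyBundle], Ledger]:
    """Generate clean study bundles, then inject data-entry errors.

    The clean bundles validate with zero issues (all mandatory fields
    present, coordinates well inside the declared country, valid dates,
    unique names, all matrix values positive so blanks read as zeros).
    ``spec.error_injection`` then maps validation codes to counts:
    swapped coordinates (COUNTRY_MISMATCH), impossible dates
    (INVALID_DATE), duplicate site/taxon names, negative conversion
    times.  Returns the bundles and an exact ledger of
    (code, record ref) pairs describing what was injected where.
    """
    from . import validation as V

    rng = _rng(spec.seed, "survey")
    if checklist is None:
        checklist, _ = gen_checklist(spec)
    if regions is None:
        regions = gen_regions(spec)

    species_pool = sorted(checklist.species_entries(), key=lambda e: e.entry_id)
    from collections import Counter

    name_counts = Counter(e.name for e in checklist.entries.values())
    # morphospecies genera must resolve uniquely (no homonym/cross-kingdom
    # names), or the clean bundle would not be clean
    genus_pool = sorted(
        e.name
        for e in checklist.entries.values()
        if e.rank == "genus" and e.status == "accepted" and name_counts[e.name] == 1
    )
    country_names = sorted(regions.country_boxes)
    land_uses = all_land_uses()
    intensities = list(UseIntensity)

    bundles: List[StudyBundle] = []
    for si in range(spec.n_sources):
        source_id = f"SRC{si + 1:03d}"
        country = country_names[int(rng.integers(len(country_names)))]
        clon0, clat0, clon1, clat1 = regions.country_boxes[country]
        source = SourceRecord(
            source_id=source_id,
            bibliographic_citation=f"Fixture et al. ({2005 + si}) Synthetic surveys {si + 1}.",
            declared_countries=[country],
            provenance_kind="journal article",
        )
        studies, sites, taxa = [], [], []
        matrices: Dict[str, pd.DataFrame] = {}
        for sj in range(spec.studies_per_source):
            study_id = f"{source_id}_ST{sj + 1}"
            studies.append(
                StudyRecord(
                    study_id=study_id,
                    source_id=source_id,
                    sampling_method=["pitfall traps", "transects"][sj % 2],
                    effort_unit=["trap nights", "meters"][sj % 2],
                    metric_type="abundance",
                )
            )
            site_ids = []
            for sk in range(spec.sites_per_study):
                year = 2005 + int(rng.integers(6))
                m1 = 1 + int(rng.integers(10))
                m2 = m1 + int(rng.integers(3))
                lu = land_uses[int(rng.integers(len(land_uses)))]
                lat = float(rng.uniform(clat0 + 1.0, clat1 - 1.0))
                lon = float(rng.uniform(clon0 + 1.0, clon1 - 1.0))
                site_id = f"P{sk + 1}"
                site_ids.append(site_id)
                sites.append(
                    SiteRecord(
                        site_id=site_id,
                        study_id=study_id,
                        latitude=lat,
                        longitude=lon,
                        habitat_description="synthetic habitat",
                        land_use=lu,
                        use_intensity=intensities[int(rng.integers(len(intensities)))],
                        fragmentation_layout=int(rng.integers(1, 6)),
                        patch_area=PatchArea.from_sentinel(
                            [None, -1.0, float(rng.integers(100, 10_000))][int(rng.integers(3))]
                        ),
                        max_linear_extent=float(rng.uniform(10, 1000)),
                        sampling_interval=make_date_interval(year, m1, None, year, m2, None),
                        raw_start=(year, m1, None),
                        raw_end=(year, m2, None),
                        effort=float(rng.integers(1, 50)),
                        time_since_conversion=(
                            float(rng.integers(0, 40)) if rng.random() < 0.5 else None
                        ),
                    )
                )
            # each study samples one focal phylum, as real surveys do
            phyla = sorted({e.classification["phylum"] for e in species_pool})
            focal = phyla[int(rng.integers(len(phyla)))]
            focal_species = [e for e in species_pool if e.classification["phylum"] == focal]
            focal_genera = [
                g for g in genus_pool
                if any(e.classification.get("genus") == g and
                       e.classification["phylum"] == focal for e in species_pool)
            ] or genus_pool
            taxon_ids = []
            used_names = set()
            for tk in range(spec.taxa_per_study):
                taxon_id = f"{study_id}_T{tk + 1}"
                if rng.random() < spec.morphospecies_rate:
                    genus = focal_genera[int(rng.integers(len(focal_genera)))]
                    name = f"{genus} sp. {tk + 1}"
                else:
                    name = focal_species[int(rng.integers(len(focal_species)))].name
                if name in used_names:  # keep the clean bundle duplicate-free
                    name = f"{name.split()[0]} sp. {tk + 1}"
                used_names.add(name)
                taxon_ids.append(taxon_id)
                taxa.append(TaxonName(taxon_id=taxon_id, study_id=study_id, name_entered=name))
            values = 1 + rng.poisson(3.0, size=(len(site_ids), len(taxon_ids))).astype(float)
            blank = rng.random(values.shape) < spec.blank_rate
            values[blank] = np.nan
            matrices[study_id] = pd.DataFrame(values, index=site_ids, columns=taxon_ids)
        bundles.append(StudyBundle(source, studies, sites, taxa, matrices))

    ledger: Ledger = []
    all_sites = [(b, s) for b in bundles for s in b.sites]
    order = rng.permutation(len(all_sites))
    cursor = 0

    def take_site() -> Tuple[StudyBundle, SiteRecord]:
        nonlocal cursor
        if cursor >= len(order):
            raise ValueError("not enough sites for the requested error injection")
        pair = all_sites[order[cursor]]
        cursor += 1
        return pair

    for _ in range(spec.error_injection.get(V.INVALID_DATE, 0)):
        _, site = take_site()
        site.raw_start = (site.raw_start[0], 1, 32)  # the 32nd of January
        site.sampling_interval = None
        ledger.append((V.INVALID_DATE, f"study {site.study_id}/site {site.site_id}"))

    for _ in range(spec.error_injection.get(V.NEGATIVE_CONVERSION_TIME, 0)):
        _, site = take_site()
        site.time_since_conversion = -3.0
        ledger.append((V.NEGATIVE_CONVERSION_TIME, f"study {site.study_id}/site {site.site_id}"))

    for _ in range(spec.error_injection.get(V.COUNTRY_MISMATCH, 0)):
        bundle, site = take_site()
        declared = bundle.source.declared_countries
        # swap latitude and longitude — the classic data-entry mistake
        swapped = (site.longitude, site.latitude)
        if (
            -90.0 <= swapped[0] <= 90.0
            and V.check_country_consistency(
                SiteRecord(site.site_id, site.study_id, swapped[0], swapped[1]),
                declared,
                regions.countries,
            )
            is not None
        ):
            site.latitude, site.longitude = swapped
        else:
            # swap would land back home; place the point squarely in a
            # neighbouring country instead (same observable mistake)
            other = next(c for c in country_names if c not in declared)
            olon0, olat0, olon1, olat1 = regions.country_boxes[other]
            site.latitude = (olat0 + olat1) / 2.0
            site.longitude = (olon0 + olon1) / 2.0
        ledger.append((V.COUNTRY_MISMATCH, f"study {site.study_id}/site {site.site_id}"))

    dup_site_studies: set = set()
    for _ in range(spec.error_injection.get(V.DUPLICATE_SITE_NAME, 0)):
        _, site = take_site()
        while site.study_id in dup_site_studies:
            _, site = take_site()
        dup_site_studies.add(site.study_id)
        bundle = next(b for b in bundles if site in b.sites)
        siblings = [s for s in bundle.sites if s.study_id == site.study_id and s is not site]
        target = siblings[0]
        matrix = bundle.matrices[site.study_id]
        matrix.rename(index={site.site_id: target.site_id}, inplace=True)
        site.site_id = target.site_id
        ledger.append((V.DUPLICATE_SITE_NAME, f"study {site.study_id}/site {site.site_id}"))

    dup_taxon_studies: set = set()
    for _ in range(spec.error_injection.get(V.DUPLICATE_TAXON_NAME, 0)):
        bundle, site = take_site()  # reuse the site stream to pick a study
        while site.study_id in dup_taxon_studies:
            bundle, site = take_site()
        dup_taxon_studies.add(site.study_id)
        study_taxa = [t for t in bundle.taxa if t.study_id == site.study_id]
        study_taxa[1].name_entered = study_taxa[0].name_entered
        study_taxa[1].parsed_name = study_taxa[0].parsed_name
        study_taxa[1].query_name = study_taxa[0].query_name
        ledger.append(
            (V.DUPLICATE_TAXON_NAME, f"study {site.study_id}/taxon {study_taxa[0].name_entered}")
        )

    return bundles, ledger


# ---------------------------------------------------------------------------
# Paired ratings with known agreement structure


def analytic_kappa(
    joint: np.ndarray, credit: Optional[np.ndarray] = None
) -> Dict[str, float]:
    """Population p_o, p_e and kappa of a joint rating distribution.

    ``joint[i, j]`` is the probability that rater 1 says category i and
    rater 2 says j; ``credit`` is an optional weight matrix (defaults to
    the identity credit).
    """
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 2 or joint.shape[0] != joint.shape[1]:
        raise ValueError("joint table must be square")
    if not np.isclose(joint.sum(), 1.0):
        raise ValueError("joint probabilities must sum to 1")
    if (joint < 0).any():
        raise ValueError("negative probability")
    k = joint.shape[0]
    w = np.eye(k) if credit is None else np.asarray(credit, dtype=float)
    r1 = joint.sum(axis=1)
    r2 = joint.sum(axis=0)
    p_o = float((w * joint).sum())
    p_e = float(r1 @ w @ r2)
    return {"p_o": p_o, "p_e": p_e, "kappa": (p_o - p_e) / (1.0 - p_e)}


def gen_ratings(
    spec: FixtureSpec,
    joint: np.ndarray,
    n: int,
    categories: Optional[Sequence] = None,
) -> Tuple[PairedRatings, Dict[str, float]]:
    """Draw ``n`` rating pairs from a known joint distribution.

    Returns the sample plus the analytic (population) p_o, p_e and kappa
    of the generating table, for recovery tests.
    """
    rng = _rng(spec.seed, "ratings")
    joint = np.asarray(joint, dtype=float)
    analytic = analytic_kappa(joint)  # also validates the table
    k = joint.shape[0]
    if categories is None:
        categories = [f"C{i}" for i in range(k)]
    flat = joint.ravel()
    draws = rng.choice(k * k, size=n, p=flat)
    pairs = [(categories[d // k], categories[d % k]) for d in draws]
    return PairedRatings(tuple(pairs), tuple(categories)), analytic
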