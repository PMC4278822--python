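"""Taxonomic name handling: parsing, checklist resolution, curation,
bird-code expansion, species counting and higher-group assignment.

Taxon names arrive in many forms — Latin binomials with or without
authorities, generic names, morphospecies labels ("Bracon sp. 1"),
higher ranks, common names, or bare codes.  Each taxon is represented by
three names: the *name entered* (exactly as deposited, never changed),
the *parsed name* (the putative Latin binomial extracted by the parser,
never changed) and the *query name* (initially the parsed name, altered
during curation with a recorded reason).  The query name is resolved
against an authoritative checklist — modelled on the Catalogue of Life
Annual Checklist, which provides a single accepted classification per
species — yielding a matched entry, rank and classification.

Resolution follows two disambiguation rules.  If a query returns several
records comprising exactly one accepted name (directly, or reachable via
the accepted-name pointers of synonyms/common names/misapplied names),
the accepted name wins: original identifiers are assumed authoritative.
If the records span zero or two-or-more distinct accepted names, the
taxon is placed at the lowest level of classification common to all
records.  A clade constraint ("consider only records within family
Carabidae") can be supplied to break homonym ties.
"""

from __future__ import annotations

import re
import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .model import SurveyDatabase

#: The rank ladder, shallowest to deepest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "infraspecies")

STATUSES = ("accepted", "synonym", "ambiguous_synonym", "misapplied", "common_name")

#: Tokens that mark open nomenclature / qualifiers; anything at or after
#: one of these is not part of the binomial.
_QUALIFIERS = {"sp", "spp", "cf", "aff", "gr", "nr", "indet"}


def normalize_name(name: str) -> str:
    """Case-insensitive, diacritic-folded key used for all name matching."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


def parse_taxon_name(name_entered: str) -> str:
    """Extract a putative Latin binomial from a deposited name.

    Every input is treated as a scientific name, so common names parse
    nonsensically ("Black and White Casqued Hornbill" -> "Black and") —
    such cases surface later in the review queue.  Grammar: the first
    token is taken as the genus; the second token is retained iff it is
    all-lowercase alphabetic and not an open-nomenclature qualifier
    (sp., cf., aff., ...); authorities (capitalised), years/digits,
    parentheticals and anything after a qualifier are dropped.
    """
    if not name_entered or not name_entered.strip():
        raise ValueError("empty taxon name")
    tokens = name_entered.split()
    genus = tokens[0].strip()
    if len(tokens) == 1:
        return genus
    second = tokens[1]
    bare = second.rstrip(".").casefold()
    if (
        second.rstrip(".").isalpha()
        and second == second.casefold()  # all-lowercase (no authority, no common-name word)
        and bare not in _QUALIFIERS
        and "(" not in second
    ):
        return f"{genus} {second}"
    return genus


@dataclass(frozen=True)
class CladeConstraint:
    """Restrict resolution to checklist records within one clade,
    e.g. ``CladeConstraint("kingdom", "Animalia")`` or
    ``CladeConstraint("family", "Carabidae")``."""

    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if not self.name:
            raise ValueError("constraint name empty")

    def admits(self, classification: Mapping[str, str]) -> bool:
        return normalize_name(classification.get(self.rank, "")) == normalize_name(self.name)


@dataclass
class ChecklistEntry:
    """One checklist record: a name with rank, status, classification and
    a pointer to its accepted record (self for accepted names)."""

    entry_id: str
    name: str
    rank: str
    status: str
    accepted_ref: str
    classification: Dict[str, str]
    common_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"entry {self.entry_id}: unknown rank {self.rank!r}")
        if self.status not in STATUSES:
            raise ValueError(f"entry {self.entry_id}: unknown status {self.status!r}")
        if self.status == "accepted" and self.accepted_ref != self.entry_id:
            raise ValueError(f"entry {self.entry_id}: accepted entry must point to itself")


class Checklist:
    """An in-memory checklist with a diacritic-folded name index covering
    scientific names and common names."""

    def __init__(self, entries: Iterable[ChecklistEntry]):
        self.entries: Dict[str, ChecklistEntry] = {}
        self._index: Dict[str, List[str]] = defaultdict(list)
        for e in entries:
            if e.entry_id in self.entries:
                raise ValueError(f"duplicate checklist entry id {e.entry_id!r}")
            self.entries[e.entry_id] = e
            self._index[normalize_name(e.name)].append(e.entry_id)
            for cn in e.common_names:
                self._index[normalize_name(cn)].append(e.entry_id)
        for e in self.entries.values():
            acc = self.entries.get(e.accepted_ref)
            if acc is None or acc.status != "accepted":
                raise ValueError(
                    f"entry {e.entry_id!r}: accepted_ref {e.accepted_ref!r} does not "
                    f"resolve to an accepted entry"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def accepted_of(self, entry: ChecklistEntry) -> ChecklistEntry:
        return self.entries[entry.accepted_ref]

    def effective_classification(self, entry: ChecklistEntry) -> Dict[str, str]:
        """An entry's classification, falling back to its accepted
        record's (common-name entries often carry none of their own)."""
        return entry.classification or self.accepted_of(entry).classification

    def search(self, query: str) -> List[ChecklistEntry]:
        """All entries whose scientific or common name matches ``query``
        (case-insensitive, diacritic-folded, otherwise exact)."""
        ids = self._index.get(normalize_name(query), [])
        # preserve insertion order, drop duplicates (name == common name)
        seen, out = set(), []
        for i in ids:
            if i not in seen:
                seen.add(i)
                out.append(self.entries[i])
        return out

    def species_entries(self) -> List[ChecklistEntry]:
        return [e for e in self.entries.values() if e.status == "accepted" and e.rank == "species"]


@dataclass
class Resolution:
    """Outcome of resolving one query name against the checklist."""

    matched_entry: Optional[str]
    rank: Optional[str]
    name: str
    classification: Dict[str, str]
    mode: str  # accepted_direct | accepted_via_status | lowest_common_rank | unmatched

    @property
    def matched(self) -> bool:
        return self.mode != "unmatched"


UNMATCHED = Resolution(None, None, "", {}, "unmatched")


def lowest_common_classification(
    classifications: Sequence[Mapping[str, str]],
) -> Optional[Tuple[str, str]]:
    """The deepest rank of the shared classification prefix, or None when
    the classifications share nothing (different kingdoms).

    Classifications are paths down the rank ladder, so agreement is
    hierarchical: the walk proceeds kingdom-to-infraspecies and stops at
    the first rank where the paths diverge (or are only partially
    present).  Homonym records that reuse one genus name in different
    families therefore resolve to the shared order, not to the
    coincidentally equal genus name.
    """
    if not classifications:
        raise ValueError("no classifications given")
    common = _common_map(classifications)
    if not common:
        return None
    rank = max(common, key=RANKS.index)
    return rank, common[rank]


def _common_map(classifications: Sequence[Mapping[str, str]]) -> Dict[str, str]:
    """Shared top-down classification prefix (empty map if none)."""
    out: Dict[str, str] = {}
    for rank in RANKS:
        present = [c.get(rank, "") for c in classifications]
        if all(not p for p in present):
            continue  # rank absent everywhere: skip without breaking the prefix
        names = {normalize_name(p) for p in present}
        if "" in names or len(names) != 1:
            break
        out[rank] = present[0]
    return out


def resolve_name(
    checklist: Checklist, query: str, constraint: Optional[CladeConstraint] = None
) -> Resolution:
    """Resolve a query name against the checklist.

    Search by scientific or common name; filter by the clade constraint
    if given; then apply the disambiguation rules described in the module
    docstring.  ``unmatched`` is a value, not an error.
    """
    results = checklist.search(query)
    if constraint is not None:
        results = [
            e for e in results if constraint.admits(checklist.effective_classification(e))
        ]
    if not results:
        return UNMATCHED

    accepted = {}
    for e in results:
        acc = checklist.accepted_of(e)
        accepted[acc.entry_id] = acc
    if len(accepted) == 1:
        acc = next(iter(accepted.values()))
        direct = any(e.status == "accepted" for e in results)
        return Resolution(
            matched_entry=acc.entry_id,
            rank=acc.rank,
            name=acc.name,
            classification=dict(acc.classification),
            mode="accepted_direct" if direct else "accepted_via_status",
        )

    # two or more distinct accepted names: lowest common classification
    classifications = [checklist.effective_classification(e) for e in results]
    common = lowest_common_classification(classifications)
    if common is None:
        return UNMATCHED
    rank, name = common
    return Resolution(
        matched_entry=None,
        rank=rank,
        name=name,
        classification=_common_map(classifications),
        mode="lowest_common_rank",
    )


@dataclass
class TaxonName:
    """A taxon as deposited within one study, with its three names and
    (once resolved) its checklist resolution and curation history."""

    taxon_id: str
    study_id: str
    name_entered: str
    parsed_name: str = ""
    query_name: str = ""
    resolution: Optional[Resolution] = None
    curation_log: List[Tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parsed_name:
            self.parsed_name = parse_taxon_name(self.name_entered)
        if not self.query_name:
            self.query_name = self.parsed_name


def resolve_database(
    db: "SurveyDatabase",
    checklist: Checklist,
    constraints: Optional[Mapping[str, CladeConstraint]] = None,
) -> None:
    """Resolve every taxon's query name in place.  ``constraints`` maps
    study ids to clade constraints; afterwards each study's lowest common
    taxon is recorded on the study record."""
    constraints = constraints or {}
    for taxon in db.taxa:
        taxon.resolution = resolve_name(
            checklist, taxon.query_name, constraints.get(taxon.study_id)
        )
    for study in db.studies:
        study.lowest_common_taxon = study_lowest_common_taxon(db, study.study_id)


def apply_curation(
    taxon: TaxonName,
    new_query: str,
    reason: str,
    checklist: Checklist,
    constraint: Optional[CladeConstraint] = None,
) -> TaxonName:
    """Curate a taxon: change its query name (recording why) and rerun
    the checklist query.  The name entered and parsed name are retained
    unchanged; repeated curations append to the log."""
    if not reason or not reason.strip():
        raise ValueError("a curation reason is required")
    if not new_query or not new_query.strip():
        raise ValueError("new query name is empty")
    updated = replace(
        taxon,
        query_name=new_query,
        curation_log=taxon.curation_log + [(taxon.query_name, new_query, reason)],
        resolution=resolve_name(checklist, new_query, constraint),
    )
    return updated


# ---------------------------------------------------------------------------
# Review queue


@dataclass(frozen=True)
class ReviewFlag:
    criterion: str  # UNMATCHED | HIGHER_RANK_BINOMIAL | INCONSISTENT_PARSED | IMPLAUSIBLE_STUDY_TAXON
    record_ref: str
    detail: str


def _looks_like_binomial(parsed_name: str) -> bool:
    return len(parsed_name.split()) >= 2


def _looks_like_common_name(name_entered: str) -> bool:
    tokens = name_entered.split()
    return len(tokens) >= 2 and any(t[:1].isupper() for t in tokens[1:])


def build_review_queue(db: "SurveyDatabase", checklist: Checklist) -> List[ReviewFlag]:
    """Flag taxa needing human curation.

    Criteria: (1) no matching checklist record; (2) a result above
    species rank for a name entered that looks like a binomial or a
    common name; (3) the same parsed name linking to different checklist
    records in different studies; (4) a study whose lowest common taxon
    falls outside its declared expected clade (a bird study should
    resolve within class Aves).
    """
    if any(t.resolution is None for t in db.taxa):
        raise ValueError("taxa not resolved: run resolve_database() first")
    flags: List[ReviewFlag] = []
    for t in db.taxa:
        res = t.resolution
        ref = f"study {t.study_id}/taxon {t.taxon_id}"
        if not res.matched:
            flags.append(ReviewFlag("UNMATCHED", ref, f"no checklist record for {t.query_name!r}"))
            continue
        if res.rank not in ("species", "infraspecies") and (
            _looks_like_binomial(t.parsed_name) or _looks_like_common_name(t.name_entered)
        ):
            flags.append(
                ReviewFlag(
                    "HIGHER_RANK_BINOMIAL",
                    ref,
                    f"{t.name_entered!r} resolved only to {res.rank} {res.name!r}",
                )
            )

    by_parsed: Dict[str, Dict[Optional[str], List[TaxonName]]] = defaultdict(lambda: defaultdict(list))
    for t in db.taxa:
        if t.resolution.matched and t.resolution.matched_entry is not None:
            by_parsed[normalize_name(t.parsed_name)][t.resolution.matched_entry].append(t)
    for parsed, groups in by_parsed.items():
        if len(groups) > 1:
            studies = {t.study_id for ts in groups.values() for t in ts}
            if len(studies) > 1:
                for ts in groups.values():
                    for t in ts:
                        flags.append(
                            ReviewFlag(
                                "INCONSISTENT_PARSED",
                                f"study {t.study_id}/taxon {t.taxon_id}",
                                f"parsed name {t.parsed_name!r} links to different "
                                f"records across studies",
                            )
                        )

    for study in db.studies:
        if study.expected_clade is None:
            continue
        rank, name = study.expected_clade
        common = study_common_classification(db, study.study_id)
        if normalize_name(common.get(rank, "")) != normalize_name(name):
            flags.append(
                ReviewFlag(
                    "IMPLAUSIBLE_STUDY_TAXON",
                    f"study {study.study_id}",
                    f"lowest common taxon {study.lowest_common_taxon} is not within "
                    f"{rank} {name}",
                )
            )
    return flags


# ---------------------------------------------------------------------------
# Bird codes


def expand_bird_code(code: str, pool: Sequence[ChecklistEntry]) -> Resolution:
    """Expand a four-letter bird code built from a binomial (first two
    letters of genus + first two of species epithet) against a pool of
    candidate species, e.g. the birds of the study's country.

    One candidate resolves to that species; several resolve to the
    lowest classification common to all matches (codes collide); none
    leaves the code unmatched.
    """
    if len(code) != 4 or not code.isalpha():
        raise ValueError(f"malformed bird code {code!r} (need 4 letters)")
    if not pool:
        raise ValueError("empty candidate pool")
    target = normalize_name(code)
    candidates = []
    for entry in pool:
        if entry.rank != "species":
            continue
        words = entry.name.split()
        if len(words) < 2:
            continue
        derived = (words[0][:2] + words[1][:2])
        if normalize_name(derived) == target:
            candidates.append(entry)
    if not candidates:
        return UNMATCHED
    if len(candidates) == 1:
        e = candidates[0]
        return Resolution(e.entry_id, e.rank, e.name, dict(e.classification), "accepted_direct")
    classifications = [e.classification for e in candidates]
    common = lowest_common_classification(classifications)
    if common is None:
        return UNMATCHED
    rank, name = common
    return Resolution(None, rank, name, _common_map(classifications), "lowest_common_rank")


# ---------------------------------------------------------------------------
# Best-guess binomial, higher groups, species counting


def best_guess_binomial(taxon: TaxonName) -> str:
    """Synthesise a genus+species string for joining to external trait
    databases.  Cascade: the resolved name if rank is species; the first
    two words of the resolved name if rank is infraspecies; the first two
    words of the parsed name if the rank is higher and the parsed name
    has two or more words; empty otherwise."""
    res = taxon.resolution
    if res is not None and res.matched:
        if res.rank == "species":
            return res.name
        if res.rank == "infraspecies":
            return " ".join(res.name.split()[:2])
    words = taxon.parsed_name.split()
    if len(words) >= 2:
        return " ".join(words[:2])
    return ""


def higher_group(classification: Mapping[str, str]) -> str:
    """Higher taxonomic group of a classification: (1) order where class
    is Insecta or Entognatha; (2) class where phylum is Arthropoda
    (excluding Insecta/Entognatha), Chordata or Tracheophyta; otherwise
    (3) phylum.  Returns "unplaced" when the needed rank is absent."""
    cls = classification.get("class", "")
    phylum = classification.get("phylum", "")
    if cls in ("Insecta", "Entognatha"):
        return classification.get("order", "") or "unplaced"
    if phylum in ("Arthropoda", "Chordata", "Tracheophyta"):
        return cls or "unplaced"
    return phylum or "unplaced"


def count_species(db: "SurveyDatabase") -> Tuple[Dict[str, int], int]:
    """Estimate the number of species per higher group.

    Names resolved to species or infraspecies rank are counted once per
    resolved name across the whole database; names resolved to higher
    ranks (morphospecies, genera, families...) are counted once per name
    per study — so identical morphospecies labels in two studies inflate
    the count, an ambiguity inherent in the deposited names.  Taxa that
    cannot be placed in a group are tallied under "unplaced".

    Returns (per-group counts, total).
    """
    keys_by_group: Dict[str, set] = defaultdict(set)
    for t in db.taxa:
        res = t.resolution
        if res is None:
            raise ValueError("taxa not resolved: run resolve_database() first")
        if res.matched and res.rank in ("species", "infraspecies"):
            group = higher_group(res.classification)
            keys_by_group[group].add(("by_name", normalize_name(res.name)))
        else:
            group = higher_group(res.classification) if res.matched else "unplaced"
            keys_by_group[group].add(("by_study", t.study_id, normalize_name(t.name_entered)))
    counts = {g: len(keys) for g, keys in keys_by_group.items()}
    return counts, sum(counts.values())


#: Roll-ups used to compare counts against described-species estimates.
GROUP_ROLLUPS = {
    "Magnoliophyta": ("Magnoliopsida", "Liliopsida"),
    "Gymnosperms": ("Pinopsida", "Gnetopsida"),
    "Ferns and allies": (
        "Polypodiopsida",
        "Lycopodiopsida",
        "Psilotopsida",
        "Equisetopsida",
        "Marattiopsida",
    ),
    "Crustacea": ("Malacostraca",),
}


def aggregate_group_counts(counts: Mapping[str, int]) -> Dict[str, int]:
    """Apply the comparison roll-ups (Magnoliophyta = Magnoliopsida +
    Liliopsida, etc.); groups not involved in a roll-up pass through."""
    rolled: Dict[str, int] = {}
    consumed = set()
    for target, members in GROUP_ROLLUPS.items():
        present = [m for m in members if m in counts]
        if present:
            rolled[target] = sum(counts[m] for m in present)
            consumed.update(present)
    for g, n in counts.items():
        if g not in consumed:
            rolled[g] = n
    return rolled


def match_attribute_names(
    binomials: Sequence[str],
    attribute_names: Sequence[str],
    genus_matching: bool = False,
) -> Tuple[int, int, int]:
    """Count best-guess binomials represented in an external attribute
    database: exact binomial matches first, then (optionally, for traits
    conserved within genera) generic-name matches among the binomials
    that had no species match.  Returns (species, genus, total)."""
    if not binomials or not attribute_names:
        raise ValueError("both name lists must be non-empty")
    attr = {normalize_name(a) for a in attribute_names}
    attr_genera = {normalize_name(a.split()[0]) for a in attribute_names}
    species = genus = 0
    for b in binomials:
        if normalize_name(b) in attr:
            species += 1
        elif genus_matching and normalize_name(b.split()[0]) in attr_genera:
            genus += 1
    return species, genus, species + genus


# ---------------------------------------------------------------------------
# Study-level taxonomy summaries


def study_common_classification(db: "SurveyDatabase", study_id: str) -> Dict[str, str]:
    """The classification shared by all matched taxa of a study (empty
    when nothing is shared or nothing matched)."""
    classifications = [
        t.resolution.classification
        for t in db.taxa_of(study_id)
        if t.resolution is not None and t.resolution.matched
    ]
    if not classifications:
        return {}
    common = lowest_common_classification(classifications)
    if common is None:
        return {}
    return _common_map(classifications)


def study_lowest_common_taxon(db: "SurveyDatabase", study_id: str) -> Optional[Tuple[str, str]]:
    classifications = [
        t.resolution.classification
        for t in db.taxa_of(study_id)
        if t.resolution is not None and t.resolution.matched
    ]
    if not classifications:
        return None
    return lowest_common_classification(classifications)


def study_taxonomic_group(db: "SurveyDatabase", study_id: str) -> str:
    """Higher taxonomic group of a study's lowest common taxon, falling
    back to the common taxon's own name when the shared classification
    stops above the rank the higher-group rules need (e.g. a study
    resolved only to phylum Chordata reports "Chordata")."""
    common = study_common_classification(db, study_id)
    if not common:
        return "unplaced"
    group = higher_group(common)
    if group == "unplaced":
        deepest = max(common, key=RANKS.index)
        return common[deepest]
    return group
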