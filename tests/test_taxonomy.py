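"""Taxonomy: parser, resolution rules, curation, codes, counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biocollate.model import SurveyDatabase, StudyRecord
from biocollate.taxonomy import (
    RANKS,
    Checklist,
    ChecklistEntry,
    CladeConstraint,
    TaxonName,
    aggregate_group_counts,
    apply_curation,
    best_guess_binomial,
    build_review_queue,
    count_species,
    expand_bird_code,
    higher_group,
    lowest_common_classification,
    match_attribute_names,
    normalize_name,
    parse_taxon_name,
    resolve_name,
)


class TestParser:
    @pytest.mark.parametrize(
        "entered,parsed",
        [
            ("Ancistrocerus trifasciatus Müll.", "Ancistrocerus trifasciatus"),
            ("Black and White Casqued Hornbill", "Black and"),
            ("Bracon sp. 1", "Bracon"),
            ("Bracon cf. variator", "Bracon"),
            ("Euophrys frontalis (Walckenaer, 1802)", "Euophrys frontalis"),
            ("Formicidae", "Formicidae"),
            ("Carabus 12", "Carabus"),
        ],
    )
    def test_parses(self, entered, parsed):
        assert parse_taxon_name(entered) == parsed

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parse_taxon_name("  ")


def _cls(kingdom=None, phylum=None, cls=None, order=None, family=None, genus=None, species=None):
    ranks = dict(kingdom=kingdom, phylum=phylum, order=order, family=family,
                 genus=genus, species=species)
    ranks["class"] = cls
    return {k: v for k, v in ranks.items() if v}


def _spider_cluster():
    """One accepted name plus two synonym records under the same name."""
    acc_cls = _cls("Animalia", "Arthropoda", "Arachnida", "Araneae", "Salticidae",
                   "Euophrys", "Euophrys frontalis")
    entries = [
        ChecklistEntry("E1", "Euophrys frontalis", "species", "accepted", "E1", acc_cls),
        ChecklistEntry("E2", "Euophrys frontalis", "species", "synonym", "E1", acc_cls),
        ChecklistEntry("E3", "Euophrys frontalis", "species", "synonym", "E1", acc_cls),
    ]
    return entries


def _beetle_homonyms():
    """One genus name accepted in two beetle families."""
    return [
        ChecklistEntry(
            "N1", "Notiophilus", "genus", "accepted", "N1",
            _cls("Animalia", "Arthropoda", "Insecta", "Coleoptera", "Carabidae", "Notiophilus"),
        ),
        ChecklistEntry(
            "N2", "Notiophilus", "genus", "accepted", "N2",
            _cls("Animalia", "Arthropoda", "Insecta", "Coleoptera", "Erirhinidae", "Notiophilus"),
        ),
    ]


class TestResolution:
    def test_accepted_name_wins_over_synonyms(self):
        cl = Checklist(_spider_cluster())
        res = resolve_name(cl, "Euophrys frontalis")
        assert res.mode == "accepted_direct"
        assert res.matched_entry == "E1"
        assert res.rank == "species"

    def test_homonyms_fall_back_to_lowest_common_rank(self):
        cl = Checklist(_beetle_homonyms())
        res = resolve_name(cl, "Notiophilus")
        assert res.mode == "lowest_common_rank"
        assert (res.rank, res.name) == ("order", "Coleoptera")

    def test_clade_constraint_breaks_the_tie(self):
        cl = Checklist(_beetle_homonyms())
        res = resolve_name(cl, "Notiophilus", CladeConstraint("family", "Carabidae"))
        assert res.mode == "accepted_direct"
        assert res.matched_entry == "N1"
        assert res.classification["family"] == "Carabidae"

    def test_synonym_under_alias_reaches_accepted_entry(self):
        acc_cls = _cls("Animalia", "Chordata", "Aves", "Falconiformes", "Falconidae",
                       "Falco", "Falco sparverius")
        cl = Checklist([
            ChecklistEntry("A1", "Falco sparverius", "species", "accepted", "A1", acc_cls),
            ChecklistEntry("A2", "Cerchneis sparveria", "species", "synonym", "A1",
                           _cls("Animalia", "Chordata", "Aves", "Falconiformes", "Falconidae",
                                "Cerchneis", "Cerchneis sparveria")),
        ])
        res = resolve_name(cl, "Cerchneis sparveria")
        assert res.mode == "accepted_via_status"
        assert res.name == "Falco sparverius"

    def test_no_result_is_unmatched_value(self):
        cl = Checklist(_spider_cluster())
        res = resolve_name(cl, "Diphaglosa gayi")
        assert res.mode == "unmatched" and res.classification == {}

    def test_single_entry_checklist_identity(self):
        entries = _spider_cluster()[:1]
        cl = Checklist(entries)
        res = resolve_name(cl, "Euophrys frontalis")
        assert res.matched_entry == entries[0].entry_id

    def test_diacritics_and_case_fold_in_matching(self):
        cl = Checklist(_spider_cluster())
        assert resolve_name(cl, "EUOPHRYS FRONTÁLIS".replace("Á", "a")).matched
        assert normalize_name("Müller") == normalize_name("MULLER".casefold().capitalize())

    def test_constrained_results_always_within_clade(self, checklist, checklist_and_truth):
        constraint = CladeConstraint("kingdom", "Plantae")
        for name in checklist_and_truth[1]:
            res = resolve_name(checklist, name, constraint)
            if res.matched:
                assert res.classification.get("kingdom", "Plantae") == "Plantae"


class TestLowestCommonClassification:
    def test_divergence_at_family_gives_order(self):
        maps = [e.classification for e in _beetle_homonyms()]
        assert lowest_common_classification(maps) == ("order", "Coleoptera")

    def test_single_map_is_its_own_deepest_rank(self):
        m = _cls("Animalia", "Chordata", "Mammalia", "Carnivora", "Canidae",
                 "Canis", "Canis lupus")
        assert lowest_common_classification([m]) == ("species", "Canis lupus")

    def test_different_kingdoms_share_nothing(self):
        a = _cls("Animalia", "Chordata")
        b = _cls("Plantae", "Tracheophyta")
        assert lowest_common_classification([a, b]) is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            lowest_common_classification([])

    @given(data=st.data())
    @settings(max_examples=1000, deadline=None)
    def test_agrees_with_brute_force_rank_scan(self, data):
        # random pair of classification paths over a small name alphabet
        def path(draw):
            depth = draw(st.integers(1, len(RANKS)))
            return {
                rank: draw(st.sampled_from(["Xa", "Xb", "Xc"])) + str(i)[:0] or
                draw(st.sampled_from(["Xa", "Xb", "Xc"]))
                for i, rank in enumerate(RANKS[:depth])
            }

        a = {r: data.draw(st.sampled_from(["Xa", "Xb", "Xc"])) for r in RANKS[: data.draw(st.integers(1, 8))]}
        b = {r: data.draw(st.sampled_from(["Xa", "Xb", "Xc"])) for r in RANKS[: data.draw(st.integers(1, 8))]}
        # brute force: walk the ladder from the top, stop at first divergence
        expected = None
        for rank in RANKS:
            va, vb = a.get(rank), b.get(rank)
            if va is None and vb is None:
                continue
            if va is None or vb is None or va != vb:
                break
            expected = (rank, va)
        assert lowest_common_classification([a, b]) == expected


class TestCuration:
    def test_typo_fix_appends_log_and_reresolves(self):
        acc_cls = _cls("Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Colletidae",
                       "Diphaglossa", "Diphaglossa gayi")
        cl = Checklist([ChecklistEntry("D1", "Diphaglossa gayi", "species", "accepted", "D1",
                                       acc_cls)])
        taxon = TaxonName("T1", "ST1", "Diphaglosa gayi")
        taxon.resolution = resolve_name(cl, taxon.query_name)
        assert not taxon.resolution.matched
        fixed = apply_curation(taxon, "Diphaglossa gayi", "typographical error", cl)
        assert fixed.resolution.matched_entry == "D1"
        assert len(fixed.curation_log) == 1
        assert fixed.name_entered == "Diphaglosa gayi"
        assert fixed.parsed_name == "Diphaglosa gayi"

    def test_repeated_curation_accumulates_log(self):
        cl = Checklist(_spider_cluster())
        taxon = TaxonName("T1", "ST1", "Euophris frontalis")
        once = apply_curation(taxon, "Euophrys frontallis", "first attempt", cl)
        twice = apply_curation(once, "Euophrys frontalis", "second attempt", cl)
        assert len(twice.curation_log) == 2
        assert twice.resolution.matched

    def test_empty_reason_rejected(self):
        cl = Checklist(_spider_cluster())
        with pytest.raises(ValueError, match="reason"):
            apply_curation(TaxonName("T1", "ST1", "Euophrys frontalis"), "X", " ", cl)


class TestReviewQueue:
    def test_clean_fixture_gives_empty_queue(self, resolved_db, checklist):
        assert build_review_queue(resolved_db, checklist) == []

    def test_unmatched_taxon_flagged(self, resolved_db, checklist):
        resolved_db.taxa[0].query_name = "Diphaglosa gayi"
        resolved_db.taxa[0].resolution = resolve_name(checklist, "Diphaglosa gayi")
        flags = build_review_queue(resolved_db, checklist)
        assert [f.criterion for f in flags] == ["UNMATCHED"]

    def test_bird_study_outside_aves_flagged(self, resolved_db, checklist):
        study = resolved_db.studies[0]
        study.expected_clade = ("class", "Aves")
        flags = build_review_queue(resolved_db, checklist)
        assert any(
            f.criterion == "IMPLAUSIBLE_STUDY_TAXON" and study.study_id in f.record_ref
            for f in flags
        )

    def test_binomial_resolving_above_species_flagged(self, checklist):
        cl = Checklist(_beetle_homonyms())
        db = SurveyDatabase()
        db.studies = [StudyRecord("ST1", "S1", "m", "u", "abundance")]
        t = TaxonName("T1", "ST1", "Notiophilus biguttatus")
        # no species record exists: a curator queried the genus, which
        # resolves to the homonyms' shared order — still above species
        t = apply_curation(t, "Notiophilus", "species not in checklist", cl)
        assert t.resolution.rank == "order"
        db.taxa = [t]
        flags = build_review_queue(db, cl)
        assert any(f.criterion == "HIGHER_RANK_BINOMIAL" for f in flags)


class TestBirdCodes:
    @pytest.fixture()
    def pool(self, checklist):
        return checklist.species_entries()

    def test_acba_expands_to_accipiter_badius(self, pool):
        res = expand_bird_code("ACBA", pool)
        assert res.name == "Accipiter badius" and res.rank == "species"

    def test_keze_expands_to_ketupa_zeylonensis(self, pool):
        res = expand_bird_code("KEZE", pool)
        assert res.name == "Ketupa zeylonensis"

    def test_collision_resolves_to_lowest_common_rank(self, pool):
        # FIPA matches both Ficedula parva and Ficedula padma
        res = expand_bird_code("FIPA", pool)
        candidates = [e for e in pool if e.name in ("Ficedula parva", "Ficedula padma")]
        expected = lowest_common_classification([e.classification for e in candidates])
        assert res.mode == "lowest_common_rank"
        assert (res.rank, res.name) == expected == ("genus", "Ficedula")

    def test_code_rederivation_recovers_input(self, pool):
        for code in ("ACBA", "KEZE", "ACNI"):
            res = expand_bird_code(code, pool)
            if res.rank == "species":
                g, e = res.name.split()[:2]
                assert (g[:2] + e[:2]).upper() == code

    def test_malformed_code_rejected(self, pool):
        with pytest.raises(ValueError):
            expand_bird_code("AC1A", pool)
        with pytest.raises(ValueError):
            expand_bird_code("ACBAX", pool)

    def test_unknown_code_is_unmatched(self, pool):
        assert not expand_bird_code("ZZZZ", pool).matched


class TestBestGuessBinomial:
    def _taxon(self, entered, rank=None, resolved_name=""):
        t = TaxonName("T1", "ST1", entered)
        if rank is not None:
            from biocollate.taxonomy import Resolution

            t.resolution = Resolution("X", rank, resolved_name, {"kingdom": "Animalia"},
                                      "accepted_direct")
        else:
            from biocollate.taxonomy import UNMATCHED

            t.resolution = UNMATCHED
        return t

    def test_species_rank_uses_resolved_name(self):
        t = self._taxon("Bombus pascuorum L.", "species", "Bombus pascuorum")
        assert best_guess_binomial(t) == "Bombus pascuorum"

    def test_infraspecies_truncates_to_two_words(self):
        t = self._taxon("x", "infraspecies", "Genus species subsp")
        assert best_guess_binomial(t) == "Genus species"

    def test_higher_rank_with_binomial_parsed_name(self):
        t = self._taxon("Unrecognita binomia Auth.", "genus", "Unrecognita")
        assert best_guess_binomial(t) == "Unrecognita binomia"

    def test_single_word_parsed_name_gives_empty(self):
        t = self._taxon("Bracon sp. 1", "genus", "Bracon")
        assert best_guess_binomial(t) == ""

    def test_unmatched_binomial_still_guessed_from_parsed(self):
        t = self._taxon("Diphaglosa gayi")
        assert best_guess_binomial(t) == "Diphaglosa gayi"


class TestHigherGroup:
    def test_bee_is_its_order(self):
        bee = _cls("Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Apidae")
        assert higher_group(bee) == "Hymenoptera"

    def test_wolf_is_its_class(self):
        wolf = _cls("Animalia", "Chordata", "Mammalia", "Carnivora")
        assert higher_group(wolf) == "Mammalia"

    def test_snail_is_its_phylum(self):
        snail = _cls("Animalia", "Mollusca", "Gastropoda")
        assert higher_group(snail) == "Mollusca"

    def test_entognatha_follows_the_insect_rule(self):
        springtail = _cls("Animalia", "Arthropoda", "Entognatha", "Collembola")
        assert higher_group(springtail) == "Collembola"

    def test_missing_needed_rank_is_unplaced(self):
        assert higher_group(_cls("Animalia", "Arthropoda", "Insecta")) == "unplaced"
        assert higher_group({}) == "unplaced"


def _morpho_db(checklist):
    """Two studies, each with three genus-rank morphospecies of one genus."""
    db = SurveyDatabase()
    db.studies = [
        StudyRecord("A", "S1", "m", "u", "abundance"),
        StudyRecord("B", "S1", "m", "u", "abundance"),
    ]
    genus = "Pteropodidella" + "a"  # a bat genus from the fixture checklist
    from biocollate.taxonomy import resolve_name as _resolve

    for study in ("A", "B"):
        for i in (1, 2, 3):
            t = TaxonName(f"{study}{i}", study, f"Eonycteris sp. {i}")
            t.resolution = _resolve(checklist, "Pteropodidellaa")
            db.taxa.append(t)
    return db


class TestCountSpecies:
    def test_morphospecies_counted_once_per_study(self, checklist):
        counts, total = count_species(_morpho_db(checklist))
        assert total == 6  # three per study, inflated across two studies

    def test_species_rank_names_counted_once_globally(self, checklist):
        db = SurveyDatabase()
        db.studies = [StudyRecord("A", "S1", "m", "u", "abundance"),
                      StudyRecord("B", "S1", "m", "u", "abundance")]
        name = checklist.species_entries()[0].name
        for study in ("A", "B"):
            t = TaxonName(f"{study}1", study, name)
            t.resolution = resolve_name(checklist, name)
            db.taxa.append(t)
        counts, total = count_species(db)
        assert total == 1

    def test_empty_database_counts_zero(self):
        counts, total = count_species(SurveyDatabase())
        assert total == 0 and counts == {}

    def test_total_invariant_to_taxon_order(self, resolved_db):
        _, total = count_species(resolved_db)
        resolved_db.taxa = list(reversed(resolved_db.taxa))
        _, total2 = count_species(resolved_db)
        assert total == total2

    def test_merging_disjoint_databases_is_subadditive(self, checklist):
        db1 = _morpho_db(checklist)
        _, t1 = count_species(db1)
        db2 = SurveyDatabase()
        db2.studies = list(db1.studies)
        db2.taxa = list(db1.taxa)
        merged = SurveyDatabase()
        merged.studies = db1.studies + db2.studies
        merged.taxa = db1.taxa + db2.taxa
        _, tm = count_species(merged)
        assert tm <= t1 + t1


class TestGroupAggregation:
    def test_flowering_plants_roll_up(self):
        assert aggregate_group_counts({"Magnoliopsida": 3, "Liliopsida": 2}) == {
            "Magnoliophyta": 5
        }

    def test_gymnosperms_roll_up_with_zero_member(self):
        out = aggregate_group_counts({"Pinopsida": 1, "Gnetopsida": 0})
        assert out["Gymnosperms"] == 1

    def test_unlisted_groups_pass_through(self):
        assert aggregate_group_counts({"Aves": 7}) == {"Aves": 7}

    def test_crustacea_from_malacostraca(self):
        assert aggregate_group_counts({"Malacostraca": 4})["Crustacea"] == 4


class TestAttributeMatching:
    def test_species_matches_only(self):
        assert match_attribute_names(["Aus bus", "Cus dus"], ["Aus bus"]) == (1, 0, 1)

    def test_genus_match_counts_only_without_species_match(self):
        assert match_attribute_names(["Aus bus"], ["Aus xus"], genus_matching=True) == (0, 1, 1)

    def test_disjoint_sets_match_nothing(self):
        assert match_attribute_names(["Aus bus"], ["Cus dus"], genus_matching=True) == (0, 0, 0)

    def test_genus_matching_off_by_default(self):
        assert match_attribute_names(["Aus bus"], ["Aus xus"]) == (0, 0, 0)
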