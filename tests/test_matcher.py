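import dataclasses

import pytest

from arachnotrade.corpus import CleanPage
from arachnotrade.matcher import (
    DEFAULT_BLOCKLIST,
    brute_force_species_search,
    capture_context,
    collapse_per_page,
    filter_spurious,
    find_genus_mentions,
    hierarchical_search,
)
from arachnotrade.taxonomy import TaxonRecord, build_name_index


class TestGenusMentions:
    def test_simple_hit(self, micro_index, page_factory):
        page = page_factory("buy Grammostola now")
        assert find_genus_mentions(page, micro_index.genus_to_names) == [
            ("grammostola", 1)]

    def test_no_left_boundary_no_hit(self, micro_index, page_factory):
        page = page_factory("xGrammostola")
        assert find_genus_mentions(page, micro_index.genus_to_names) == []

    def test_right_boundary_unconstrained(self, micro_index, page_factory):
        """Genus 'Neon' fires inside 'Neonate' — the one-sided behaviour the
        blocklist exists to clean up."""
        page = page_factory("Neonate spiders")
        assert find_genus_mentions(page, micro_index.genus_to_names) == [("neon", 0)]
        assert find_genus_mentions(page, micro_index.genus_to_names,
                                   strict_boundaries=True) == []


class TestCaptureContext:
    def test_start_of_page_truncates_before(self):
        before, after = capture_context(["Genus", "a", "b"], 0)
        assert before == [] and after == ["a", "b"]

    def test_full_window(self):
        tokens = "big beautiful blue Chilobrachys sp Electric Blue sling".split()
        before, after = capture_context(tokens, 3)
        assert before == ["big", "beautiful", "blue"]
        assert after == ["sp", "Electric", "Blue", "sling"]

    def test_single_token_page(self):
        before, after = capture_context(["Genus"], 0)
        assert before == [] and after == []


class TestHierarchicalSearch:
    def test_synonym_detected_and_resolved(self, micro_index, page_factory):
        page = page_factory("offer Haplopelma lividum adults")
        (det,) = [d for d in hierarchical_search(page, micro_index)
                  if d.match_kind != "genus_only"]
        assert det.accepted_name == "Cyriopagopus lividus"
        assert det.match_kind == "synonym"
        assert det.matched_name == "Haplopelma lividum"

    def test_genus_only_detection(self, micro_index, page_factory):
        page = page_factory("large Pandinus in stock")
        (det,) = hierarchical_search(page, micro_index)
        assert det.match_kind == "genus_only"
        assert det.genus_token == "pandinus"
        assert det.context_before == ["large"]

    def test_split_binomial_not_detected(self, micro_index, page_factory):
        page = page_factory("Grammostola beautiful pulchra")
        dets = hierarchical_search(page, micro_index)
        assert all(d.match_kind == "genus_only" for d in dets)

    def test_epithet_alone_not_detected(self, micro_index, page_factory):
        assert hierarchical_search(page_factory("pulchra for sale"), micro_index) == []

    def test_case_insensitive_fixed_string(self, micro_index, page_factory):
        page = page_factory("GRAMMOSTOLA PULCHRA slings")
        (det,) = [d for d in hierarchical_search(page, micro_index)
                  if d.match_kind != "genus_only"]
        assert det.accepted_name == "Grammostola pulchra"
        assert det.match_kind == "exact_current"


def _species_set(detections):
    return {(d.site_id, d.page_id, d.position,
             d.matched_name.lower()) for d in detections
            if d.match_kind != "genus_only"}


class TestEquivalenceOracle:
    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("adversarial", [False, True])
    def test_hierarchical_equals_brute_force(self, seed, adversarial):
        """The genus pre-filter is an optimisation, not a semantics change."""
        from arachnotrade.corpus import clean_html
        from arachnotrade.synth import gen_corpus, gen_registry
        records, _ = gen_registry(n_species=15, n_genera=4, synonym_rate=1.0,
                                  seed=seed)
        index = build_name_index(records)
        pages_spec, _ = gen_corpus(records, n_sites=3, pages_per_site=3,
                                   species_per_page=3, adversarial=adversarial,
                                   seed=seed)
        for site, pid, year, html in pages_spec:
            page = CleanPage(site, pid, year, clean_html(html))
            assert _species_set(hierarchical_search(page, index)) == \
                brute_force_species_search(page, index)

    def test_monotone_in_synonyms(self, page_factory):
        """Adding a synonym never removes detections."""
        base = TaxonRecord(accepted_name="Aaxx bbyy", genus="Aaxx", epithet="bbyy")
        richer = dataclasses.replace(base, synonyms=["Cczz ddww"])
        page = page_factory("Aaxx bbyy and Cczz ddww on offer")
        small = _species_set(hierarchical_search(page, build_name_index([base])))
        big = _species_set(hierarchical_search(page, build_name_index([richer])))
        assert small <= big
        assert len(big) == 2


class TestFilterSpurious:
    def _genus_only(self, token, page_factory, index):
        page = page_factory(f"{token}ate spiders")
        return hierarchical_search(page, index)

    def test_blocklisted_genus_only_removed(self, micro_index, page_factory):
        dets = hierarchical_search(page_factory("Neonate spiders"), micro_index)
        kept, report = filter_spurious(dets, DEFAULT_BLOCKLIST)
        assert kept == []
        assert report["removed"] == 1

    def test_species_detection_in_blocklisted_genus_retained(
            self, micro_index, page_factory):
        dets = hierarchical_search(
            page_factory("Neon levis beside Neonate spiders"), micro_index)
        kept, report = filter_spurious(dets, DEFAULT_BLOCKLIST)
        assert any(d.accepted_name == "Neon levis" for d in kept)
        assert report["warnings"]  # blocklist rationale violated -> warning

    def test_empty_blocklist_identity(self, micro_index, page_factory):
        dets = hierarchical_search(page_factory("Neonate Pandinus stock"),
                                   micro_index)
        kept, _ = filter_spurious(dets, set())
        assert kept == dets

    def test_audit_lists_genus_only_genera_without_species(
            self, micro_index, page_factory):
        dets = hierarchical_search(
            page_factory("Pandinus stock and Grammostola pulchra"), micro_index)
        _, report = filter_spurious(dets, DEFAULT_BLOCKLIST)
        assert report["review_candidates"] == ["pandinus"]


class TestPlantedTruth:
    def test_perfect_recovery_without_adversarial_text(self):
        from arachnotrade.corpus import clean_html
        from arachnotrade.synth import gen_corpus, gen_registry
        records, truth = gen_registry(n_species=30, n_genera=6, synonym_rate=1.0,
                                      seed=4)
        index = build_name_index(records)
        pages_spec, truth = gen_corpus(records, n_sites=6, pages_per_site=4,
                                       species_per_page=4, adversarial=False,
                                       seed=4, truth=truth)
        got = {}
        for site, pid, year, html in pages_spec:
            page = CleanPage(site, pid, year, clean_html(html))
            for d in hierarchical_search(page, index):
                if d.match_kind != "genus_only":
                    got.setdefault((site, pid), set()).add(d.accepted_name)
        expected = {k: v for k, v in truth.planted_species_per_page.items() if v}
        assert got == expected  # precision = recall = 1

    def test_adversarial_traps_not_detected_as_species(self):
        from arachnotrade.corpus import clean_html
        from arachnotrade.synth import gen_corpus, gen_registry
        records, truth = gen_registry(n_species=20, n_genera=5, seed=6)
        index = build_name_index(records)
        pages_spec, truth = gen_corpus(records, n_sites=4, pages_per_site=4,
                                       species_per_page=2, adversarial=True,
                                       seed=6, truth=truth)
        for site, pid, year, html in pages_spec:
            page = CleanPage(site, pid, year, clean_html(html))
            species = {d.accepted_name for d in hierarchical_search(page, index)
                       if d.match_kind != "genus_only"}
            assert species == truth.planted_species_per_page[(site, pid)]


def test_collapse_per_page_keeps_presence_only(micro_index, page_factory):
    page = page_factory("Grammostola pulchra and again Grammostola pulchra")
    dets = [d for d in hierarchical_search(page, micro_index)
            if d.match_kind != "genus_only"]
    assert len(dets) == 2
    assert len(collapse_per_page(dets)) == 1
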