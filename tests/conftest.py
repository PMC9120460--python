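import pytest

from arachnotrade import build_name_index
from arachnotrade.corpus import CleanPage
from arachnotrade.taxonomy import TaxonRecord


@pytest.fixture(scope="session")
def micro_registry():
    """Hand-built registry of real arachnid names exercising every case:
    a synonym that is a genus transfer (Haplopelma lividum), a jumping
    spider whose genus collides with an English word prefix (Neon), and a
    scorpion genus for genus-only hits (Pandinus)."""
    return [
        TaxonRecord(
            accepted_name="Grammostola pulchra", genus="Grammostola",
            epithet="pulchra", family="Theraphosidae", group="spider",
            description_year=1921,
        ),
        TaxonRecord(
            accepted_name="Grammostola rosea", genus="Grammostola",
            epithet="rosea", family="Theraphosidae", group="spider",
            description_year=1837, synonyms=["Grammostola spathulata"],
        ),
        TaxonRecord(
            accepted_name="Cyriopagopus lividus", genus="Cyriopagopus",
            epithet="lividus", family="Theraphosidae", group="spider",
            description_year=1996, synonyms=["Haplopelma lividum"],
        ),
        TaxonRecord(
            accepted_name="Chilobrachys dyscolus", genus="Chilobrachys",
            epithet="dyscolus", family="Theraphosidae", group="spider",
            description_year=1895,
        ),
        TaxonRecord(
            accepted_name="Neon levis", genus="Neon", epithet="levis",
            family="Salticidae", group="spider", description_year=1871,
        ),
        TaxonRecord(
            accepted_name="Pandinus imperator", genus="Pandinus",
            epithet="imperator", family="Scorpionidae", group="scorpion",
            description_year=1841,
        ),
    ]


@pytest.fixture(scope="session")
def micro_index(micro_registry):
    return build_name_index(micro_registry)


def make_page(text, site_id="s1", page_id="p1", snapshot_year=None):
    return CleanPage(site_id=site_id, page_id=page_id,
                     snapshot_year=snapshot_year, text=text)


@pytest.fixture
def page_factory():
    return make_page
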