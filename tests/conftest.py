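import hypothesis

import pytest

from egt_screen import TaxonEntry, TaxonScheme

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def toy_scheme() -> TaxonScheme:
    """Small mixed-domain scheme used across the unit tests."""
    entries = {
        "GAV001": TaxonEntry("Goniomonas_avonlea", "Goniomonadea", "Eukaryota"),
        "GTH001": TaxonEntry("Guillardia_theta", "Cryptophyceae", "Eukaryota"),
        "RHO001": TaxonEntry("Porphyra_sp", "Rhodophyta", "Eukaryota"),
        "RHO002": TaxonEntry("Chondrus_sp", "Rhodophyta", "Eukaryota"),
        "VIR001": TaxonEntry("Arabidopsis_sp", "Viridiplantae", "Eukaryota"),
        "GLA001": TaxonEntry("Cyanophora_sp", "Glaucophyta", "Eukaryota"),
        "STR001": TaxonEntry("Thalassiosira_sp", "Stramenopiles", "Eukaryota"),
        "ALV001": TaxonEntry("Plasmodium_sp", "Alveolata", "Eukaryota"),
        "AMO001": TaxonEntry("Dictyostelium_sp", "Amoebozoa", "Eukaryota"),
        "BAC001": TaxonEntry("Escherichia_sp", "Bacteria", "Bacteria"),
        "BAC002": TaxonEntry("Bacillus_sp", "Bacteria", "Bacteria"),
        "ARC001": TaxonEntry("Sulfolobus_sp", "Archaea", "Archaea"),
    }
    return TaxonScheme(entries)
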