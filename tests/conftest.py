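import pytest

from cladesubs.msa import Msa
from cladesubs.records import SpeciesConfig


@pytest.fixture(scope="session")
def panel() -> SpeciesConfig:
    """Two-foreground / nine-outgroup mammalian-style panel used throughout."""
    return SpeciesConfig(
        foreground_species=("ags", "itri"),
        outgroup_species=(
            "mmus", "rnor", "sara", "pabe", "hsap", "ecab", "btau", "ocun", "sscr"
        ),
        reference_species=("hsap", "mmus", "itri"),
    )


def make_msa(columns: list[str], species: list[str], gene: str = "GENE1") -> Msa:
    """Build an Msa from a list of column strings (one char per species)."""
    rows = {
        sp: "".join(col[i] for col in columns) for i, sp in enumerate(species)
    }
    return Msa(gene, rows)


@pytest.fixture(scope="session")
def panel_species(panel) -> list[str]:
    return list(panel.all_species)
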