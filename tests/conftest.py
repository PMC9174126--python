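import pytest
from hypothesis import HealthCheck, settings

from fucoquant.chem import (
    NTERM,
    GlycanComposition,
    Glycopeptide,
    default_mass_table,
    standard_modifications,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

REMNANT_FUC = GlycanComposition({"HexNAc": 1, "dHex": 1}, core_fucosylated=True)
REMNANT_PLAIN = GlycanComposition({"HexNAc": 1})


@pytest.fixture(scope="session")
def table():
    return default_mass_table()


@pytest.fixture(scope="session")
def mods():
    return standard_modifications(tmt=True)


@pytest.fixture(scope="session")
def sparc_mouse_glycopeptide(mods):
    """The TMT-labelled, Endo F3-simplified mouse glycopeptide VCSNDNK:
    TMT6 on the N-terminus and K7, carbamidomethyl C2, core-fucosylated
    remnant on N6."""
    return Glycopeptide(
        "VCSNDNK",
        mods=(
            (NTERM, mods["TMT6-Nterm"]),
            (2, mods["Carbamidomethyl"]),
            (7, mods["TMT6-K"]),
        ),
        glyco_site=6,
        glycan=REMNANT_FUC,
    )


@pytest.fixture(scope="session")
def sparc_human_peptide(mods):
    """Label-free human tryptic peptide LHLDYIGPCK with carbamidomethyl C9."""
    return Glycopeptide("LHLDYIGPCK", mods=((9, mods["Carbamidomethyl"]),))


@pytest.fixture(scope="session")
def sparc_human_glycopeptide(mods):
    """Label-free human glycopeptide VCSNDNKTFDSSCHFFATK with both cysteines
    carbamidomethylated and the core-fucosylated remnant on N6 (the N116
    site in protein numbering)."""
    return Glycopeptide(
        "VCSNDNKTFDSSCHFFATK",
        mods=((2, mods["Carbamidomethyl"]), (13, mods["Carbamidomethyl"])),
        glyco_site=6,
        glycan=REMNANT_FUC,
        missed_cleavages=1,
    )
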