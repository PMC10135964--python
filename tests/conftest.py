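import pytest

from inspeq.chem_model import ChemicalModel, SpeciesDef, load_builtin


@pytest.fixture(scope="session")
def insp8():
    return load_builtin("insp8")


@pytest.fixture(scope="session")
def insp8_h(insp8):
    """H+-only protonation ladder of the InsP8 model."""
    return insp8.protonation_only()


@pytest.fixture(scope="session")
def insp8_k(insp8):
    """InsP8 with protonation states and K+ complexes (no Mg)."""
    return insp8.subset(lambda s: s.n_mg == 0)


@pytest.fixture(scope="session")
def pcp_insp5():
    return load_builtin("pcp_insp5")


@pytest.fixture(scope="session")
def insp6():
    return load_builtin("insp6")


@pytest.fixture(scope="session")
def toy_monoprotic():
    """L- + H+ <-> HL with log beta 7."""
    return ChemicalModel(
        "toy-monoprotic",
        -1,
        (SpeciesDef("L", 0, 0, 0, 0.0), SpeciesDef("HL", 1, 0, 0, 7.0)),
    )


@pytest.fixture(scope="session")
def toy_k_binding():
    """K+ + L- <-> KL with log beta 1."""
    return ChemicalModel(
        "toy-k",
        -1,
        (SpeciesDef("L", 0, 0, 0, 0.0), SpeciesDef("KL", 0, 1, 0, 1.0)),
    )


@pytest.fixture(scope="session")
def toy_diprotic():
    """Two protonation steps: log betas 8 and 13 (pK 8 and 5)."""
    return ChemicalModel(
        "toy-diprotic",
        -2,
        (
            SpeciesDef("L", 0, 0, 0, 0.0),
            SpeciesDef("HL", 1, 0, 0, 8.0),
            SpeciesDef("H2L", 2, 0, 0, 13.0),
        ),
    )
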