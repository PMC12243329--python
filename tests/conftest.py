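import pytest

from residueflow import (
    CompositionProfile,
    QualityMeta,
    Residue,
    ResourceMatrix,
    reference_fixture,
)


def make_residue(
    residue_id: str,
    potential: float,
    sector: str = "industry",
    usable: float = 1.0,
    quality: QualityMeta | None = None,
    **means: float,
) -> Residue:
    """Small helper: residue with mean-only composition and default quality."""
    return Residue(
        id=residue_id,
        name=residue_id,
        sector=sector,
        technical_potential=potential,
        composition=CompositionProfile.from_means(**means),
        quality=quality or QualityMeta(2, "detailed", 2020, 2025),
        usable_share=usable,
    )


def make_matrix(*residues: Residue) -> ResourceMatrix:
    return ResourceMatrix(tuple(residues))


@pytest.fixture(scope="session")
def fixture_data():
    return reference_fixture()


@pytest.fixture(scope="session")
def ref_matrix(fixture_data):
    return fixture_data.matrix
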