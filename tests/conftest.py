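import numpy as np
import pytest
from hypothesis import settings

from gldcscore import (
    CodingSequence,
    default_registry,
    enumerate_missense,
    generate_fixture,
    translate,
)
from gldcscore.parameters import (
    conserved_substitution_provider,
    consurf_provider,
    ddg_provider,
    position_class_provider,
    property_change_provider,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def bundle():
    """Deterministic synthetic study bundle (seed 1)."""
    return generate_fixture(1)


@pytest.fixture(scope="session")
def toy_cds():
    return CodingSequence(id="toy", nucleotides="ATGAAA")


@pytest.fixture(scope="session")
def scored_cds_setup():
    """A small coding sequence with full synthetic provider data.

    Provides (cds, mutations, providers) where every registry parameter can
    be evaluated for every enumerated mutation.
    """
    rng = np.random.default_rng(7)
    cds = generate_fixture(7, n_codons=30).human_cds
    muts, _ = enumerate_missense(cds)
    protein = translate(cds)
    n = len(protein)
    ddg = {m.label: float(rng.normal(0, 4)) for m in muts}
    grades = {p: int(rng.integers(1, 10)) for p in range(1, n + 1)}
    positions = np.arange(1, n + 1)
    providers = {
        "ddg": ddg_provider(ddg),
        "position": position_class_provider(
            helix=positions[: n // 3],
            sheet=positions[n // 3 : n // 2],
            dimer_interface=rng.choice(positions, size=5, replace=False),
            active_site=rng.choice(positions, size=4, replace=False),
        ),
        "consurf": consurf_provider(
            grades, functional=rng.choice(positions, size=3, replace=False)
        ),
        "properties": property_change_provider(),
        "substitution_matrix": conserved_substitution_provider(),
        "codon_usage": lambda m, name: int(
            (m.cdna_position or 0) % 7 == 0
        ),  # synthetic rare-codon pattern
    }
    return cds, muts, providers
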