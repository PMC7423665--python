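import numpy as np
import pytest

from paleotrait.traits import Trait, TraitScheme, SpeciesTraitTable


@pytest.fixture
def mollusc_scheme() -> TraitScheme:
    """Five traits with six states each, as in a mollusc functional-trait
    scoring (body size, life habit, locomotion, environment, diet)."""
    names = ["body_size", "life_habit", "locomotion", "environment", "diet"]
    return TraitScheme(
        tuple(
            Trait(n, tuple(f"{n}_s{k}" for k in range(6)), ordinal=(n == "body_size"))
            for n in names
        )
    )


@pytest.fixture
def small_scheme() -> TraitScheme:
    return TraitScheme(
        (
            Trait("size", ("small", "large")),
            Trait("diet", ("grazer", "predator", "suspension")),
        )
    )


@pytest.fixture
def small_table(small_scheme) -> SpeciesTraitTable:
    states = np.array(
        [[0, 0], [0, 0], [0, 1], [1, 1], [1, 2], [1, 2], [1, 2], [0, 2]]
    )
    return SpeciesTraitTable(
        scheme=small_scheme,
        species_ids=[f"sp{i}" for i in range(len(states))],
        states=states,
    )
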