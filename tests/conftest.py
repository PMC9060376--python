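import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from crnforge.core import ComplexSpecies, Species

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# name alphabets avoid reserved material tokens by construction
species_names = st.text(alphabet="abcxy", min_size=1, max_size=4)
attribute_tags = st.lists(
    st.sampled_from(["degradable", "machinery", "tag1"]),
    max_size=2, unique=True,
)
simple_species = st.builds(
    Species,
    name=species_names,
    material_type=st.sampled_from(["dna", "rna", "protein", "small_molecule", "none"]),
    attributes=attribute_tags,
)
species_trees = st.recursive(
    simple_species,
    lambda children: st.builds(
        ComplexSpecies,
        st.lists(children, min_size=2, max_size=4),
        attribute_tags,
    ),
    max_leaves=10,
)


@pytest.fixture
def expression_mixture():
    from crnforge.fixtures import make_example_2_7
    return make_example_2_7("simple")


@pytest.fixture
def mm_mixture():
    from crnforge.fixtures import make_example_2_7
    return make_example_2_7("mm")


@pytest.fixture
def examples_dir():
    from pathlib import Path
    import crnforge
    return Path(crnforge.__file__).parent / "examples"


@pytest.fixture
def golden_dir():
    from pathlib import Path
    return Path(__file__).parent / "golden"
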