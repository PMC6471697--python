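import pytest

from maplayers.model import Alias, Annotation, Box, Entity, EntityClass, MapDocument, Point, Reaction
from maplayers.synthetic import generate, preset


@pytest.fixture(scope="session")
def small_bundle():
    return generate(preset("small", rng_seed=0))


@pytest.fixture(scope="session")
def dense_bundle():
    return generate(preset("dense", rng_seed=0))


def toy_map() -> MapDocument:
    """3 species, 1 reaction, hand-laid geometry (easy to verify by hand)."""
    canvas = Box(Point(0, 0), 400.0, 300.0)
    entities = (
        Entity("s1", "glc", EntityClass.METABOLITE),
        Entity("s2", "g6p", EntityClass.METABOLITE),
        Entity("s3", "GCK", EntityClass.PROTEIN),
    )
    aliases = (
        Alias("sa1", "s1", Box(Point(20.0, 40.0), 60.0, 20.0)),
        Alias("sa2", "s2", Box(Point(300.0, 200.0), 60.0, 20.0)),
        Alias("sa3", "s3", Box(Point(150.0, 30.0), 80.0, 40.0)),
    )
    reactions = (
        Reaction(
            "re1",
            reactant_alias_ids=("sa1",),
            product_alias_ids=("sa2",),
            modifier_alias_ids=("sa3",),
            annotation=Annotation({"Identifiers": ("GCK",)}),
        ),
    )
    return MapDocument(canvas=canvas, entities=entities, aliases=aliases,
                       reactions=reactions, model_id="toy")


@pytest.fixture
def toy_doc():
    return toy_map()
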