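import numpy as np
import pytest

from kelpweb.web_model import Assembly, FoodWeb, Link, SpeciesNode


def make_species(spec):
    """spec: iterable of (species_id, role) or (species_id, role, extinct)."""
    out = {}
    for row in spec:
        sid, role = row[0], row[1]
        extinct = row[2] if len(row) > 2 else False
        out[sid] = SpeciesNode(species_id=sid, role=role, extinct=extinct)
    return out


def make_web(species_spec, link_spec, version="PP_PH_PC", include_fn=False):
    """link_spec: iterable of (consumer, resource, link_class) or Link kwargs dicts."""
    links = []
    for row in link_spec:
        if isinstance(row, dict):
            links.append(Link(**row))
        else:
            links.append(Link(consumer_id=row[0], resource_id=row[1], link_class=row[2]))
    return FoodWeb(
        species=make_species(species_spec),
        links=links,
        assembly=Assembly(version=version, include_false_negatives=include_fn),
    )


def random_pp_web(rng, s, p_link=0.15):
    """A random free-living web (possibly cyclic, no self-links)."""
    species = [(f"X{i:02d}", "free_living") for i in range(s)]
    links = []
    for i in range(s):
        for j in range(s):
            if i != j and rng.random() < p_link:
                links.append((f"X{i:02d}", f"X{j:02d}", "predator_prey"))
    return make_web(species, links, version="PP")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_web():
    """C eats B eats A (consumer -> resource convention)."""
    return make_web(
        [("A", "free_living"), ("B", "free_living"), ("C", "free_living")],
        [("B", "A", "predator_prey"), ("C", "B", "predator_prey")],
        version="PP",
    )


@pytest.fixture
def parasite_web():
    """Small mixed web: plant -> herbivore -> predator, one parasite of the
    herbivore and predator, with the concomitant link on the non-transmitting
    encounter."""
    return make_web(
        [("plant", "free_living"), ("herb", "free_living"), ("pred", "free_living"), ("worm", "parasite")],
        [
            ("herb", "plant", "predator_prey"),
            ("pred", "herb", "predator_prey"),
            {"consumer_id": "worm", "resource_id": "herb", "link_class": "parasite_host"},
            {
                "consumer_id": "worm",
                "resource_id": "pred",
                "link_class": "parasite_host",
                "trophic_transmission": True,
            },
        ],
    )
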