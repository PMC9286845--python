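"""Parsing, life-stage aggregation, assembly filtering and validation."""


import pytest

from conftest import make_web
from kelpweb import web_model as wm
from kelpweb.web_model import (
    Assembly,
    Link,
    StageNode,
    WebParseError,
    WebValidationError,
    aggregate_stages,
    build_assembly,
    read_links,
    read_nodes,
    validate_web,
    write_links,
    write_nodes,
)

NODE_CSV = """node_id,species_id,stage,role,extinct,habitat
a1,A,adult,free_living,false,reef
b1,B,larva,free_living,false,pelagic
p1,P,adult,parasite,false,host
"""

LINK_CSV = """consumer_id,resource_id,link_class,trophic_transmission
b1,a1,predator_prey,false
p1,b1,parasite_host,true
a1,p1,predator_parasite,false
p1,p1,parasite_parasite,false
"""


def test_read_nodes_parses_roles_and_metadata(tmp_path):
    path = tmp_path / "nodes.csv"
    path.write_text(NODE_CSV)
    nodes = read_nodes(path)
    assert len(nodes) == 3
    assert sum(n.role == "parasite" for n in nodes) == 1
    assert nodes[0].metadata == {"habitat": "reef"}  # unknown columns preserved


def test_read_nodes_duplicate_id_names_offender(tmp_path):
    path = tmp_path / "nodes.csv"
    path.write_text("node_id,species_id,role\nx,X,free_living\nx,X,free_living\n")
    with pytest.raises(WebValidationError, match="x"):
        read_nodes(path)


def test_read_nodes_missing_column_named(tmp_path):
    path = tmp_path / "nodes.csv"
    path.write_text("node_id,role\nx,free_living\n")
    with pytest.raises(WebParseError, match="species_id"):
        read_nodes(path)


def test_read_nodes_dialect_mapping(tmp_path):
    path = tmp_path / "nodes.csv"
    path.write_text("NodeID,Species,Type\nx,X,parasite\n")
    nodes = read_nodes(path, dialect={"node_id": "NodeID", "species_id": "Species", "role": "Type"})
    assert nodes[0].node_id == "x" and nodes[0].role == "parasite"


def test_read_links_all_four_classes(tmp_path):
    npath, lpath = tmp_path / "n.csv", tmp_path / "l.csv"
    npath.write_text(NODE_CSV)
    lpath.write_text(LINK_CSV)
    nodes = read_nodes(npath)
    links = read_links(lpath, nodes=nodes)
    assert sorted(l.link_class for l in links) == sorted(wm.LINK_CLASSES)
    assert sum(l.trophic_transmission for l in links) == 1


def test_read_links_rejects_unknown_class_and_dangling(tmp_path):
    lpath = tmp_path / "l.csv"
    lpath.write_text("consumer_id,resource_id,link_class\na,b,mutualism\n")
    with pytest.raises(WebParseError, match="mutualism"):
        read_links(lpath)
    lpath.write_text("consumer_id,resource_id,link_class\na,ghost,predator_prey\n")
    nodes = [StageNode(node_id="a", species_id="A")]
    with pytest.raises(WebValidationError, match="ghost"):
        read_links(lpath, nodes=nodes)


def test_tables_round_trip(tmp_path):
    npath, lpath = tmp_path / "n.csv", tmp_path / "l.csv"
    nodes = [
        StageNode(node_id="a1", species_id="A", stage="adult"),
        StageNode(node_id="p1", species_id="P", role="parasite", extinct=True),
    ]
    links = [
        Link(consumer_id="p1", resource_id="a1", link_class="parasite_host", paratenic=True),
    ]
    write_nodes(nodes, npath, header_comment="seed=5")
    write_links(links, lpath, header_comment="seed=5")
    rn = read_nodes(npath)
    rl = read_links(lpath, nodes=rn)
    assert [(n.node_id, n.species_id, n.role, n.extinct) for n in rn] == [
        (n.node_id, n.species_id, n.role, n.extinct) for n in nodes
    ]
    assert rl == links


def test_aggregate_collapses_duplicates_and_ors_flags():
    nodes = [
        StageNode(node_id="x1", species_id="X", stage="larva"),
        StageNode(node_id="x2", species_id="X", stage="adult"),
        StageNode(node_id="y1", species_id="Y"),
    ]
    links = [
        Link(consumer_id="x1", resource_id="y1"),
        Link(consumer_id="x2", resource_id="y1"),
    ]
    species, agg = aggregate_stages(nodes, links)
    assert len(agg) == 1 and agg[0].key == ("X", "Y", "predator_prey")
    # flags OR-combine across stage-level instances
    ph = [
        Link(consumer_id="x1", resource_id="y1", link_class="parasite_host", trophic_transmission=True),
        Link(consumer_id="x2", resource_id="y1", link_class="parasite_host"),
    ]
    nodes_p = [
        StageNode(node_id="x1", species_id="X", role="parasite"),
        StageNode(node_id="x2", species_id="X", role="parasite"),
        StageNode(node_id="y1", species_id="Y"),
    ]
    _, agg = aggregate_stages(nodes_p, ph)
    assert len(agg) == 1 and agg[0].trophic_transmission


def test_parasite_species_keeps_free_living_links():
    nodes = [
        StageNode(node_id="w.adult", species_id="W", stage="adult", role="parasite"),
        StageNode(node_id="w.larva", species_id="W", stage="larva", role="free_living"),
        StageNode(node_id="z", species_id="Z"),
    ]
    links = [
        Link(consumer_id="w.adult", resource_id="z", link_class="parasite_host"),
        Link(consumer_id="w.larva", resource_id="z", link_class="predator_prey"),
    ]
    species, agg = aggregate_stages(nodes, links)
    roles = {s.species_id: s.role for s in species}
    assert roles["W"] == "parasite"
    assert {l.link_class for l in agg} == {"parasite_host", "predator_prey"}


def test_aggregate_self_links_from_cross_stage_feeding():
    """Brute-force enumeration of collapsed pairs on a 6-stage fixture,
    including a stage-on-stage link within one species."""
    nodes = [
        StageNode(node_id=f"{sp}{k}", species_id=sp, stage=str(k))
        for sp, k in [("A", 1), ("A", 2), ("B", 1), ("B", 2), ("C", 1), ("C", 2)]
    ]
    stage_links = [
        ("A1", "A2"),  # becomes a species-level self-link
        ("A2", "B1"),
        ("A1", "B2"),  # duplicate of A->B after aggregation
        ("B1", "C1"),
        ("B2", "C2"),  # duplicate of B->C
        ("C1", "A1"),
    ]
    links = [Link(consumer_id=c, resource_id=r) for c, r in stage_links]
    species_map = {n.node_id: n.species_id for n in nodes}
    expected = {(species_map[c], species_map[r]) for c, r in stage_links}
    _, agg = aggregate_stages(nodes, links)
    assert {(l.consumer_id, l.resource_id) for l in agg} == expected
    assert ("A", "A") in {(l.consumer_id, l.resource_id) for l in agg}


def test_aggregation_idempotent():
    nodes = [
        StageNode(node_id="A", species_id="A"),
        StageNode(node_id="B", species_id="B", role="parasite"),
    ]
    links = [Link(consumer_id="B", resource_id="A", link_class="parasite_host")]
    species, agg = aggregate_stages(nodes, links)
    nodes2 = [StageNode(node_id=s.species_id, species_id=s.species_id, role=s.role) for s in species]
    species2, agg2 = aggregate_stages(nodes2, agg)
    assert sorted(l.key for l in agg2) == sorted(l.key for l in agg)
    assert sorted((s.species_id, s.role) for s in species2) == sorted(
        (s.species_id, s.role) for s in species
    )


FULL_SPECIES = [
    wm.SpeciesNode(species_id="plant"),
    wm.SpeciesNode(species_id="herb"),
    wm.SpeciesNode(species_id="pred"),
    wm.SpeciesNode(species_id="worm", role="parasite"),
    wm.SpeciesNode(species_id="ghost", extinct=True),
]
FULL_LINKS = [
    Link(consumer_id="herb", resource_id="plant"),
    Link(consumer_id="pred", resource_id="herb"),
    Link(consumer_id="pred", resource_id="ghost"),
    Link(consumer_id="worm", resource_id="herb", link_class="parasite_host"),
    Link(consumer_id="worm", resource_id="plant", link_class="parasite_host", false_negative=True),
    Link(consumer_id="pred", resource_id="worm", link_class="predator_parasite"),
]


def test_build_assembly_pp_only_free_living():
    web = build_assembly(FULL_SPECIES, FULL_LINKS, Assembly(version="PP"))
    assert set(web.species) == {"plant", "herb", "pred"}
    assert all(l.link_class == "predator_prey" for l in web.links)
    assert web.n_links == 2  # extinct 'ghost' and its link dropped


def test_build_assembly_false_negatives_grow_link_count():
    base = build_assembly(FULL_SPECIES, FULL_LINKS, Assembly(version="PP_PH"))
    with_fn = build_assembly(
        FULL_SPECIES, FULL_LINKS, Assembly(version="PP_PH", include_false_negatives=True)
    )
    n_flagged = sum(
        1 for l in FULL_LINKS if l.false_negative and l.link_class in ("predator_prey", "parasite_host")
    )
    assert with_fn.n_links == base.n_links + n_flagged


def test_assembly_monotone_and_union():
    webs = {
        v: build_assembly(FULL_SPECIES, FULL_LINKS, Assembly(version=v))
        for v in ("PP", "PP_PH", "PP_PH_PC")
    }
    keys = {v: {l.key for l in w.links} for v, w in webs.items()}
    assert keys["PP"] <= keys["PP_PH"] <= keys["PP_PH_PC"]
    pc = {l.key for l in webs["PP_PH_PC"].links if l.link_class == "predator_parasite"}
    assert keys["PP_PH_PC"] == keys["PP_PH"] | pc


def test_subweb_counts_partition_links():
    web = build_assembly(FULL_SPECIES, FULL_LINKS, Assembly(version="PP_PH_PC"))
    by_class = {}
    for l in web.links:
        by_class[l.link_class] = by_class.get(l.link_class, 0) + 1
    assert sum(by_class.values()) == web.n_links


def test_validate_clean_web_is_empty(parasite_web):
    assert validate_web(parasite_web) == []


def test_validate_flags_bad_predator_parasite_resource():
    web = make_web(
        [("a", "free_living"), ("b", "free_living")],
        [("a", "b", "predator_parasite")],
    )
    violations = validate_web(web)
    assert len(violations) == 1 and violations[0].rule == "predator_parasite_resource"


def test_validate_fault_injection_counts(rng):
    """Corrupting k links yields exactly k violations."""
    species = [(f"F{i}", "free_living") for i in range(6)] + [(f"Q{i}", "parasite") for i in range(3)]
    links = [
        ("F1", "F0", "predator_prey"),
        ("F2", "F1", "predator_prey"),
        ("Q0", "F1", "parasite_host"),
        ("Q1", "F2", "parasite_host"),
        ("F2", "Q0", "predator_parasite"),
    ]
    web = make_web(species, links)
    assert validate_web(web) == []
    # corrupt k=3 links: wrong consumer role, wrong resource role, stray flag
    web.links[2] = Link(consumer_id="F0", resource_id="F1", link_class="parasite_host")
    web.links[4] = Link(consumer_id="F2", resource_id="F0", link_class="predator_parasite")
    web.links[0] = Link(consumer_id="F1", resource_id="F0", trophic_transmission=True)
    assert len(validate_web(web)) == 3


def test_export_edgelist_and_graphml(tmp_path, parasite_web):
    wm.export_edgelist(parasite_web, tmp_path / "edges.tsv")
    lines = (tmp_path / "edges.tsv").read_text().strip().splitlines()
    assert len(lines) == parasite_web.n_links + 1
    wm.export_graphml(parasite_web, tmp_path / "web.graphml")
    import networkx as nx

    g = nx.read_graphml(tmp_path / "web.graphml")
    assert g.number_of_edges() == parasite_web.n_links
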