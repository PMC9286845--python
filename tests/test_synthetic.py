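"""The synthetic parasite-augmented metaweb generator."""

import numpy as np
import pytest

from kelpweb import metrics as m
from kelpweb import web_model as wm
from kelpweb.synthetic_data import (
    SynthParams,
    assemble,
    generate_parasite_web,
    generate_stage_level_fixture,
    write_web,
)

SMALL = dict(s_free=60, c_free=0.06, n_parasites=40, n_supergeneralists=1, seed=3)


def link_signature(links):
    return sorted(
        (l.consumer_id, l.resource_id, l.link_class, l.trophic_transmission, l.paratenic, l.false_negative)
        for l in links
    )


def test_no_parasites_reduces_to_niche_core():
    params = SynthParams(s_free=40, c_free=0.08, n_parasites=0, n_supergeneralists=0,
                         p_extinct=0.0, p_false_negative=0.0, seed=2)
    nodes, links, man = generate_parasite_web(params)
    assert len(nodes) == 40
    assert all(n.role == "free_living" for n in nodes)
    assert all(l.link_class == "predator_prey" for l in links)
    assert man["n_predator_parasite"] == 0


def test_parasite_fraction_exact():
    nodes, _, _ = generate_parasite_web(SynthParams(**SMALL))
    s_par = sum(1 for n in nodes if n.role == "parasite")
    assert s_par / len(nodes) == 40 / 100


def test_concomitant_rule_simple_case():
    """One parasite on one host with three predators (none of them hosts)
    yields exactly three predator_parasite links -- built by hand through the
    same assembly path."""
    nodes = [wm.StageNode(node_id=s, species_id=s) for s in ("h", "q1", "q2", "q3", "b")]
    nodes.append(wm.StageNode(node_id="p", species_id="p", role="parasite"))
    links = [wm.Link(consumer_id=q, resource_id="h") for q in ("q1", "q2", "q3")]
    links += [wm.Link(consumer_id="h", resource_id="b")]
    links += [wm.Link(consumer_id="p", resource_id="h", link_class="parasite_host")]
    links += [
        wm.Link(consumer_id=q, resource_id="p", link_class="predator_parasite")
        for q in ("q1", "q2", "q3")
    ]
    web = assemble(nodes, links, "PP_PH_PC")
    assert len(web.links_of_class("predator_parasite")) == 3
    assert wm.validate_web(web) == []


def test_concomitant_completeness_audit():
    """Every (parasite, host, free-living predator) triple resolves to exactly
    one of: a trophic-transmission parasite_host link p->q, or a concomitant
    q->p link."""
    nodes, links, _ = generate_parasite_web(SynthParams(**SMALL))
    roles = {n.species_id: n.role for n in nodes}
    ph = {
        (l.consumer_id, l.resource_id): l
        for l in links
        if l.link_class == "parasite_host" and not l.false_negative
    }
    pc = {(l.consumer_id, l.resource_id) for l in links if l.link_class == "predator_parasite"}
    predators = {}
    for l in links:
        if l.link_class == "predator_prey" and l.consumer_id != l.resource_id:
            if roles[l.consumer_id] == "free_living":
                predators.setdefault(l.resource_id, set()).add(l.consumer_id)
    checked = 0
    for (p, h) in ph:
        for q in predators.get(h, ()):
            transmits = (p, q) in ph and ph[(p, q)].trophic_transmission
            assert transmits != ((q, p) in pc), (p, h, q)
            checked += 1
    assert checked > 50
    # and every concomitant link is justified by some (p, h, q) triple
    justified = {
        (q, p)
        for (p, h) in ph
        for q in predators.get(h, ())
        if not ((p, q) in ph and ph[(p, q)].trophic_transmission)
    }
    assert pc == justified


def test_host_breadth_specialists_and_supergeneralists():
    from collections import Counter

    nodes, links, man = generate_parasite_web(SynthParams(seed=11))
    breadth = Counter()
    for l in links:
        if l.link_class == "parasite_host" and not l.false_negative:
            breadth[l.consumer_id] += 1
    supers = {f"P{i:04d}" for i in range(3)}
    specialist_b = [v for k, v in breadth.items() if k not in supers]
    assert np.median(specialist_b) <= 4
    assert min(breadth[s] for s in supers) > np.percentile(specialist_b, 99)
    assert man["n_paratenic"] > 0


def test_flags_and_counts_in_manifest():
    nodes, links, man = generate_parasite_web(SynthParams(**SMALL))
    by_class = {}
    for l in links:
        by_class[l.link_class] = by_class.get(l.link_class, 0) + 1
    assert by_class["predator_parasite"] == man["n_predator_parasite"]
    n_fn = sum(1 for l in links if l.false_negative)
    assert n_fn == man["n_false_negative"]
    assert man["n_trophic_transmission"] == sum(
        l.trophic_transmission for l in links if not l.false_negative
    )


def test_false_negatives_only_enter_when_requested():
    nodes, links, man = generate_parasite_web(SynthParams(**SMALL))
    base = assemble(nodes, links, "PP_PH")
    with_fn = assemble(nodes, links, "PP_PH", include_false_negatives=True)
    extinct = {n.species_id for n in nodes if n.extinct}
    visible_fn = sum(
        1
        for l in links
        if l.false_negative and l.consumer_id not in extinct and l.resource_id not in extinct
    )
    assert with_fn.n_links == base.n_links + visible_fn


def test_assemblies_validate_cleanly():
    nodes, links, _ = generate_parasite_web(SynthParams(**SMALL))
    for version in ("PP", "PP_PH", "PP_PH_PC"):
        web = assemble(nodes, links, version)
        assert wm.validate_web(web) == []


def test_headline_directions_at_defaults():
    """Adding a specialist-dominated parasite fauna lowers connectance, and
    the concomitant web's adjusted connectance stays below the free-living
    web's connectance (checked across seeded paper-scale replicates)."""
    for seed in range(3):
        nodes, links, _ = generate_parasite_web(SynthParams(seed=seed))
        pp = assemble(nodes, links, "PP")
        pph = assemble(nodes, links, "PP_PH")
        full = assemble(nodes, links, "PP_PH_PC")
        c_pp = m.connectance(pp)
        assert m.connectance(pph) < c_pp
        assert m.adjusted_connectance(full) < c_pp


def test_stage_fixture_round_trip():
    species_nodes, species_links, _ = generate_parasite_web(SynthParams(**SMALL))
    stage_nodes, stage_links, _ = generate_stage_level_fixture(SynthParams(**SMALL))
    assert len(stage_nodes) > len(species_nodes)  # stages were actually split
    assert len(stage_links) > len(species_links)  # duplicates were injected
    agg_species, agg_links = wm.aggregate_stages(stage_nodes, stage_links)
    assert link_signature(agg_links) == link_signature(species_links)
    assert sorted((s.species_id, s.role, s.extinct) for s in agg_species) == sorted(
        (n.species_id, n.role, n.extinct) for n in species_nodes
    )


def test_stage_fixture_parasite_with_free_living_larva():
    stage_nodes, stage_links, man = generate_stage_level_fixture(SynthParams(**SMALL))
    special = man["free_living_larva_parasite"]
    assert special is not None
    stages = [n for n in stage_nodes if n.species_id == special]
    assert any(n.role == "free_living" for n in stages)
    agg_species, agg_links = wm.aggregate_stages(stage_nodes, stage_links)
    roles = {s.species_id: s.role for s in agg_species}
    assert roles[special] == "parasite"
    assert any(
        l.consumer_id == special and l.link_class == "predator_prey" for l in agg_links
    )


def test_write_web_round_trips_and_embeds_seed(tmp_path):
    nodes, links, man = generate_parasite_web(SynthParams(**SMALL))
    paths = write_web(nodes, links, man, tmp_path)
    assert paths["nodes"].read_text().startswith("# seed=3")
    rn = wm.read_nodes(paths["nodes"])
    rl = wm.read_links(paths["links"], nodes=rn)
    assert sorted(n.node_id for n in rn) == sorted(n.node_id for n in nodes)
    assert link_signature(rl) == link_signature(links)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SynthParams(p_complex=1.5)
    with pytest.raises(ValueError):
        SynthParams(n_parasites=2, n_supergeneralists=3)
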