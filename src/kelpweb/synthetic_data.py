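"""Synthetic parasite-augmented metawebs.

The generator emulates the statistical structure of a parasite-resolved
kelp-forest-style metaweb so that every pipeline stage is exercisable without
any download: a free-living niche-model core of several hundred species with
low connectance, a parasite fauna dominated by host specialists (host breadth
typically 1-4) with a few extreme paratenic-host generalists, trophically
transmitted multi-host life cycles running up food chains, and concomitant
predator->parasite links composed from predator-prey x parasite-host pairs.

Concomitant rule: for every parasite-host pair (p, h) and every free-living
predator q of h, a q->p predator_parasite link is added *unless* p->q exists as a
trophic-transmission parasite_host link -- in that case eating h transmits the
parasite to q rather than killing it, so the encounter is not concomitant. A
predator that hosts the parasite non-trophically still ingests (and kills) the
parasite individuals riding in its prey, which is what makes mutual
consumption (D-class) motifs more common once parasites are added. A parasite
species acting as a predator through a free-living stage does not compose
concomitant links (that would be a parasite_parasite interaction, the sub-web
that stays empty here as it is typically unobserved).

Host placement follows the biology the structure is meant to mimic: direct
specialists (parasitic-copepod-like) attach preferentially to higher trophic
levels (fish-like hosts with few predators), while complex life cycles start
in the lowest trophic-level tercile and move up through predators. This keeps
the concomitant sub-web a small multiple of the parasite-host sub-web rather
than an explosion, as observed in real parasite webs.

The generator targets qualitative structure; it makes no attempt to fit any
particular deposited web's degree sequences.
"""

from __future__ import annotations

import json

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import metrics as _metrics
from .niche_null import NicheParams, generate_niche_web
from .web_model import (
    Assembly,
    FoodWeb,
    Link,
    StageNode,
    aggregate_stages,
    build_assembly,
    write_links,
    write_nodes,
)


@dataclass(frozen=True)
class SynthParams:
    """Generator settings. Defaults mirror a kelp-forest-scale metaweb:
    485 free-living species at connectance 0.036 plus 433 parasites, most of
    them specialists under a heavy-tailed (zeta, exponent 2.5) host-breadth
    law, with a handful of paratenic-host supergeneralists."""

    s_free: int = 485
    c_free: float = 0.036
    n_parasites: int = 433
    p_complex: float = 0.45
    host_breadth_law: tuple = ("zeta", 2.5)
    n_supergeneralists: int = 3
    paratenic_expansion: float = 0.8
    p_extinct: float = 0.02
    p_false_negative: float = 0.24
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_complex", "paratenic_expansion", "p_extinct", "p_false_negative"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_parasites < 0 or self.s_free < 2:
            raise ValueError("need s_free >= 2 and n_parasites >= 0")
        if self.n_supergeneralists > self.n_parasites:
            raise ValueError("n_supergeneralists cannot exceed n_parasites")


def _sample_breadth(law: tuple, rng: np.random.Generator, cap: int) -> int:
    family, param = law
    if family == "zeta":
        k = int(rng.zipf(param))
        while k > cap:
            k = int(rng.zipf(param))
        return k
    if family == "constant":
        return min(int(param), cap)
    if family == "uniform":
        return int(rng.integers(1, min(int(param), cap) + 1))
    raise ValueError(f"unknown host-breadth law family {family!r}")


def generate_parasite_web(params: SynthParams) -> tuple:
    """Generate one species-level metaweb.

    Returns ``(nodes, links, manifest)``: one StageNode per species (the
    species-level table; see :func:`generate_stage_level_fixture` for a
    stage-split version), the full typed link table, and a manifest of
    realized counts.
    """
    rng = np.random.default_rng(params.seed)
    core = generate_niche_web(NicheParams(s=params.s_free, c=params.c_free), rng=rng, prefix="F")
    free_ids = sorted(core.species)
    core_links = list(core.links)

    tl = _metrics.trophic_levels(core)
    resources_of: dict = {sid: set() for sid in free_ids}
    predators_of: dict = {sid: [] for sid in free_ids}
    for link in core_links:
        resources_of[link.consumer_id].add(link.resource_id)
        if link.consumer_id != link.resource_id:
            predators_of[link.resource_id].append(link.consumer_id)
    basal = [sid for sid in free_ids if not resources_of[sid]]

    tl_arr = np.array([tl[sid] for sid in free_ids])
    tercile = np.quantile(tl_arr, 1 / 3)
    low_tercile = [sid for sid in free_ids if tl[sid] <= tercile and predators_of[sid]]
    # Direct specialists attach preferentially to higher trophic levels and to
    # hosts with few predators of their own (fish- and mammal-like consumers):
    # in parasite-resolved webs the average top predator hosts many parasites
    # but has few predators, which keeps the concomitant sub-web a small
    # multiple of the parasite-host sub-web.
    n_preds_arr = np.array([len(predators_of[sid]) for sid in free_ids], dtype=float)
    host_weights = ((tl_arr - 1.0) ** 2 + 0.05) / (1.0 + n_preds_arr)
    host_weights /= host_weights.sum()

    width = max(4, len(str(params.n_parasites)))
    parasite_ids = [f"P{i:0{width}d}" for i in range(params.n_parasites)]

    ph_links: dict = {}  # (p, h) -> Link
    complex_flags: dict = {}
    chain_fallbacks = 0
    free_larva_parasite = None

    def add_ph(p, h, tt=False, paratenic=False):
        key = (p, h)
        prev = ph_links.get(key)
        if prev is None:
            ph_links[key] = Link(
                consumer_id=p,
                resource_id=h,
                link_class="parasite_host",
                trophic_transmission=tt,
                paratenic=paratenic,
            )
        elif (tt and not prev.trophic_transmission) or (paratenic and not prev.paratenic):
            ph_links[key] = Link(
                consumer_id=p,
                resource_id=h,
                link_class="parasite_host",
                trophic_transmission=prev.trophic_transmission or tt,
                paratenic=prev.paratenic or paratenic,
            )

    parasite_pp_links = []
    for i, pid in enumerate(parasite_ids):
        supergeneralist = i < params.n_supergeneralists
        is_complex = supergeneralist or (rng.random() < params.p_complex)
        complex_flags[pid] = is_complex
        breadth = _sample_breadth(params.host_breadth_law, rng, params.s_free)
        hosts: list = []

        if is_complex and low_tercile:
            n_first = 3 if supergeneralist else 1
            firsts = rng.choice(low_tercile, size=min(n_first, len(low_tercile)), replace=False)
            for h in firsts:
                add_ph(pid, h)
                hosts.append(h)
            # life-cycle chain climbs through predators of the current host
            current = hosts[0]
            for _ in range(int(rng.integers(1, 3))):
                options = [q for q in predators_of[current] if q not in hosts]
                if not options:
                    chain_fallbacks += 1
                    break
                nxt = options[int(rng.integers(len(options)))]
                add_ph(pid, nxt, tt=True)
                hosts.append(nxt)
                current = nxt
            if supergeneralist:
                candidates = sorted(
                    {q for h in hosts for q in predators_of[h]} - set(hosts)
                )
                n_para = int(round(params.paratenic_expansion * len(candidates)))
                if n_para:
                    chosen = rng.choice(candidates, size=n_para, replace=False)
                    for q in chosen:
                        add_ph(pid, q, tt=True, paratenic=True)
                        hosts.append(q)
            # same-stage extra hosts up to the drawn breadth
            extra_pool = [h for h in low_tercile if h not in hosts]
            n_extra = min(max(0, breadth - len(hosts)), len(extra_pool))
            if n_extra:
                for h in rng.choice(extra_pool, size=n_extra, replace=False):
                    add_ph(pid, h)
                    hosts.append(h)
            if free_larva_parasite is None and not supergeneralist and basal:
                # one parasite species keeps a free-living predatory larva
                free_larva_parasite = pid
                prey = basal[int(rng.integers(len(basal)))]
                parasite_pp_links.append(Link(consumer_id=pid, resource_id=prey))
        else:
            k = min(breadth, params.s_free)
            chosen = rng.choice(free_ids, size=k, replace=False, p=host_weights)
            for h in chosen:
                add_ph(pid, h)
                hosts.append(h)

    n_ph_observed = len(ph_links)

    # statistically predicted but unobserved parasite-host links
    n_fn = int(round(params.p_false_negative * n_ph_observed))
    fn_links = []
    attempts = 0
    while len(fn_links) < n_fn and attempts < 50 * max(n_fn, 1):
        attempts += 1
        p = parasite_ids[int(rng.integers(params.n_parasites))]
        h = free_ids[int(rng.integers(params.s_free))]
        if (p, h) in ph_links:
            continue
        ph_links[(p, h)] = None  # reserve the pair
        fn_links.append(
            Link(consumer_id=p, resource_id=h, link_class="parasite_host", false_negative=True)
        )
    observed_ph = [l for l in ph_links.values() if l is not None]

    # concomitant predation: predators of hosts ingest the hosts' parasites
    tt_pairs = {
        (l.consumer_id, l.resource_id) for l in observed_ph if l.trophic_transmission
    }
    pc_pairs = set()
    for l in observed_ph:
        p, h = l.consumer_id, l.resource_id
        for q in predators_of[h]:
            if (p, q) in tt_pairs:
                continue
            pc_pairs.add((q, p))
    pc_links = [
        Link(consumer_id=q, resource_id=p, link_class="predator_parasite")
        for q, p in sorted(pc_pairs)
    ]

    all_ids = free_ids + parasite_ids
    extinct = {sid: bool(rng.random() < params.p_extinct) for sid in all_ids}
    nodes = []
    for sid in free_ids:
        nodes.append(
            StageNode(
                node_id=sid,
                species_id=sid,
                stage="all",
                role="free_living",
                strategy="autotroph" if sid in set(basal) else "predator",
                group="autotroph" if sid in set(basal) else "animal",
                extinct=extinct[sid],
            )
        )
    for pid in parasite_ids:
        nodes.append(
            StageNode(
                node_id=pid,
                species_id=pid,
                stage="all",
                role="parasite",
                strategy="trophically transmitted parasite" if complex_flags[pid] else "parasite",
                group="parasite",
                extinct=extinct[pid],
            )
        )

    links = core_links + parasite_pp_links + observed_ph + fn_links + pc_links
    manifest = {
        "params": {**asdict(params), "host_breadth_law": list(params.host_breadth_law)},
        "seed": params.seed,
        "s_free": params.s_free,
        "s_parasite": params.n_parasites,
        "n_predator_prey": len(core_links) + len(parasite_pp_links),
        "n_parasite_host_observed": n_ph_observed,
        "n_false_negative": len(fn_links),
        "n_predator_parasite": len(pc_links),
        "n_trophic_transmission": sum(l.trophic_transmission for l in observed_ph),
        "n_paratenic": sum(l.paratenic for l in observed_ph),
        "n_extinct_flagged": sum(extinct.values()),
        "chain_fallbacks": chain_fallbacks,
        "free_living_larva_parasite": free_larva_parasite,
    }
    return nodes, links, manifest


def generate_stage_level_fixture(params: SynthParams) -> tuple:
    """Split the species-level web into 1-3 life stages per species, with
    deliberately injected duplicate stage links, such that
    :func:`kelpweb.web_model.aggregate_stages` reproduces the species-level
    web link-for-link (flags OR-combine back to the originals).

    The parasite that carries a free-living predatory link gets a dedicated
    free-living larva stage holding that link.
    """
    species_nodes, links, manifest = generate_parasite_web(params)
    rng = np.random.default_rng(0 if params.seed is None else (params.seed + 10_007) % 2**31)

    stage_nodes: list = []
    stages_of: dict = {}
    special = manifest["free_living_larva_parasite"]
    for node in species_nodes:
        n_stages = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        names = ["adult", "juvenile", "larva"][:n_stages]
        ids = []
        for name in names:
            nid = f"{node.species_id}.{name}"
            role = node.role
            if node.species_id == special and name == "larva":
                role = "free_living"
            stage_nodes.append(
                StageNode(
                    node_id=nid,
                    species_id=node.species_id,
                    stage=name,
                    role=role,
                    strategy=node.strategy,
                    group=node.group,
                    extinct=node.extinct,
                )
            )
        ids = [f"{node.species_id}.{name}" for name in names]
        stages_of[node.species_id] = ids
        if node.species_id == special and f"{node.species_id}.larva" not in ids:
            stage_nodes.append(
                StageNode(
                    node_id=f"{node.species_id}.larva",
                    species_id=node.species_id,
                    stage="larva",
                    role="free_living",
                    strategy=node.strategy,
                    group=node.group,
                    extinct=node.extinct,
                )
            )
            stages_of[node.species_id].append(f"{node.species_id}.larva")

    def pick_stage(sid):
        opts = stages_of[sid]
        return opts[int(rng.integers(len(opts)))]

    stage_links = []
    for link in links:
        if link.consumer_id == special and link.link_class == "predator_prey":
            cons = f"{special}.larva"
        else:
            cons = pick_stage(link.consumer_id)
        stage_links.append(
            Link(
                consumer_id=cons,
                resource_id=pick_stage(link.resource_id),
                link_class=link.link_class,
                trophic_transmission=link.trophic_transmission,
                paratenic=link.paratenic,
                false_negative=link.false_negative,
            )
        )
        if rng.random() < 0.15:  # duplicate via a second stage pairing; flags weakened
            stage_links.append(
                Link(
                    consumer_id=pick_stage(link.consumer_id),
                    resource_id=pick_stage(link.resource_id),
                    link_class=link.link_class,
                    trophic_transmission=bool(link.trophic_transmission and rng.random() < 0.5),
                    paratenic=link.paratenic,
                    false_negative=link.false_negative,
                )
            )
    return stage_nodes, stage_links, manifest


def assemble(nodes: list, links: list, version: str, include_false_negatives: bool = False) -> FoodWeb:
    """Aggregate stage tables to species and build one assembly version."""
    species, sp_links = aggregate_stages(nodes, links)
    return build_assembly(
        species, sp_links, Assembly(version=version, include_false_negatives=include_false_negatives)
    )


def write_web(nodes: list, links: list, manifest: dict, outdir) -> dict:
    """Emit nodes.csv / links.csv in the canonical dialect (seed embedded in a
    header comment) plus manifest.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comment = f"seed={manifest.get('seed')}"
    paths = {
        "nodes": outdir / "nodes.csv",
        "links": outdir / "links.csv",
        "manifest": outdir / "manifest.json",
    }
    write_nodes(nodes, paths["nodes"], header_comment=comment)
    write_links(links, paths["links"], header_comment=comment)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
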