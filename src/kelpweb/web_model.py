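"""Data model for parasite-inclusive food webs.

A food web is a directed graph of consumer -> resource records. Webs are
recorded at the life-stage level (a species' larva and adult may have
different diets) and aggregated to the species level before analysis.
Links are partitioned into four sub-web classes:

* ``predator_prey``      -- a free-living consumer eating a free-living resource
  (a parasite species may also carry predator_prey links contributed by a
  free-living life stage);
* ``parasite_host``      -- a parasite consuming a host;
* ``predator_parasite``  -- concomitant predation: a predator ingesting the
  parasites of its prey along with the prey;
* ``parasite_parasite``  -- hyperparasitism / intra-host predation (allowed by
  the vocabulary, typically unobserved).

Three standard assembly versions are analyzed: the free-living web (``PP``),
the web with parasite-host links added (``PP_PH``), and the full web with
concomitant predation (``PP_PH_PC``).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

ROLES = frozenset({"free_living", "parasite"})
LINK_CLASSES = ("predator_prey", "parasite_host", "predator_parasite", "parasite_parasite")
ASSEMBLY_VERSIONS = ("PP", "PP_PH", "PP_PH_PC")

#: link classes permitted in each assembly version
PERMITTED_CLASSES = {
    "PP": frozenset({"predator_prey"}),
    "PP_PH": frozenset({"predator_prey", "parasite_host"}),
    "PP_PH_PC": frozenset(
        {"predator_prey", "parasite_host", "predator_parasite", "parasite_parasite"}
    ),
}

#: canonical column names of the node and link tables
NODE_COLUMNS = ("node_id", "species_id", "stage", "role", "strategy", "group", "extinct")
LINK_COLUMNS = (
    "consumer_id",
    "resource_id",
    "link_class",
    "trophic_transmission",
    "paratenic",
    "false_negative",
    "confidence",
)

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", "", "nan", "none", "na"}


class WebParseError(ValueError):
    """Raised when a node or link table cannot be parsed."""


class WebValidationError(ValueError):
    """Raised when a table parses but violates a structural invariant."""


@dataclass
class StageNode:
    """One life stage (or aggregate node) of the stage-resolved web."""

    node_id: str
    species_id: str
    stage: str = "all"
    role: str = "free_living"
    strategy: str = ""
    group: str = ""
    extinct: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise WebValidationError(f"unknown role {self.role!r} for node {self.node_id!r}")


@dataclass
class SpeciesNode:
    """A taxonomic species after life-stage aggregation.

    ``role`` is ``parasite`` if *any* constituent stage is parasitic.
    """

    species_id: str
    role: str = "free_living"
    group: str = ""
    extinct: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise WebValidationError(f"unknown role {self.role!r} for species {self.species_id!r}")


@dataclass(frozen=True)
class Link:
    """A directed consumer -> resource record with its sub-web class.

    ``trophic_transmission`` and ``paratenic`` are meaningful only on
    parasite_host links; ``false_negative`` marks statistically predicted but
    unobserved links consumed from upstream data.
    """

    consumer_id: str
    resource_id: str
    link_class: str = "predator_prey"
    trophic_transmission: bool = False
    paratenic: bool = False
    false_negative: bool = False
    confidence: str = ""

    def __post_init__(self) -> None:
        if self.link_class not in LINK_CLASSES:
            raise WebParseError(f"unknown link_class {self.link_class!r}")

    @property
    def key(self) -> tuple:
        return (self.consumer_id, self.resource_id, self.link_class)


@dataclass(frozen=True)
class Assembly:
    """Which sub-webs a FoodWeb contains, and whether predicted false-negative
    links are folded in."""

    version: str = "PP_PH_PC"
    include_false_negatives: bool = False

    def __post_init__(self) -> None:
        if self.version not in ASSEMBLY_VERSIONS:
            raise WebValidationError(f"unknown assembly version {self.version!r}")

    @property
    def permitted_classes(self) -> frozenset:
        return PERMITTED_CLASSES[self.version]


@dataclass
class FoodWeb:
    """A species-level web for one assembly version (no extinct species)."""

    species: dict  # species_id -> SpeciesNode
    links: list  # of Link
    assembly: Assembly

    @property
    def s_total(self) -> int:
        return len(self.species)

    @property
    def s_free(self) -> int:
        return sum(1 for sp in self.species.values() if sp.role == "free_living")

    @property
    def s_parasite(self) -> int:
        return sum(1 for sp in self.species.values() if sp.role == "parasite")

    @property
    def n_links(self) -> int:
        return len(self.links)

    def links_of_class(self, link_class: str) -> list:
        return [l for l in self.links if l.link_class == link_class]


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _TRUTHY:
        return True
    if token in _FALSY:
        return False
    raise WebParseError(f"cannot interpret {value!r} as a boolean flag")


def _read_table(path, dialect: dict | None, required: tuple) -> pd.DataFrame:
    dialect = dialect or {}
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    rename = {src: canon for canon, src in dialect.items() if src in df.columns}
    df = df.rename(columns=rename)
    for col in required:
        if col not in df.columns:
            raise WebParseError(f"missing required column {col!r} in {path}")
    return df


def read_nodes(path, dialect: dict | None = None) -> list:
    """Read a stage-level node table (CSV with header).

    ``dialect`` maps canonical column names to the file's column names so
    deposited tables with different headers can be read without code changes.
    Unknown columns are preserved in each node's ``metadata``.
    """
    df = _read_table(path, dialect, ("node_id", "species_id", "role"))
    known = set(NODE_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    nodes = []
    for rec in df.to_dict("records"):
        nodes.append(
            StageNode(
                node_id=rec["node_id"],
                species_id=rec["species_id"],
                stage=rec.get("stage", "all") or "all",
                role=rec["role"],
                strategy=rec.get("strategy", ""),
                group=rec.get("group", ""),
                extinct=_parse_bool(rec.get("extinct", False)),
                metadata={c: rec[c] for c in extra},
            )
        )
    counts: dict = {}
    for n in nodes:
        counts[n.node_id] = counts.get(n.node_id, 0) + 1
    dupes = sorted(k for k, v in counts.items() if v > 1)
    if dupes:
        raise WebValidationError(f"duplicate node_id(s): {', '.join(dupes)}")
    return nodes


def read_links(path, dialect: dict | None = None, nodes: list | None = None) -> list:
    """Read a link table (CSV with header); flags default to false when the
    column is absent. If ``nodes`` is given, endpoints are checked against it."""
    df = _read_table(path, dialect, ("consumer_id", "resource_id", "link_class"))
    links = []
    for rec in df.to_dict("records"):
        lc = rec["link_class"]
        if lc not in LINK_CLASSES:
            raise WebParseError(f"unknown link_class token {lc!r}")
        links.append(
            Link(
                consumer_id=rec["consumer_id"],
                resource_id=rec["resource_id"],
                link_class=lc,
                trophic_transmission=_parse_bool(rec.get("trophic_transmission", False)),
                paratenic=_parse_bool(rec.get("paratenic", False)),
                false_negative=_parse_bool(rec.get("false_negative", False)),
                confidence=rec.get("confidence", ""),
            )
        )
    if nodes is not None:
        ids = {n.node_id for n in nodes}
        for link in links:
            for end in (link.consumer_id, link.resource_id):
                if end not in ids:
                    raise WebValidationError(f"link endpoint {end!r} not in node table")
    return links


def write_nodes(nodes: list, path, header_comment: str | None = None) -> None:
    """Write stage nodes in the canonical CSV dialect."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(NODE_COLUMNS)
        for n in nodes:
            writer.writerow(
                [n.node_id, n.species_id, n.stage, n.role, n.strategy, n.group, str(n.extinct).lower()]
            )


def write_links(links: list, path, header_comment: str | None = None) -> None:
    """Write links in the canonical CSV dialect."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(LINK_COLUMNS)
        for l in links:
            writer.writerow(
                [
                    l.consumer_id,
                    l.resource_id,
                    l.link_class,
                    str(l.trophic_transmission).lower(),
                    str(l.paratenic).lower(),
                    str(l.false_negative).lower(),
                    l.confidence,
                ]
            )


def aggregate_stages(nodes: list, links: list) -> tuple:
    """Collapse life-stage nodes to species and re-key the links.

    Species role is parasite if any stage is parasitic, but predator_prey
    links contributed by free-living stages are retained. Exact duplicate
    (consumer, resource, link_class) triples collapse to a single link with
    flags OR-combined. Self-links created by aggregation (stage A of a species
    eating stage B of the same species) are retained.
    """
    stage_to_species = {n.node_id: n.species_id for n in nodes}
    species: dict = {}
    for n in nodes:
        sp = species.get(n.species_id)
        if sp is None:
            species[n.species_id] = SpeciesNode(
                species_id=n.species_id, role=n.role, group=n.group, extinct=n.extinct
            )
        else:
            if n.role == "parasite":
                sp.role = "parasite"
            if n.extinct:
                sp.extinct = True
            if not sp.group and n.group:
                sp.group = n.group

    merged: dict = {}
    for link in links:
        for end in (link.consumer_id, link.resource_id):
            if end not in stage_to_species:
                raise WebValidationError(f"link endpoint {end!r} not in node table")
        key = (
            stage_to_species[link.consumer_id],
            stage_to_species[link.resource_id],
            link.link_class,
        )
        prev = merged.get(key)
        if prev is None:
            merged[key] = replace(link, consumer_id=key[0], resource_id=key[1])
        else:
            merged[key] = replace(
                prev,
                trophic_transmission=prev.trophic_transmission or link.trophic_transmission,
                paratenic=prev.paratenic or link.paratenic,
                false_negative=prev.false_negative or link.false_negative,
            )
    return list(species.values()), list(merged.values())


def build_assembly(species: list, links: list, assembly: Assembly) -> FoodWeb:
    """Filter a species-level web down to one assembly version.

    Drops extinct-flagged species (and their links) first, then restricts
    links to the classes the version permits, dropping false_negative links
    unless the assembly folds them in. The PP version contains free-living
    species only.
    """
    keep = {sp.species_id: sp for sp in species if not sp.extinct}
    if assembly.version == "PP":
        keep = {sid: sp for sid, sp in keep.items() if sp.role == "free_living"}
    permitted = assembly.permitted_classes
    out: dict = {}
    for link in links:
        if link.link_class not in permitted:
            continue
        if link.false_negative and not assembly.include_false_negatives:
            continue
        if link.consumer_id not in keep or link.resource_id not in keep:
            continue
        out.setdefault(link.key, link)
    web = FoodWeb(species=keep, links=list(out.values()), assembly=assembly)
    if web.n_links == 0:
        warnings.warn(f"assembly {assembly.version} produced an empty web", stacklevel=2)
    return web


@dataclass(frozen=True)
class Violation:
    rule: str
    ids: tuple
    message: str


def validate_web(web: FoodWeb) -> list:
    """Report every invariant violation (empty list means the web conforms)."""
    out = []
    permitted = web.assembly.permitted_classes
    seen = set()
    for link in web.links:
        cid, rid = link.consumer_id, link.resource_id
        if cid not in web.species or rid not in web.species:
            out.append(Violation("dangling_endpoint", (cid, rid), "link endpoint missing from species set"))
            continue
        if link.link_class not in permitted:
            out.append(
                Violation("class_not_permitted", (cid, rid), f"{link.link_class} not in {web.assembly.version}")
            )
        if link.link_class == "parasite_host" and web.species[cid].role != "parasite":
            out.append(Violation("parasite_host_consumer", (cid, rid), "parasite_host consumer is not a parasite"))
        if link.link_class == "predator_parasite" and web.species[rid].role != "parasite":
            out.append(Violation("predator_parasite_resource", (cid, rid), "predator_parasite resource is not a parasite"))
        if (link.trophic_transmission or link.paratenic) and link.link_class != "parasite_host":
            out.append(Violation("flag_on_nonparasitic_link", (cid, rid), "life-cycle flag on non parasite_host link"))
        if link.key in seen:
            out.append(Violation("duplicate_link", (cid, rid), "duplicate (consumer, resource, class) triple"))
        seen.add(link.key)
    for sp in web.species.values():
        if sp.extinct:
            out.append(Violation("extinct_species_present", (sp.species_id,), "extinct species in assembled web"))
    return out


def to_networkx(
    web: FoodWeb,
    link_classes: tuple | None = None,
    drop_self_links: bool = False,
    orientation: str = "consumer_to_resource",
) -> nx.DiGraph:
    """Directed graph view of a web. ``orientation='resource_to_consumer'``
    flips edges so paths follow energy flow (basal -> apex)."""
    g = nx.DiGraph()
    for sid, sp in web.species.items():
        g.add_node(sid, role=sp.role, group=sp.group)
    for link in web.links:
        if link_classes is not None and link.link_class not in link_classes:
            continue
        if drop_self_links and link.consumer_id == link.resource_id:
            continue
        if orientation == "consumer_to_resource":
            u, v = link.consumer_id, link.resource_id
        else:
            u, v = link.resource_id, link.consumer_id
        g.add_edge(u, v, link_class=link.link_class)
    return g


def export_edgelist(web: FoodWeb, path) -> None:
    """Directed edge list as TSV (consumer, resource, link_class)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["consumer_id", "resource_id", "link_class"])
        for l in sorted(web.links, key=lambda x: x.key):
            writer.writerow([l.consumer_id, l.resource_id, l.link_class])


def export_graphml(web: FoodWeb, path) -> None:
    nx.write_graphml(to_networkx(web), path)
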