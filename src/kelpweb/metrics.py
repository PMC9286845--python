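"""Scalar and distributional structure metrics for a food web.

Connectance is L/S^2. For parasite-containing assemblies an *adjusted*
connectance shrinks the denominator to the links that are actually possible
given which sub-webs the assembly contains:

* PP_PH:     L / (S_free * (S_free + S_parasite)) — only free-living species
  can be resources when concomitant predation is excluded;
* PP_PH_PC:  L / (S_total^2 - S_parasite^2) — all pairs except the (unobserved)
  parasite-on-parasite quadrant.

Trophic level is prey-averaged (1 for basal species, otherwise 1 + the mean
level of the diet), solved as a linear system so feeding cycles are handled;
predator-parasite (concomitant) links are excluded because accidental
ingestion of a parasite carries no meaningful energy to the consumer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .web_model import FoodWeb


class UndefinedMetricError(ValueError):
    """A metric is not defined for this assembly or web shape."""


def basic_counts(web: FoodWeb) -> tuple:
    """(S_total, S_free, S_parasite, L, proportion of parasite species)."""
    s_total, s_free, s_par = web.s_total, web.s_free, web.s_parasite
    prop = s_par / s_total if s_total else 0.0
    return s_total, s_free, s_par, web.n_links, prop


def link_density(web: FoodWeb) -> float:
    return web.n_links / web.s_total


def connectance(web: FoodWeb) -> float:
    """L / S^2; self-links count toward L."""
    return web.n_links / web.s_total**2


def adjusted_connectance_from_counts(
    n_links: int, s_free: int, s_parasite: int, version: str
) -> float:
    """Adjusted connectance from raw counts (also usable on published tables)."""
    if version == "PP_PH":
        denom = s_free * (s_free + s_parasite)
    elif version == "PP_PH_PC":
        s_total = s_free + s_parasite
        denom = s_total**2 - s_parasite**2
    else:
        raise UndefinedMetricError(f"adjusted connectance undefined for assembly {version!r}")
    return n_links / denom


def adjusted_connectance(web: FoodWeb) -> float:
    return adjusted_connectance_from_counts(
        web.n_links, web.s_free, web.s_parasite, web.assembly.version
    )


@dataclass
class DegreeStats:
    """Per-species generality (diet breadth), vulnerability (enemy count) and
    total degree, with their means and SDs."""

    generality: dict
    vulnerability: dict
    degree: dict
    mean_degree: float
    sd_degree: float
    mean_generality: float
    sd_generality: float
    mean_vulnerability: float
    sd_vulnerability: float


def degree_stats(web: FoodWeb, ddof: int = 1, denominator: str = "all") -> DegreeStats:
    """Tabulate generality g_i (resources of i), vulnerability v_i (consumers
    of i), and degree d_i = g_i + v_i.

    ``denominator='all'`` averages over every species (so mean generality =
    mean vulnerability = L/S); ``'participants'`` restricts the generality
    mean/SD to consumers and the vulnerability mean/SD to resources.
    SDs use ``ddof`` (sample convention by default).
    """
    g = {sid: 0 for sid in web.species}
    v = {sid: 0 for sid in web.species}
    for link in web.links:
        g[link.consumer_id] += 1
        v[link.resource_id] += 1
    d = {sid: g[sid] + v[sid] for sid in web.species}

    def _stats(values):
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            return math.nan, math.nan
        sd = float(arr.std(ddof=ddof)) if arr.size > ddof else math.nan
        return float(arr.mean()), sd

    if denominator == "all":
        gvals, vvals = list(g.values()), list(v.values())
    elif denominator == "participants":
        gvals = [x for x in g.values() if x > 0]
        vvals = [x for x in v.values() if x > 0]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    mean_g, sd_g = _stats(gvals)
    mean_v, sd_v = _stats(vvals)
    mean_d, sd_d = _stats(list(d.values()))
    return DegreeStats(g, v, d, mean_d, sd_d, mean_g, sd_g, mean_v, sd_v)


def trophic_levels(web: FoodWeb) -> dict:
    """Prey-averaged trophic level per species.

    Basal species (no resources after dropping predator_parasite links and
    self-links) have level 1; every other species has 1 + the mean level of
    its resources. Solved as (I - W) t = 1 with W the row-normalized diet
    matrix, which handles feeding loops.
    """
    ids = sorted(web.species)
    idx = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    diets: list = [[] for _ in range(n)]
    for link in web.links:
        if link.link_class == "predator_parasite":
            continue
        if link.consumer_id == link.resource_id:
            continue
        diets[idx[link.consumer_id]].append(idx[link.resource_id])
    a = np.eye(n)
    for i, diet in enumerate(diets):
        if diet:
            w = 1.0 / len(diet)
            for j in diet:
                a[i, j] -= w
    try:
        tl = np.linalg.solve(a, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise UndefinedMetricError(
            "trophic levels are undefined: diet matrix is singular (no basal species reachable)"
        ) from exc
    return {sid: float(tl[idx[sid]]) for sid in ids}


def _scc_longest_paths(vertices: list, succ: dict, budget: list) -> dict:
    """All-pairs longest simple path lengths (in nodes, endpoints included)
    inside one strongly connected component, by exhaustive DFS. Cheap because
    feeding loops in food webs are small; ``budget`` guards pathology."""
    inside = set(vertices)
    table: dict = {}

    def dfs(start, v, visited):
        budget[0] -= 1
        if budget[0] < 0:
            raise RuntimeError("longest_chain node budget exhausted; raise node_budget")
        key = (start, v)
        if len(visited) > table.get(key, 0):
            table[key] = len(visited)
        for w in succ[v]:
            if w in inside and w not in visited:
                visited.add(w)
                dfs(start, w, visited)
                visited.remove(w)

    for s in vertices:
        dfs(s, s, {s})
    return table


NEG = -(10**9)


def longest_chain(web: FoodWeb, node_budget: int = 5_000_000) -> int:
    """Node count of the longest acyclic food chain from a basal species (no
    resources) to an apex species (no consumers), over all links in the
    assembly; self-links are ignored.

    Exact also on cyclic webs: a simple path crosses each strongly connected
    component at most once, so the maximum decomposes into within-component
    longest simple paths (exhaustive DFS over the component only, guarded by
    ``node_budget``) chained by dynamic programming over the acyclic
    condensation.
    """
    import networkx as nx

    from .web_model import to_networkx

    g = to_networkx(web, drop_self_links=True, orientation="resource_to_consumer")
    basal = {v for v in g if g.in_degree(v) == 0}
    apex = [v for v in g if g.out_degree(v) == 0]
    if not basal or not apex:
        raise UndefinedMetricError("no basal or no apex species: longest chain undefined")

    succ = {v: list(g.successors(v)) for v in g}
    cond = nx.condensation(g)
    budget = [node_budget]
    best = {v: NEG for v in g}  # longest basal-started chain ending at v
    for comp_id in nx.topological_sort(cond):
        members = sorted(cond.nodes[comp_id]["members"])
        # chain enters the component here: either starting basal or arriving
        # over a cross edge from an already-finished component
        entry = {}
        for v in members:
            e = 1 if v in basal else NEG
            for u in g.predecessors(v):
                if u not in cond.nodes[comp_id]["members"] and best[u] + 1 > e:
                    e = best[u] + 1
            entry[v] = e
        if len(members) == 1:
            v = members[0]
            best[v] = entry[v]
            continue
        table = _scc_longest_paths(members, succ, budget)
        for w in members:
            best[w] = max(
                (entry[v] + table[(v, w)] - 1 for v in members if entry[v] > NEG and (v, w) in table),
                default=NEG,
            )
    result = max(best[a] for a in apex)
    if result < 1:
        raise UndefinedMetricError("no basal-to-apex chain exists")
    return result


@dataclass
class SubwebReport:
    counts: dict
    fractions: dict
    tt_count: int
    tt_fraction_of_links: float
    tt_fraction_of_parasite_host: float
    paratenic_count: int
    paratenic_fraction_of_links: float
    paratenic_fraction_of_parasite_host: float


def subweb_proportions(web: FoodWeb) -> SubwebReport:
    """Counts and fractions of links per sub-web class, plus the trophically
    transmitted and paratenic fractions of the parasite-host sub-web."""
    counts = {lc: 0 for lc in ("predator_prey", "parasite_host", "predator_parasite", "parasite_parasite")}
    tt = par = 0
    for link in web.links:
        counts[link.link_class] += 1
        if link.link_class == "parasite_host":
            tt += link.trophic_transmission
            par += link.paratenic
    total = web.n_links
    fractions = {lc: (c / total if total else 0.0) for lc, c in counts.items()}
    ph = counts["parasite_host"]
    return SubwebReport(
        counts=counts,
        fractions=fractions,
        tt_count=tt,
        tt_fraction_of_links=tt / total if total else 0.0,
        tt_fraction_of_parasite_host=tt / ph if ph else 0.0,
        paratenic_count=par,
        paratenic_fraction_of_links=par / total if total else 0.0,
        paratenic_fraction_of_parasite_host=par / ph if ph else 0.0,
    )


@dataclass
class MetricReport:
    """The standard metric panel for one assembly."""

    assembly: str
    s_total: int
    s_free: int
    s_parasite: int
    n_links: int
    proportion_parasite_species: float
    link_density: float
    connectance: float
    adjusted_connectance: float | None
    longest_chain: int | None
    mean_degree: float
    sd_degree: float
    mean_generality: float
    sd_generality: float
    mean_vulnerability: float
    sd_vulnerability: float
    subweb_counts: dict = field(default_factory=dict)
    subweb_fractions: dict = field(default_factory=dict)
    trophic_level: dict = field(default_factory=dict)

    def to_flat_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "assembly",
                "s_total",
                "s_free",
                "s_parasite",
                "n_links",
                "proportion_parasite_species",
                "link_density",
                "connectance",
                "adjusted_connectance",
                "longest_chain",
                "mean_degree",
                "sd_degree",
                "mean_generality",
                "sd_generality",
                "mean_vulnerability",
                "sd_vulnerability",
            )
        }
        for lc, c in self.subweb_counts.items():
            out[f"n_{lc}"] = c
            out[f"frac_{lc}"] = self.subweb_fractions[lc]
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat_dict(), fh, indent=2)


def metric_report(
    web: FoodWeb,
    compute_longest_chain: bool = True,
    compute_trophic_levels: bool = True,
    ddof: int = 1,
    node_budget: int = 5_000_000,
) -> MetricReport:
    """Assemble the full metric panel for a web."""
    s_total, s_free, s_par, n_links, prop = basic_counts(web)
    deg = degree_stats(web, ddof=ddof)
    sub = subweb_proportions(web)
    try:
        adj = adjusted_connectance(web)
    except UndefinedMetricError:
        adj = None
    chain = None
    if compute_longest_chain:
        try:
            chain = longest_chain(web, node_budget=node_budget)
        except (UndefinedMetricError, RuntimeError):
            chain = None
    tl = trophic_levels(web) if compute_trophic_levels else {}
    return MetricReport(
        assembly=web.assembly.version,
        s_total=s_total,
        s_free=s_free,
        s_parasite=s_par,
        n_links=n_links,
        proportion_parasite_species=prop,
        link_density=link_density(web),
        connectance=connectance(web),
        adjusted_connectance=adj,
        longest_chain=chain,
        mean_degree=deg.mean_degree,
        sd_degree=deg.sd_degree,
        mean_generality=deg.mean_generality,
        sd_generality=deg.sd_generality,
        mean_vulnerability=deg.mean_vulnerability,
        sd_vulnerability=deg.sd_vulnerability,
        subweb_counts=sub.counts,
        subweb_fractions=sub.fractions,
        trophic_level=tl,
    )
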