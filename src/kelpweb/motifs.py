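"""Census of the 13 connected three-node motif classes.

Directed three-node subgraphs (triads) are the base structural units of a food
web: chains, omnivory, apparent and exploitative competition, loops, and their
"double" variants that contain at least one mutually consuming pair (e.g. a
predator that eats a parasite which also infects it). Classes S1-S5 have no
mutual pair; D1-D8 do. The canonical adjacency of each class ships as a JSON
fixture (``data/motif_classes.json``), the single source of truth: a lookup
table over all 64 possible edge subsets on three nodes is built from it by
brute-force isomorphism at import time.

The census itself is edge-driven (it touches only connected triples, never all
C(S,3) combinations) and strips self-links first, as triad censuses
conventionally do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import permutations

import pandas as pd

from .niche_null import model_error
from .web_model import FoodWeb

DISCONNECTED = "disconnected"

#: bit position of each ordered edge among nodes (0, 1, 2)
_EDGE_BITS = {(0, 1): 1, (1, 0): 2, (0, 2): 4, (2, 0): 8, (1, 2): 16, (2, 1): 32}


def _load_canonical() -> dict:
    text = resources.files("kelpweb.data").joinpath("motif_classes.json").read_text()
    spec = json.loads(text)
    return {cls["label"]: frozenset(map(tuple, cls["edges"])) for cls in spec["classes"]}


CANONICAL_EDGES = _load_canonical()
CLASS_LABELS = tuple(CANONICAL_EDGES)
S_CLASSES = tuple(l for l in CLASS_LABELS if l.startswith("S"))
D_CLASSES = tuple(l for l in CLASS_LABELS if l.startswith("D"))


def _code(edges) -> int:
    return sum(_EDGE_BITS[e] for e in edges)


def _build_lut() -> list:
    # every relabeling of each canonical class fills its codes in the table
    lut = [DISCONNECTED] * 64
    for label, edges in CANONICAL_EDGES.items():
        for perm in permutations(range(3)):
            relabeled = {(perm[a], perm[b]) for a, b in edges}
            lut[_code(relabeled)] = label
    return lut


_LUT = _build_lut()


def classify_triad(edges, nodes=None) -> str:
    """Class label of a directed edge set among three labeled nodes, or
    ``"disconnected"`` when the triple is not weakly connected. Self-links
    are ignored."""
    edges = [(a, b) for a, b in edges if a != b]
    if nodes is None:
        nodes = sorted({x for e in edges for x in e})
    else:
        nodes = sorted(nodes)
    if len(nodes) != 3:
        if len(nodes) > 3:
            raise ValueError("triad classification needs exactly three nodes")
        return DISCONNECTED
    index = {v: i for i, v in enumerate(nodes)}
    return _LUT[_code((index[a], index[b]) for a, b in edges)]


@dataclass
class TriadCensus:
    """Counts and proportions over the 13 connected triad classes."""

    counts: dict
    n_connected_triads: int

    @property
    def proportions(self) -> dict:
        n = self.n_connected_triads
        return {l: (c / n if n else 0.0) for l, c in self.counts.items()}

    def d_class_proportion(self) -> float:
        n = self.n_connected_triads
        return sum(self.counts[l] for l in D_CLASSES) / n if n else 0.0


def triad_census(web: FoodWeb) -> TriadCensus:
    """Edge-driven census: iterates over connected triples only, counting each
    once (Batagelj-Mrvar style enumeration). Self-links are stripped."""
    ids = sorted(web.species)
    index = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    out = [set() for _ in range(n)]
    und = [set() for _ in range(n)]
    for link in web.links:
        i, j = index[link.consumer_id], index[link.resource_id]
        if i == j:
            continue
        out[i].add(j)
        und[i].add(j)
        und[j].add(i)

    counts = {l: 0 for l in CLASS_LABELS}
    total = 0
    for u in range(n):
        for v in und[u]:
            if v <= u:
                continue
            third = (und[u] | und[v]) - {u, v}
            for w in third:
                if not (v < w or (u < w < v and w not in und[u])):
                    continue  # this triple is handled at another anchor pair
                code = 0
                a, b, c = sorted((u, v, w))
                if b in out[a]:
                    code |= 1
                if a in out[b]:
                    code |= 2
                if c in out[a]:
                    code |= 4
                if a in out[c]:
                    code |= 8
                if c in out[b]:
                    code |= 16
                if b in out[c]:
                    code |= 32
                counts[_LUT[code]] += 1
                total += 1
    return TriadCensus(counts=counts, n_connected_triads=total)


@dataclass
class MotifStandardizationRow:
    label: str
    empirical_count: int
    empirical_proportion: float
    model_median_proportion: float
    ratio: float
    me: float
    zero_median: bool


def motif_standardization(census: TriadCensus, ensemble_censuses: list) -> list:
    """Per class: empirical proportion, model median proportion, the
    overrepresentation ratio (empirical / model median) and the model error.

    Classes whose model median proportion is zero get a pseudocount of
    1 / n_connected_triads (of the empirical census) in the ratio denominator
    and are flagged ``zero_median``.
    """
    if not ensemble_censuses:
        raise ValueError("empty null-census ensemble")
    emp = census.proportions
    pseudo = 1.0 / census.n_connected_triads if census.n_connected_triads else 1.0
    rows = []
    for label in CLASS_LABELS:
        null_props = [c.proportions[label] for c in ensemble_censuses]
        res = model_error(emp[label], null_props, metric=label)
        zero = res.model_median == 0.0
        denom = res.model_median + (pseudo if zero else 0.0)
        rows.append(
            MotifStandardizationRow(
                label=label,
                empirical_count=census.counts[label],
                empirical_proportion=emp[label],
                model_median_proportion=res.model_median,
                ratio=emp[label] / denom,
                me=res.me,
                zero_median=zero,
            )
        )
    return rows


def standardization_to_frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.label for r in rows],
            "count": [r.empirical_count for r in rows],
            "proportion": [r.empirical_proportion for r in rows],
            "model_median": [r.model_median_proportion for r in rows],
            "ratio": [r.ratio for r in rows],
            "me": [r.me for r in rows],
            "zero_median_flag": [r.zero_median for r in rows],
        }
    )
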