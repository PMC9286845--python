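"""Vulnerability and generality decomposed by enemy type.

Free-living species are vulnerable to free-living predators and to parasites;
parasites here are vulnerable only through concomitant predation (a predator
eating their host). Generality (diet breadth) excludes concomitant links:
a parasite's breadth is its host count (plus any predatory links contributed
by free-living life stages).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from . import metrics as _metrics
from .web_model import FoodWeb


@dataclass
class EnemyProfile:
    """Per-species enemy counts by consumer link class."""

    species_id: str
    role: str
    n_predators: int
    n_parasites: int
    n_concomitant: int
    trophic_level: float

    @property
    def total_vulnerability(self) -> int:
        return self.n_predators + self.n_parasites + self.n_concomitant


def enemy_profiles(web: FoodWeb, trophic_level: dict | None = None) -> list:
    """Tabulate, for every species, its predators (predator_prey consumers),
    parasites (parasite_host consumers) and concomitant predators
    (predator_parasite consumers). Prefer a PP_PH_PC web so all enemy classes
    are present. Trophic levels are computed if not supplied."""
    if trophic_level is None:
        trophic_level = _metrics.trophic_levels(web)
    pred = {sid: 0 for sid in web.species}
    para = {sid: 0 for sid in web.species}
    conc = {sid: 0 for sid in web.species}
    for link in web.links:
        rid = link.resource_id
        if link.link_class == "predator_prey":
            pred[rid] += 1
        elif link.link_class == "parasite_host":
            para[rid] += 1
        elif link.link_class == "predator_parasite":
            conc[rid] += 1
    return [
        EnemyProfile(
            species_id=sid,
            role=sp.role,
            n_predators=pred[sid],
            n_parasites=para[sid],
            n_concomitant=conc[sid],
            trophic_level=trophic_level.get(sid, math.nan),
        )
        for sid, sp in sorted(web.species.items())
    ]


@dataclass
class GeneralityProfile:
    """Diet breadth per species, split by link class; concomitant
    (predator_parasite) links never count as diet items."""

    species_id: str
    role: str
    n_prey: int  # predator_prey resources
    n_hosts: int  # parasite_host resources

    @property
    def diet_breadth(self) -> int:
        return self.n_prey + self.n_hosts


def generality_profiles(web: FoodWeb) -> list:
    prey = {sid: 0 for sid in web.species}
    hosts = {sid: 0 for sid in web.species}
    for link in web.links:
        if link.link_class == "predator_prey":
            prey[link.consumer_id] += 1
        elif link.link_class == "parasite_host":
            hosts[link.consumer_id] += 1
    return [
        GeneralityProfile(species_id=sid, role=sp.role, n_prey=prey[sid], n_hosts=hosts[sid])
        for sid, sp in sorted(web.species.items())
    ]


@dataclass
class RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of two samples."""

    u: float
    z: float
    p_two_sided: float
    n1: int
    n2: int
    method: str


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def rank_sum_test(sample_a, sample_b, method: str = "auto", continuity: bool = True) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    U is taken from sample_a's rank sum. The normal approximation uses the
    tie-corrected variance of U and, by default, the continuity correction
    (as JMP and R apply). ``method='exact'`` enumerates every assignment of
    the pooled (mid-)ranks to the two samples; ``'auto'`` switches to exact
    when n1 + n2 <= 12.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n = n1 + n2
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u == 0:
        z = 0.0
    else:
        cc = 0.5 if (continuity and u != mu) else 0.0
        z = math.copysign(max(abs(u - mu) - cc, 0.0), u - mu) / math.sqrt(var_u)

    if method == "auto":
        method = "exact" if n <= 12 else "normal"
    if method == "normal":
        p = min(1.0, 2.0 * _sstats.norm.sf(abs(z))) if var_u > 0 else 1.0
    elif method == "exact":
        obs_dev = abs(u - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n), n1):
            u_perm = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankSumResult(u=float(u), z=float(z), p_two_sided=float(p), n1=n1, n2=n2, method=method)


def top_generalists(web: FoodWeb, k: int = 10) -> pd.DataFrame:
    """The k most general consumers by diet breadth (concomitant links never
    counted), ties broken lexicographically by species id."""
    profiles = generality_profiles(web)
    ranked = sorted(profiles, key=lambda p: (-p.diet_breadth, p.species_id))[:k]
    return pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "species_id": [p.species_id for p in ranked],
            "diet_breadth": [p.diet_breadth for p in ranked],
            "role": [p.role for p in ranked],
        }
    )


def enemies_by_trophic_level(profiles: list, bin_width: float = 1.0) -> pd.DataFrame:
    """Mean predator and parasite enemy counts of free-living species binned
    by trophic level (bins labeled by their floor). Empty bins carry count 0
    and NaN means."""
    free = [p for p in profiles if p.role == "free_living" and not math.isnan(p.trophic_level)]
    if not free:
        return pd.DataFrame(columns=["tl_bin", "n_species", "mean_predators", "mean_parasites"])
    tls = np.array([p.trophic_level for p in free])
    lo = math.floor(tls.min() / bin_width) * bin_width
    hi = math.floor(tls.max() / bin_width) * bin_width
    rows = []
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    for left in edges:
        mask = (tls >= left) & (tls < left + bin_width)
        if left == edges[-1]:  # top bin closed so the maximum is included
            mask = (tls >= left) & (tls <= left + bin_width)
        members = [p for p, m in zip(free, mask) if m]
        rows.append(
            {
                "tl_bin": float(left),
                "n_species": len(members),
                "mean_predators": float(np.mean([p.n_predators for p in members])) if members else math.nan,
                "mean_parasites": float(np.mean([p.n_parasites for p in members])) if members else math.nan,
            }
        )
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: list) -> pd.DataFrame:
    if profiles and isinstance(profiles[0], EnemyProfile):
        return pd.DataFrame(
            {
                "species_id": [p.species_id for p in profiles],
                "role": [p.role for p in profiles],
                "n_predators": [p.n_predators for p in profiles],
                "n_parasites": [p.n_parasites for p in profiles],
                "n_concomitant": [p.n_concomitant for p in profiles],
                "trophic_level": [p.trophic_level for p in profiles],
            }
        )
    return pd.DataFrame(
        {
            "species_id": [p.species_id for p in profiles],
            "role": [p.role for p in profiles],
            "n_prey": [p.n_prey for p in profiles],
            "n_hosts": [p.n_hosts for p in profiles],
            "diet_breadth": [p.diet_breadth for p in profiles],
        }
    )
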