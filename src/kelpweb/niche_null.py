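"""Niche-model null webs and the model-error (ME) statistic.

The niche model places each species at a niche value n_i ~ U(0,1), gives it a
feeding range r_i = x * n_i with x ~ Beta(1, beta) where
beta = (1 - 2C) / (2C), and a range center c_i ~ U(r_i/2, n_i); species i then
consumes everything whose niche value falls inside
[c_i - r_i/2, c_i + r_i/2]. The species with the smallest niche value gets
r = 0 so at least one basal species exists. Webs with isolated species or
more than one weakly connected component are rejected and redrawn, as in the
standard protocol.

The model error compares an empirical metric against an ensemble of such webs
matched on S and C:

    ME = (x - med) / (q975 - med)   if x >= med
    ME = (x - med) / (med - q025)   otherwise

so |ME| > 1 exactly when the empirical value falls outside the central 95% of
model values, and the sign says whether the metric is over- or
under-represented relative to the model median.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .web_model import Assembly, FoodWeb, Link, SpeciesNode


@dataclass(frozen=True)
class NicheParams:
    """Size and connectance target of a niche-model ensemble."""

    s: int
    c: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.c < 0.5:
            raise ValueError(f"connectance target must be in (0, 0.5), got {self.c}")
        if self.s < 2:
            raise ValueError("need at least two species")

    @property
    def beta(self) -> float:
        return (1 - 2 * self.c) / (2 * self.c)


def _niche_adjacency(params: NicheParams, rng: np.random.Generator) -> np.ndarray:
    s = params.s
    n = rng.uniform(size=s)
    r = n * rng.beta(1.0, params.beta, size=s)
    r[np.argmin(n)] = 0.0
    c = rng.uniform(r / 2.0, n)
    low = c - r / 2.0
    high = c + r / 2.0
    # a[i, j] True when consumer i's range covers species j's niche value
    return (n[None, :] >= low[:, None]) & (n[None, :] <= high[:, None])


def _acceptable(a: np.ndarray) -> bool:
    off = a.copy()
    np.fill_diagonal(off, False)
    und = off | off.T
    deg = und.sum(axis=0)
    if (deg == 0).any():  # isolated species (self-links do not count)
        return False
    # single weakly connected component via BFS on the undirected adjacency
    s = a.shape[0]
    seen = np.zeros(s, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        v = stack.pop()
        nbrs = np.flatnonzero(und[v] & ~seen)
        seen[nbrs] = True
        stack.extend(nbrs.tolist())
    return bool(seen.all())


def generate_niche_web(
    params: NicheParams,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
    prefix: str = "N",
) -> FoodWeb:
    """Draw one niche-model web as a PP-assembly FoodWeb (all links
    predator_prey, all species free-living). Rejected draws (isolated species
    or a disconnected web) are resampled up to ``max_attempts`` times."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    for _ in range(max_attempts):
        a = _niche_adjacency(params, rng)
        if _acceptable(a):
            break
    else:
        raise RuntimeError(f"niche web rejected {max_attempts} times (S={params.s}, C={params.c})")
    width = max(4, len(str(params.s)))
    ids = [f"{prefix}{i:0{width}d}" for i in range(params.s)]
    species = {sid: SpeciesNode(species_id=sid) for sid in ids}
    cons, res = np.nonzero(a)
    links = [Link(consumer_id=ids[i], resource_id=ids[j]) for i, j in zip(cons.tolist(), res.tolist())]
    return FoodWeb(species=species, links=links, assembly=Assembly(version="PP"))


def _sd_degree(web: FoodWeb) -> float:
    return _metrics.degree_stats(web).sd_degree


def _sd_generality(web: FoodWeb) -> float:
    return _metrics.degree_stats(web).sd_generality


def _sd_vulnerability(web: FoodWeb) -> float:
    return _metrics.degree_stats(web).sd_vulnerability


def _longest_chain(web: FoodWeb) -> float:
    return float(_metrics.longest_chain(web))


def _min_sum_diet_gaps(web: FoodWeb) -> float:
    from .contiguity import min_sum_diet_gaps

    # single optimization per null web keeps thousand-web ensembles tractable
    return float(min_sum_diet_gaps(web, n_restarts=1, seed=0).sum_diet_gaps)


#: metric names resolvable inside ensembles
METRIC_FUNCS = {
    "connectance": _metrics.connectance,
    "link_density": _metrics.link_density,
    "longest_chain": _longest_chain,
    "sd_degree": _sd_degree,
    "sd_generality": _sd_generality,
    "sd_vulnerability": _sd_vulnerability,
    "min_sum_diet_gaps": _min_sum_diet_gaps,
}


@dataclass
class NicheEnsemble:
    """Per-simulation metric values from a matched niche-model ensemble."""

    params: NicheParams
    n_sims: int
    metric_values: dict = field(default_factory=dict)
    triad_censuses: list = field(default_factory=list)

    def values(self, metric: str) -> list:
        return self.metric_values[metric]


def ensemble_metrics(
    params: NicheParams,
    n_sims: int,
    metric_names: list,
    seed: int | None = None,
    collect_triads: bool = False,
) -> NicheEnsemble:
    """Simulate ``n_sims`` matched niche webs and evaluate the named metrics
    on each; per-simulation values are retained. Reproducible under a fixed
    seed (falls back to ``params.seed``)."""
    unknown = [m for m in metric_names if m not in METRIC_FUNCS]
    if unknown:
        raise KeyError(f"unknown metric name(s): {unknown}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    values: dict = {m: [] for m in metric_names}
    censuses = []
    for _ in range(n_sims):
        web = generate_niche_web(params, rng=rng)
        for m in metric_names:
            try:
                values[m].append(float(METRIC_FUNCS[m](web)))
            except (_metrics.UndefinedMetricError, RuntimeError):
                # e.g. a null web whose top is a feeding loop has no apex, so
                # no basal-to-apex chain exists (or a pathological draw blows
                # the chain-search budget); recorded as NaN and ignored by
                # model_error
                values[m].append(float("nan"))
        if collect_triads:
            from .motifs import triad_census

            censuses.append(triad_census(web))
    return NicheEnsemble(params=params, n_sims=n_sims, metric_values=values, triad_censuses=censuses)


@dataclass
class MEResult:
    """Model error of one empirical metric against one ensemble."""

    metric: str
    empirical: float
    model_median: float
    q025: float
    q975: float
    me: float
    zero_width: bool = False


def model_error(empirical: float, values, metric: str = "") -> MEResult:
    """Normalized deviation of an empirical value from a null ensemble.

    Quantiles use linear interpolation. NaN ensemble entries (metric undefined
    on a null draw) are dropped. A zero-width half-interval yields ME = 0 when
    the empirical value sits on the median, otherwise a signed infinity with
    ``zero_width`` flagged.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("empty ensemble value list")
    q025, med, q975 = np.quantile(arr, [0.025, 0.5, 0.975])
    if empirical >= med:
        half = q975 - med
        sign = 1.0
    else:
        half = med - q025
        sign = -1.0
    if half == 0:
        if empirical == med:
            me, zero = 0.0, False
        else:
            me, zero = sign * math.inf, True
    else:
        me, zero = (empirical - med) / half, False
    return MEResult(
        metric=metric,
        empirical=float(empirical),
        model_median=float(med),
        q025=float(q025),
        q975=float(q975),
        me=float(me),
        zero_width=zero,
    )


def me_table(empirical_values: dict, ensemble: NicheEnsemble) -> pd.DataFrame:
    """Model errors for several metrics at once, as a tidy DataFrame."""
    rows = []
    for metric, emp in empirical_values.items():
        res = model_error(emp, ensemble.values(metric), metric=metric)
        rows.append(
            {
                "metric": metric,
                "empirical": res.empirical,
                "model_median": res.model_median,
                "q025": res.q025,
                "q975": res.q975,
                "me": res.me,
                "outside_central_95": abs(res.me) > 1,
            }
        )
    return pd.DataFrame(rows)


def save_ensemble(ensemble: NicheEnsemble, csv_path, sidecar_path=None) -> None:
    """Persist per-simulation values as long-form CSV plus a JSON sidecar with
    the generating parameters."""
    rows = []
    for metric, vals in ensemble.metric_values.items():
        for i, v in enumerate(vals):
            rows.append({"sim_index": i, "metric": metric, "value": v})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "S": ensemble.params.s,
                    "C": ensemble.params.c,
                    "seed": ensemble.params.seed,
                    "n_sims": ensemble.n_sims,
                },
                fh,
                indent=2,
            )


def load_ensemble(csv_path, sidecar_path) -> NicheEnsemble:
    df = pd.read_csv(csv_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    values = {m: g.sort_values("sim_index")["value"].tolist() for m, g in df.groupby("metric")}
    return NicheEnsemble(
        params=NicheParams(s=meta["S"], c=meta["C"], seed=meta.get("seed")),
        n_sims=meta["n_sims"],
        metric_values=values,
    )
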