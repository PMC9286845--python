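"""One-command reproduction of the full analysis battery on any input web.

For each requested assembly version the run produces: the metric panel,
a model-error table against a matched niche ensemble, the triad census with
its niche-model standardization, the diet-gap minimization, and the
enemy/generality profiles with rank-sum comparisons. All outputs are CSV/JSON
with provenance metadata (seed, config hash, package version); ensembles are
cached per (S, C, n_sims, seed) so assemblies sharing a null do not regenerate
it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import metrics as _metrics
from .contiguity import AnnealSchedule, min_sum_diet_gaps
from .enemies import (
    enemies_by_trophic_level,
    enemy_profiles,
    generality_profiles,
    profiles_to_frame,
    rank_sum_test,
    top_generalists,
)
from .motifs import motif_standardization, standardization_to_frame, triad_census
from .niche_null import NicheParams, ensemble_metrics, me_table
from .synthetic_data import SynthParams, assemble, generate_parasite_web
from .web_model import read_links, read_nodes

logger = logging.getLogger("kelpweb")

#: Metrics standardized against the niche model by default (the ones that
#: vary within the model; connectance and the means do not).
DEFAULT_ME_METRICS = ("longest_chain", "sd_degree", "sd_generality", "sd_vulnerability")


@dataclass
class RunConfig:
    """Inputs, assemblies, null-ensemble and annealing settings for one run."""

    nodes_path: str | None = None
    links_path: str | None = None
    synth: dict | None = None
    assemblies: tuple = ("PP", "PP_PH", "PP_PH_PC")
    include_false_negatives: bool = False
    n_sims: int = 1000
    me_metrics: tuple = DEFAULT_ME_METRICS
    include_diet_gap_me: bool = False
    n_restarts: int = 10
    anneal: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "kelpweb_run"
    longest_chain_budget: int = 5_000_000

    def __post_init__(self) -> None:
        if not self.assemblies:
            raise ValueError("at least one assembly version must be requested")
        has_files = self.nodes_path is not None and self.links_path is not None
        if has_files == (self.synth is not None):
            raise ValueError("provide either nodes/links paths or synth params, not both")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "assemblies" in raw:
            raw["assemblies"] = tuple(raw["assemblies"])
        if "me_metrics" in raw:
            raw["me_metrics"] = tuple(raw["me_metrics"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_tables(config: RunConfig) -> tuple:
    if config.synth is not None:
        params = SynthParams(**{**config.synth, "seed": config.synth.get("seed", config.seed)})
        nodes, links, manifest = generate_parasite_web(params)
        return nodes, links, manifest
    nodes = read_nodes(config.nodes_path)
    links = read_links(config.links_path, nodes=nodes)
    return nodes, links, {"nodes_path": str(config.nodes_path), "links_path": str(config.links_path)}


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage for every requested assembly; returns the output paths.

    Any stage failure aborts with the stage name in the exception; outputs
    written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes, links, source_meta = _load_tables(config)
    ensemble_cache: dict = {}
    schedule = AnnealSchedule(**config.anneal) if config.anneal else AnnealSchedule()
    produced: dict = {}

    for version in config.assemblies:
        stage = f"{version}:assemble"
        try:
            web = assemble(nodes, links, version, config.include_false_negatives)
            vdir = outdir / version
            vdir.mkdir(exist_ok=True)

            stage = f"{version}:metrics"
            report = _metrics.metric_report(web, node_budget=config.longest_chain_budget)
            report.to_json(vdir / "metrics.json")

            stage = f"{version}:contiguity"
            ordering = min_sum_diet_gaps(
                web, n_restarts=config.n_restarts, schedule=schedule, seed=config.seed
            )
            with open(vdir / "diet_gaps.json", "w") as fh:
                json.dump(
                    {
                        "mean_sum_diet_gaps": ordering.mean_sum_diet_gaps,
                        "min_sum_diet_gaps": ordering.min_sum_diet_gaps,
                        "per_restart": ordering.per_restart_values,
                    },
                    fh,
                    indent=2,
                )

            stage = f"{version}:null_ensemble"
            c_match = (
                _metrics.adjusted_connectance(web)
                if version != "PP"
                else _metrics.connectance(web)
            )
            me_metric_names = list(config.me_metrics)
            if config.include_diet_gap_me and "min_sum_diet_gaps" not in me_metric_names:
                me_metric_names.append("min_sum_diet_gaps")
            key = (web.s_total, round(c_match, 6), config.n_sims, config.seed, tuple(me_metric_names))
            if key not in ensemble_cache:
                logger.info("simulating %d niche webs at S=%d C=%.4f", config.n_sims, web.s_total, c_match)
                ensemble_cache[key] = ensemble_metrics(
                    NicheParams(s=web.s_total, c=c_match),
                    n_sims=config.n_sims,
                    metric_names=me_metric_names,
                    seed=config.seed,
                    collect_triads=True,
                )
            ensemble = ensemble_cache[key]

            stage = f"{version}:model_error"
            empirical = {
                "longest_chain": report.longest_chain,
                "sd_degree": report.sd_degree,
                "sd_generality": report.sd_generality,
                "sd_vulnerability": report.sd_vulnerability,
            }
            if "min_sum_diet_gaps" in me_metric_names:
                empirical["min_sum_diet_gaps"] = ordering.mean_sum_diet_gaps
            empirical = {
                k: v for k, v in empirical.items() if k in me_metric_names and v is not None
            }
            me_table(empirical, ensemble).to_csv(vdir / "model_error.csv", index=False)

            stage = f"{version}:motifs"
            census = triad_census(web)
            rows = motif_standardization(census, ensemble.triad_censuses)
            standardization_to_frame(rows).to_csv(vdir / "motifs.csv", index=False)

            stage = f"{version}:enemies"
            eprofiles = enemy_profiles(web, trophic_level=report.trophic_level or None)
            profiles_to_frame(eprofiles).to_csv(vdir / "enemy_profiles.csv", index=False)
            gprofiles = generality_profiles(web)
            profiles_to_frame(gprofiles).to_csv(vdir / "generality_profiles.csv", index=False)
            top_generalists(web).to_csv(vdir / "top_generalists.csv", index=False)
            enemies_by_trophic_level(eprofiles).to_csv(vdir / "enemies_by_tl.csv", index=False)

            free_breadths = [p.diet_breadth for p in gprofiles if p.role == "free_living" and p.diet_breadth > 0]
            par_breadths = [p.diet_breadth for p in gprofiles if p.role == "parasite" and p.diet_breadth > 0]
            tests = {}
            if free_breadths and par_breadths:
                res = rank_sum_test(free_breadths, par_breadths, method="normal")
                tests["generality_free_vs_parasite"] = asdict(res)
            free_vuln = [p.n_predators + p.n_parasites for p in eprofiles if p.role == "free_living"]
            par_vuln = [p.n_concomitant for p in eprofiles if p.role == "parasite"]
            if free_vuln and par_vuln:
                res = rank_sum_test(free_vuln, par_vuln, method="normal")
                tests["vulnerability_free_vs_parasite"] = asdict(res)
            with open(vdir / "rank_sum_tests.json", "w") as fh:
                json.dump(tests, fh, indent=2)

            produced[version] = str(vdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "source": source_meta,
        "assemblies": produced,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    produced["provenance"] = str(outdir / "provenance.json")
    return produced
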