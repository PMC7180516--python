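"""End-to-end pipeline: simulate/load -> windows -> associations -> network
-> communities -> export, with a JSON run manifest.

Every stage's key counts are recorded in the manifest and all randomness
derives from a single root seed, so a rerun with the same configuration
produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (EdgeFilter, adjust_p, filter_edges, pair_stats,
                          pair_universe, percentile_cutoff)
from .cohort import (WindowConfig, build_exposure, load_claims, select_codes,
                     truncate_codes)
from .community import (category_partition, enrich, modularity,
                        profile_cluster, walktrap)
from .network import build_network, metric_correlation, node_metrics
from .simulate import demo_scenario, generate_cohort, write_claims
from .viz import encode_glyphs, export_cytoscape, export_graphml, render_static

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


def _date(v, fallback):
    if v is None:
        return fallback
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; echoed into the manifest."""

    out_dir: str = "disnet_out"
    seed: int = 1
    # simulation (omit claims/demographics paths to simulate)
    simulate: bool = True
    n_patients: int = 100_000
    claims_path: str | None = None
    demographics_path: str | None = None
    # windows
    windows: WindowConfig = field(default_factory=WindowConfig)
    # code selection
    coverage: float = 1.0
    min_patients: int = 100
    # association & filtering
    rr_tail: float = 0.1
    rr_cutoff: int | None = None   # explicit cutoff overrides the percentile
    p_threshold: float = 0.001
    adjust: str = "bonferroni"
    test: str = "fisher"
    # clustering
    walk_length: int = 4
    cluster_weights: bool = False
    # rendering
    size_scale: str = "sqrt"
    render: bool = True

    def validate(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ConfigError("coverage must lie in (0, 1]")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigError("p_threshold must lie in (0, 1]")
        if not 0.0 < self.rr_tail < 1.0:
            raise ConfigError("rr_tail must lie in (0, 1)")
        if self.adjust not in ("bonferroni", "bh"):
            raise ConfigError("adjust must be 'bonferroni' or 'bh'")
        if self.test not in ("fisher", "chi2"):
            raise ConfigError("test must be 'fisher' or 'chi2'")
        if self.size_scale not in ("sqrt", "linear"):
            raise ConfigError("size_scale must be 'sqrt' or 'linear'")
        if self.walk_length < 1:
            raise ConfigError("walk_length must be >= 1")
        if self.min_patients < 1:
            raise ConfigError("min_patients must be >= 1")
        if not self.simulate and not (self.claims_path
                                      and self.demographics_path):
            raise ConfigError("either simulate or give claims/demographics "
                              "paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        w = raw.pop("windows", {}) or {}
        defaults = WindowConfig()
        try:
            windows = WindowConfig(
                _date(w.get("observation_start"), defaults.observation_start),
                _date(w.get("observation_end"), defaults.observation_end),
                _date(w.get("outcome_start"), defaults.outcome_start),
                _date(w.get("outcome_end"), defaults.outcome_end),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(windows=windows, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = {k: v.isoformat()
                        for k, v in dataclasses.asdict(self.windows).items()}
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts into ``config.out_dir``.

    Returns a bundle dict with the in-memory objects (exposures, statistics
    table, network, cluster result, ...) plus the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"disnet_version": __version__,
                      "config": config.to_dict(), "stages": {}}
    st = manifest["stages"]

    # --- stage: obtain claims -------------------------------------------
    claims_path = out / "claims.csv"
    demo_path = out / "demographics.csv"
    if config.simulate:
        pop, diseases, progressions = demo_scenario(config.n_patients)
        cohort = generate_cohort(pop, diseases, progressions, config.windows,
                                 seed=config.seed)
        write_claims(cohort, claims_path, demo_path)
        truth = [dataclasses.asdict(p) for p in cohort.truth]
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        st["simulated_patients"] = config.n_patients
    else:
        claims_path = Path(config.claims_path)
        demo_path = Path(config.demographics_path)

    claims, demographics = load_claims(claims_path, demo_path)
    st["claims_loaded"] = int(len(claims))

    # --- stage: windows and code selection ------------------------------
    claims = truncate_codes(claims)
    observation = build_exposure(claims, config.windows.observation,
                                 "observation")
    st["cohort_size"] = int(observation.n_patients)
    selection = select_codes(observation, config.coverage,
                             config.min_patients)
    st["codes_selected"] = len(selection)
    st["coverage_achieved"] = round(selection.coverage_achieved, 6)
    observation = observation.restrict(selection.selected_codes)
    outcome = build_exposure(claims, config.windows.outcome, "outcome",
                             patients=observation.patients,
                             codes=selection.selected_codes)

    # --- stage: associations --------------------------------------------
    stats_table = pair_stats(observation, outcome, test=config.test)
    st["pairs_tested"] = int(len(stats_table))
    st["pair_universe"] = pair_universe(len(selection))
    stats_table["p_adj"] = adjust_p(stats_table["p_raw"].values,
                                    method=config.adjust)
    if config.rr_cutoff is not None:
        cutoff = int(config.rr_cutoff)
    else:
        cutoff = percentile_cutoff(stats_table["rr"].values, config.rr_tail)
    st["rr_cutoff"] = cutoff
    edge_filter = EdgeFilter(cutoff, config.p_threshold, config.adjust)
    edges = filter_edges(stats_table, edge_filter)
    st["edges_kept"] = int(len(edges))
    st["infinite_rr_pairs"] = int(np.isinf(stats_table["rr"]).sum())
    _write_tsv(stats_table, out / "pair_stats.tsv")
    _write_tsv(edges, out / "edges.tsv")

    # --- stage: network --------------------------------------------------
    if len(edges) == 0:
        raise RuntimeError("no edges survived filtering; nothing to build")
    G = build_network(edges, observation, demographics,
                      reference_date=config.windows.outcome_start)
    st["nodes"] = G.number_of_nodes()
    st["edges"] = G.number_of_edges()
    metrics = node_metrics(G)
    _write_tsv(metrics, out / "metrics.tsv")
    st["strength_correlation"] = _safe_round(
        metric_correlation(metrics, "out_strength", "in_strength"))
    st["degree_correlation"] = _safe_round(
        metric_correlation(metrics, "out_degree", "in_degree"))

    # --- stage: communities ----------------------------------------------
    result = walktrap(G, t=config.walk_length,
                      use_weights=config.cluster_weights)
    st["clusters"] = len(result.clusters())
    st["modularity"] = round(result.modularity, 6)
    chapters = category_partition(G.nodes)
    st["category_modularity"] = round(modularity(G, chapters), 6)
    _write_tsv(
        pd.DataFrame(sorted(result.partition.items()),
                     columns=["code", "cluster_id"]),
        out / "clusters.tsv",
    )
    profiles = []
    for cid, codes in sorted(result.clusters().items()):
        p = profile_cluster(cid, codes, observation, demographics,
                            config.windows.observation_start)
        profiles.append({
            "cluster_id": cid, "n_codes": len(codes),
            "pooled_patients": p.pooled_patient_count,
            "n_female": p.n_female, "n_male": p.n_male,
            "male_to_female": p.male_to_female,
            "mean_age": round(p.mean_age, 2), "sd_age": round(p.sd_age, 2),
            "n_under30": p.age_histogram[0], "n_30_59": p.age_histogram[1],
            "n_60plus": p.age_histogram[2],
            "codes": " ".join(p.codes),
        })
    _write_tsv(pd.DataFrame(profiles), out / "cluster_profiles.tsv")
    enrichment = enrich(result.partition, chapters)
    _write_tsv(enrichment, out / "enrichment.tsv")
    st["enriched_pairs"] = int((enrichment["p_adj"] < 0.05).sum())

    # --- stage: export / render ------------------------------------------
    node_glyphs, edge_glyphs = encode_glyphs(G, size_scale=config.size_scale)
    export_graphml(G, node_glyphs, edge_glyphs, out / "network.graphml")
    export_cytoscape(G, node_glyphs, edge_glyphs, out / "network.cyjs.json")
    if config.render:
        render_static(G, node_glyphs, edge_glyphs, out / "network.svg",
                      layout_seed=config.seed)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return {
        "manifest": manifest,
        "observation": observation,
        "outcome": outcome,
        "selection": selection,
        "stats": stats_table,
        "edges": edges,
        "network": G,
        "metrics": metrics,
        "clusters": result,
        "enrichment": enrichment,
        "out_dir": out,
    }


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _safe_round(x: float, nd: int = 6):
    return None if x is None or not np.isfinite(x) else round(float(x), nd)
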