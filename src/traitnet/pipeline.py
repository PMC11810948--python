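"""End-to-end orchestration: survey -> comparisons -> PCA -> models -> K -> networks.

A single config (paths to real inputs, or a synthetic-generator spec)
drives every stage in order.  Stages whose inputs are absent are skipped;
a stage failure is recorded and later independent stages still run.  The
report is a plain JSON-serializable dict whose provenance block (seed,
thresholds, config echo, package version) suffices to reproduce every
number; with a fixed seed two runs produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .catalog import DEFAULT_CATALOG
from .comparison import compare_all, pca, standardize
from .data import TraitTable, read_environment_table, read_trait_table
from .errors import ConfigError
from .models import env_regressions, fit_all_models
from .network import build_network, compare_networks, hub_traits
from .physig import k_table
from .survey import QuadratSurvey, important_value, rank_species
from .synthetic import SyntheticConfig, generate_dataset
from .tree import Phylogeny

log = logging.getLogger("traitnet.pipeline")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full analysis run."""

    traits_path: str | None = None
    survey_path: str | None = None
    env_path: str | None = None
    tree_path: str | None = None
    synthetic: SyntheticConfig | None = None
    r_threshold: float = 0.2
    p_threshold: float = 0.05
    alpha: float = 0.05
    n_permutations: int = 999
    seed: int = 42
    stratify: tuple[str, ...] = ("type", "elevation")
    top_k_iv: int = 15
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.traits_path is not None
        if has_paths == (self.synthetic is not None):
            raise ConfigError("provide exactly one of traits_path or a synthetic config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        if "stratify" in raw:
            raw["stratify"] = tuple(raw["stratify"])
        return cls(synthetic=syn, **raw)


def _records(df: pd.DataFrame) -> list[dict]:
    out = df.replace({np.nan: None}).to_dict(orient="records")
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages and return (and optionally write) the report dict."""
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "traitnet_version": __version__,
            "seed": config.seed,
            "r_threshold": config.r_threshold,
            "p_threshold": config.p_threshold,
            "alpha": config.alpha,
            "n_permutations": config.n_permutations,
            "stratify": list(config.stratify),
            "synthetic": dataclasses.asdict(config.synthetic) | {"tree": None, "catalog": None}
            if config.synthetic is not None
            else None,
            "inputs": {
                "traits": config.traits_path,
                "survey": config.survey_path,
                "env": config.env_path,
                "tree": config.tree_path,
            },
        },
        "stages": {},
        "warnings": [],
    }
    stages = report["stages"]

    # ---- load or generate inputs -------------------------------------
    survey = None
    if config.synthetic is not None:
        table, tree, env, truth = generate_dataset(config.synthetic)
        report["provenance"]["ground_truth"] = truth
    else:
        table = read_trait_table(config.traits_path, DEFAULT_CATALOG)
        tree = Phylogeny.from_file(config.tree_path) if config.tree_path else None
        env = read_environment_table(config.env_path) if config.env_path else None
        if config.survey_path:
            survey = QuadratSurvey.from_csv(config.survey_path)

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
            stages[name] = {"status": "ok", "result": result}
            log.info("stage %s ok (%.2fs)", name, time.perf_counter() - t0)
        except Exception as exc:  # keep independent stages running
            stages[name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            log.warning("stage %s failed: %s", name, exc)

    # ---- IV ----------------------------------------------------------
    if survey is not None:
        def _iv():
            iv = important_value(survey)
            return {
                "table": _records(iv.table.reset_index()),
                "top": rank_species(iv, config.top_k_iv),
                "flags": iv.flags,
            }

        stage("importance_value", _iv)
    else:
        stages["importance_value"] = {"status": "skipped", "reason": "no survey input"}

    # ---- group comparison + PCA --------------------------------------
    stage("comparison", lambda: {"table": _records(compare_all(table, alpha=config.alpha))})

    def _pca():
        res = pca(standardize(table.trait_matrix()))
        return {
            "variance_explained": [round(float(v), 6) for v in res.variance_explained],
            "pc1_top_loadings": _records(
                res.loadings["PC1"].abs().sort_values(ascending=False).head(5).reset_index()
            ),
        }

    stage("pca", _pca)

    # ---- linear models -----------------------------------------------
    stage("elevation_models", lambda: {"table": _records(fit_all_models(table))})
    if env is not None:
        stage("env_regressions", lambda: {"table": _records(env_regressions(table, env))})
    else:
        stages["env_regressions"] = {"status": "skipped", "reason": "no environment input"}

    # ---- phylogenetic signal -----------------------------------------
    if tree is not None:
        def _k():
            means = table.species_means().loc[list(tree.tip_labels)]
            tab = k_table(tree, means, n_perm=config.n_permutations, seed=config.seed)
            return {"table": _records(tab)}

        stage("phylo_signal", _k)
    else:
        stages["phylo_signal"] = {"status": "skipped", "reason": "no tree input"}

    # ---- trait networks ----------------------------------------------
    def _networks():
        out: dict[str, Any] = {}
        _, m = build_network(table, config.r_threshold, config.p_threshold)
        out["all"] = _metrics_dict(m)
        strata: dict[str, TraitTable] = {}
        if "type" in config.stratify:
            for t in ("ephemeral", "non_ephemeral"):
                sub = table.data[table.data["plant_type"] == t]
                if len(sub):
                    strata[f"type:{t}"] = TraitTable(sub.reset_index(drop=True), table.catalog)
        if "elevation" in config.stratify:
            for e in table.elevations:
                sub = table.data[table.data["elevation_m"] == e]
                strata[f"elevation:{int(e)}"] = TraitTable(sub.reset_index(drop=True), table.catalog)
        if len(strata) >= 2:
            metrics, contrast, hubs = compare_networks(
                strata, config.r_threshold, config.p_threshold
            )
            out["strata"] = {k: _metrics_dict(v) for k, v in metrics.items()}
            out["contrast"] = _records(contrast)
            out["hubs"] = {k: [[t, d] for t, d in v] for k, v in hubs.items()}
        return out

    stage("trait_networks", _networks)

    # ---- write -------------------------------------------------------
    if config.out_dir is not None:
        write_report(report, table, config)
    return report


def _metrics_dict(m) -> dict[str, Any]:
    apl = m.average_path_length
    return {
        "n_edges": m.n_edges,
        "edge_density": round(m.edge_density, 6),
        "modularity": round(m.modularity, 6),
        "average_path_length": None if np.isnan(apl) else round(apl, 6),
        "connected": m.connected,
        "degree": {k: int(v) for k, v in sorted(m.degree.items())},
        "modules": {k: int(v) for k, v in sorted(m.modules.items())},
        "relative_importance": {k: round(v, 6) for k, v in m.relative_importance.items()},
        "flags": m.flags,
    }


def write_report(report: dict, table: TraitTable, config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    table.to_csv(out / "traits.csv")
    for name in ("comparison", "elevation_models", "env_regressions", "phylo_signal"):
        st = report["stages"].get(name, {})
        if st.get("status") == "ok" and "table" in st["result"]:
            pd.DataFrame(st["result"]["table"]).to_csv(out / f"{name}.csv", index=False)
    return out / "report.json"
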