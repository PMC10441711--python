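"""End-to-end orchestration: cohort -> weights -> regressions -> networks ->
communities -> node metrics -> stability, with a machine-readable manifest.

Every run is driven by a `RunConfig` (YAML-loadable) and a single seed; all
child seeds are drawn from one stream, so a rerun with the same config
produces byte-identical artifacts and the same manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import DISEASES, HOSPITALISED, NETWORK_NODES, SEX
from .communities import community_bootstrap, name_communities, walktrap
from .io import read_cohort_csv, write_cohort_csv
from .ising import EstimatorConfig, estimate_stratified_networks
from .node_metrics import node_metrics
from .preprocess import classify_mm, complete_cases, fit_ipw_weights, stratify
from .regression import format_results_table, results_to_frame, run_regression_suite
from .stability import case_dropping_cs, nonparametric_bootstrap
from .synthetic import elsi_like_truth, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either `scenario` names a bundled synthetic scenario ("elsi-like") or
    `input_path` points at a cohort CSV. Bootstrap budgets default to small
    values suitable for interactive runs; raise `b_edges` / `b_communities` /
    `cs_b` to the publication-scale 500/100/500 for final analyses.
    """

    scenario: str | None = "elsi-like"
    input_path: str | None = None
    n: int = 9412
    seed: int = 0
    gamma: float = 0.25
    rule: str = "and"
    n_lambda: int = 100
    min_stratum_n: int = 200
    walk_length: int = 4
    b_edges: int = 10
    b_communities: int = 10
    case_dropping: bool = False
    cs_b: int = 25
    cs_proportions: tuple[float, ...] = (0.9, 0.7, 0.5)
    strata_keys: tuple[str, ...] = ("sex", "age_group")
    readmission_family: str = "linear"
    outdir: str = "morbnet_run"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("cs_proportions", "strata_keys"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.scenario is None and self.input_path is None:
            raise ValueError("config needs either a scenario name or an input path")
        for name in ("n", "n_lambda", "b_edges", "b_communities", "cs_b"):
            if getattr(self, name) < 0 or (name in ("n", "n_lambda") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    def estimator(self) -> EstimatorConfig:
        return EstimatorConfig(
            gamma=self.gamma, rule=self.rule, n_lambda=self.n_lambda,
            min_stratum_n=self.min_stratum_n,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def manifest_hash(manifest: dict) -> str:
    """Stable hash of a manifest.

    Timing and filesystem-location fields are excluded so two runs of the
    same configuration and seed hash identically regardless of where or how
    fast they ran.
    """
    scrubbed = {
        k: v for k, v in manifest.items() if k not in ("stage_seconds", "input")
    }
    if "config" in scrubbed:
        scrubbed["config"] = {
            k: v for k, v in scrubbed["config"].items()
            if k not in ("outdir", "input_path")
        }
    return hashlib.sha256(json.dumps(scrubbed, sort_keys=True).encode()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("networks", "communities", "metrics", "stability"):
        (outdir / sub).mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)
    timing: dict[str, float] = {}
    manifest: dict = {
        "tool": "morbnet",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "files": {},
    }

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    def stage(name):
        start = time.perf_counter()

        def done():
            timing[name] = round(time.perf_counter() - start, 3)
            logger.info("stage %s: %.1fs", name, timing[name])

        return done

    # --- cohort -------------------------------------------------------------
    done = stage("cohort")
    if config.input_path is not None:
        table = read_cohort_csv(config.input_path)
        manifest["input"] = str(config.input_path)
    elif config.scenario == "elsi-like":
        truth = elsi_like_truth(seed=config.seed)
        table = generate_cohort(truth, config.n, seed=int(rng.integers(2**31)))
        write_cohort_csv(table, outdir / "cohort.csv")
        truth.to_json(outdir / "ground_truth.json")
        record(outdir / "cohort.csv")
        record(outdir / "ground_truth.json")
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    done()

    # --- preprocess ----------------------------------------------------------
    done = stage("preprocess")
    weights = fit_ipw_weights(table)
    complete = complete_cases(table)
    mm = classify_mm(complete)
    w = pd.Series(weights.combined_weight, index=weights.index)
    pd.DataFrame(
        {
            "survey_weight": weights.survey_weight,
            "completeness_prob": weights.completeness_prob,
            "combined_weight": weights.combined_weight,
        },
        index=weights.index,
    ).to_csv(outdir / "weights.csv", index_label="row")
    record(outdir / "weights.csv")
    manifest["counts"] = {
        "n_rows": int(len(table)),
        "n_complete": int(len(complete)),
        "n_female": int((complete[SEX] == "female").sum()),
        "n_male": int((complete[SEX] == "male").sum()),
        "n_mm2": int(mm["mm2"].sum()),
        "n_mm3": int(mm["mm3"].sum()),
        "n_hospitalised": int(complete[HOSPITALISED].sum()),
    }
    done()

    # --- regressions ----------------------------------------------------------
    done = stage("regression")
    results = run_regression_suite(
        complete, w.loc[complete.index].to_numpy(), mm,
        readmission_family=config.readmission_family,
    )
    results_to_frame(results).to_csv(outdir / "regression_results.csv", index=False)
    (outdir / "regression_tables.txt").write_text(format_results_table(results))
    record(outdir / "regression_results.csv")
    record(outdir / "regression_tables.txt")
    done()

    # --- networks ---------------------------------------------------------------
    done = stage("networks")
    networks = estimate_stratified_networks(
        complete, config.estimator(), strata_keys=config.strata_keys
    )
    manifest["networks"] = {}
    for name, net in networks.items():
        net.edge_list().to_csv(outdir / "networks" / f"{name}_edges.csv", index=False)
        net.to_json(outdir / "networks" / f"{name}.json")
        net.to_graphml(outdir / "networks" / f"{name}.graphml")
        for suffix in (f"{name}_edges.csv", f"{name}.json", f"{name}.graphml"):
            record(outdir / "networks" / suffix)
        manifest["networks"][name] = {
            "n": net.n,
            "n_edges": int(len(net.edge_list())),
            "dropped_nodes": net.dropped_nodes,
        }
    done()

    # --- communities ---------------------------------------------------------
    done = stage("communities")
    strata_tables = {}
    for key in config.strata_keys:
        strata_tables.update(stratify(complete, key))
    manifest["communities"] = {}
    partitions = {}
    for name, net in networks.items():
        part = walktrap(net, t=config.walk_length)
        partitions[name] = part
        names = name_communities(part)
        payload = {
            "membership": part.membership,
            "modularity": part.modularity,
            "walk_length": part.walk_length,
            "group_names": {str(k): v for k, v in names.items()},
        }
        if config.b_communities > 0:
            stab = community_bootstrap(
                strata_tables[name], config.estimator(),
                n_boot=config.b_communities, seed=int(rng.integers(2**31)),
                t=config.walk_length,
            )
            stab.to_frame().to_csv(
                outdir / "communities" / f"{name}_stability.csv", index=False
            )
            record(outdir / "communities" / f"{name}_stability.csv")
            payload["mean_agreement"] = float(np.nanmean(stab.agreement))
            payload["stable"] = bool(stab.is_stable())
        (outdir / "communities" / f"{name}.json").write_text(json.dumps(payload, indent=2))
        record(outdir / "communities" / f"{name}.json")
        sizes = pd.Series(list(part.membership.values())).value_counts()
        manifest["communities"][name] = {
            "n_groups": part.n_communities,
            "n_multi_groups": int((sizes >= 2).sum()),
            "modularity": round(part.modularity, 6),
            "group_names": sorted(names.values()),
        }
    done()

    # --- node metrics -----------------------------------------------------------
    done = stage("node_metrics")
    for name, net in networks.items():
        nm = node_metrics(strata_tables[name], net, partitions[name])
        nm.to_csv(outdir / "metrics" / f"{name}_node_metrics.csv")
        record(outdir / "metrics" / f"{name}_node_metrics.csv")
    done()

    # --- stability suite ---------------------------------------------------------
    done = stage("stability")
    manifest["stability"] = {}
    for name in networks:
        entry = {}
        if config.b_edges > 0:
            ens = nonparametric_bootstrap(
                strata_tables[name], config.estimator(),
                B=config.b_edges, seed=int(rng.integers(2**31)),
            )
            ens.edge_cis().to_csv(outdir / "stability" / f"{name}_edge_cis.csv", index=False)
            record(outdir / "stability" / f"{name}_edge_cis.csv")
            entry["b_edges"] = config.b_edges
            entry["n_failures"] = ens.n_failures
        if config.case_dropping:
            cs = case_dropping_cs(
                strata_tables[name], config.estimator(),
                proportions=config.cs_proportions, B=config.cs_b,
                seed=int(rng.integers(2**31)),
            )
            pd.DataFrame(
                [
                    {"measure": m, "cs": c.cs, "at_grid_max": c.at_grid_max,
                     "below_grid_min": c.below_grid_min}
                    for m, c in cs.items()
                ]
            ).to_csv(outdir / "stability" / f"{name}_cs.csv", index=False)
            record(outdir / "stability" / f"{name}_cs.csv")
            entry["cs"] = {m: c.cs for m, c in cs.items()}
        manifest["stability"][name] = entry
    done()

    manifest["stage_seconds"] = timing
    write_report(manifest, outdir / "report.md")
    manifest["files"]["report.md"] = _sha256(outdir / "report.md")
    manifest["manifest_hash"] = manifest_hash(manifest)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_report(manifest: dict, path: str | Path) -> None:
    """Human-readable summary mirroring the analysis structure."""
    lines = [
        "# Multimorbidity–hospitalisation analysis report",
        "",
        f"seed: {manifest['seed']}  |  tool version: {manifest['version']}",
        "",
        "## Sample",
    ]
    c = manifest.get("counts", {})
    lines += [
        f"- rows: {c.get('n_rows')} (complete cases: {c.get('n_complete')})",
        f"- sex: {c.get('n_female')} female / {c.get('n_male')} male",
        f"- multimorbidity: {c.get('n_mm2')} with >=2 conditions, "
        f"{c.get('n_mm3')} with >=3",
        f"- hospitalised in the last 12 months: {c.get('n_hospitalised')}",
        "",
        "## Networks",
    ]
    networks = manifest.get("networks", {})
    for name in sorted(networks):
        info = networks[name]
        lines.append(
            f"- **{name}** (n={info['n']}): {info['n_edges']} edges"
            + (f"; dropped: {sorted(info['dropped_nodes'])}" if info["dropped_nodes"] else "")
        )
    lines += ["", "## Community groups"]
    communities = manifest.get("communities", {})
    for name in sorted(communities):
        info = communities[name]
        lines.append(f"- **{name}**: {info['n_groups']} groups "
                     f"(modularity {info['modularity']:.3f})")
        for g in info["group_names"]:
            lines.append(f"    - {g}")
    lines.append("")
    Path(path).write_text("\n".join(lines))
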