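"""Config-driven orchestration of the full analysis with run manifests.

Three entry points mirror the study's workflow: ``run_model_choice``
(prior-predictive reference table -> ABC-rf comparison, optionally followed
by head-to-head refinements such as MIG2 vs MIG12), ``run_estimation``
(rejection + regression posterior for the admixture proportions of a chosen
model) and ``run_f3`` (an outgroup-f3 scan over a genotype triplet).

Every run emits a JSON manifest holding the config hash, seeds, row counts,
sha256 checksums of written files and wall-clock timing, sufficient to
re-run the computation and compare outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import config_hash, default_config, merge_config
from .demography import PriorSpec, build_model
from .estimation import estimate_parameter
from .f3 import outgroup_f3, read_genotypes
from .model_choice import (
    MODEL_COLUMN,
    ReferenceTable,
    build_reference_table,
    classification_error_by_pod,
    classify_observed,
    train_classifier,
)
from .sumstats import impute_summary_table, summarize
from .synthetic import StudyDesign, generate_pod

logger = logging.getLogger("steppeabc")


class PipelineError(ValueError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(cfg: Mapping[str, Any], seed: int, stage: str) -> dict[str, Any]:
    return {
        "stage": stage,
        "version": __version__,
        "config_hash": config_hash(cfg),
        "config": json.loads(json.dumps(cfg, default=str)),
        "seed": seed,
        "row_counts": {},
        "outputs": {},
        "timing_s": {},
    }


def _write(df: pd.DataFrame, path: Path, manifest: dict[str, Any]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = _sha256(path)


def resolve_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    return merge_config(default_config(), config or {})


def _load_reference_table(cfg: Mapping[str, Any]) -> ReferenceTable:
    spec = cfg["reference_table"]
    data = pd.read_csv(spec["path"])
    stat_cols = tuple(spec["stat_columns"])
    param_cols = tuple(c for c in data.columns if c not in stat_cols and c != MODEL_COLUMN)
    data[list(stat_cols)] = impute_summary_table(data[list(stat_cols)])[list(stat_cols)]
    return ReferenceTable(
        data=data,
        stat_columns=stat_cols,
        param_columns=param_cols,
        provenance={"path": str(spec["path"])},
    )


def _build_table(cfg: Mapping[str, Any], seed: int, model_names: Sequence[str],
                 n_per_model: int) -> ReferenceTable:
    priors = PriorSpec.from_config(cfg["priors"])
    models = [build_model(m, cfg) for m in model_names]
    return build_reference_table(
        models, priors, n_per_model, seed, cfg["locus"]
    )


def _get_observed(cfg: Mapping[str, Any], seed: int) -> pd.Series:
    obs_cfg = cfg.get("observed")
    if obs_cfg is None:
        raise PipelineError("config must define 'observed' (stats_path or pod)")
    if "stats_path" in obs_cfg:
        ser = pd.read_csv(obs_cfg["stats_path"]).iloc[0]
        return ser.astype(float)
    pod = obs_cfg["pod"]
    design = StudyDesign.from_config(cfg)
    aln, _ = generate_pod(
        pod["model"], pod["params"], design, int(pod.get("seed", seed)), config=cfg
    )
    pops = [p["name"] for p in cfg["populations"]]
    stats = summarize(aln, pops)
    return impute_summary_table(stats.to_frame().T).iloc[0]


def run_model_choice(
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    dry_run: bool = False,
) -> dict[str, Any]:
    """First-round model comparison plus optional head-to-head refinements.

    Returns a dict with the ReferenceTable, per-round ModelChoiceResult and
    error reports, and the manifest.  ``config['abc']['refinements']`` is a
    list of model-name pairs (e.g. ``[["MIG2", "MIG12"]]``) re-run as
    two-model forests on the same reference table.
    """
    cfg = resolve_config(config)
    if dry_run:
        logger.info("dry run: resolved config echoed, no computation")
        return {"config": cfg, "dry_run": True}
    manifest = _manifest(cfg, seed, "model_choice")
    t0 = time.perf_counter()

    abc = cfg["abc"]
    if "reference_table" in cfg:
        table = _load_reference_table(cfg)
    else:
        table = _build_table(cfg, seed, cfg["models"], int(abc["n_per_model"]))
    manifest["row_counts"]["reference_table"] = len(table.data)
    manifest["timing_s"]["reference_table"] = time.perf_counter() - t0

    obs = _get_observed(cfg, seed)
    rounds: dict[str, Any] = {}
    round_specs = [("round1", list(table.models))]
    for pair in abc.get("refinements", []):
        round_specs.append((f"round2-{'-vs-'.join(pair)}", list(pair)))

    for name, model_names in round_specs:
        t1 = time.perf_counter()
        sub = table if set(model_names) == set(table.models) else table.restrict(model_names)
        forest = train_classifier(sub, int(abc["n_trees"]), seed)
        result = classify_observed(forest, obs)
        errors = classification_error_by_pod(forest)
        logger.info(
            "%s: selected %s (posterior %.3f, prior error %.3f)",
            name, result.selected_model, result.posterior_probability,
            errors.global_error,
        )
        rounds[name] = {"result": result, "errors": errors}
        manifest["timing_s"][name] = time.perf_counter() - t1

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.data.to_csv(out / "reference_table.csv", index=False)
        manifest["outputs"]["reference_table.csv"] = _sha256(out / "reference_table.csv")
        for name, payload in rounds.items():
            res = payload["result"]
            votes = pd.DataFrame(
                {
                    "model": list(res.votes),
                    "votes": list(res.votes.values()),
                }
            )
            votes["posterior_probability"] = [
                res.posterior_probability if m == res.selected_model else np.nan
                for m in votes["model"]
            ]
            _write(votes, out / f"votes_{name}.csv", manifest)
            conf = payload["errors"].confusion.reset_index(names="true_model")
            _write(conf, out / f"confusion_{name}.csv", manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {"config": cfg, "table": table, "rounds": rounds, "manifest": manifest}


def run_estimation(
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Posterior estimation for one model's parameters.

    ``config['estimation']``: ``model`` (name), ``parameters`` (list of
    names; defaults to the model's admixture proportions), optional
    ``transforms`` mapping, ``n_rows`` (table rows to simulate when no
    reference table is given).  The acceptance count is
    ``accept_fraction * rows`` bounded below by ``min_keep`` (mirroring the
    published 5000-of-1e6 at full scale, proportionally for smaller tables).
    """
    cfg = resolve_config(config)
    manifest = _manifest(cfg, seed, "estimation")
    t0 = time.perf_counter()
    est_cfg = cfg.get("estimation", {})
    model_name = est_cfg.get("model", "MIG2")

    if "reference_table" in cfg:
        table = _load_reference_table(cfg)
    else:
        n_rows = int(est_cfg.get("n_rows", cfg["abc"]["n_per_model"]))
        table = _build_table(cfg, seed, [model_name], n_rows)
    rows = table.rows_for_model(model_name) if model_name in table.models else table.data
    manifest["row_counts"]["reference_table"] = len(rows)
    manifest["timing_s"]["reference_table"] = time.perf_counter() - t0

    obs = _get_observed(cfg, seed)
    abc = cfg["abc"]
    n_keep = max(
        int(round(float(abc["accept_fraction"]) * len(rows))),
        min(int(abc["min_keep"]), len(rows)),
    )
    manifest["row_counts"]["accepted"] = n_keep
    manifest["acceptance_fraction"] = n_keep / len(rows)

    import re

    params = est_cfg.get("parameters")
    if params is None:  # default: the model's admixture proportions
        params = [c for c in table.param_columns if re.fullmatch(r"m\d+", c)]
    transforms = dict(est_cfg.get("transforms", {}))
    results = []
    posteriors = {}
    for p in params:
        tr = transforms.get(p, "logit" if re.fullmatch(r"m\d+", p) else "identity")
        ps, pe = estimate_parameter(
            rows, obs, p, table.stat_columns, n_keep, transform=tr
        )
        posteriors[p] = ps
        results.append(pe.to_series())
        logger.info(
            "%s: median %.3f mode %.3f CI95 [%.3f, %.3f] R2 %.3f",
            p, pe.median, pe.mode, pe.ci_low, pe.ci_high, pe.r_squared,
        )
    estimates = pd.DataFrame(results)
    manifest["timing_s"]["estimation"] = time.perf_counter() - t0

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(estimates, out / "estimates.csv", manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "config": cfg,
        "estimates": estimates,
        "posteriors": posteriors,
        "manifest": manifest,
    }


def run_f3(
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Outgroup-f3 scan: f3(X, target; outgroup) for every candidate X.

    ``config['f3']``: ``geno``/``snp``/``ind`` paths, ``target``,
    ``outgroup``, optional ``candidates`` list and ``block_size``.
    Results are sorted by descending estimate.
    """
    cfg = resolve_config(config)
    f3_cfg = cfg.get("f3")
    if not f3_cfg:
        raise PipelineError("config must define an 'f3' section")
    manifest = _manifest(cfg, seed, "f3")
    t0 = time.perf_counter()
    G = read_genotypes(f3_cfg["geno"], f3_cfg["snp"], f3_cfg["ind"])
    target = f3_cfg["target"]
    outgroup = f3_cfg["outgroup"]
    if target == outgroup:
        raise PipelineError("target and outgroup must differ: f3(X, T; T) is ill-posed")
    for pop in (target, outgroup):
        if pop not in G.populations:
            raise PipelineError(f"unknown population label {pop!r}")
    candidates = f3_cfg.get(
        "candidates",
        [p for p in G.populations if p not in (target, outgroup)],
    )
    block_size = int(f3_cfg.get("block_size", 5_000_000))
    rows = []
    for x in candidates:
        if x not in G.populations:
            raise PipelineError(f"unknown population label {x!r}")
        rows.append(outgroup_f3(G, x, target, outgroup, block_size).to_series())
    results = (
        pd.DataFrame(rows)
        .sort_values("f3", ascending=False)
        .reset_index(drop=True)
    )
    manifest["row_counts"]["triples"] = len(results)
    manifest["timing_s"]["f3"] = time.perf_counter() - t0

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(results, out / "f3_results.csv", manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"config": cfg, "results": results, "manifest": manifest}
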