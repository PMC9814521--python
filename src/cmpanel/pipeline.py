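"""End-to-end orchestration: simulate -> summarize -> de -> discover -> permute -> compare.

A single root seed drives every stage: named substreams are spawned from it
with :class:`numpy.random.SeedSequence` in a fixed order (simulate, discover,
permute), so reruns with the same config file and seed are byte-identical and
no stage touches global RNG state.  Each run writes a manifest recording the
echoed config, derived seeds, stage timings, and a SHA-256 inventory of every
output file.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .cohort import SimulationConfig, generate_cohort
from .differential import differential_test
from .discovery import WorkflowConfig, run_workflow_on_cohort
from .errors import ConfigurationError
from .io import write_cohort
from .permutation import compare_distributions, run_permuted
from .summary import summarize_cohort

__all__ = ["RunManifest", "run_end_to_end", "load_config", "default_config"]

_STAGE_ORDER = ("simulate", "summarize", "de", "discover", "permute", "compare")


def default_config() -> dict:
    """The full configuration tree with every default made explicit."""
    sim = SimulationConfig()
    wf = WorkflowConfig()
    return {
        "seed": 0,
        "simulate": {
            k: getattr(sim, k)
            for k in (
                "n_cases", "n_proteins", "n_planted", "effect_size",
                "within_subject_corr", "missing_rate", "match_ratio",
                "ga_window_weeks",
            )
        },
        "workflow": {
            k: getattr(wf, k)
            for k in (
                "train_fraction", "n_folds", "top_k", "max_panel_size",
                "n_iterations", "l1_strength_rule", "n_bootstrap",
                "n_lambdas", "lambda_min_ratio", "standardize",
                "stratify_splits",
            )
        },
        "de": {"trimester": "T2"},
        "discover": {"trimester": "T2"},
        "permute": {"n_runs": 5},
        "compare": {"test": "ranksum"},
    }


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge the defaults with a YAML config file and explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        for section, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(val)
            else:
                cfg[section] = val
    for section, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(val)
        else:
            cfg[section] = val
    return cfg


@dataclass
class RunManifest:
    """What a pipeline run did: config echo, seeds, timings, file inventory."""

    config: dict
    seeds: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = __version__
    failed_stage: str | None = None
    error: str | None = None

    @property
    def succeeded(self) -> bool:
        return self.failed_stage is None

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "seeds": self.seeds,
            "timings_s": self.timings,
            "outputs_sha256": self.outputs,
            "failed_stage": self.failed_stage,
            "error": self.error,
        }

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(root_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(3)
    names = ("simulate", "discover", "permute")
    return {
        name: int(np.random.default_rng(child).integers(2**31 - 1))
        for name, child in zip(names, children)
    }


def run_end_to_end(
    config: dict | str | None = None,
    out_dir: str = "cmpanel_run",
    seed: int | None = None,
) -> RunManifest:
    """Execute the whole pipeline on a freshly simulated cohort.

    Parameters
    ----------
    config : dict or path to a YAML file, optional
        Partial configs are merged over :func:`default_config`.
    out_dir : str
        Output directory (created if needed).
    seed : int, optional
        Overrides the config's root seed.

    All configuration is validated before any stage runs.  If a stage fails,
    the manifest (written regardless) records the failing stage and the error,
    partial outputs are left in place, and the exception propagates.
    """
    cfg = load_config(config) if isinstance(config, (str, os.PathLike)) else load_config(
        None, overrides=config
    )
    if seed is not None:
        cfg["seed"] = int(seed)
    seeds = _stage_seeds(int(cfg["seed"]))
    # validate everything up front so a bad config fails before any stage
    sim_cfg = SimulationConfig(**cfg["simulate"], seed=seeds["simulate"])
    wf_cfg = WorkflowConfig(**cfg["workflow"], seed=seeds["discover"])

    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(config=cfg, seeds=seeds)
    manifest_path = os.path.join(out_dir, "manifest.json")
    outputs: dict[str, str] = {}
    state: dict = {}

    def _register(*paths):
        for p in paths:
            outputs[os.path.relpath(p, out_dir)] = _sha256(p)

    def _stage_simulate():
        matrices, cohort, truth = generate_cohort(sim_cfg)
        paths = write_cohort(matrices, cohort, truth, os.path.join(out_dir, "cohort"))
        state.update(matrices=matrices, cohort=cohort, truth=truth)
        _register(*paths.values())

    def _stage_summarize():
        report = summarize_cohort(state["cohort"])
        path = os.path.join(out_dir, "summary.json")
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=_json_default)
        _register(path)

    def _stage_de():
        t = cfg["de"]["trimester"]
        res = differential_test(state["matrices"][t], state["cohort"])
        path = os.path.join(out_dir, f"differential_{t}.csv")
        res.to_csv(path, index=False)
        _register(path)

    def _stage_discover():
        t = cfg["discover"]["trimester"]
        result = run_workflow_on_cohort(state["matrices"][t], state["cohort"], wf_cfg)
        state["discover_result"] = result
        it_path = os.path.join(out_dir, "iterations.csv")
        rank_path = os.path.join(out_dir, "panels.csv")
        top_path = os.path.join(out_dir, "top_panel.json")
        result.iterations_frame().to_csv(it_path, index=False)
        result.ranking.to_csv(rank_path, index=False)
        with open(top_path, "w") as fh:
            json.dump(
                {
                    **result.top_panel,
                    "pooled_mean_external_auc": result.mean_external_auc,
                    "n_iterations_retained": len(result.retained),
                },
                fh,
                indent=2,
                default=_json_default,
            )
        _register(it_path, rank_path, top_path)

    def _stage_permute():
        t = cfg["discover"]["trimester"]
        matrix, cohort = state["matrices"][t], state["cohort"]
        status = cohort.drop_duplicates("sample_id").set_index("sample_id")["status"]
        common = [s for s in matrix.sample_ids if s in status.index]
        idx = [matrix.sample_ids.index(s) for s in common]
        y = (status.loc[common] == "case").astype(int).to_numpy()
        aucs = run_permuted(
            matrix.values[idx, :],
            y,
            wf_cfg,
            n_runs=int(cfg["permute"]["n_runs"]),
            feature_names=matrix.protein_ids,
            seed=seeds["permute"],
        )
        state["permuted_aucs"] = aucs
        path = os.path.join(out_dir, "permuted_aucs.csv")
        np.savetxt(path, aucs, header="external_auc", comments="", fmt="%.17g")
        _register(path)

    def _stage_compare():
        comp = compare_distributions(
            state["discover_result"].external_aucs,
            state["permuted_aucs"],
            test=cfg["compare"]["test"],
        )
        cmp_path = os.path.join(out_dir, "comparison.json")
        dens_path = os.path.join(out_dir, "density.csv")
        with open(cmp_path, "w") as fh:
            json.dump(comp.to_dict(), fh, indent=2, default=_json_default)
        comp.density.to_csv(dens_path, index=False)
        _register(cmp_path, dens_path)

    stages = {
        "simulate": _stage_simulate,
        "summarize": _stage_summarize,
        "de": _stage_de,
        "discover": _stage_discover,
        "permute": _stage_permute,
        "compare": _stage_compare,
    }
    try:
        for name in _STAGE_ORDER:
            t0 = time.perf_counter()
            stages[name]()
            manifest.timings[name] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        manifest.failed_stage = name
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.outputs = outputs
        manifest.write(manifest_path)
        raise
    manifest.outputs = outputs
    manifest.write(manifest_path)
    return manifest
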