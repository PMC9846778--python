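"""End-to-end pipeline driver with manifest-based reproducibility.

A single flat configuration (YAML-loadable dict) names the signature source
(a COSMIC-dialect file, or a synthetic-signature spec for download-free
runs), the simulation scenario and the stages to run:

``metrics``     pairwise similarity, flatness, cluster map of the signatures
``simulate``    replicate catalogues from the scenario signatures
``extract``     de novo extraction on the first replicate
``evaluate``    recovery metrics (F, MSE, stability) over all replicates
``archetypes``  explained-variance scan, model fit, alpha grouping

Every stage derives its own random generator from the single global seed,
writes only inside its stage directory, and is recorded in a
:class:`RunManifest` (config snapshot, derived seeds, timings and a sha256
inventory of every output file) sufficient to re-run deterministic stages
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .archetypes import (
    alpha_grouping,
    explained_variance_curve,
    reconstruction_report,
    select_num_archetypes,
)
from .catalogue_io import (
    SignatureMatrix,
    filter_artefact_signatures,
    read_signature_table,
    write_catalogue,
    write_signature_table,
)
from .extraction import SignatureExtractor, evaluate_scenario
from .profile_metrics import build_cluster_map, pairwise_similarity, flatness, scenario_summary
from .synthetic import (
    SCENARIO_PRESETS,
    ScenarioConfig,
    generate_scenario,
    generate_synthetic_signatures,
    resolve_scenario_signatures,
)

__all__ = ["RunManifest", "pipeline_run", "report_tables", "load_signatures"]

_STAGES = ("metrics", "simulate", "extract", "evaluate", "archetypes")


@dataclass
class RunManifest:
    """Record of one pipeline run: configuration, seeds, timings, outputs."""

    config: dict
    version: str
    stage_seeds: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    completed_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_signatures(config: dict) -> SignatureMatrix:
    """Resolve the configured signature source to a matrix.

    Either ``signatures`` (path to a COSMIC-dialect TSV, with optional
    artefact filtering) or ``synthetic_signatures`` (a spec handed to
    :func:`generate_synthetic_signatures`) must be present.
    """
    if config.get("signatures"):
        sig = read_signature_table(config["signatures"])
        if config.get("filter_artefacts", True):
            kwargs = {}
            if config.get("artefact_names") is not None:
                kwargs["exclude"] = config["artefact_names"]
            sig = filter_artefact_signatures(sig, **kwargs)
        return sig
    if config.get("synthetic_signatures"):
        spec = dict(config["synthetic_signatures"])
        seed = _stage_seed(int(config.get("seed", 0)), "synthetic_signatures")
        rng = np.random.default_rng(spec.pop("seed", seed))
        return generate_synthetic_signatures(rng=rng, **spec)
    raise ValueError(
        "config must provide 'signatures' (a COSMIC-dialect TSV path) or "
        "'synthetic_signatures' (a generation spec)"
    )


def _scenario_signatures(config: dict, sig: SignatureMatrix) -> SignatureMatrix:
    if config.get("signature_names"):
        return sig.select(config["signature_names"])
    if config.get("scenario") is not None:
        preset = SCENARIO_PRESETS[int(config["scenario"])]
        return sig.select(resolve_scenario_signatures(preset, sig))
    return sig


def pipeline_run(config: dict, out_dir) -> RunManifest:
    """Execute the configured stages, writing all artifacts under *out_dir*.

    On a stage failure the manifest records the partial completion and the
    exception is re-raised after the manifest is written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", _STAGES))
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages: {unknown}")
    manifest = RunManifest(config=dict(config), version=__version__)
    manifest_path = out / "manifest.json"

    sig = load_signatures(config)
    scenario_sig = _scenario_signatures(config, sig)
    scen_cfg = ScenarioConfig(
        n_samples=int(config.get("n_samples", 200)),
        mutations_per_sample=int(config.get("mutations_per_sample", 5000)),
        n_replicates=int(config.get("n_replicates", 10)),
        seed=_stage_seed(seed, "simulate"),
    )
    replicates = None

    def record(stage: str, directory: Path) -> None:
        for p in sorted(directory.rglob("*")):
            if p.is_file():
                manifest.outputs[str(p.relative_to(out))] = _sha256(p)
        manifest.completed_stages.append(stage)

    try:
        for stage in stages:
            t0 = time.perf_counter()
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            manifest.stage_seeds[stage] = _stage_seed(seed, stage)
            if stage == "metrics":
                _run_metrics(sig, scenario_sig, sdir)
            elif stage == "simulate":
                replicates = generate_scenario(scenario_sig, scen_cfg)
                _write_replicates(replicates, sdir)
            elif stage == "extract":
                if replicates is None:
                    replicates = generate_scenario(scenario_sig, scen_cfg)
                _run_extract(replicates[0].catalogue, config, seed, sdir)
            elif stage == "evaluate":
                if replicates is None:
                    replicates = generate_scenario(scenario_sig, scen_cfg)
                _run_evaluate(replicates, config, seed, sdir)
            elif stage == "archetypes":
                _run_archetypes(sig, config, seed, sdir)
            manifest.stage_seconds[stage] = time.perf_counter() - t0
            record(stage, sdir)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    manifest.outputs["manifest.json"] = _sha256(manifest_path)
    return manifest


def _run_metrics(sig, scenario_sig, sdir: Path) -> None:
    simm = pairwise_similarity(sig)
    cmap = build_cluster_map(simm)
    order = cmap.leaf_order
    simm.to_frame().iloc[order, order].to_csv(sdir / "similarity.tsv", sep="\t")
    (sdir / "cluster_map.nwk").write_text(cmap.to_newick() + "\n")
    pd.Series(
        {n: flatness(v) for n, v in zip(sig.names, sig.values)}, name="flatness"
    ).to_csv(sdir / "flatness.tsv", sep="\t")
    summary = scenario_summary(scenario_sig)
    summary["max_similarity_pair"] = list(summary["max_similarity_pair"])
    (sdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _write_replicates(replicates, sdir: Path) -> None:
    for i, rep in enumerate(replicates):
        write_catalogue(rep.catalogue, sdir / f"catalogue_rep{i}.tsv")
        pd.DataFrame(
            rep.true_exposures,
            index=rep.true_signatures.names,
            columns=rep.catalogue.sample_ids,
        ).to_csv(sdir / f"exposures_rep{i}.tsv", sep="\t")
    write_signature_table(replicates[0].true_signatures, sdir / "true_signatures.tsv")


def _extractor_kwargs(config: dict) -> dict:
    opts = dict(config.get("extract", {}))
    return {
        "k_range": tuple(opts.get("k_range", (2, 3, 4, 5, 6, 7, 8))),
        "n_runs": int(opts.get("n_runs", 30)),
        "resample": bool(opts.get("resample", True)),
    }


def _run_extract(catalogue, config, seed, sdir: Path) -> None:
    kwargs = _extractor_kwargs(config)
    est = SignatureExtractor(
        random_state=_stage_seed(seed, "extract"), **kwargs
    ).fit(catalogue)
    write_signature_table(est.signature_matrix_, sdir / "consensus_signatures.tsv")
    pd.DataFrame(
        est.exposures_.T,
        index=est.signature_matrix_.names,
        columns=catalogue.sample_ids,
    ).to_csv(sdir / "exposures.tsv", sep="\t")
    (sdir / "diagnostics.json").write_text(
        json.dumps(
            {
                "chosen_k": est.rank_,
                "selection_stable": est.selection_stable_,
                "per_k": est.diagnostics_,
            },
            indent=2,
        )
    )


def _run_evaluate(replicates, config, seed, sdir: Path) -> None:
    kwargs = _extractor_kwargs(config)
    rng = np.random.default_rng(_stage_seed(seed, "evaluate"))
    ev = evaluate_scenario(
        replicates,
        rng,
        k_range=kwargs["k_range"],
        n_runs=kwargs["n_runs"],
        resample=kwargs["resample"],
    )
    (sdir / "evaluation.json").write_text(
        json.dumps(
            {
                "F": ev.f_success,
                "MSE_median": ev.mse_median,
                "MSE_iqr": list(ev.mse_iqr),
                "C_mean_median": ev.c_mean_median,
                "C_min_median": ev.c_min_median,
                "n_replicates": len(ev.per_replicate),
            },
            indent=2,
        )
    )


def _run_archetypes(sig, config, seed, sdir: Path) -> None:
    opts = dict(config.get("archetypes", {}))
    r_min = int(opts.get("r_min", 2))
    r_max = int(opts.get("r_max", min(12, sig.n_signatures)))
    restarts = int(opts.get("restarts", 3))
    threshold = float(opts.get("threshold", 0.95))
    curve, models = explained_variance_curve(
        sig,
        range(r_min, r_max + 1),
        n_restarts=restarts,
        random_state=_stage_seed(seed, "archetypes"),
    )
    r = select_num_archetypes(curve, threshold=threshold)
    model = models[r]
    arch_names = [f"A{k + 1}" for k in range(model.r)]
    write_signature_table(
        SignatureMatrix.from_profiles(arch_names, np.maximum(model.archetypes, 0.0)),
        sdir / "archetypes.tsv",
    )
    pd.DataFrame(model.alpha, index=sig.names, columns=arch_names).to_csv(
        sdir / "alpha.tsv", sep="\t"
    )
    pd.DataFrame(model.beta, index=arch_names, columns=sig.names).to_csv(
        sdir / "beta.tsv", sep="\t"
    )
    report = reconstruction_report(model, sig)
    groups, table = alpha_grouping(model, sig)
    table.to_csv(sdir / "alpha_display.tsv", sep="\t")
    (sdir / "report.json").write_text(
        json.dumps(
            {
                "ev_curve": [[r_, ev_] for r_, ev_ in curve],
                "selected_r": r,
                "explained_variance": model.explained_variance,
                "sse": model.sse,
                "signature_cosines": report.signature_cosines,
                "archetype_best_match": [list(t) for t in report.archetype_best_match],
                "n_correspondent": report.n_correspondent,
                "one_to_one_archetypes": report.one_to_one_archetypes,
                "groups": groups,
            },
            indent=2,
        )
    )


def report_tables(out_dir) -> dict[str, pd.DataFrame]:
    """Summary tables from a completed run directory.

    ``scenario`` mirrors the scenario-description layout (signature count,
    median similarity and flatness, sample count); ``performance`` mirrors
    the extraction-performance layout (F, MSE median and IQR, stability).
    A missing stage output raises an error naming the stage.
    """
    out = Path(out_dir)
    tables: dict[str, pd.DataFrame] = {}
    summary_path = out / "metrics" / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError("metrics stage output missing (metrics/summary.json)")
    s = json.loads(summary_path.read_text())
    manifest = json.loads((out / "manifest.json").read_text())
    tables["scenario"] = pd.DataFrame(
        [
            {
                "n_signatures": s["n_signatures"],
                "median_similarity": round(s["median_similarity"], 2),
                "median_flatness": round(s["median_flatness"], 2),
                "n_samples": manifest["config"].get("n_samples", 200),
            }
        ]
    )
    eval_path = out / "evaluate" / "evaluation.json"
    if not eval_path.exists():
        raise FileNotFoundError("evaluate stage output missing (evaluate/evaluation.json)")
    e = json.loads(eval_path.read_text())
    tables["performance"] = pd.DataFrame(
        [
            {
                "F": e["F"],
                "MSE": f"{e['MSE_median']:.2f} ({e['MSE_iqr'][0]:.2f}, {e['MSE_iqr'][1]:.2f})",
                "C_mean": round(e["C_mean_median"], 2),
                "C_min": round(e["C_min_median"], 2),
            }
        ]
    )
    return tables
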