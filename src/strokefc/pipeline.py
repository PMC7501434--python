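"""End-to-end orchestration: simulate → netmats → classify → group stats.

A :class:`RunConfig` collects every constant of the study design (cohort
sizes 44/100, 30 nodes, 200 rest / 152 task frames, FDR q = 0.05) together
with desk-scale analysis settings (reduced permutation and subsampling
counts) that a ``paper_scale`` preset restores to 100 subsampling
iterations and 10,000 permutations. All randomness flows from the single
config seed, so a rerun with an identical config reproduces identical
numeric tables; a manifest records the config, file checksums, and stage
timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, group_stats, io, netmats, synth
from .synth import DEFAULT_FRAMES


@dataclass
class RunConfig:
    n_patients: int = 44
    n_controls: int = 100
    n_nodes: int = 30
    frames: dict = field(default_factory=lambda: dict(DEFAULT_FRAMES))
    sparsity: float = 0.1
    # effect specification (see synth.default_effect_spec)
    n_condition_edges: int = 20
    condition_delta: tuple = (0.1, 0.3)
    group_delta: float = 0.1
    n_sdsa_nodes: int = 4
    sdsa_task_factor: float = 0.8
    # network estimation
    lam: float | str = "cv"
    lambda_grid: list | None = None
    cv_folds: int = 5
    # classification
    n_subsample: int = 25
    n_perm: int = 100
    group_condition: str = "rest"
    # statistics
    fdr_q: float = 0.05
    seed: int = 0
    outdir: str = "strokefc_run"

    def paper_scale(self) -> "RunConfig":
        cfg = RunConfig(**{**asdict(self)})
        cfg.n_subsample = 100
        cfg.n_perm = 10_000
        return cfg


@dataclass
class RunManifest:
    config: dict
    version: str
    files: dict
    timings: dict
    summary: dict

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "version": self.version, "files": self.files,
             "timings": self.timings, "summary": self.summary},
            indent=2, default=str))


def _effect_spec(cfg: RunConfig) -> synth.EffectSpec:
    return synth.default_effect_spec(
        n_nodes=cfg.n_nodes,
        n_condition_edges=cfg.n_condition_edges,
        condition_delta=tuple(cfg.condition_delta),
        group_delta=cfg.group_delta,
        n_sdsa_nodes=cfg.n_sdsa_nodes,
        sdsa_task_factor=cfg.sdsa_task_factor,
        seed=cfg.seed,
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage, writing all artifacts under ``config.outdir``."""
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    timings: dict[str, float] = {}
    summary: dict = {}

    def _record(name: str, path: Path) -> None:
        files[name] = str(path.relative_to(out)) if path.is_relative_to(out) else str(path)

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    # --- simulate -----------------------------------------------------
    def _simulate():
        model = synth.make_ground_truth(
            config.n_nodes, config.sparsity, _effect_spec(config), seed=config.seed
        )
        cohort = synth.generate_cohort(
            model, config.n_patients, config.n_controls, frames=config.frames, seed=config.seed
        )
        mpath = io.write_cohort(cohort, out / "timeseries")
        _record("cohort_manifest", mpath)
        return model, cohort

    model, cohort = _stage("simulate", _simulate)

    # --- netmats ------------------------------------------------------
    def _netmats():
        table = netmats.cohort_edge_table(
            cohort, lam=config.lam, grid=config.lambda_grid,
            folds=config.cv_folds, seed=config.seed,
        )
        path = out / "edge_table.csv"
        table.to_csv(path, index=False)
        _record("edge_table", path)
        return table

    edge_table = _stage("netmats", _netmats)
    summary["n_edge_rows"] = int(len(edge_table))
    summary["n_edges"] = netmats.count_edges(config.n_nodes)

    # --- classify -----------------------------------------------------
    def _classify():
        reports = []
        cond_ds = classify.dataset_from_edge_table(edge_table, task="condition")
        cond_rep = classify.loso_cv(cond_ds)
        cond_rep.p_perm = classify.permutation_test(
            cond_ds, cond_rep.mean_accuracy, config.n_perm,
            seed=config.seed, scheme="within_subject",
        )
        cond_rep.n_permutations = config.n_perm
        reports.append(("condition", cond_rep))

        grp_ds = classify.dataset_from_edge_table(
            edge_table, task="group", condition=config.group_condition
        )
        grp_rep = classify.balanced_group_classification(
            grp_ds, n_iterations=config.n_subsample, seed=config.seed
        )
        grp_rep.p_perm = classify.permutation_test(
            grp_ds, grp_rep.mean_accuracy, config.n_perm, seed=config.seed,
            classifier_runner=lambda ds: classify.balanced_group_classification(
                ds, n_iterations=1, seed=config.seed
            ).mean_accuracy,
            scheme="subject",
        )
        grp_rep.n_permutations = config.n_perm
        reports.append((f"group@{config.group_condition}", grp_rep))

        frames = pd.concat([rep.to_frame(task=t, seed=config.seed) for t, rep in reports])
        cpath = out / "classification.csv"
        frames.to_csv(cpath, index=False)
        _record("classification_table", cpath)
        tpath = out / "classification.txt"
        tpath.write_text("\n\n".join(f"== {t} ==\n{rep.summary()}" for t, rep in reports))
        _record("classification_report", tpath)
        return reports

    reports = _stage("classify", _classify)
    for t, rep in reports:
        summary[f"accuracy[{t}]"] = rep.mean_accuracy
        summary[f"p_perm[{t}]"] = rep.p_perm

    # --- anova --------------------------------------------------------
    def _anova():
        stats_table = group_stats.edgewise_anova(edge_table, q=config.fdr_q)
        path = out / "edgewise_anova.csv"
        stats_table.to_csv(path, index=False)
        _record("edgewise_anova", path)
        return stats_table

    edge_stats = _stage("anova", _anova)
    summary["fdr_group_edges"] = int(edge_stats["fdr_group"].sum())
    summary["fdr_condition_edges"] = int(edge_stats["fdr_condition"].sum())
    summary["fdr_interaction_edges"] = int(edge_stats["fdr_interaction"].sum())

    # --- sdsa ---------------------------------------------------------
    def _sdsa():
        sd = group_stats.sdsa_table(cohort)
        spath = out / "sdsa.csv"
        sd.to_csv(spath, index=False)
        _record("sdsa_table", spath)
        nstats = group_stats.nodewise_sdsa_anova(sd, q=config.fdr_q)
        npath = out / "nodewise_sdsa_anova.csv"
        nstats.to_csv(npath, index=False)
        _record("nodewise_sdsa_anova", npath)
        return nstats

    node_stats = _stage("sdsa", _sdsa)
    summary["fdr_condition_nodes"] = int(node_stats["fdr_condition"].sum())

    checksums = {k: io.sha256_of(out / v) for k, v in files.items()}
    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        files={k: {"path": v, "sha256": checksums[k]} for k, v in files.items()},
        timings=timings,
        summary=summary,
    )
    manifest.save(out / "run_manifest.json")
    return manifest


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict[str, Path]:
    """Write the small deterministic datasets used by the test suite.

    Bundle: a 2-node and a 5-node chain-graph run, a 4-subject ANOVA
    instance, and a toy volume set with a lesion.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    two = synth.make_ground_truth(
        2, 0.5,
        synth.EffectSpec(condition_edges=[(1, 2, {"rest": 0.5, "L1": 0.5, "L2": 0.5})]),
        seed=seed,
    )
    ts2 = synth.sample_timeseries(two, "control", "rest", 200, seed=seed)
    paths["two_node"] = out / "two_node_rest.tsv"
    io.write_timeseries(paths["two_node"], ts2)

    chain = synth.make_ground_truth(
        5, 0.2,
        synth.EffectSpec(condition_edges=[
            (i, i + 1, {"rest": 0.4, "L1": 0.4, "L2": 0.4}) for i in range(1, 5)
        ]),
        seed=seed,
    )
    ts5 = synth.sample_timeseries(chain, "control", "rest", 500, seed=seed + 1)
    paths["chain_five"] = out / "chain_five_rest.tsv"
    io.write_timeseries(paths["chain_five"], ts5)

    anova = pd.DataFrame({
        "subject_id": np.repeat([f"s{i}" for i in range(1, 5)], 3),
        "group": np.repeat(["patient", "patient", "control", "control"], 3),
        "condition": list(synth.CONDITIONS) * 4,
        "value": np.round(rng.normal(size=12), 3),
    })
    paths["anova_instance"] = out / "anova_four_subjects.csv"
    anova.to_csv(paths["anova_instance"], index=False)

    maps = synth.random_maps(200, 5, seed=seed)
    cohort = synth.generate_cohort(chain, 2, 2,
                                   frames={"rest": 100, "L1": 80, "L2": 80}, seed=seed)
    mask = np.zeros(200)
    mask[:20] = 1.0
    vols = synth.make_toy_volumes(maps, cohort, {"mask": mask, "amplitude": 1.0},
                                  noise_sd=0.1, seed=seed)
    sid, cond = "sub-P001", "rest"
    paths["toy_volume"] = out / "toy_volume.nii.gz"
    io.vectors_to_nifti(vols.volumes[(sid, cond)], paths["toy_volume"])
    paths["toy_maps"] = out / "toy_maps.nii.gz"
    io.vectors_to_nifti(maps, paths["toy_maps"])
    paths["toy_lesion"] = out / "toy_lesion_mask.nii.gz"
    io.vectors_to_nifti(mask, paths["toy_lesion"])
    return paths
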