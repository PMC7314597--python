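"""End-to-end orchestration of the five-step analysis pipeline.

Given (or simulating) a baseline cohort and a paired pre/post training
cohort, the pipeline: trains the baseline map, cross-validates it,
generalizes it to the training timepoints, trains pre/post maps and
compares their component-plane similarity, clusters the baseline map's
nodes (with silhouette and retrain-stability checks), allocates the
training participants at both timepoints, and produces the interest-group
trajectory report.  Every stage seed derives deterministically from one
master seed and every artifact is written to the output directory with a
machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import clustering, datasets, prediction, similarity, trajectories
from .datasets import ScoreTable
from .som import SOMConfig, batch_train

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = (
    "data",
    "baseline_som",
    "cross_validation",
    "generalization",
    "timepoint_soms",
    "rsa",
    "clustering",
    "trajectories",
)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults mirror the reference analysis."""

    # either paths to CSV tables ...
    baseline_path: str | None = None
    pre_path: str | None = None
    post_path: str | None = None
    # ... or a simulation request
    simulate: bool = False
    n_baseline: int = datasets.N_BASELINE
    n_training: int = datasets.N_TRAINING
    separated_profiles: bool = False

    grid_rows: int = 8
    grid_cols: int = 8
    initial_neighbourhood: float = 2.0
    ordering_steps: int = 10
    fine_tune_steps: int = 2

    cv_reps: int = 1000
    holdout_fraction: float = 0.2
    k_neighbours: int = 3
    shuffles_per_rep: int = 100
    generalization_shuffles: int = 10000

    rsa_bootstrap: int = 10000
    rsa_alpha: float = 0.05
    tail_rule: str = "two_sided"

    k_clusters: int = 4
    kmeans_restarts: int = 100
    stability_reps: int = 1000
    silhouette_ks: tuple[int, ...] = (2, 3, 4, 5, 6)

    covariate: str | None = "gf_score"
    seed: int = 0
    out_dir: str = "cogmap_out"

    def validate(self) -> None:
        have_paths = all(p is not None for p in (self.baseline_path, self.pre_path, self.post_path))
        if not (have_paths or self.simulate):
            raise ValueError(
                "config must provide baseline_path/pre_path/post_path or set simulate: true"
            )
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie strictly between 0 and 1")
        for name in ("cv_reps", "shuffles_per_rep", "rsa_bootstrap", "k_clusters",
                     "kmeans_restarts", "stability_reps", "k_neighbours"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tail_rule not in similarity.TAIL_RULES:
            raise ValueError(f"tail_rule must be one of {similarity.TAIL_RULES}")

    def som_config(self, seed: int) -> SOMConfig:
        return SOMConfig(
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            initial_neighbourhood=self.initial_neighbourhood,
            ordering_steps=self.ordering_steps,
            fine_tune_steps=self.fine_tune_steps,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "silhouette_ks" in doc:
            doc["silhouette_ks"] = tuple(doc["silhouette_ks"])
        return cls(**doc)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("out_dir")  # where results land does not change what they are
        canon = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _dump(doc, path: Path) -> None:
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Fully reproducible given the master seed: all stage seeds derive from
    it and no artifact embeds wall-clock information (timing goes to the
    log only).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            _STAGES, np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=len(_STAGES))
        )
    }
    manifest: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": stage_seeds,
        "artifacts": {},
    }

    def finish(stage: str, artifact: Path, started: float) -> None:
        logger.info("stage %s done in %.2fs (seed %d)", stage, time.time() - started, stage_seeds[stage])
        manifest["artifacts"][stage] = artifact.name

    # --- stage 1: data -----------------------------------------------------
    t0 = time.time()
    if config.simulate:
        seed = stage_seeds["data"]
        make_base = (
            datasets.separated_baseline_spec if config.separated_profiles
            else datasets.default_baseline_spec
        )
        make_train = (
            datasets.separated_training_spec if config.separated_profiles
            else datasets.default_training_spec
        )
        baseline = datasets.simulate_baseline_cohort(make_base(config.n_baseline, seed))
        paired = datasets.simulate_training_cohort(make_train(config.n_training, seed + 1))
        pre, post = paired.pre, paired.post
    else:
        cov = (config.covariate,) if config.covariate else ()
        baseline = datasets.read_score_table(config.baseline_path)
        pre = datasets.read_score_table(config.pre_path, covariate_names=cov)
        post = datasets.read_score_table(config.post_path)
    datasets.write_score_table(baseline, out / "baseline.csv")
    datasets.write_score_table(pre, out / "pre.csv")
    datasets.write_score_table(post, out / "post.csv")
    finish("data", out / "baseline.csv", t0)

    # --- stage 2: baseline SOM --------------------------------------------
    t0 = time.time()
    baseline_model = batch_train(baseline, config.som_config(stage_seeds["baseline_som"]))
    baseline_model.save(out / "baseline_som.json")
    finish("baseline_som", out / "baseline_som.json", t0)

    # --- stage 3: cross-validation ----------------------------------------
    t0 = time.time()
    cv = prediction.cross_validate(
        baseline,
        config.som_config(stage_seeds["baseline_som"]),
        n_reps=config.cv_reps,
        holdout_fraction=config.holdout_fraction,
        k=config.k_neighbours,
        shuffles_per_rep=config.shuffles_per_rep,
        seed=stage_seeds["cross_validation"],
    )
    cv.to_json(out / "cross_validation.json")
    cv.errors_frame().to_csv(out / "cv_errors.csv", index=False)
    finish("cross_validation", out / "cross_validation.json", t0)

    # --- stage 4: generalization to pre/post -------------------------------
    t0 = time.time()
    gen_doc = {}
    for label, table in (("pre", pre), ("post", post)):
        rep = prediction.generalization_errors(
            baseline_model,
            table,
            k=config.k_neighbours,
            n_shuffles=config.generalization_shuffles,
            seed=stage_seeds["generalization"],
        )
        gen_doc[label] = {
            "per_task_mae": {t: float(v) for t, v in zip(rep.task_names, rep.per_task_mae)},
            "per_task_p": {
                t: float(r.p_value) for t, r in zip(rep.task_names, rep.per_task_result)
            },
        }
    _dump(gen_doc, out / "generalization.json")
    finish("generalization", out / "generalization.json", t0)

    # --- stage 5: pre/post SOMs -------------------------------------------
    t0 = time.time()
    pre_model = batch_train(pre, config.som_config(stage_seeds["timepoint_soms"]))
    post_model = batch_train(post, config.som_config(stage_seeds["timepoint_soms"]))
    pre_model.save(out / "pre_som.json")
    post_model.save(out / "post_som.json")
    finish("timepoint_soms", out / "pre_som.json", t0)

    # --- stage 6: representational similarity ------------------------------
    t0 = time.time()
    sim_pre = similarity.similarity_matrix(pre_model)
    sim_post = similarity.similarity_matrix(post_model)
    sim_pre.to_csv(out / "similarity_pre.csv")
    sim_post.to_csv(out / "similarity_post.csv")
    tests = similarity.compare_all_pairs(
        pre_model,
        post_model,
        b=config.rsa_bootstrap,
        alpha=config.rsa_alpha,
        tail_rule=config.tail_rule,
        seed=stage_seeds["rsa"],
    )
    similarity.write_difference_tests(tests, out / "rsa.json")
    finish("rsa", out / "rsa.json", t0)

    # --- stage 7: clustering ------------------------------------------------
    t0 = time.time()
    solution = clustering.kmeans_nodes(
        baseline_model,
        k=config.k_clusters,
        n_restarts=config.kmeans_restarts,
        seed=stage_seeds["clustering"],
    )
    solution.to_json(out / "cluster_solution.json")
    alloc = clustering.allocate_to_clusters(baseline_model, solution, baseline)
    alloc.to_csv(out / "baseline_allocations.csv", index=False)
    clustering.profile_summary(alloc, baseline).to_csv(out / "baseline_profiles.csv", index=False)
    sil = clustering.silhouette_scan(
        baseline_model, config.silhouette_ks, seed=stage_seeds["clustering"]
    )
    stab = clustering.stability_analysis(
        baseline,
        config.som_config(stage_seeds["baseline_som"]),
        k=config.k_clusters,
        n_reps=config.stability_reps,
        seed=stage_seeds["clustering"],
    )
    _dump(
        {
            "silhouette": {str(k): v for k, v in sil.items()},
            "stability_mean_ari": stab.mean_agreement,
            "stability_min_ari": stab.min_agreement,
            "stability_reps": stab.n_reps,
        },
        out / "clustering.json",
    )
    finish("clustering", out / "cluster_solution.json", t0)

    # --- stage 8: trajectories ----------------------------------------------
    t0 = time.time()
    transitions = trajectories.allocate_timepoints(baseline_model, solution, pre, post)
    transitions.to_csv(out / "transitions.csv", index=False)
    grouping = trajectories.interest_groups(transitions)
    covariate = config.covariate if config.covariate in transitions.columns else None
    report = trajectories.trajectory_report(transitions, grouping, covariate_name=covariate)
    report.to_json(out / "trajectory_report.json")
    finish("trajectories", out / "trajectory_report.json", t0)

    _dump(manifest, out / "manifest.json")
    return manifest
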