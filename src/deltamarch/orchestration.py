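"""Configuration and the one-command end-to-end synthetic experiment.

``run_full_experiment`` composes the whole pipeline: cohort generation,
backend + latent class model fitting, grade-up/grade-down traversals plus
within-grade control swaps, Delta-March maps, component enrichment,
phenotype tables per node, and the counterfactual power analysis.  Every
stochastic stage receives its own seed fanned out deterministically from the
single experiment seed, so identical configs produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counterfactual_stats import PowerConfig, power_analysis, trajectory_grade_features
from .delta_march import march, sub_transition_indices, compute_delta_map, normalize_binarize
from .enrichment import EnrichmentItem, composite_from_patches, enrichment_analysis
from .grade_predictor import fit_image_grade_predictor
from .latent_backend import fit_latent_class_model, latent_quality_metrics, train_toy_autoencoder
from .nn import random_conv_filter
from .phenotypes import nuclear_morphometrics, phenotype_table
from .synthetic_tissue import GradeAnchors, ParameterClipWarning, analytic_backend, make_cohort
from .traversal import traverse_grade, within_grade_swap

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_full_experiment", "stage_seeds"]


@dataclass
class ExperimentConfig:
    """All knobs of the synthetic end-to-end study, serializable to YAML."""

    seed: int = 0
    out_dir: str = "deltamarch_report"
    # synthetic cohort
    patch_size: int = 96
    n_per_grade: int = 100
    n_slides: int = 8
    anchors: dict = field(default_factory=dict)  # overrides for GradeAnchors fields
    # backend
    backend: str = "analytic"  # "analytic" | "toy_autoencoder"
    # traversal
    step_scale: float = 1.0
    max_steps: int = 4
    n_nodes: int = 20
    n_trajectories: int = 140
    n_swaps: int = 20
    # delta march filter
    filter_channels: tuple = (3, 16, 32)
    filter_depth: int | None = None
    binarize_threshold: float = 0.5
    normalization_mode: str = "minmax"
    # phenotypes
    nucleoli_sigma: float = 1.0
    nucleoli_prominence: float = 0.08
    # power analysis
    power_n_per_group: int = 100
    power_reps: int = 1000
    power_grade_pairs: tuple = ((1, 2), (2, 3), (3, 4), (1, 4))

    def grade_anchors(self) -> GradeAnchors:
        over = {k: tuple(v) if isinstance(v, list) else v for k, v in self.anchors.items()}
        return dataclasses.replace(GradeAnchors(), **over)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["filter_channels"] = list(self.filter_channels)
        d["power_grade_pairs"] = [list(p) for p in self.power_grade_pairs]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "filter_channels" in d:
            d["filter_channels"] = tuple(d["filter_channels"])
        if "power_grade_pairs" in d:
            d["power_grade_pairs"] = tuple(tuple(p) for p in d["power_grade_pairs"])
        return cls(**d)


_STAGES = ("cohort", "backend", "classifier", "traversal", "march", "enrichment",
           "phenotypes", "power")


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds fanned out from the experiment seed."""
    children = np.random.SeedSequence(int(seed)).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31) for name, c in zip(_STAGES, children)}


def _mean_tumor_area(node) -> float:
    if node.patch is None:
        return float("nan")
    means, _ = nuclear_morphometrics(node.patch.nuclei_mask)
    return means["mean_tumor_area"]


def run_full_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the complete synthetic study and write a report directory.

    Returns the in-memory results (tables and objects); CSV/JSON artifacts and
    a manifest of seeds and versions are written under ``out_dir``.  A stage
    failure aborts with the stage name; artifacts of completed stages remain
    on disk.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    anchors = config.grade_anchors()
    results: dict = {"config": config, "seeds": seeds}
    manifest = {"version": __version__, "seeds": seeds, "stages_completed": []}
    config.to_yaml(out / "config.yaml")

    def _finish(stage):
        manifest["stages_completed"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    stage = "cohort"
    try:
        patches, meta = make_cohort(
            config.n_per_grade, n_slides=config.n_slides, seed=seeds[stage],
            patch_size=config.patch_size, anchors=anchors,
        )
        meta.to_csv(out / "cohort_metadata.csv", index=False)
        results["patches"], results["metadata"] = patches, meta
        _finish(stage)

        stage = "backend"
        if config.backend == "analytic":
            backend = analytic_backend(anchors=anchors, patch_size=config.patch_size)
        elif config.backend == "toy_autoencoder":
            backend = train_toy_autoencoder(patches, seed=seeds[stage])
        else:
            raise ValueError(f"unknown backend {config.backend!r}")
        results["backend"] = backend
        _finish(stage)

        stage = "classifier"
        codes = [backend.encode_patch(p) for p in patches]
        grades = [p.grade_label for p in patches]
        class_model = fit_latent_class_model(codes, grades, seed=seeds[stage])
        quality = latent_quality_metrics(
            codes, [p.slide_id for p in patches], grades, seed=seeds[stage]
        )
        quality["latent_training_accuracy"] = class_model.training_accuracy
        (out / "latent_metrics.json").write_text(json.dumps(quality, indent=1, sort_keys=True))
        predictor = fit_image_grade_predictor(patches, seed=seeds[stage])
        results["class_model"], results["predictor"] = class_model, predictor
        results["latent_metrics"] = quality
        _finish(stage)

        stage = "traversal"
        rng = np.random.default_rng(seeds[stage])
        g1_patches = [p for p in patches if p.grade_label == 1]
        trajectories = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ParameterClipWarning)
            for i in range(config.n_trajectories):
                p = g1_patches[int(rng.integers(len(g1_patches)))]
                traj = traverse_grade(
                    backend.encode_patch(p), backend.state_of(p), class_model, 4,
                    predictor.predict, backend, step_scale=config.step_scale,
                    max_steps=config.max_steps, n_nodes=config.n_nodes,
                    trajectory_id=f"traj_{i:04d}",
                )
                trajectories.append(traj)
            # within-grade control swaps
            swaps = []
            for i in range(config.n_swaps):
                g = int(rng.integers(1, 5))
                pool = [p for p in patches if p.grade_label == g]
                a = pool[int(rng.integers(len(pool)))]
                bs = [p for p in pool if p.slide_id != a.slide_id]
                if not bs:
                    continue
                b = bs[int(rng.integers(len(bs)))]
                swaps.append((a, b, within_grade_swap(a, b, backend)))
        results["trajectories"], results["swaps"] = trajectories, swaps
        traj_rows = [
            dict(trajectory_id=t.trajectory_id, n_shift_steps=t.n_shift_steps,
                 halted_by=t.halted_by, final_grade=t.end.predicted_grade,
                 node_grades=json.dumps(t.predicted_grades()))
            for t in trajectories
        ]
        pd.DataFrame(traj_rows).to_csv(out / "trajectories.csv", index=False)
        _finish(stage)

        stage = "march"
        filt = random_conv_filter(config.filter_channels, seed=seeds[stage])
        items = []
        for traj in trajectories:
            maps = march(traj, filt, depth=config.filter_depth,
                         threshold=config.binarize_threshold, mode=config.normalization_mode)
            nodes = traj.all_nodes()
            for dm, (label, i, j) in zip(maps, sub_transition_indices(traj)):
                if nodes[i].patch is None:
                    continue
                comp = composite_from_patches(nodes[i].patch, nodes[j].patch, seed=seeds[stage])
                items.append(EnrichmentItem(
                    patch_id=traj.trajectory_id, transition=label,
                    binary_delta=dm.binary, composite=comp,
                ))
        # within-grade controls march as a single swap transition
        for k, (a, b, swapped) in enumerate(swaps):
            if not hasattr(swapped, "nuclei_mask"):
                continue  # backend without mask emission: no composite possible
            dm = compute_delta_map(a.image, swapped.image, filt, depth=config.filter_depth,
                                   label=f"within-{a.grade_label}")
            dm = normalize_binarize(dm, threshold=config.binarize_threshold,
                                    mode=config.normalization_mode)
            comp = composite_from_patches(a, swapped, seed=seeds[stage] + k)
            items.append(EnrichmentItem(
                patch_id=f"swap_{k:03d}", transition=f"within-{a.grade_label}",
                binary_delta=dm.binary, composite=comp,
            ))
        results["filter"], results["enrichment_items"] = filt, items
        _finish(stage)

        stage = "enrichment"
        table = enrichment_analysis(items, seed=seeds[stage])
        table.rows.to_csv(out / "enrichment_rows.csv", index=False)
        table.aggregates.to_csv(out / "enrichment_aggregates.csv", index=False)
        results["enrichment"] = table
        _finish(stage)

        stage = "phenotypes"
        pheno_real = phenotype_table(
            patches, sigma=config.nucleoli_sigma, prominence=config.nucleoli_prominence
        )
        pheno_real.to_csv(out / "phenotypes_real.csv", index=False)
        grade_fn = None
        if config.backend == "analytic":
            grade_fn = lambda code: float(np.clip(code[0], 1.0, 4.0))  # noqa: E731
        syn_feats = trajectory_grade_features(trajectories, _mean_tumor_area,
                                              select="progression", grade_of_code=grade_fn)
        syn_feats.to_csv(out / "phenotypes_nodes.csv", index=False)
        results["phenotypes_real"], results["phenotypes_nodes"] = pheno_real, syn_feats
        _finish(stage)

        stage = "power"
        real_feats = pheno_real.rename(columns={"mean_tumor_nuclear_area": "value"})[
            ["grade", "value"]
        ]
        pcfg = PowerConfig(
            n_per_group=config.power_n_per_group, n_reps=config.power_reps,
            grade_pairs=config.power_grade_pairs, seed=seeds[stage],
        )
        power = power_analysis(real_feats, syn_feats, pcfg)
        power.summary.to_csv(out / "power_summary.csv", index=False)
        results["power"] = power
        _finish(stage)
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"experiment stage '{stage}' failed: {exc}") from exc

    return results
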