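"""Statistical power of trajectory-paired vs unpaired grade comparisons.

Builds grade-1 -> grade-4 trajectories, extracts per-grade mean tumor nuclear
area from each, and compares the sign-test power of three sampling
strategies: real unpaired patches, synthetic patches from independent
trajectories, and trajectory-matched counterfactual pairs.
"""

import warnings

import numpy as np

from deltamarch.counterfactual_stats import (
    PowerConfig, power_analysis, trajectory_grade_features,
)
from deltamarch.grade_predictor import fit_image_grade_predictor
from deltamarch.latent_backend import fit_latent_class_model
from deltamarch.phenotypes import nuclear_morphometrics, phenotype_table
from deltamarch.synthetic_tissue import ParameterClipWarning, analytic_backend, make_cohort
from deltamarch.traversal import traverse_grade

warnings.simplefilter("ignore", ParameterClipWarning)

backend = analytic_backend()
patches, _ = make_cohort(n_per_grade=40, seed=5)
class_model = fit_latent_class_model(
    [backend.encode_patch(p) for p in patches], [p.grade_label for p in patches], seed=0
)
predictor = fit_image_grade_predictor(patches, seed=0)

rng = np.random.default_rng(5)
g1 = [p for p in patches if p.grade_label == 1]
trajectories = []
for i in range(60):
    base = g1[int(rng.integers(len(g1)))]
    code = backend.encode_patch(base).copy()
    code[3] = np.clip(rng.normal(0.0, 0.18), np.log(0.75), np.log(1.35))
    trajectories.append(
        traverse_grade(code, int(rng.integers(2**31)), class_model, 4,
                       predictor.predict, backend)
    )

syn = trajectory_grade_features(
    trajectories,
    lambda node: nuclear_morphometrics(node.patch.nuclei_mask)[0]["mean_tumor_area"],
    select="progression",
    grade_of_code=lambda code: float(np.clip(code[0], 1.0, 4.0)),
)
real = phenotype_table(patches).rename(
    columns={"mean_tumor_nuclear_area": "value"})[["grade", "value"]]

cfg = PowerConfig(n_per_group=30, n_reps=300, grade_pairs=((1, 2),), seed=7)
result = power_analysis(real, syn, cfg)
print(result.summary.to_string(index=False))
print(
    "\nSmaller (more negative) mean log p = more power. Trajectory-matched "
    "pairs (syn_pair) cancel patient-level nuclear-size heterogeneity, so "
    "they dominate both unpaired strategies."
)
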