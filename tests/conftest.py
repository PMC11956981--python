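"""Shared fixtures.

Heavy artifacts (cohorts, fitted models, trajectory ensembles) are session
scoped so the unit suite and the acceptance suite reuse them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from deltamarch.delta_march import march, sub_transition_indices
from deltamarch.enrichment import EnrichmentItem, composite_from_patches
from deltamarch.grade_predictor import fit_image_grade_predictor
from deltamarch.latent_backend import fit_latent_class_model
from deltamarch.nn import random_conv_filter
from deltamarch.synthetic_tissue import (
    GradeAnchors,
    ParameterClipWarning,
    analytic_backend,
    make_cohort,
)
from deltamarch.traversal import traverse_grade


@pytest.fixture(scope="session")
def backend():
    return analytic_backend()


@pytest.fixture(scope="session")
def small_cohort():
    """20 patches per grade, default anchors."""
    patches, meta = make_cohort(20, seed=11)
    return patches, meta


@pytest.fixture(scope="session")
def class_model(backend, small_cohort):
    patches, _ = small_cohort
    codes = [backend.encode_patch(p) for p in patches]
    return fit_latent_class_model(codes, [p.grade_label for p in patches], seed=0)


@pytest.fixture(scope="session")
def predictor(small_cohort):
    patches, _ = small_cohort
    return fit_image_grade_predictor(patches, seed=0)


@pytest.fixture(scope="session")
def filter_net():
    return random_conv_filter(seed=0)


@pytest.fixture(scope="session")
def sample_trajectory(backend, class_model, predictor, small_cohort):
    """One grade-1 -> grade-4 trajectory on the default analytic backend."""
    patches, _ = small_cohort
    start = next(p for p in patches if p.grade_label == 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ParameterClipWarning)
        return traverse_grade(
            backend.encode_patch(start), backend.state_of(start), class_model, 4,
            predictor.predict, backend, trajectory_id="fixture",
        )


def _traverse_ensemble(n, anchors, seed, predictor_cohort_per_grade=30):
    """Cohort + fitted models + n grade-1->4 trajectories under given anchors."""
    bk = analytic_backend(anchors=anchors)
    patches, _ = make_cohort(predictor_cohort_per_grade, seed=seed, anchors=anchors)
    model = fit_latent_class_model(
        [bk.encode_patch(p) for p in patches], [p.grade_label for p in patches], seed=seed
    )
    gp = fit_image_grade_predictor(patches, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A11]))
    g1 = [p for p in patches if p.grade_label == 1]
    trajectories = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ParameterClipWarning)
        for i in range(n):
            # fresh grade-1 scenes beyond the cohort so trajectories are distinct
            base = g1[int(rng.integers(len(g1)))]
            code = bk.encode_patch(base).copy()
            code[3] = np.clip(rng.normal(0.0, 0.18), np.log(0.75), np.log(1.35))
            state = int(rng.integers(2**31))
            trajectories.append(
                traverse_grade(code, state, model, 4, gp.predict, bk,
                               trajectory_id=f"traj_{i:04d}")
            )
    return bk, patches, model, gp, trajectories


@pytest.fixture(scope="session")
def tumor_only_march():
    """200 trajectories in which only tumor nuclei change with grade.

    Anchors hold nucleoli rate and vasculature density constant across grades,
    so the tumor-radius axis is the sole grade-linked change; returns the
    marched enrichment items plus the trajectories.
    """
    anchors = GradeAnchors(nucleoli_rate=(1.5,) * 4, vasc_density=(0.07,) * 4)
    bk, patches, model, gp, trajectories = _traverse_ensemble(200, anchors, seed=21)
    filt = random_conv_filter(seed=21)
    items = []
    for traj in trajectories:
        nodes = traj.all_nodes()
        for dm, (label, i, j) in zip(march(traj, filt), sub_transition_indices(traj)):
            items.append(
                EnrichmentItem(
                    patch_id=traj.trajectory_id, transition=label, binary_delta=dm.binary,
                    composite=composite_from_patches(nodes[i].patch, nodes[j].patch, seed=i),
                )
            )
    return items, trajectories


@pytest.fixture(scope="session")
def default_trajectories():
    """140 grade-1 -> grade-4 trajectories under the default anchors."""
    _, patches, _, _, trajectories = _traverse_ensemble(140, GradeAnchors(), seed=33)
    return patches, trajectories
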