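"""Counterfactual latent-space traversal.

A trajectory shifts a patch's standardized semantic code along a target
class's weight vector in steps of ``step_scale * sqrt(d)`` (the isotropic
random-walk step length in d-dimensional code space), decoding with a fixed
stochastic state after each shift and halting when the image grade predictor
reports the target grade or after a step cap.  The endpoint fixed, interior
nodes are interpolated linearly in standardized space and decoded with the
same state, yielding an ordered counterfactual image series in which only
class-linked morphology changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .latent_backend import LatentClassModel, destandardize, standardize
from .synthetic_tissue import LabeledPatch

__all__ = ["Trajectory", "TrajectoryNode", "traverse_grade", "grade_down", "within_grade_swap"]


@dataclass
class TrajectoryNode:
    code: np.ndarray  # raw (destandardized) semantic code
    image: np.ndarray
    predicted_grade: int
    patch: LabeledPatch | None = None  # masks available for mask-emitting backends


@dataclass
class Trajectory:
    """Ordered counterfactual series sharing one stochastic state.

    ``nodes`` holds the interior interpolated nodes only; the endpoints are
    ``start`` and ``end``.  All images were decoded with the same ``state``.
    """

    start: TrajectoryNode
    end: TrajectoryNode
    nodes: list  # interior TrajectoryNodes, ordered start -> end
    state: object
    direction_class: int
    n_shift_steps: int
    halted_by: str  # "terminal_grade" | "step_cap"
    trajectory_id: str = ""

    def all_nodes(self) -> list:
        return [self.start, *self.nodes, self.end]

    def images(self) -> list:
        return [n.image for n in self.all_nodes()]

    def predicted_grades(self) -> list:
        return [n.predicted_grade for n in self.all_nodes()]


def _as_node(decoded, code, predictor) -> TrajectoryNode:
    if isinstance(decoded, LabeledPatch):
        image, patch = decoded.image, decoded
    else:
        image, patch = decoded, None
    return TrajectoryNode(
        code=np.asarray(code, dtype=float),
        image=image,
        predicted_grade=int(predictor(image)),
        patch=patch,
    )


def traverse_grade(
    start_code: np.ndarray,
    state,
    class_model: LatentClassModel,
    target_grade: int,
    grade_predictor: Callable[[np.ndarray], int],
    backend,
    step_scale: float = 1.0,
    max_steps: int = 4,
    n_nodes: int = 20,
    trajectory_id: str = "",
) -> Trajectory:
    """Shift-and-halt traversal toward ``target_grade``, then node interpolation.

    If the start image is already predicted as the target grade, a degenerate
    zero-shift trajectory is returned (documented behaviour, not an error).
    """
    if step_scale < 0:
        raise ValueError("step_scale must be >= 0")
    start_code = np.asarray(start_code, dtype=float)
    d = start_code.shape[0]
    w = class_model.weight_vector(target_grade)
    norm = float(np.linalg.norm(w))
    if norm == 0:
        raise ValueError(f"zero weight vector for grade {target_grade}")
    step = step_scale * np.sqrt(d) * (w / norm)

    z0 = standardize(start_code, class_model)
    start_node = _as_node(backend.decode(start_code, state), start_code, grade_predictor)

    z = z0.copy()
    n_shifts = 0
    halted_by = "terminal_grade"
    last_node = start_node
    if start_node.predicted_grade != int(target_grade):
        halted_by = "step_cap"
        for _ in range(max_steps):
            z = z + step
            n_shifts += 1
            code = destandardize(z, class_model)
            node = _as_node(backend.decode(code, state), code, grade_predictor)
            last_node = node
            if node.predicted_grade == int(target_grade):
                halted_by = "terminal_grade"
                break

    z_end = z
    end_node = last_node if n_shifts > 0 else start_node

    interior = []
    for i in range(1, n_nodes + 1):
        t = i / (n_nodes + 1)
        zi = z0 + t * (z_end - z0)
        code = destandardize(zi, class_model)
        interior.append(_as_node(backend.decode(code, state), code, grade_predictor))

    return Trajectory(
        start=start_node,
        end=end_node,
        nodes=interior,
        state=state,
        direction_class=int(target_grade),
        n_shift_steps=n_shifts,
        halted_by=halted_by,
        trajectory_id=trajectory_id,
    )


def grade_down(start_code, state, class_model, grade_predictor, backend, **kwargs) -> Trajectory:
    """Traversal toward lower grades: shift along the grade-1 weight vector."""
    return traverse_grade(
        start_code, state, class_model, 1, grade_predictor, backend, **kwargs
    )


def within_grade_swap(patch_a: LabeledPatch, patch_b: LabeledPatch, backend):
    """Across-patient control counterfactual.

    Keeps patch A's stochastic state but replaces its semantic code with that
    of a same-grade patch from a different slide; the decoded image shows
    patch B's grade statistics in patch A's spatial layout.
    """
    if patch_a.grade_label != patch_b.grade_label:
        raise ValueError(
            f"within-grade swap requires equal grades, got "
            f"{patch_a.grade_label} and {patch_b.grade_label}"
        )
    # a self-swap (identity counterfactual, i.e. reconstruction) is permitted;
    # distinct patches must come from different slides ("different patient")
    if patch_a is not patch_b and patch_a.slide_id == patch_b.slide_id:
        raise ValueError("within-grade swap requires patches from different slides")
    code_b = backend.encode_patch(patch_b)
    state_a = backend.state_of(patch_a)
    return backend.decode(code_b, state_a)
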