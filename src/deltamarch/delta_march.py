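"""Delta-Maps: deep-feature differencing saliency for counterfactual image pairs.

For an image pair the filter network's intermediate feature stacks are
subtracted channel-wise, each difference channel is upscaled bilinearly to the
image size, absolute values are taken, and the channels are averaged — the
resulting non-negative map localizes where the pair differs in feature space.
A march applies this to the consecutive sub-transitions of a trajectory
(grade g to g+1) rather than to the single large start/end jump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from . import nn
from .traversal import Trajectory

__all__ = [
    "FeatureStack",
    "DeltaMap",
    "extract_features",
    "compute_delta_map",
    "normalize_binarize",
    "upscale_bilinear",
    "sub_transition_indices",
    "march",
    "save_delta_map",
]


@dataclass
class FeatureStack:
    """(C, h, w) intermediate activations of a filter network for one image."""

    values: np.ndarray
    image_shape: tuple

    @property
    def channels(self) -> int:
        return self.values.shape[0]


@dataclass
class DeltaMap:
    raw: np.ndarray
    normalized: np.ndarray | None = None
    binary: np.ndarray | None = None
    threshold: float | None = None
    label: str = ""


def _forward_features(image: np.ndarray, filter_net, depth: int | None) -> np.ndarray:
    if hasattr(filter_net, "features"):  # e.g. a backend exposing encoder features
        return np.asarray(filter_net.features(image, depth))
    return np.asarray(filter_net.forward(nn.image_to_tensor(image), depth=depth)[0])


def extract_features(image: np.ndarray, filter_net, depth: int | None = None) -> FeatureStack:
    """Deterministic intermediate feature stack of ``image`` at the given depth."""
    vals = _forward_features(image, filter_net, depth)
    return FeatureStack(values=vals, image_shape=image.shape[:2])


def upscale_bilinear(channel: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear upscaling with the half-pixel (align-corners-off) convention.

    Output pixel (i, j) samples source coordinate ((i + .5) * h/out_h - .5,
    (j + .5) * w/out_w - .5), clamped to the source grid.
    """
    h, w = channel.shape
    ys = np.clip((np.arange(out_h) + 0.5) * h / out_h - 0.5, 0, h - 1)
    xs = np.clip((np.arange(out_w) + 0.5) * w / out_w - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    return (
        channel[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
        + channel[np.ix_(y0, x1)] * (1 - wy) * wx
        + channel[np.ix_(y1, x0)] * wy * (1 - wx)
        + channel[np.ix_(y1, x1)] * wy * wx
    )


def compute_delta_map(
    image_a: np.ndarray,
    image_b: np.ndarray,
    filter_net,
    depth: int | None = None,
    label: str = "",
) -> DeltaMap:
    """Raw Delta-Map of an image pair.

    Pipeline order: per-channel feature subtraction, bilinear upscaling of
    each difference channel to the image size, absolute value, mean over
    channels.
    """
    if image_a.shape != image_b.shape:
        raise ValueError(f"image shapes differ: {image_a.shape} vs {image_b.shape}")
    fa = _forward_features(image_a, filter_net, depth)
    fb = _forward_features(image_b, filter_net, depth)
    h, w = image_a.shape[:2]
    diff = fa - fb
    acc = np.zeros((h, w))
    for c in range(diff.shape[0]):
        acc += np.abs(upscale_bilinear(diff[c], h, w))
    return DeltaMap(raw=acc / diff.shape[0], label=label)


def normalize_binarize(
    dmap: DeltaMap, threshold: float = 0.5, mode: str = "minmax"
) -> DeltaMap:
    """Per-patch normalization of the raw map and strict-threshold binarization.

    ``mode='minmax'`` (default) rescales (raw - min)/(max - min) to [0,1];
    ``mode='min'`` only subtracts the per-patch minimum.  A constant raw map
    normalizes to all zeros.  Binary pixels are those strictly above the
    threshold.
    """
    raw = dmap.raw
    lo, hi = float(raw.min()), float(raw.max())
    if hi > lo:
        if mode == "minmax":
            norm = (raw - lo) / (hi - lo)
        elif mode == "min":
            norm = raw - lo
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    else:
        norm = np.zeros_like(raw)
    dmap.normalized = norm
    dmap.binary = (norm > threshold).astype(np.uint8)
    dmap.threshold = float(threshold)
    return dmap


def sub_transition_indices(trajectory: Trajectory) -> list[tuple[str, int, int]]:
    """Grade-boundary node indices of a trajectory.

    Returns ``(label, i, j)`` triples over the full node sequence
    (start + interior + end): for each intermediate grade the boundary is the
    first node whose predicted grade has reached it.  Works for both grade-up
    and grade-down trajectories.
    """
    grades = trajectory.predicted_grades()
    g0, g1 = grades[0], trajectory.direction_class
    if g0 == g1:
        return [(f"{g0}->{g1}", 0, len(grades) - 1)]
    sign = 1 if g1 > g0 else -1
    bounds = [0]
    labels = []
    prev_g = g0
    for g in range(g0 + sign, g1 + sign, sign):
        idx = next(
            (i for i, pg in enumerate(grades) if sign * (pg - g) >= 0 and i > 0),
            len(grades) - 1,
        )
        bounds.append(idx)
        labels.append(f"{prev_g}->{g}")
        prev_g = g
    return [(lab, a, b) for lab, a, b in zip(labels, bounds[:-1], bounds[1:])]


def march(
    trajectory: Trajectory,
    filter_net,
    depth: int | None = None,
    include_direct: bool = False,
    threshold: float = 0.5,
    mode: str = "minmax",
) -> list[DeltaMap]:
    """One normalized/binarized Delta-Map per consecutive sub-transition.

    With ``include_direct`` an extra map for the direct start-to-end jump is
    appended (labelled ``direct``) for comparison with the small-step march.
    """
    all_nodes = trajectory.all_nodes()
    if len(all_nodes) < 2:
        raise ValueError("trajectory must contain at least two images to march over")
    maps = []
    for label, i, j in sub_transition_indices(trajectory):
        dm = compute_delta_map(all_nodes[i].image, all_nodes[j].image, filter_net, depth, label=label)
        maps.append(normalize_binarize(dm, threshold=threshold, mode=mode))
    if include_direct:
        dm = compute_delta_map(all_nodes[0].image, all_nodes[-1].image, filter_net, depth, label="direct")
        maps.append(normalize_binarize(dm, threshold=threshold, mode=mode))
    return maps


def save_delta_map(dmap: DeltaMap, directory: str | Path, stem: str,
                   manifest: dict | None = None) -> None:
    """Raw map as 32-bit TIFF plus normalized/binary 8-bit PNG previews.

    A JSON manifest (label, threshold, plus any caller-supplied filter/depth
    metadata) is written alongside.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}_raw.tif", dmap.raw.astype(np.float32))
    if dmap.normalized is not None:
        Image.fromarray((dmap.normalized * 255).round().astype(np.uint8)).save(
            directory / f"{stem}_norm.png"
        )
    if dmap.binary is not None:
        Image.fromarray(dmap.binary * 255).save(directory / f"{stem}_binary.png")
    info = {"label": dmap.label, "threshold": dmap.threshold}
    info.update(manifest or {})
    (directory / f"{stem}_manifest.json").write_text(json.dumps(info, indent=1, sort_keys=True))
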