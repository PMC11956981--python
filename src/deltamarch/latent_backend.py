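"""Generative-backend contract, latent class model, and latent/reconstruction metrics.

A backend is anything with ``decode(code, state)`` plus ``encode_patch`` /
``state_of`` to read codes and stochastic states off labeled patches.  Two
implementations ship: the exactly invertible analytic backend
(:mod:`deltamarch.synthetic_tissue`) and the trainable toy convolutional
autoencoder below.  The latent class model is a multinomial logistic
regression on standardized semantic codes; its per-class weight vectors are
the traversal directions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import zoom as _ndzoom
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from . import nn
from .synthetic_tissue import LabeledPatch

logger = logging.getLogger(__name__)

__all__ = [
    "LatentClassModel",
    "standardize",
    "destandardize",
    "fit_latent_class_model",
    "latent_quality_metrics",
    "reconstruction_metrics",
    "ToyAutoencoderBackend",
    "train_toy_autoencoder",
]


class NotFittedError(RuntimeError):
    pass


@dataclass
class LatentClassModel:
    """Linear 4-class grade model on standardized semantic codes."""

    mu: np.ndarray
    sigma: np.ndarray
    weights: np.ndarray  # (C, d), rows aligned with `classes`
    bias: np.ndarray
    classes: np.ndarray
    training_accuracy: float = float("nan")
    fitted: bool = True

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    def class_index(self, grade) -> int:
        idx = np.nonzero(self.classes == grade)[0]
        if idx.size == 0:
            raise ValueError(f"grade {grade!r} not among fitted classes {self.classes.tolist()}")
        return int(idx[0])

    def weight_vector(self, grade) -> np.ndarray:
        return self.weights[self.class_index(grade)]

    def logits(self, z: np.ndarray) -> np.ndarray:
        """Class scores for an already-standardized code."""
        return self.weights @ np.asarray(z, dtype=float) + self.bias

    def predict_code(self, code: np.ndarray):
        return self.classes[int(np.argmax(self.logits(standardize(code, self))))]


def _check_fitted(model: LatentClassModel) -> None:
    if model is None or not getattr(model, "fitted", False):
        raise NotFittedError("LatentClassModel is not fitted")


def standardize(code: np.ndarray, model: LatentClassModel) -> np.ndarray:
    """Per-dimension centering/scaling by the model's frozen training statistics."""
    _check_fitted(model)
    return (np.asarray(code, dtype=float) - model.mu) / model.sigma


def destandardize(z: np.ndarray, model: LatentClassModel) -> np.ndarray:
    _check_fitted(model)
    return np.asarray(z, dtype=float) * model.sigma + model.mu


def fit_latent_class_model(
    codes: Sequence[np.ndarray], grades: Sequence, seed: int = 0
) -> LatentClassModel:
    """Fit the multinomial linear grade model on standardized codes.

    The standardizer statistics are computed on this training set and frozen.
    Dimensions with zero variance are rejected (they cannot be standardized).
    """
    x = np.asarray(codes, dtype=float)
    y = np.asarray(grades)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit a latent class model")
    if x.shape[0] < x.shape[1] / 10:
        logger.warning(
            "only %d samples for %d code dimensions; weights may be unstable",
            x.shape[0], x.shape[1],
        )
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    if np.any(sigma <= 0):
        raise ValueError("constant code dimensions cannot be standardized (sigma == 0)")
    z = (x - mu) / sigma
    clf = LogisticRegression(C=1e3, max_iter=5000, random_state=int(seed))
    clf.fit(z, y)
    acc = float(clf.score(z, y))
    logger.info("latent class model training accuracy: %.3f", acc)
    if clf.coef_.shape[0] == classes.size:
        weights, bias = clf.coef_.copy(), clf.intercept_.copy()
    else:  # binary: sklearn stores one row for the positive class
        weights = np.vstack([-clf.coef_[0], clf.coef_[0]])
        bias = np.array([-clf.intercept_[0], clf.intercept_[0]])
    return LatentClassModel(
        mu=mu, sigma=sigma, weights=weights, bias=bias,
        classes=clf.classes_.copy(), training_accuracy=acc,
    )


def latent_quality_metrics(
    codes: Sequence[np.ndarray],
    slide_ids: Sequence,
    grades: Sequence,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Neighborhood purity and low/high linear separability of a code space.

    Returns the fraction of each patch's k nearest neighbours (Euclidean,
    self excluded) sharing its slide, the fraction sharing its grade, and the
    held-out accuracy of a linear discriminant separating low ({1,2}) from
    high ({3,4}) grades.
    """
    x = np.asarray(codes, dtype=float)
    slide_ids = np.asarray(slide_ids)
    grades = np.asarray(grades)
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nbrs.kneighbors(x)
    idx = idx[:, 1:]  # drop self
    same_slide = float(np.mean(slide_ids[idx] == slide_ids[:, None]))
    same_grade = float(np.mean(grades[idx] == grades[:, None]))

    low_high = np.where(np.isin(grades, (1, 2)), 0, 1)
    xtr, xte, ytr, yte = train_test_split(
        x, low_high, test_size=0.25, random_state=int(seed), stratify=low_high
    )
    lda = LinearDiscriminantAnalysis().fit(xtr, ytr)
    acc = float(lda.score(xte, yte))
    return {
        "same_slide_fraction": same_slide,
        "same_grade_fraction": same_grade,
        "low_vs_high_linear_accuracy": acc,
    }


def reconstruction_metrics(original: np.ndarray, reconstruction: np.ndarray) -> dict:
    """MSE, PSNR (dB, peak 1) and SSIM between two [0,1] images."""
    a = np.asarray(original, dtype=float)
    b = np.asarray(reconstruction, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    psnr = float("inf") if mse == 0 else float(peak_signal_noise_ratio(a, b, data_range=1.0))
    channel_axis = -1 if a.ndim == 3 else None
    ssim = float(structural_similarity(a, b, data_range=1.0, channel_axis=channel_axis))
    return {"mse": mse, "psnr": psnr, "ssim": ssim}


# ---------------------------------------------------------------------------
# toy convolutional autoencoder backend


@dataclass
class ToyAutoencoderBackend:
    """Small trained convolutional autoencoder satisfying the backend contract.

    The decoder is a deterministic function of the code alone, so the
    stochastic state is a null token; intermediate encoder activations serve
    as the Delta-March filter.
    """

    encoder: nn.Sequential
    decoder: nn.Sequential
    patch_size: int
    d: int
    loss_history: list = field(default_factory=list)

    def encode_image(self, image: np.ndarray) -> np.ndarray:
        t = nn.image_to_tensor(self._fit_size(image))
        return self.encoder.forward(t)[0]

    def encode_patch(self, patch: LabeledPatch) -> np.ndarray:
        return self.encode_image(patch.image)

    def state_of(self, patch: LabeledPatch):
        return None

    def encode_stochastic(self, patch: LabeledPatch):
        return None

    def decode(self, code: np.ndarray, state=None) -> np.ndarray:
        return nn.tensor_to_image(self.decoder.forward(np.asarray(code, dtype=float)[None]))

    def features(self, image: np.ndarray, depth: int) -> np.ndarray:
        t = nn.image_to_tensor(self._fit_size(image))
        return self.encoder.forward(t, depth=depth)[0]

    def _fit_size(self, image: np.ndarray) -> np.ndarray:
        if image.shape[0] == self.patch_size:
            return image
        f = self.patch_size / image.shape[0]
        return np.clip(_ndzoom(image, (f, f, 1), order=1), 0.0, 1.0)

    # -- serialization ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for prefix, net in (("enc", self.encoder), ("dec", self.decoder)):
            for i, layer in enumerate(net.layers):
                for j, p in enumerate(layer.params):
                    arrays[f"{prefix}_{i}_{j}"] = p
        np.savez(directory / "weights.npz", **arrays)
        manifest = {"d": self.d, "patch_size": self.patch_size, "loss_history": self.loss_history}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ToyAutoencoderBackend":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        rng = np.random.default_rng(0)
        encoder, decoder = _build_toy_nets(manifest["patch_size"], manifest["d"], rng)
        arrays = np.load(directory / "weights.npz")
        for prefix, net in (("enc", encoder), ("dec", decoder)):
            for i, layer in enumerate(net.layers):
                for j, p in enumerate(layer.params):
                    p[...] = arrays[f"{prefix}_{i}_{j}"]
        return cls(encoder=encoder, decoder=decoder, patch_size=manifest["patch_size"],
                   d=manifest["d"], loss_history=list(manifest["loss_history"]))


def _build_toy_nets(patch_size: int, d: int, rng) -> tuple[nn.Sequential, nn.Sequential]:
    s4 = patch_size // 4
    encoder = nn.Sequential([
        nn.Conv2D(3, 12, rng=rng), nn.ReLU(), nn.AvgPool2(),
        nn.Conv2D(12, 24, rng=rng), nn.ReLU(), nn.AvgPool2(),
        nn.Flatten(), nn.Dense(24 * s4 * s4, d, rng=rng),
    ])
    decoder = nn.Sequential([
        nn.Dense(d, 24 * s4 * s4, rng=rng), nn.ReLU(), nn.Reshape((24, s4, s4)),
        nn.Upsample2(), nn.Conv2D(24, 12, rng=rng), nn.ReLU(),
        nn.Upsample2(), nn.Conv2D(12, 12, rng=rng), nn.ReLU(),
        nn.Conv2D(12, 3, rng=rng), nn.Sigmoid(),
    ])
    return encoder, decoder


def train_toy_autoencoder(
    patches: Sequence[LabeledPatch],
    patch_size: int = 32,
    d: int = 128,
    epochs: int = 40,
    batch_size: int = 16,
    lr: float = 3e-3,
    seed: int = 0,
) -> ToyAutoencoderBackend:
    """Train the toy autoencoder on (downscaled) synthetic patches.

    Deterministic given the seed.  Raises if the reconstruction loss diverges;
    warns through the logger if the epoch-level moving average ever increases.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAE]))
    encoder, decoder = _build_toy_nets(patch_size, d, rng)
    backend = ToyAutoencoderBackend(encoder=encoder, decoder=decoder, patch_size=patch_size, d=d)
    x = np.concatenate([nn.image_to_tensor(backend._fit_size(p.image)) for p in patches], axis=0)
    n = x.shape[0]
    opt = nn.Adam([encoder, decoder], lr=lr)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            xb = x[order[start : start + batch_size]]
            code = encoder.forward(xb)
            recon = decoder.forward(code)
            diff = recon - xb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"toy autoencoder diverged at epoch {epoch} (loss={loss}); lower lr"
                )
            losses.append(loss)
            g = 2.0 * diff / diff.size
            encoder.backward(decoder.backward(g))
            opt.step()
        epoch_loss = float(np.mean(losses))
        backend.loss_history.append(epoch_loss)
        logger.info("toy AE epoch %d loss %.5f", epoch, epoch_loss)
    hist = backend.loss_history
    if len(hist) >= 4 and hist[-1] > hist[0]:
        logger.warning("toy AE loss did not decrease over training: %s", hist)
    return backend
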