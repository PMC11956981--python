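"""Image-based tumor-grade prediction.

Plays the role a fine-tuned deep grade classifier plays on real cohorts:
validating traversal endpoints and node grades from pixels alone.  At toy
scale a deep model is unnecessary — grade-linked morphology is captured by a
handful of stain-derived features (nuclear component sizes, nuclear area
fraction, vessel-colored area) fed to a multinomial logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hed
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .synthetic_tissue import LabeledPatch

__all__ = ["GradePredictor", "fit_image_grade_predictor", "image_grade_features"]

_EIGHT = np.ones((3, 3), dtype=bool)
# Optical-density thresholds separating the hematoxylin-dominant nuclei and
# eosin-dominant vessels from the faint background wash.
_H_THRESH = 0.30
_E_THRESH = 0.28


def image_grade_features(image: np.ndarray) -> np.ndarray:
    """Stain-space morphology features of one RGB patch.

    Features: log mean area of the larger half of nuclear components, log mean
    area of all components, nuclear area fraction, vessel-colored area
    fraction, and component count per unit area.
    """
    hed = rgb2hed(image)
    h, e = hed[..., 0], hed[..., 1]
    nuc = h > _H_THRESH
    vessel = (e > _E_THRESH) & ~nuc
    lab, n = ndimage.label(nuc, structure=_EIGHT)
    if n > 0:
        areas = ndimage.sum(np.ones_like(lab), lab, index=range(1, n + 1))
        areas = areas[areas >= 4]
    else:
        areas = np.array([])
    if areas.size == 0:
        big_mean = all_mean = 1.0
    else:
        all_mean = float(np.mean(areas))
        big = areas[areas >= np.median(areas)]
        big_mean = float(np.mean(big))
    npx = image.shape[0] * image.shape[1]
    return np.array([
        np.log(big_mean),
        np.log(all_mean),
        float(nuc.mean()),
        float(vessel.mean()),
        areas.size / npx * 1e3,
    ])


@dataclass
class GradePredictor:
    scaler: StandardScaler
    clf: LogisticRegression
    training_accuracy: float

    def predict(self, image: np.ndarray) -> int:
        f = image_grade_features(image)[None]
        return int(self.clf.predict(self.scaler.transform(f))[0])

    def predict_batch(self, images: Sequence[np.ndarray]) -> np.ndarray:
        f = np.stack([image_grade_features(im) for im in images])
        return self.clf.predict(self.scaler.transform(f)).astype(int)


def fit_image_grade_predictor(
    patches: Sequence[LabeledPatch],
    grades: Sequence[int] | None = None,
    seed: int = 0,
) -> GradePredictor:
    """Fit the feature-based grade classifier on a labeled cohort."""
    if grades is None:
        grades = [p.grade_label for p in patches]
    x = np.stack([image_grade_features(p.image) for p in patches])
    y = np.asarray(grades)
    scaler = StandardScaler().fit(x)
    clf = LogisticRegression(C=10.0, max_iter=5000, random_state=int(seed))
    clf.fit(scaler.transform(x), y)
    acc = float(clf.score(scaler.transform(x), y))
    return GradePredictor(scaler=scaler, clf=clf, training_accuracy=acc)
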