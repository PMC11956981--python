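"""Train the toy convolutional autoencoder backend and score its codes.

A scaled-down stand-in for the full generative backends: trains on small
synthetic patches, reports reconstruction quality (MSE/PSNR/SSIM) and the
latent-neighborhood quality of its semantic codes.
"""

import numpy as np

from deltamarch.latent_backend import (
    latent_quality_metrics, reconstruction_metrics, train_toy_autoencoder,
)
from deltamarch.synthetic_tissue import make_cohort

patches, _ = make_cohort(n_per_grade=40, seed=7)
backend = train_toy_autoencoder(patches, patch_size=32, seed=0)
print(f"training loss: {backend.loss_history[0]:.4f} -> {backend.loss_history[-1]:.4f}")

held_out, _ = make_cohort(n_per_grade=5, seed=900)
metrics = [
    reconstruction_metrics(backend._fit_size(p.image),
                           backend.decode(backend.encode_image(p.image)))
    for p in held_out
]
print("held-out reconstruction: "
      f"MSE={np.mean([m['mse'] for m in metrics]):.4f} "
      f"PSNR={np.mean([m['psnr'] for m in metrics]):.1f} dB "
      f"SSIM={np.mean([m['ssim'] for m in metrics]):.3f}")

codes = [backend.encode_patch(p) for p in patches]
quality = latent_quality_metrics(
    codes, [p.slide_id for p in patches], [p.grade_label for p in patches], k=10
)
print("code-space quality:", {k: round(v, 3) for k, v in quality.items()})
print(
    "\nsame_grade_fraction above chance (0.25) shows the learned codes carry "
    "grade signal; at this toy scale the linear low/high separation stays "
    "modest, which is why the exactly invertible analytic backend is the "
    "default for quantitative studies."
)
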