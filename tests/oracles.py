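"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own implementation paths (explicit
loops, BFS) so that agreement is evidence, not tautology.
"""

from collections import deque

import numpy as np

from deltamarch import nn


def flood_fill_components(mask):
    """8-connectivity connected components by BFS (no scipy)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        q = deque([(sy, sx)])
        seen[sy, sx] = True
        pix = []
        while q:
            y, x = q.popleft()
            pix.append((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                        and mask[ny, nx] and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        q.append((ny, nx))
        comps.append(pix)
    return comps


def hand_filter(seed=5):
    """A fixed 2-layer filter: 3->2 channel conv (3x3, pad 1) + 2x2 avg pool."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 0.5, (2, 3, 3, 3))
    b = rng.normal(0, 0.1, 2)
    return nn.Sequential([nn.Conv2D(3, 2, weight=w, bias=b), nn.AvgPool2()]), w, b


def brute_force_delta(img_a, img_b, w, b):
    """Explicit-loop Delta-Map: conv, pool, subtract, bilinear upscale, |.|, mean."""
    h, wd = img_a.shape[:2]

    def conv_pool(img):
        cout = w.shape[0]
        padded = np.zeros((3, h + 2, wd + 2))
        for c in range(3):
            padded[c, 1:-1, 1:-1] = img[:, :, c]
        conv = np.zeros((cout, h, wd))
        for co in range(cout):
            for y in range(h):
                for x in range(wd):
                    acc = b[co]
                    for ci in range(3):
                        for ky in range(3):
                            for kx in range(3):
                                acc += w[co, ci, ky, kx] * padded[ci, y + ky, x + kx]
                    conv[co, y, x] = acc
        pooled = np.zeros((cout, h // 2, wd // 2))
        for co in range(cout):
            for y in range(h // 2):
                for x in range(wd // 2):
                    pooled[co, y, x] = conv[co, 2 * y : 2 * y + 2, 2 * x : 2 * x + 2].mean()
        return pooled

    fa, fb = conv_pool(img_a), conv_pool(img_b)
    ph, pw = fa.shape[1:]
    total = np.zeros((h, wd))
    for co in range(fa.shape[0]):
        diff = fa[co] - fb[co]
        up = np.zeros((h, wd))
        for y in range(h):
            for x in range(wd):
                sy = min(max((y + 0.5) * ph / h - 0.5, 0), ph - 1)
                sx = min(max((x + 0.5) * pw / wd - 0.5, 0), pw - 1)
                y0, x0 = int(np.floor(sy)), int(np.floor(sx))
                y1, x1 = min(y0 + 1, ph - 1), min(x0 + 1, pw - 1)
                fy, fx = sy - y0, sx - x0
                up[y, x] = (
                    diff[y0, x0] * (1 - fy) * (1 - fx)
                    + diff[y0, x1] * (1 - fy) * fx
                    + diff[y1, x0] * fy * (1 - fx)
                    + diff[y1, x1] * fy * fx
                )
        total += np.abs(up)
    return total / fa.shape[0]
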