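"""Independent brute-force oracles, kept free of the package's FFT paths."""

import numpy as np


def direct_cross_correlation(a, b):
    """O(N⁴) direct-sum linear correlation [a ⋆ b](Δ) = Σ a(x) b(x+Δ).

    Inputs are mean-subtracted copies of the frames; the output is the full
    (2H−1, 2W−1) lag map with zero lag at (H−1, W−1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    h, w = a.shape
    out = np.zeros((2 * h - 1, 2 * w - 1))
    for dr in range(-(h - 1), h):
        for dc in range(-(w - 1), w):
            total = 0.0
            for r in range(h):
                for c in range(w):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        total += a[r, c] * b[rr, cc]
            out[dr + h - 1, dc + w - 1] = total
    return out


def pairwise_overlap_free(centers, radii):
    """Brute-force check that disks (center, radius) never overlap."""
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dist = np.hypot(
                centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
            )
            if dist <= radii[i] + radii[j]:
                return False
    return True
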