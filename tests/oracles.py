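"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (pure-Python loops, explicit dense
double sums) that share no code with the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np


def moran_oracle(values2d: np.ndarray, mask: np.ndarray, k: int = 8) -> float:
    """Moran's I by exhaustive double sum with a dense row-standardized
    k-NN weight matrix.

    Neighbour ranking: squared Euclidean distance, ties broken by
    smaller (y, x). I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2.
    """
    coords = [(int(y), int(x)) for y, x in zip(*np.nonzero(np.asarray(mask, bool)))]
    n = len(coords)
    vals = [float(values2d[c]) for c in coords]
    kk = min(k, n - 1)

    w = [[0.0] * n for _ in range(n)]
    for i, (yi, xi) in enumerate(coords):
        ranked = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (
                (coords[j][0] - yi) ** 2 + (coords[j][1] - xi) ** 2,
                coords[j][0],
                coords[j][1],
            ),
        )
        for j in ranked[:kk]:
            w[i][j] = 1.0 / kk

    mean = sum(vals) / n
    z = [v - mean for v in vals]
    s0 = sum(sum(row) for row in w)
    num = sum(w[i][j] * z[i] * z[j] for i in range(n) for j in range(n))
    den = sum(zi * zi for zi in z)
    return (n / s0) * num / den


def gaussian_band_integral(amplitude: float, sigma: float) -> float:
    """Closed-form full integral of a Gaussian band."""
    return amplitude * sigma * np.sqrt(2.0 * np.pi)
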