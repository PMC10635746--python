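"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own computation paths: the GLCM
oracle counts pixel pairs with an explicit double loop, and the Dempster
combination oracle enumerates focal-element pairs as Python sets.
"""

from __future__ import annotations

import numpy as np

# offsets (drow, dcol) for the four standard GLCM angles at distance d,
# matching the convention that 0 deg pairs a pixel with its right neighbor
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(
    quantized: np.ndarray, levels: int, distance: int, angle: int,
    symmetric: bool = True, normalized: bool = True,
) -> np.ndarray:
    """Count co-occurring level pairs with an explicit double loop."""
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = quantized.shape
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                mat[quantized[r, c], quantized[r2, c2]] += 1
    if symmetric:
        mat = mat + mat.T
    if normalized and mat.sum() > 0:
        mat = mat / mat.sum()
    return mat


def _focal_sets(variant: str) -> list[frozenset]:
    if variant == "disjoint_singleton":
        return [frozenset({"B"}), frozenset({"M"}), frozenset({"I"})]
    return [frozenset({"B"}), frozenset({"M"}), frozenset({"B", "M"})]


def dempster_bruteforce(m1, m2, variant: str):
    """Set-based enumeration of Dempster's rule.

    Returns (combined_masses: length-3 array, k: float) or None at total
    conflict.  ``m1``/``m2`` are length-3 arrays over (benign, malignant,
    ignorance) in the same order as the package's MassFunction.
    """
    sets = _focal_sets(variant)
    acc = {s: 0.0 for s in sets}
    k = 0.0
    for a, wa in zip(sets, m1):
        for b, wb in zip(sets, m2):
            inter = a & b
            if not inter:
                k += wa * wb
            else:
                acc[inter] += wa * wb
    if 1.0 - k <= 1e-12:
        return None
    combined = np.array([acc[s] for s in sets]) / (1.0 - k)
    return combined, k
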