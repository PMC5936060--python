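"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive re-implementations (pure-Python
loops) used to validate the vectorized library code; they must stay
independent of the package internals.
"""

from __future__ import annotations

import numpy as np
import pytest

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_find_cuts(bases: str, site: str, cut_offset: int) -> list[int]:
    """Sliding-window site scan; N in the sequence matches nothing."""
    cuts = set()
    for start in range(len(bases) - len(site) + 1):
        window = bases[start : start + len(site)]
        if all(b in IUPAC[c] for c, b in zip(site, window)):
            cuts.add(start + cut_offset)
    return sorted(cuts)


def oracle_point_in_polygon(x: float, y: float, verts) -> bool:
    """Even-odd rule by explicit ray casting (per-point loop)."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x > x_cross:
                inside = not inside
    return inside


def oracle_mask(verts, height: int, width: int) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            mask[r, c] = oracle_point_in_polygon(c + 0.5, r + 0.5, verts)
    return mask


def oracle_masked_mean(img: np.ndarray, verts) -> float:
    """Explicit masked-pixel loop mean."""
    total, count = 0.0, 0
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            if oracle_point_in_polygon(c + 0.5, r + 0.5, verts):
                total += float(img[r, c])
                count += 1
    return total / count


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int, with_n: bool = False) -> str:
    alphabet = list("ACGTN" if with_n else "ACGT")
    return "".join(rng.choice(alphabet, size=n))
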