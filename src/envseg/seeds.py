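"""Per-plane seed detection on the envelope signal.

Tracing starts from points of maximum fluorescence, found with a
Difference-of-Gaussian band-pass followed by strict local-maximum
detection.  Seeding is strictly per plane; the detector is deterministic,
including on plateaus of equal values (the lexicographically smallest
``(y, x)`` pixel of a plateau is reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .ridge import gaussian_smooth

__all__ = ["SeedPoint", "dog_filter", "detect_maxima", "seeds_to_tsv"]


@dataclass(frozen=True)
class SeedPoint:
    """A tracing start point: ``position`` is ``(x, y)`` px in plane
    ``plane_index``; ``score`` is the DoG response there."""

    position: tuple[int, int]
    plane_index: int
    score: float


def dog_filter(plane: np.ndarray, sigma_small: float, sigma_large: float) -> np.ndarray:
    """Difference of two Gaussian blurs, ``G(s1)*I - G(s2)*I``."""
    if not 0 < sigma_small < sigma_large:
        raise ValueError("need 0 < sigma_small < sigma_large")
    p = np.asarray(plane, dtype=np.float64)
    return gaussian_smooth(p, sigma_small) - gaussian_smooth(p, sigma_large)


def detect_maxima(dog_plane: np.ndarray, threshold: float,
                  min_separation: float = 0.0, plane_index: int = 0) -> list[SeedPoint]:
    """Strict 8-neighbourhood local maxima with score >= threshold.

    A plateau of equal maxima contributes its lexicographically smallest
    ``(y, x)`` pixel.  When ``min_separation > 0`` the list is thinned
    greedily by descending score so no two returned seeds are closer than
    that distance.  The result is sorted by descending score (ties by
    ``(y, x)``).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    p = np.asarray(dog_plane, dtype=np.float64)
    if p.size == 0:
        return []
    maxf = ndi.maximum_filter(p, size=3, mode="reflect")
    cand = (p >= threshold) & (p == maxf)
    if not cand.any():
        return []
    # group plateau candidates (adjacent candidates always share a value)
    lab, n = ndi.label(cand, structure=np.ones((3, 3), dtype=bool))
    points: list[tuple[float, int, int]] = []  # (score, y, x)
    for comp in range(1, n + 1):
        ys, xs = np.nonzero(lab == comp)
        value = p[ys[0], xs[0]]
        # strict maximum: every pixel outside the plateau that touches it
        # must be strictly smaller; a plateau with no exterior (e.g. a
        # constant plane) is not a maximum
        strict = True
        has_exterior = False
        for y, x in zip(ys, xs):
            y0, y1 = max(0, y - 1), min(p.shape[0], y + 2)
            x0, x1 = max(0, x - 1), min(p.shape[1], x + 2)
            window = p[y0:y1, x0:x1]
            wl = lab[y0:y1, x0:x1]
            outside = window[wl != comp]
            if outside.size:
                has_exterior = True
                if outside.max() >= value:
                    strict = False
                    break
        if not strict or not has_exterior:
            continue
        order = np.lexsort((xs, ys))  # smallest (y, x)
        points.append((float(value), int(ys[order[0]]), int(xs[order[0]])))

    points.sort(key=lambda t: (-t[0], t[1], t[2]))
    if min_separation > 0:
        kept: list[tuple[float, int, int]] = []
        d2 = min_separation * min_separation
        for s, y, x in points:
            if all((y - ky) ** 2 + (x - kx) ** 2 >= d2 for _, ky, kx in kept):
                kept.append((s, y, x))
        points = kept
    return [SeedPoint(position=(x, y), plane_index=plane_index, score=s)
            for s, y, x in points]


def seeds_to_tsv(seeds, path):
    """Export a seed list as TSV (x, y, z, score) for inspection."""
    import pandas as pd

    df = pd.DataFrame([{"x": s.position[0], "y": s.position[1],
                        "z": s.plane_index, "score": s.score}
                       for s in seeds])
    df.to_csv(path, sep="\t", index=False)
    return path
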