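"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's own abstractions: connected
components are found by breadth-first flood fill, per-frame FAI values by a
monolithic scalar routine over raw index ranges, and variances by a direct
mean/sum-of-squares loop.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


def flood_fill_regions(grid: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of True cells via BFS, as sets of (r, c)."""
    grid = np.asarray(grid, dtype=bool)
    h, w = grid.shape
    seen = np.zeros_like(grid, dtype=bool)
    regions = []
    for r0 in range(h):
        for c0 in range(w):
            if not grid[r0, c0] or seen[r0, c0]:
                continue
            component = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                component.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h
                            and 0 <= cc < w
                            and grid[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            regions.append(component)
    return regions


def frame_fai_oracle(pixels: np.ndarray) -> tuple[float, float, float, float]:
    """Monolithic re-computation of the four quadrant FAI values.

    Works directly on index ranges of the full frame and the BFS flood fill;
    never touches the package's quadrant/region abstractions.
    """
    pixels = np.asarray(pixels, dtype=bool)
    h, w = pixels.shape
    rm, cm = (h + 1) // 2, (w + 1) // 2
    bounds = [
        (0, rm, 0, cm),
        (0, rm, cm, w),
        (rm, h, 0, cm),
        (rm, h, cm, w),
    ]
    fais = []
    for r0, r1, c0, c1 in bounds:
        sub = pixels[r0:r1, c0:c1]
        total = (r1 - r0) * (c1 - c0)
        fish = int(sub.sum())
        regions = flood_fill_regions(sub)
        biggest = max((len(reg) for reg in regions), default=0)
        fais.append(100.0 * fish / total + 100.0 * biggest / total)
    return tuple(fais)


def population_mean_var(values) -> tuple[float, float]:
    """Textbook population mean and variance via explicit sums."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    return mean, var


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20241130)


def random_mask(rng: np.random.Generator, max_side: int = 32) -> np.ndarray:
    """A random boolean grid with random density, 2..max_side per side."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    density = float(rng.uniform(0.05, 0.9))
    return rng.random((h, w)) < density
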