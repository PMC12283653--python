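"""Independent brute-force oracles used to validate the geometry code.

These deliberately avoid the closed-form formulas in :mod:`crownprof.competition`:
overlap areas are estimated by Monte-Carlo sampling, and Voronoi adjacency by
nearest-stem labelling of a dense grid.  They are slower but conceptually
trivial, which is what makes them useful as cross-checks.
"""

from __future__ import annotations

import numpy as np


def mc_overlap_area(
    r1: float, r2: float, d: float, n_samples: int = 10_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the overlap area of two discs.

    Samples uniformly inside the smaller disc and counts the fraction that
    also falls inside the larger one; the estimate is that fraction times the
    smaller disc's area.  Standard error ~ area * sqrt((1-p)/(p*n)).
    """
    rng = np.random.default_rng(seed)
    rmin, rmax = min(r1, r2), max(r1, r2)
    if rmin <= 0 or d >= r1 + r2:
        return 0.0
    inside = 0
    remaining = n_samples
    chunk = 2_000_000
    while remaining > 0:
        m = min(chunk, remaining)
        rad = rmin * np.sqrt(rng.random(m))
        theta = rng.random(m) * 2 * np.pi
        x = rad * np.cos(theta)
        y = rad * np.sin(theta)
        # the larger disc is centred at (d, 0) relative to the smaller one
        inside += int(np.count_nonzero((x - d) ** 2 + y**2 <= rmax**2))
        remaining -= m
    return np.pi * rmin**2 * inside / n_samples


def grid_voronoi_adjacency(
    positions: dict[str, tuple[float, float]],
    plot_radius: float,
    n_grid: int = 400,
) -> tuple[set[tuple[str, str]], float]:
    """Brute-force Voronoi adjacency by nearest-stem labelling of a dense grid.

    Every grid point inside the plot circle is labelled with its closest stem;
    two stems are adjacent when their labels touch (4-neighbourhood) in at
    least two places, which filters single corner contacts.  Returns the set
    of unordered adjacent pairs and the grid spacing (the oracle cannot
    resolve shared edges shorter than about one cell).
    """
    ids = list(positions)
    pts = np.array([positions[i] for i in ids])
    xs = np.linspace(-plot_radius, plot_radius, n_grid)
    spacing = xs[1] - xs[0]
    gx, gy = np.meshgrid(xs, xs)
    inside = gx**2 + gy**2 <= plot_radius**2
    d2 = (gx[..., None] - pts[:, 0]) ** 2 + (gy[..., None] - pts[:, 1]) ** 2
    label = np.argmin(d2, axis=2)
    label[~inside] = -1

    counts: dict[tuple[int, int], int] = {}
    for a, b in [(label[:, :-1], label[:, 1:]), (label[:-1, :], label[1:, :])]:
        touch = (a != b) & (a >= 0) & (b >= 0)
        for i, j in zip(a[touch].ravel(), b[touch].ravel()):
            key = (min(i, j), max(i, j))
            counts[key] = counts.get(key, 0) + 1
    pairs = {
        tuple(sorted((ids[i], ids[j])))
        for (i, j), c in counts.items() if c >= 2
    }
    return pairs, float(spacing)
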