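"""Regularise measured crown radii onto the uniform 11-point relative-height grid.

Field crews record the crown radius at four relative crown heights
(RCH = 0.25, 0.5, 0.75, 1.0, depth below the treetop over largest crown
length).  With the known zero-radius anchor at the tree top (RCH = 0) the
five knots are interpolated with shape-preserving piecewise cubic Hermite
polynomials (PCHIP), which pass through the knots exactly, stay monotone on
monotone data segments and never overshoot local extrema — the properties
that make them preferable to Lagrange/Newton/cubic-spline interpolation for
crown profiles.  The result is radii CR_0..CR_10 on the grid
RCH = 0.0, 0.1, ..., 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

log = logging.getLogger(__name__)

#: the uniform relative-crown-height grid (11 layers, spacing 0.1)
RCH_GRID = np.round(np.linspace(0.0, 1.0, 11), 10)
N_LAYERS = 10  # layers k = 1..10 carry nonzero depth; layer 0 is the treetop anchor

MEAN = "MEAN"


@dataclass
class CrownProfile:
    """Radii of one tree in one direction (or the directional MEAN) on the grid."""

    tree_id: str
    direction: str
    radii: np.ndarray  # shape (11,), metres, radii[0] == 0

    @property
    def grid(self) -> np.ndarray:
        return RCH_GRID

    def heights(self, lcl: float) -> np.ndarray:
        """Crown heights from the treetop, CH_k = RCH_k * LCL (m)."""
        return RCH_GRID * lcl


def interpolate_profile(
    measured: list[tuple[float, float]],
    tree_id: str = "",
    direction: str = "",
    include_top_zero: bool = True,
) -> CrownProfile:
    """PCHIP-interpolate measured (RCH, CR) pairs onto the 11-point grid.

    Parameters
    ----------
    measured
        Four (RCH, CR) pairs with strictly increasing RCH in (0, 1].
    include_top_zero
        Prepend the treetop anchor (RCH=0, CR=0).  On by default; the grid
        always starts at RCH=0, so disabling it is only sensible when the
        caller supplies its own RCH=0 knot.
    """
    pts = sorted(measured)
    if len(pts) < 4:
        raise ValueError(f"need at least 4 measured pairs, got {len(pts)}")
    rch = np.array([p[0] for p in pts], dtype=float)
    cr = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(rch) <= 0):
        raise ValueError("duplicate or non-increasing RCH values")
    if np.any(cr < 0):
        raise ValueError("negative crown radius")
    if rch[0] <= 0 and include_top_zero:
        raise ValueError("measured RCH must be > 0 when the top anchor is added")
    if rch[-1] > 1.0:
        raise ValueError("RCH beyond 1.0 should have been filtered out")

    if include_top_zero:
        rch = np.concatenate(([0.0], rch))
        cr = np.concatenate(([0.0], cr))

    interp = PchipInterpolator(rch, cr, extrapolate=False)
    grid = np.clip(RCH_GRID, rch[0], rch[-1])  # bottom knot may sit above RCH=1
    radii = interp(grid)
    if np.any(radii < 0):
        log.warning("PCHIP produced negative radii for tree %s %s; clipping at 0",
                    tree_id, direction)
        radii = np.maximum(radii, 0.0)
    return CrownProfile(tree_id=tree_id, direction=direction, radii=radii)


def mean_profile(profiles: list[CrownProfile]) -> CrownProfile:
    """Arithmetic mean of the four directional profiles, layer by layer."""
    if len(profiles) != 4:
        raise ValueError(f"expected 4 directional profiles, got {len(profiles)}")
    tree_ids = {p.tree_id for p in profiles}
    if len(tree_ids) != 1:
        raise ValueError(f"profiles belong to different trees: {tree_ids}")
    shapes = {p.radii.shape for p in profiles}
    if shapes != {(11,)}:
        raise ValueError("mismatched profile grids")
    radii = np.mean([p.radii for p in profiles], axis=0)
    return CrownProfile(tree_id=profiles[0].tree_id, direction=MEAN, radii=radii)
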