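"""Layered, direction-aware crown competition: Voronoi competitor units,
circle-overlap geometry and the Crown Profile Competition Index (CPCI).

Competitors of a subject tree are the trees whose Voronoi cells share an
edge of positive length with the subject's cell, after clipping all cells to
the circular plot boundary.  Crowns at each interpolated layer are treated
as horizontal discs centred on the stem; two layers compete only when their
crown heights from the treetop differ by at most 2 m (the layer gate).  The
pairwise disc overlap has three regimes — disjoint, lens (partial overlap)
and complete containment — and the layer-wise total overlap, weighted by the
competitor/subject size ratio and normalised by the subject's disc area,
yields CPCI per layer.  A directional allocation splits each layer's CPCI
across the four cardinal directions, giving smaller shares to directions
where the subject's own radius is larger (less suppressed growth).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import QhullError, Voronoi
from shapely.geometry import MultiPoint, Point
from shapely.ops import voronoi_diagram

from .profile_interp import CrownProfile
from .stand_io import DIRECTIONS, DerivedVars, PlotRecord

log = logging.getLogger(__name__)

#: vertical layer gate: crown layers compete when |CH_ik - CH_jt| <= 2 m
GATE_DELTA_CH_M = 2.0

#: tolerance for classifying the overlap regime at its boundaries (m)
_REGIME_TOL = 1e-12

#: minimum shared Voronoi edge length to count as adjacency (m)
_EDGE_TOL = 1e-9


@dataclass
class CompetitorSet:
    subject_id: str
    competitor_ids: set[str]
    cell_polygon: np.ndarray  # (n_vertices, 2) of the clipped Voronoi cell


@dataclass
class CompetitionTable:
    """Per-subject layered competition summary (layers k = 1..10)."""

    subject_id: str
    ao: np.ndarray          # (10,) total overlap area AO_i(k), m²
    z: np.ndarray           # (10,) subject disc area Z_ik = pi*CR_ik², m²
    cpci: np.ndarray        # (10,) CPCI_k, dimensionless
    directional: dict[str, np.ndarray] = field(default_factory=dict)  # dir -> (10,)


class DegenerateGeometryError(ValueError):
    """Fewer than 3 stems or all stems collinear: no Voronoi diagram exists."""


# ---------------------------------------------------------------------------
# Voronoi competitor units
# ---------------------------------------------------------------------------

def voronoi_neighbors(
    positions: dict[str, tuple[float, float]],
    plot_radius: float,
    center: tuple[float, float] = (0.0, 0.0),
) -> dict[str, CompetitorSet]:
    """Voronoi-adjacency competitor sets, cells clipped to the plot circle.

    Falls back to "all other trees are neighbours" (with a warning) when the
    configuration is degenerate (< 3 stems or collinear stems).
    """
    ids = list(positions)
    pts = np.array([positions[i] for i in ids], dtype=float)
    n = len(ids)
    try:
        if n < 3:
            raise DegenerateGeometryError(f"need >= 3 stems, got {n}")
        vor = Voronoi(pts)
    except (QhullError, DegenerateGeometryError) as exc:
        log.warning("degenerate stem geometry (%s); using all-pairs neighbours", exc)
        poly = _plot_circle(plot_radius, center)
        ring = np.asarray(poly.exterior.coords)
        return {
            i: CompetitorSet(i, set(ids) - {i}, ring) for i in ids
        }

    circle = _plot_circle(plot_radius, center, pts)
    cells = _clipped_cells(pts, circle)

    neighbors: dict[str, set[str]] = {i: set() for i in ids}
    for (a, b) in vor.ridge_points:
        shared = cells[a].intersection(cells[b])
        if shared.length > _EDGE_TOL:
            neighbors[ids[a]].add(ids[b])
            neighbors[ids[b]].add(ids[a])

    out = {}
    for idx, i in enumerate(ids):
        ring = np.asarray(cells[idx].exterior.coords) if not cells[idx].is_empty else np.empty((0, 2))
        out[i] = CompetitorSet(i, neighbors[i], ring)
    return out


def _plot_circle(radius: float, center: tuple[float, float], pts: np.ndarray | None = None):
    if not math.isfinite(radius) or radius <= 0:
        if pts is None:
            raise ValueError(f"invalid plot radius {radius}")
        c = pts.mean(axis=0)
        radius = float(np.max(np.hypot(*(pts - c).T))) * 1.1 + 1.0
        center = tuple(c)
        log.warning("no finite plot radius; clipping cells to an enclosing circle r=%.1f", radius)
    return Point(center).buffer(radius, quad_segs=128)


def _clipped_cells(pts: np.ndarray, circle):
    """Voronoi cell polygon of each input point, clipped to the plot circle."""
    envelope = circle.buffer(1.0).envelope
    diagram = voronoi_diagram(MultiPoint(pts.tolist()), envelope=envelope)
    cells = [None] * len(pts)
    polys = list(diagram.geoms)
    for poly in polys:
        # a Voronoi cell contains exactly its generating point
        dists = [poly.distance(Point(p)) for p in pts]
        owner = int(np.argmin(dists))
        cells[owner] = poly.intersection(circle)
    for k, c in enumerate(cells):
        if c is None:  # pragma: no cover - safety net
            cells[k] = Point(pts[k]).buffer(1e-6)
    return cells


# ---------------------------------------------------------------------------
# Layer gate and disc-overlap geometry
# ---------------------------------------------------------------------------

def layer_gate(ch_ik: float, ch_jt: float, threshold: float = GATE_DELTA_CH_M) -> bool:
    """True when two crown layers are close enough vertically to compete."""
    if ch_ik < 0 or ch_jt < 0:
        raise ValueError("crown heights must be non-negative")
    return abs(ch_ik - ch_jt) <= threshold


def pair_overlap_area(cr_ik: float, cr_jt: float, dist: float) -> float:
    """Overlap area (m²) of two crown discs with radii ``cr_ik``, ``cr_jt``
    whose stems are ``dist`` apart.

    Three regimes: disjoint (zero), partial overlap (circular lens: the two
    circular-segment terms minus twice the Heron triangle area) and complete
    containment (area of the smaller disc).
    """
    if cr_ik < 0 or cr_jt < 0 or dist < 0:
        raise ValueError("radii and distance must be non-negative")
    return float(_overlap_area_vec(np.array(cr_ik), np.array(cr_jt), np.array(dist)))


def _overlap_area_vec(r1: np.ndarray, r2: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorised disc-overlap area; inputs broadcast together."""
    r1, r2, d = np.broadcast_arrays(np.asarray(r1, float), np.asarray(r2, float),
                                    np.asarray(d, float))
    out = np.zeros(r1.shape)
    rmin = np.minimum(r1, r2)
    contained = d <= np.abs(r1 - r2) + _REGIME_TOL
    disjoint = d >= r1 + r2 - _REGIME_TOL
    lens = ~contained & ~disjoint

    out[contained] = np.pi * rmin[contained] ** 2

    if np.any(lens):
        a, b, dd = r1[lens], r2[lens], d[lens]
        cos1 = np.clip((a**2 + dd**2 - b**2) / (2 * dd * a), -1.0, 1.0)
        cos2 = np.clip((b**2 + dd**2 - a**2) / (2 * dd * b), -1.0, 1.0)
        p = (a + b + dd) / 2
        heron = np.sqrt(np.maximum(p * (p - a) * (p - b) * (p - dd), 0.0))
        area = np.arccos(cos1) * a**2 + np.arccos(cos2) * b**2 - 2 * heron
        # cancellation near degenerate configurations (e.g. one radius ~ 0)
        # can leave an O(1e-9) negative residue; clamp to the true bounds
        out[lens] = np.clip(area, 0.0, np.pi * rmin[lens] ** 2)
    return out


def total_overlap(
    subject_radii: np.ndarray,
    subject_heights: np.ndarray,
    competitors: list[tuple[np.ndarray, np.ndarray, float]],
    k: int,
) -> float:
    """Total overlap AO_i(k): sum over competitors j and layers t of the
    gated disc-overlap areas.

    ``subject_radii``/``subject_heights`` are the 11-point layer arrays
    (index 0 = treetop); each competitor is (radii, heights, stem distance).
    Layers with zero competitor radius contribute nothing.
    """
    if not 1 <= k <= 10:
        raise ValueError(f"layer k must be in 1..10, got {k}")
    ao = 0.0
    ch_ik = subject_heights[k]
    cr_ik = subject_radii[k]
    for radii_j, heights_j, dist in competitors:
        for t in range(1, 11):
            if radii_j[t] <= 0:
                continue
            if layer_gate(ch_ik, heights_j[t]):
                ao += pair_overlap_area(cr_ik, radii_j[t], dist)
    return ao


# ---------------------------------------------------------------------------
# CPCI
# ---------------------------------------------------------------------------

def cpci_layers(
    subject_radii: np.ndarray,
    subject_heights: np.ndarray,
    competitors: list[tuple[np.ndarray, np.ndarray, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CPCI for all 10 layers of one subject tree.

    Returns (ao, z, cpci), each of shape (10,) for layers k = 1..10.
    The size ratio (CH_jt*CR_jt)/(CH_ik*CR_ik) weights every gated pair term
    inside the double sum, and the total is normalised by the subject's disc
    area Z_ik = pi*CR_ik².  Layers with CR_ik = 0 have CPCI 0 by definition.
    """
    cr_i = np.asarray(subject_radii, float)[1:]      # (10,)
    ch_i = np.asarray(subject_heights, float)[1:]    # (10,)
    ao = np.zeros(10)
    weighted = np.zeros(10)
    for radii_j, heights_j, dist in competitors:
        cr_j = np.asarray(radii_j, float)[1:]
        ch_j = np.asarray(heights_j, float)[1:]
        gate = np.abs(ch_i[:, None] - ch_j[None, :]) <= GATE_DELTA_CH_M
        active = gate & (cr_j[None, :] > 0)
        if not np.any(active):
            continue
        ov = _overlap_area_vec(cr_i[:, None], cr_j[None, :], np.asarray(dist))
        ov = np.where(active, ov, 0.0)
        ao += ov.sum(axis=1)
        size = ch_j[None, :] * cr_j[None, :]
        denom = ch_i[:, None] * cr_i[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, size / np.where(denom > 0, denom, 1.0), 0.0)
        weighted += (ov * ratio).sum(axis=1)

    z = np.pi * cr_i**2
    cpci = np.zeros(10)
    ok = cr_i > 0
    cpci[ok] = weighted[ok] / z[ok]
    if np.any(~ok & (ao > 0)):
        log.debug("subject layer with zero radius but positive overlap; CPCI set to 0")
    return ao, z, cpci


def directional_cpci(
    cpci_k: float, radii_by_direction: dict[str, float]
) -> dict[str, float]:
    """Allocate one layer's CPCI across the four cardinal directions.

    Each direction receives CPCI_k * (1 - CR_dir / sum(CR_dir)); larger own
    radii mean less competitive suppression, hence a smaller share.  The four
    shares sum to 3*CPCI_k.  All shares are zero when every radius is zero.
    """
    radii = np.array([radii_by_direction[d] for d in DIRECTIONS], dtype=float)
    if np.any(radii < 0):
        raise ValueError("negative directional radius")
    total = radii.sum()
    if total == 0:
        return {d: 0.0 for d in DIRECTIONS}
    shares = cpci_k * (1.0 - radii / total)
    return dict(zip(DIRECTIONS, shares.tolist()))


# ---------------------------------------------------------------------------
# Plot-level driver
# ---------------------------------------------------------------------------

def compute_competition(
    plot: PlotRecord,
    mean_profiles: dict[str, CrownProfile],
    directional_profiles: dict[str, dict[str, CrownProfile]],
    derived: dict[str, DerivedVars],
    neighbors: dict[str, CompetitorSet] | None = None,
) -> dict[str, CompetitionTable]:
    """CPCI tables for every tree of a plot.

    Geometry (overlap, CPCI_k) uses the directional-MEAN profiles; the
    directional variants then allocate each layer's CPCI_k across E/W/S/N
    using the subject's own directional radii at that layer.
    """
    positions = {t.tree_id: (t.x, t.y) for t in plot.trees}
    if neighbors is None:
        neighbors = voronoi_neighbors(positions, plot.radius_m)

    layer_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in plot.trees:
        prof = mean_profiles[t.tree_id]
        heights = prof.heights(derived[t.tree_id].lcl)
        layer_data[t.tree_id] = (prof.radii, heights)

    tables: dict[str, CompetitionTable] = {}
    for t in plot.trees:
        comp = []
        for j in neighbors[t.tree_id].competitor_ids:
            radii_j, heights_j = layer_data[j]
            dist = math.hypot(t.x - positions[j][0], t.y - positions[j][1])
            comp.append((radii_j, heights_j, dist))
        radii_i, heights_i = layer_data[t.tree_id]
        ao, z, cpci = cpci_layers(radii_i, heights_i, comp)

        directional: dict[str, np.ndarray] = {d: np.zeros(10) for d in DIRECTIONS}
        dirs = directional_profiles.get(t.tree_id, {})
        if len(dirs) == 4:
            for k in range(1, 11):
                shares = directional_cpci(
                    float(cpci[k - 1]),
                    {d: float(dirs[d].radii[k]) for d in DIRECTIONS},
                )
                for d in DIRECTIONS:
                    directional[d][k - 1] = shares[d]
        tables[t.tree_id] = CompetitionTable(
            subject_id=t.tree_id, ao=ao, z=z, cpci=cpci, directional=directional
        )
    return tables
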