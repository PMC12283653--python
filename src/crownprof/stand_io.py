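"""Tree/plot data model, delimited-file I/O, quality filters and derived stand variables.

The data model mirrors a standard individual-tree crown survey: each tree carries
its stem position inside a circular plot, the usual dendrometric variables
(DBH, total height TH, height to crown base HCB, height of maximum crown width
HCW, crown width CW, age) and crown radii measured in the four cardinal
directions at a small set of relative crown heights (RCH, measured as depth
below the tree top divided by the largest crown length).

File formats are plain CSV (UTF-8, header row, '.' decimal separator):

``plots.csv``   plot_id,radius_m,slope_deg,aspect
``trees.csv``   plot_id,tree_id,x,y,dbh_cm,th_m,hcb_m,hcw_m,cw_m,age_yr
``radii.csv``   plot_id,tree_id,direction,rch,cr_m     (long format, direction in E/W/S/N)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

DIRECTIONS = ("E", "W", "S", "N")

#: minimum diameter at breast height admitted by the measurement protocol (cm)
MIN_DBH_CM = 5.0

TREE_COLUMNS = [
    "plot_id", "tree_id", "x", "y", "dbh_cm", "th_m", "hcb_m", "hcw_m", "cw_m", "age_yr",
]
RADII_COLUMNS = ["plot_id", "tree_id", "direction", "rch", "cr_m"]
PLOT_COLUMNS = ["plot_id", "radius_m", "slope_deg", "aspect"]


class SchemaError(ValueError):
    """A mandatory column is missing or a file cannot be understood at all."""


class RowError(ValueError):
    """A row holds a non-numeric or otherwise unusable measurement."""


class InvalidTreeError(ValueError):
    """A tree violates a hard geometric invariant (e.g. TH <= HCB)."""


@dataclass
class TreeRecord:
    """One measured tree.

    ``raw_radii`` maps direction -> list of (RCH, CR) pairs, RCH in (0, 1],
    CR in metres.  HCW may be NaN (it is not needed by the competition index
    and is imputed as the plot mean when used as a model feature).
    """

    tree_id: str
    plot_id: str
    x: float
    y: float
    dbh: float
    th: float
    hcb: float
    hcw: float
    cw: float
    age: float
    raw_radii: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


@dataclass
class PlotRecord:
    plot_id: str
    radius_m: float
    slope_deg: float = 0.0
    aspect: str = "flat"
    trees: list[TreeRecord] = field(default_factory=list)

    @property
    def area_ha(self) -> float:
        return math.pi * self.radius_m**2 / 10_000.0


@dataclass
class DerivedVars:
    """Per-tree derived variables.

    LCL   largest crown length, TH - HCB (m)
    CLR   crown length ratio, LCL / TH
    TSC   tree slenderness, TH (m) / DBH (cm)
    BA    stand basal area (m²/ha), same value for every tree in a plot
    SDI   Reineke stand density index (trees/ha at reference diameter 25 cm)
    """

    lcl: float
    clr: float
    tsc: float
    ba: float
    sdi: float

    def ch_at_layer(self, k: int) -> float:
        """Crown height from the treetop at interpolated layer k (k = 0..10)."""
        return 0.1 * k * self.lcl


@dataclass
class RejectedTree:
    tree: TreeRecord
    reason: str


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _numeric(df: pd.DataFrame, cols: Iterable[str], path: str) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = pd.to_numeric(out[c], errors="coerce")
        bad = out.index[out[c].isna() & df[c].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 0-base
            raise RowError(f"{path}: non-numeric value in column '{c}' (file row(s) {rows})")
    return out


def read_tree_table(
    trees_path: str | Path,
    radii_path: str | Path,
    plots_path: str | Path | None = None,
    sep: str = ",",
) -> list[PlotRecord]:
    """Read the three-file survey schema into a list of :class:`PlotRecord`.

    Malformed rows raise :class:`RowError` with the offending file rows;
    missing columns raise :class:`SchemaError`.  No quality filtering happens
    here — see :func:`apply_filters`.
    """
    trees = pd.read_csv(trees_path, sep=sep, dtype={"plot_id": str, "tree_id": str})
    _require_columns(trees, TREE_COLUMNS, str(trees_path))
    trees = _numeric(trees, TREE_COLUMNS[2:], str(trees_path))

    radii = pd.read_csv(radii_path, sep=sep, dtype={"plot_id": str, "tree_id": str})
    _require_columns(radii, RADII_COLUMNS, str(radii_path))
    radii = _numeric(radii, ["rch", "cr_m"], str(radii_path))
    bad_dir = ~radii["direction"].isin(DIRECTIONS)
    if bad_dir.any():
        rows = ", ".join(str(i + 2) for i in radii.index[bad_dir][:5])
        raise RowError(f"{radii_path}: direction not in {DIRECTIONS} (file row(s) {rows})")

    if plots_path is not None:
        plots = pd.read_csv(plots_path, sep=sep, dtype={"plot_id": str})
        _require_columns(plots, PLOT_COLUMNS, str(plots_path))
        plots = _numeric(plots, ["radius_m", "slope_deg"], str(plots_path))
        plot_meta = {
            r.plot_id: (float(r.radius_m), float(r.slope_deg), str(r.aspect))
            for r in plots.itertuples()
        }
    else:
        plot_meta = {}

    radii_by_tree: dict[tuple[str, str], dict[str, list[tuple[float, float]]]] = {}
    for r in radii.itertuples():
        key = (r.plot_id, r.tree_id)
        radii_by_tree.setdefault(key, {d: [] for d in DIRECTIONS})
        radii_by_tree[key][r.direction].append((float(r.rch), float(r.cr_m)))

    plot_records: dict[str, PlotRecord] = {}
    for row in trees.itertuples():
        pid = row.plot_id
        if pid not in plot_records:
            radius, slope, aspect = plot_meta.get(pid, (math.inf, 0.0, "flat"))
            plot_records[pid] = PlotRecord(pid, radius, slope, aspect)
        raw = radii_by_tree.get((pid, row.tree_id), {d: [] for d in DIRECTIONS})
        raw = {d: sorted(v) for d, v in raw.items()}
        plot_records[pid].trees.append(
            TreeRecord(
                tree_id=row.tree_id, plot_id=pid,
                x=float(row.x), y=float(row.y),
                dbh=float(row.dbh_cm), th=float(row.th_m), hcb=float(row.hcb_m),
                hcw=float(row.hcw_m), cw=float(row.cw_m), age=float(row.age_yr),
                raw_radii=raw,
            )
        )
    return list(plot_records.values())


def write_tree_table(
    plots: list[PlotRecord],
    trees_path: str | Path,
    radii_path: str | Path,
    plots_path: str | Path | None = None,
) -> None:
    """Inverse of :func:`read_tree_table` (round-trips well-formed data)."""
    tree_rows, radii_rows, plot_rows = [], [], []
    for plot in plots:
        plot_rows.append(
            dict(plot_id=plot.plot_id, radius_m=plot.radius_m,
                 slope_deg=plot.slope_deg, aspect=plot.aspect)
        )
        for t in plot.trees:
            tree_rows.append(
                dict(plot_id=t.plot_id, tree_id=t.tree_id, x=t.x, y=t.y,
                     dbh_cm=t.dbh, th_m=t.th, hcb_m=t.hcb, hcw_m=t.hcw,
                     cw_m=t.cw, age_yr=t.age)
            )
            for d in DIRECTIONS:
                for rch, cr in t.raw_radii.get(d, []):
                    radii_rows.append(
                        dict(plot_id=t.plot_id, tree_id=t.tree_id,
                             direction=d, rch=rch, cr_m=cr)
                    )
    pd.DataFrame(tree_rows, columns=TREE_COLUMNS).to_csv(trees_path, index=False)
    pd.DataFrame(radii_rows, columns=RADII_COLUMNS).to_csv(radii_path, index=False)
    if plots_path is not None:
        pd.DataFrame(plot_rows, columns=PLOT_COLUMNS).to_csv(plots_path, index=False)


def apply_filters(trees: list[TreeRecord]) -> tuple[list[TreeRecord], list[RejectedTree]]:
    """Quality screen for directional crown-radius records.

    A tree is kept only if, in every cardinal direction, it has exactly four
    valid (RCH, CR) pairs with RCH <= 1.0 and CR >= 0 and DBH >= 5 cm.
    Rejections carry a reason code: ``rch_gt_1``, ``lt_4_radii``,
    ``negative_radius``, ``dbh_lt_5``, ``bad_heights``.
    """
    kept: list[TreeRecord] = []
    rejected: list[RejectedTree] = []
    for t in trees:
        reason = None
        if t.dbh < MIN_DBH_CM:
            reason = "dbh_lt_5"
        elif not (0 < t.hcb < t.th):
            reason = "bad_heights"
        else:
            for d in DIRECTIONS:
                pairs = t.raw_radii.get(d, [])
                if any(rch > 1.0 for rch, _ in pairs):
                    reason = "rch_gt_1"
                    break
                if any(cr < 0 for _, cr in pairs):
                    reason = "negative_radius"
                    break
                if len(pairs) < 4:
                    reason = "lt_4_radii"
                    break
        if reason is None:
            kept.append(t)
        else:
            rejected.append(RejectedTree(t, reason))
    return kept, rejected


def derive_variables(plot: PlotRecord) -> dict[str, DerivedVars]:
    """Per-tree derived variables plus the plot-level density terms.

    BA is total basal area scaled to per-hectare by the circular plot area;
    SDI is Reineke's index N_ha * (Dg/25)**1.605 with Dg the quadratic mean
    DBH.  Both are stand-level values repeated on every tree of the plot.
    """
    if not plot.trees:
        return {}
    if not math.isfinite(plot.radius_m) or plot.radius_m <= 0:
        raise InvalidTreeError(f"plot {plot.plot_id}: invalid radius {plot.radius_m}")
    area_ha = plot.area_ha
    dbh = np.array([t.dbh for t in plot.trees], dtype=float)
    ba = float(np.sum(np.pi * (dbh / 200.0) ** 2) / area_ha)
    n_ha = len(plot.trees) / area_ha
    dg = float(np.sqrt(np.mean(dbh**2)))
    sdi = float(n_ha * (dg / 25.0) ** 1.605)

    out: dict[str, DerivedVars] = {}
    for t in plot.trees:
        if t.th <= t.hcb:
            raise InvalidTreeError(
                f"tree {t.tree_id}: TH ({t.th}) must exceed HCB ({t.hcb})"
            )
        lcl = t.th - t.hcb
        out[t.tree_id] = DerivedVars(
            lcl=lcl, clr=lcl / t.th, tsc=t.th / t.dbh, ba=ba, sdi=sdi
        )
    return out
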