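"""Assemble per-tree 10-step feature sequences, min-max normalise, split 8:1:1.

Each tree (or tree x direction) becomes an ordered sequence over the crown
layers k = 1..10 (top to base by default).  The per-step feature vector holds
the 14 predictors: AGE, DBH, TH, CW, HCW, HCB, CH_k, LCL, TSC, CLR, BA, SDI,
the lagged radius CR_(k-1) and CPCI_k; the target is the layer radius CR_k.
Dropping the CPCI slot (13 features) reproduces the "no competition index"
ablation condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .competition import CompetitionTable
from .profile_interp import MEAN, CrownProfile
from .stand_io import DIRECTIONS, DerivedVars, PlotRecord

FEATURE_NAMES = (
    "AGE", "DBH", "TH", "CW", "HCW", "HCB", "CH", "LCL", "TSC", "CLR",
    "BA", "SDI", "CR_lag", "CPCI",
)
#: features that change from layer to layer (everything else is static per tree)
STEP_VARYING = ("CH", "CR_lag", "CPCI")

N_STEPS = 10


@dataclass
class FeatureSequence:
    tree_id: str
    direction: str
    x: np.ndarray        # (10, n_features) raw (un-normalised) features
    y: np.ndarray        # (10,) target radii CR_1..CR_10 (m)
    feature_names: tuple[str, ...]


def build_sequences(
    plot: PlotRecord,
    mean_profiles: dict[str, CrownProfile],
    directional_profiles: dict[str, dict[str, CrownProfile]],
    tables: dict[str, CompetitionTable],
    derived: dict[str, DerivedVars],
    direction_mode: str = "mean",
    use_cpci: bool = True,
    step_order: str = "top_down",
) -> list[FeatureSequence]:
    """One sequence per tree in the chosen direction mode.

    ``direction_mode`` is ``mean`` or one of E/W/S/N.  In directional modes
    the targets come from that direction's profile and the CPCI slot holds the
    directional allocation; in mean mode both come from the directional-mean
    profile and the undirected CPCI_k.
    """
    if direction_mode != "mean" and direction_mode not in DIRECTIONS:
        raise ValueError(f"direction_mode must be 'mean' or one of {DIRECTIONS}")
    if step_order not in ("top_down", "bottom_up"):
        raise ValueError("step_order must be 'top_down' or 'bottom_up'")

    names = FEATURE_NAMES if use_cpci else FEATURE_NAMES[:-1]
    hcw_values = [t.hcw for t in plot.trees if np.isfinite(t.hcw)]
    hcw_fill = float(np.mean(hcw_values)) if hcw_values else 0.0

    out: list[FeatureSequence] = []
    for t in plot.trees:
        dv = derived[t.tree_id]
        if direction_mode == "mean":
            prof = mean_profiles[t.tree_id]
            cpci = tables[t.tree_id].cpci if use_cpci else None
            direction = MEAN
        else:
            prof = directional_profiles[t.tree_id][direction_mode]
            cpci = (
                tables[t.tree_id].directional[direction_mode] if use_cpci else None
            )
            direction = direction_mode
        if use_cpci and cpci is None:
            raise ValueError(f"CPCI requested but missing for tree {t.tree_id}")

        radii = prof.radii                      # (11,), index 0 = treetop
        hcw = t.hcw if np.isfinite(t.hcw) else hcw_fill
        x = np.empty((N_STEPS, len(names)))
        y = np.empty(N_STEPS)
        for k in range(1, N_STEPS + 1):
            row = [
                t.age, t.dbh, t.th, t.cw, hcw, t.hcb,
                dv.ch_at_layer(k), dv.lcl, dv.tsc, dv.clr, dv.ba, dv.sdi,
                radii[k - 1],                   # lag CR_(k-1); CR_0 = 0 anchor
            ]
            if use_cpci:
                row.append(float(cpci[k - 1]))
            x[k - 1] = row
            y[k - 1] = radii[k]
        if step_order == "bottom_up":
            x, y = x[::-1].copy(), y[::-1].copy()
            lag_idx = names.index("CR_lag")
            # in base-to-top order the previous step is the layer below;
            # the sequence is seeded with the (unknown) below-base radius -> 0
            x[1:, lag_idx] = y[:-1]
            x[0, lag_idx] = 0.0
        out.append(FeatureSequence(t.tree_id, direction, x, y, names))
    return out


@dataclass
class Normalizer:
    """Per-variable min-max scaler fitted on the training partition only.

    Constant variables map to 0.  Values outside the training range map
    outside [0, 1] and are deliberately not clipped.
    """

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    feature_names: tuple[str, ...]

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        out = (x - self.x_min) / span
        out[..., self.x_max <= self.x_min] = 0.0
        return out

    def inverse_x(self, xn: np.ndarray) -> np.ndarray:
        return xn * (self.x_max - self.x_min) + self.x_min

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        if self.y_max > self.y_min:
            return (y - self.y_min) / (self.y_max - self.y_min)
        return np.zeros_like(y)

    def inverse_y(self, yn: np.ndarray) -> np.ndarray:
        return yn * (self.y_max - self.y_min) + self.y_min


def fit_normalizer(train: list[FeatureSequence]) -> Normalizer:
    if not train:
        raise ValueError("empty training partition")
    x = np.stack([s.x for s in train])
    y = np.stack([s.y for s in train])
    return Normalizer(
        x_min=x.min(axis=(0, 1)), x_max=x.max(axis=(0, 1)),
        y_min=float(y.min()), y_max=float(y.max()),
        feature_names=train[0].feature_names,
    )


@dataclass
class Dataset:
    """Normalised arrays ready for model training."""

    x: np.ndarray                    # (n, 10, n_features), in [0, 1] on train
    y: np.ndarray                    # (n, 10) normalised targets
    y_m: np.ndarray                  # (n, 10) targets in metres
    ids: list[str]
    feature_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.ids)


def to_dataset(sequences: list[FeatureSequence], norm: Normalizer) -> Dataset:
    x = np.stack([s.x for s in sequences])
    y_m = np.stack([s.y for s in sequences])
    return Dataset(
        x=norm.transform_x(x), y=norm.transform_y(y_m), y_m=y_m,
        ids=[s.tree_id for s in sequences],
        feature_names=sequences[0].feature_names,
    )


def split_dataset(
    sequences: list[FeatureSequence],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[FeatureSequence], list[FeatureSequence], list[FeatureSequence]]:
    """Tree-level 8:1:1 split: every sequence of one tree lands in the same
    partition so the lagged-radius feature cannot leak across partitions."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    trees = sorted({s.tree_id for s in sequences})
    if len(trees) < 10:
        raise ValueError(f"need at least 10 trees to split, got {len(trees)}")
    rng = np.random.default_rng(seed)
    order = list(trees)
    rng.shuffle(order)
    n = len(order)
    n_val = max(1, round(ratios[1] * n))
    n_test = max(1, round(ratios[2] * n))
    val_ids = set(order[:n_val])
    test_ids = set(order[n_val:n_val + n_test])
    train, val, test = [], [], []
    for s in sequences:
        if s.tree_id in val_ids:
            val.append(s)
        elif s.tree_id in test_ids:
            test.append(s)
        else:
            train.append(s)
    return train, val, test
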