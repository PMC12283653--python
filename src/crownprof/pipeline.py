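"""End-to-end orchestration: stand -> profiles -> CPCI -> sequences -> models.

``prepare_stand`` runs the deterministic data stages for a list of plots;
``run_experiment`` trains one architecture under one condition and returns
test-set metrics; ``recovery_suite`` runs the full factorial analogue
experiment (3 architectures x ±CPCI over several seeds) on synthetic stands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import competition, evaluate, features, profile_interp, stand_io, synthetic
from .features import Dataset, FeatureSequence
from .models import ARCHITECTURES, ModelConfig, TrainedModel, fit
from .stand_io import DIRECTIONS, PlotRecord


@dataclass
class PreparedStand:
    """All deterministic per-plot artefacts of the data pipeline."""

    plots: list[PlotRecord]
    mean_profiles: dict[str, profile_interp.CrownProfile]
    directional_profiles: dict[str, dict[str, profile_interp.CrownProfile]]
    derived: dict[str, stand_io.DerivedVars]
    tables: dict[str, competition.CompetitionTable]
    rejected: list[stand_io.RejectedTree] = field(default_factory=list)


def prepare_stand(plots: list[PlotRecord]) -> PreparedStand:
    """Filter, interpolate, derive variables and compute CPCI for every plot."""
    mean_profiles: dict[str, profile_interp.CrownProfile] = {}
    directional: dict[str, dict[str, profile_interp.CrownProfile]] = {}
    derived: dict[str, stand_io.DerivedVars] = {}
    tables: dict[str, competition.CompetitionTable] = {}
    all_rejected: list[stand_io.RejectedTree] = []
    kept_plots: list[PlotRecord] = []

    for plot in plots:
        kept, rejected = stand_io.apply_filters(plot.trees)
        all_rejected.extend(rejected)
        fplot = PlotRecord(plot.plot_id, plot.radius_m, plot.slope_deg,
                           plot.aspect, kept)
        kept_plots.append(fplot)
        derived.update(stand_io.derive_variables(fplot))
        for t in kept:
            dirs = {}
            for d in DIRECTIONS:
                dirs[d] = profile_interp.interpolate_profile(
                    t.raw_radii[d], tree_id=t.tree_id, direction=d
                )
            directional[t.tree_id] = dirs
            mean_profiles[t.tree_id] = profile_interp.mean_profile(
                [dirs[d] for d in DIRECTIONS]
            )
        tables.update(
            competition.compute_competition(
                fplot, mean_profiles, directional, derived
            )
        )
    return PreparedStand(kept_plots, mean_profiles, directional, derived,
                         tables, all_rejected)


def build_split_datasets(
    prepared: PreparedStand,
    direction_mode: str = "mean",
    use_cpci: bool = True,
    split_seed: int = 0,
    step_order: str = "top_down",
) -> tuple[Dataset, Dataset, Dataset, features.Normalizer]:
    """Sequences for one condition, tree-level 8:1:1 split, train-fitted scaler."""
    seqs: list[FeatureSequence] = []
    for plot in prepared.plots:
        seqs.extend(
            features.build_sequences(
                plot, prepared.mean_profiles, prepared.directional_profiles,
                prepared.tables, prepared.derived,
                direction_mode=direction_mode, use_cpci=use_cpci,
                step_order=step_order,
            )
        )
    train_seqs, val_seqs, test_seqs = features.split_dataset(
        seqs, seed=split_seed
    )
    norm = features.fit_normalizer(train_seqs)
    return (
        features.to_dataset(train_seqs, norm),
        features.to_dataset(val_seqs, norm),
        features.to_dataset(test_seqs, norm),
        norm,
    )


def run_experiment(
    prepared: PreparedStand,
    config: ModelConfig,
    direction_mode: str = "mean",
    use_cpci: bool = True,
    split_seed: int = 0,
    lag_mode: str = "teacher",
) -> tuple[TrainedModel, dict[str, float]]:
    """Train one condition cell and return the model plus test metrics (m)."""
    train_d, val_d, test_d, norm = build_split_datasets(
        prepared, direction_mode=direction_mode, use_cpci=use_cpci,
        split_seed=split_seed,
    )
    model = fit(train_d, val_d, config, normalizer=norm)
    pred = model.predict_radii(test_d, lag_mode=lag_mode)
    metrics = evaluate.compute_metrics(test_d.y_m, pred)
    return model, metrics


def recovery_suite(
    params: synthetic.StandParams,
    n_plots: int = 4,
    seeds: tuple[int, ...] = (0, 1, 2),
    architectures: tuple[str, ...] = ARCHITECTURES,
    direction_mode: str = "mean",
    max_epochs: int = 200,
    patience: int = 20,
) -> pd.DataFrame:
    """Full analogue experiment: for each seed, generate stands, compute CPCI,
    train every architecture with and without the CPCI feature, and record
    held-out R² (teacher-forced lag).  Returns one row per
    (seed, architecture, use_cpci)."""
    rows = []
    for seed in seeds:
        stand_params = synthetic.StandParams(**{
            **params.__dict__, "seed": seed,
            "directional_multipliers": dict(params.directional_multipliers),
        })
        plots, _ = synthetic.generate_stands(stand_params, n_plots, seed=seed)
        prepared = prepare_stand(plots)
        for arch in architectures:
            for use_cpci in (False, True):
                cfg = ModelConfig(
                    kind=arch, max_epochs=max_epochs, patience=patience,
                    seed=seed,
                )
                _, metrics = run_experiment(
                    prepared, cfg, direction_mode=direction_mode,
                    use_cpci=use_cpci, split_seed=seed,
                )
                rows.append({
                    "seed": seed, "arch": arch, "use_cpci": use_cpci, **metrics,
                })
    return pd.DataFrame(rows)


def median_r2(suite: pd.DataFrame) -> pd.DataFrame:
    """Median held-out R² per (architecture, use_cpci) across seeds."""
    return (
        suite.groupby(["arch", "use_cpci"], as_index=False)["r2"].median()
    )
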