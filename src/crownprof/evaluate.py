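"""Evaluation metrics, condition/direction report tables and permutation
feature importance.

All metrics are computed in metres over the pooled (tree x layer) records of
a condition, after inverse normalisation:

    MSE  = mean (y - yhat)^2            [m²]
    RMSE = sqrt(MSE)                    [m]
    MAE  = mean |y - yhat|              [m]
    ME   = mean (y - yhat)              [m]  (signed bias)
    R²   = 1 - SSE / SST                (test-set mean in SST)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .features import Dataset, STEP_VARYING

REPORT_COLUMNS = [
    "arch", "direction", "use_cpci", "mse_m2", "rmse_m", "mae_m", "me_m", "r2", "n",
]


def compute_metrics(observed: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """The five-statistic metric row for one condition."""
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("observed and predicted must be equal-length and nonempty")
    err = y - yhat
    mse = float(np.mean(err**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero variance in observed values; R² undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / sst
    return {
        "mse_m2": mse,
        "rmse_m": float(np.sqrt(mse)),
        "mae_m": float(np.mean(np.abs(err))),
        "me_m": float(np.mean(err)),
        "r2": r2,
        "n": int(y.size),
    }


def evaluation_matrix(results: dict[tuple[str, str, bool], tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Metric table over condition cells.

    ``results`` maps (architecture, direction, use_cpci) to an
    (observed, predicted) pair in metres.  Missing cells are simply absent
    rows.  Row order: architecture, then direction, then CPCI condition.
    """
    rows = []
    for (arch, direction, use_cpci), (obs, pred) in sorted(results.items()):
        row = {"arch": arch, "direction": direction, "use_cpci": use_cpci}
        row.update(compute_metrics(obs, pred))
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def format_report(report: pd.DataFrame) -> str:
    """Plain-text rendering with the best value per error column starred."""
    if report.empty:
        return "(empty report)"
    best = {
        "mse_m2": report["mse_m2"].idxmin(),
        "rmse_m": report["rmse_m"].idxmin(),
        "mae_m": report["mae_m"].idxmin(),
        "me_m": report["me_m"].abs().idxmin(),
        "r2": report["r2"].idxmax(),
    }
    lines = ["arch                 dir   CPCI   MSE(m²)    RMSE(m)    MAE(m)     ME(m)      R²"]
    for idx, r in report.iterrows():
        cells = []
        for col, fmt in [("mse_m2", "%.5f"), ("rmse_m", "%.5f"), ("mae_m", "%.5f"),
                         ("me_m", "% .5f"), ("r2", "%.5f")]:
            s = fmt % r[col]
            if best[col] == idx:
                s = f"*{s}*"
            cells.append(f"{s:<10}")
        lines.append(
            f"{r['arch']:<20} {r['direction']:<5} {'yes' if r['use_cpci'] else 'no':<6} "
            + " ".join(cells)
        )
    return "\n".join(lines)


def permutation_importance(
    model,
    dataset: Dataset,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Increase in MSE (m²) when one feature is shuffled across sequences.

    Static features are permuted with one draw per sequence (the whole
    10-step column moves together); step-varying features (CH, lagged CR,
    CPCI) are permuted independently within each step slot.  Averaged over
    ``n_repeats``; returned in descending importance order.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    base_pred = model.predict_radii(dataset)
    base_mse = compute_metrics(dataset.y_m, base_pred)["mse_m2"]

    rows = []
    for f, name in enumerate(dataset.feature_names):
        deltas = []
        for _ in range(n_repeats):
            x = dataset.x.copy()
            if name in STEP_VARYING:
                for k in range(x.shape[1]):
                    x[:, k, f] = x[rng.permutation(len(x)), k, f]
            else:
                x[:, :, f] = x[rng.permutation(len(x)), :, f]
            shuffled = Dataset(x=x, y=dataset.y, y_m=dataset.y_m,
                               ids=dataset.ids, feature_names=dataset.feature_names)
            pred = model.predict_radii(shuffled)
            deltas.append(compute_metrics(dataset.y_m, pred)["mse_m2"] - base_mse)
        rows.append({
            "feature": name,
            "importance_mse_m2": float(np.mean(deltas)),
            "importance_sd": float(np.std(deltas)),
        })
    df = pd.DataFrame(rows).sort_values(
        "importance_mse_m2", ascending=False, ignore_index=True
    )
    df.attrs["baseline_mse_m2"] = base_mse
    return df
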