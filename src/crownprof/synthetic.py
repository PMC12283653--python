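"""Synthetic *Pinus yunnanensis*-like stands for end-to-end pipeline testing.

The generator emulates the statistical structure the pipeline assumes:

* circular plots with hard-core (sequential-inhibition) stem placement;
* marginal distributions calibrated to the published stand summary
  (mean DBH 19.5 cm, TH 11.8 m, CW 2.1 m, HCB 6.8 m, AGE 27.3 yr);
* power-function crown profiles r(u) = R_max * u**beta on relative crown
  height u, with per-tree shape jitter;
* directional asymmetry through cardinal multipliers (south largest, as
  expected for northern-hemisphere light regimes);
* competition-dependent crown reduction: a sector-crowding covariate in
  [0, 1] per cardinal direction shrinks the radius by a factor
  (1 - gamma * crowding).

Noise-free truth is returned alongside the observed records so that
parameter-recovery and feature-importance tests have ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .stand_io import DIRECTIONS, PlotRecord, TreeRecord

#: RCH positions at which the virtual field crew records radii
MEASURED_RCH = (0.25, 0.5, 0.75, 1.0)

#: compass bearing unit vectors (x east, y north)
_BEARINGS = {"E": (1.0, 0.0), "W": (-1.0, 0.0), "S": (0.0, -1.0), "N": (0.0, 1.0)}


@dataclass
class StandParams:
    """Generator configuration.  Defaults reproduce a middle-aged, moderately
    dense pine stand; allometries are calibrated so large-sample marginal
    means approach DBH 19.5 cm, TH 11.8 m, HCB 6.8 m, AGE 27.3 yr."""

    n_trees: int = 125
    plot_radius_m: float = 25.0
    min_spacing_m: float = 1.5
    # DBH ~ lognormal with these natural-scale moments (cm)
    dbh_mean: float = 19.5
    dbh_sd: float = 6.8
    dbh_range: tuple[float, float] = (5.4, 42.1)
    # TH = th_a * DBH**th_b * exp(eps), eps ~ N(0, th_noise_sd)
    # (coefficients carry the lognormal Jensen correction so that the
    # large-sample mean TH at the configured DBH distribution is 11.8 m)
    th_a: float = 2.3321
    th_b: float = 0.55
    th_noise_sd: float = 0.06
    # crown length ratio (LCL/TH), truncated normal
    clr_mean: float = 0.42
    clr_sd: float = 0.10
    clr_range: tuple[float, float] = (0.15, 0.80)
    # crown width allometry CW = cw_a * DBH**cw_b (m), pre-competition
    cw_a: float = 0.26487
    cw_b: float = 0.70
    cw_noise_sd: float = 0.08
    # age scales with relative diameter
    age_mean: float = 27.3
    age_noise_sd: float = 3.0
    age_range: tuple[float, float] = (10.0, 52.0)
    # profile shape exponent r(u) ∝ u**beta
    beta: float = 0.6
    beta_sd: float = 0.08
    # cardinal multipliers, south-largest asymmetry
    directional_multipliers: dict[str, float] = field(
        default_factory=lambda: {"E": 0.97, "W": 0.95, "S": 1.18, "N": 0.90}
    )
    # competition sensitivity: radius factor (1 - gamma * crowding)
    gamma: float = 0.5
    crowding_radius_m: float = 8.0
    crowding_norm: float = 3.0
    # multiplicative lognormal measurement noise on recorded radii
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 3:
            raise ValueError("need at least 3 trees")
        if self.min_spacing_m <= 0 or self.plot_radius_m <= 0:
            raise ValueError("spacing and plot radius must be positive")
        if any(m <= 0 for m in self.directional_multipliers.values()):
            raise ValueError("directional multipliers must be positive")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class TreeTruth:
    """Noise-free generator state for one tree."""

    tree_id: str
    r_max: float                      # pre-competition radius scale (m)
    beta: float
    crowding: dict[str, float]        # per-direction crowding in [0, 1]
    true_radii: dict[str, np.ndarray]  # direction -> radii on the 11-pt grid


@dataclass
class SyntheticTruth:
    params: StandParams
    trees: dict[str, TreeTruth]


class PackingError(RuntimeError):
    """The hard-core point process could not place all stems."""


def _hard_core_positions(params: StandParams, rng: np.random.Generator) -> np.ndarray:
    """Sequential-inhibition placement inside the plot circle."""
    pts = np.empty((params.n_trees, 2))
    n_placed = 0
    max_tries = 2000 * params.n_trees
    tries = 0
    spacing2 = params.min_spacing_m**2
    while n_placed < params.n_trees:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {params.n_trees} stems with spacing "
                f"{params.min_spacing_m} m in a {params.plot_radius_m} m plot"
            )
        tries += 1
        r = params.plot_radius_m * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        cand = np.array([r * math.cos(theta), r * math.sin(theta)])
        d2 = np.sum((pts[:n_placed] - cand) ** 2, axis=1)
        if n_placed == 0 or float(d2.min()) >= spacing2:
            pts[n_placed] = cand
            n_placed += 1
    return pts


def _sector_crowding(
    pos: np.ndarray, i: int, params: StandParams
) -> dict[str, float]:
    """Per-direction crowding in [0, 1]: neighbours inside the crowding radius
    weighted by a cosine window on their bearing and by proximity."""
    d = pos - pos[i]
    dist = np.hypot(d[:, 0], d[:, 1])
    near = (dist > 0) & (dist < params.crowding_radius_m)
    out = {}
    for name, (bx, by) in _BEARINGS.items():
        if not np.any(near):
            out[name] = 0.0
            continue
        dx, dy = d[near, 0] / dist[near], d[near, 1] / dist[near]
        cosang = np.maximum(0.0, dx * bx + dy * by)
        w = cosang * (1.0 - dist[near] / params.crowding_radius_m)
        out[name] = min(1.0, float(w.sum()) / params.crowding_norm)
    return out


def generate_stand(
    params: StandParams, plot_id: str = "S1", rng: np.random.Generator | None = None
) -> tuple[PlotRecord, SyntheticTruth]:
    """Generate one plot plus its noise-free truth, reproducible from the seed."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    pos = _hard_core_positions(params, rng)
    n = params.n_trees

    # lognormal DBH with the requested natural-scale mean/sd
    sigma2 = math.log(1.0 + (params.dbh_sd / params.dbh_mean) ** 2)
    mu = math.log(params.dbh_mean) - sigma2 / 2.0
    dbh = np.clip(rng.lognormal(mu, math.sqrt(sigma2), n), *params.dbh_range)

    th = params.th_a * dbh**params.th_b * np.exp(rng.normal(0, params.th_noise_sd, n))
    clr = np.clip(rng.normal(params.clr_mean, params.clr_sd, n), *params.clr_range)
    hcb = th * (1.0 - clr)
    lcl = th - hcb
    # 0.9909 = E[(DBH/mean)^0.8] under the lognormal: keeps the mean age on target
    age = np.clip(
        (params.age_mean / 0.9909) * (dbh / params.dbh_mean) ** 0.8
        + rng.normal(0, params.age_noise_sd, n),
        *params.age_range,
    )
    cw_allom = params.cw_a * dbh**params.cw_b * np.exp(
        rng.normal(0, params.cw_noise_sd, n)
    )
    betas = np.clip(rng.normal(params.beta, params.beta_sd, n), 0.25, 1.2)

    grid = np.linspace(0.0, 1.0, 11)
    plot = PlotRecord(plot_id=plot_id, radius_m=params.plot_radius_m)
    truth = SyntheticTruth(params=replace(params), trees={})

    for i in range(n):
        tid = f"{plot_id}_t{i + 1}"
        crowding = _sector_crowding(pos, i, params)
        r_max = cw_allom[i] / 2.0
        true_radii = {}
        raw: dict[str, list[tuple[float, float]]] = {}
        for d in DIRECTIONS:
            mult = params.directional_multipliers[d]
            factor = max(0.0, 1.0 - params.gamma * crowding[d])
            curve = mult * r_max * grid**betas[i] * factor
            true_radii[d] = curve
            noise = rng.lognormal(
                -params.noise_sd**2 / 2.0, params.noise_sd, len(MEASURED_RCH)
            ) if params.noise_sd > 0 else np.ones(len(MEASURED_RCH))
            raw[d] = [
                (u, float(mult * r_max * u**betas[i] * factor * z))
                for u, z in zip(MEASURED_RCH, noise)
            ]
        # CW is the allometric (pre-competition) crown width: competition and
        # directional asymmetry act on the radii relative to this scale, so
        # the crowding signal is carried by stem geometry/CPCI, not by CW
        cw = 2.0 * r_max
        hcw = hcb[i] + 0.2 * lcl[i]

        plot.trees.append(
            TreeRecord(
                tree_id=tid, plot_id=plot_id, x=float(pos[i, 0]), y=float(pos[i, 1]),
                dbh=float(dbh[i]), th=float(th[i]), hcb=float(hcb[i]),
                hcw=float(hcw), cw=float(cw), age=float(age[i]), raw_radii=raw,
            )
        )
        truth.trees[tid] = TreeTruth(
            tree_id=tid, r_max=float(r_max), beta=float(betas[i]),
            crowding=crowding, true_radii=true_radii,
        )
    return plot, truth


def generate_stands(
    params: StandParams, n_plots: int, seed: int | None = None
) -> tuple[list[PlotRecord], list[SyntheticTruth]]:
    """Generate several independent plots from one master seed."""
    master = np.random.default_rng(params.seed if seed is None else seed)
    plots, truths = [], []
    for p in range(n_plots):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        plot, truth = generate_stand(params, plot_id=f"S{p + 1}", rng=rng)
        plots.append(plot)
        truths.append(truth)
    return plots, truths
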