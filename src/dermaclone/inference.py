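"""End-to-end estimation: division number from tables, rate recovery from clones.

:class:`DivisionNumberEstimator` composes the cylinder-shell morphometry with
the density tables: per-animal dermis volumes are averaged per (age, sex)
group, group means are averaged over the sexes present at each age (matching
the male/female averaging of the adult time point), and the division number is
n = log2((dv1 * rho1) / (dv0 * rho0)).  An optional bootstrap over animals
(and density replicates) gives a percentile confidence interval; with n = 3
animals per group the CI is necessarily coarse.

:class:`DivisionRateFitter` recovers the simulator's division budget from an
observed clone-size summary by grid search: each candidate rate is simulated
``reps`` times, clone calling and per-compartment mean clone sizes are applied
exactly as to data, and the sum of squared differences to the observed summary
is minimised.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import morphometry, quantify, simulate
from .morphometry import DivisionEstimate

_MEASUREMENT_COLS = ["age_days", "sex", "length_cm", "width_cm", "dermis_depth_cm"]
_DENSITY_COLS = ["age_days", "layer", "rho_per_mm2"]


def _check_table(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")


def _group_dermis_volume(measurements: pd.DataFrame, age: float) -> float:
    """Mean dermis volume at an age: per-animal volumes -> per-sex means -> sex mean."""
    sub = measurements[measurements["age_days"] == age]
    if sub.empty:
        raise ValueError(f"no body measurements at age {age} days")
    per_sex = []
    for _, grp in sub.groupby("sex"):
        vols = [
            morphometry.dermis_volume(
                row.width_cm / 2.0, row.length_cm, row.dermis_depth_cm
            )
            for row in grp.itertuples()
        ]
        per_sex.append(float(np.mean(vols)))
    return float(np.mean(per_sex))


def _group_density(densities: pd.DataFrame, age: float, layer: str) -> float:
    sub = densities[(densities["age_days"] == age) & (densities["layer"] == layer)]
    if sub.empty:
        raise ValueError(f"no density for layer {layer!r} at age {age} days")
    return float(sub["rho_per_mm2"].mean())


class DivisionNumberEstimator(BaseEstimator):
    """Division-number estimator n = log2(N/N0) from morphometry + density tables.

    Parameters
    ----------
    t0, t1 : ages (days) of the earlier and later time point.
    layer : which density layer enters the cell-number product (default the
        total-dermis density).
    n_bootstrap : bootstrap replicates over animals/density replicates for a
        percentile CI (0 disables).
    seed : bootstrap RNG seed.

    Fitted attributes: ``n_divisions_``, ``cell_ratio_``, ``volume_ratio_``,
    ``density_ratio_``, ``dv_t0_``, ``dv_t1_``, ``estimate_`` (a
    :class:`~dermaclone.morphometry.DivisionEstimate`), and ``ci_`` when
    bootstrapping.
    """

    def __init__(
        self,
        t0: float = 2,
        t1: float = 50,
        layer: str = "total",
        n_bootstrap: int = 0,
        ci_level: float = 0.95,
        seed: int = 0,
    ):
        self.t0 = t0
        self.t1 = t1
        self.layer = layer
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.seed = seed

    def _point_estimate(
        self, measurements: pd.DataFrame, densities: pd.DataFrame
    ) -> Tuple[float, float, float, float]:
        dv0 = _group_dermis_volume(measurements, self.t0)
        dv1 = _group_dermis_volume(measurements, self.t1)
        rho0 = _group_density(densities, self.t0, self.layer)
        rho1 = _group_density(densities, self.t1, self.layer)
        return dv0, dv1, rho0, rho1

    def fit(self, measurements: pd.DataFrame, densities: pd.DataFrame):
        _check_table(measurements, _MEASUREMENT_COLS, "measurements")
        _check_table(densities, _DENSITY_COLS, "densities")
        dv0, dv1, rho0, rho1 = self._point_estimate(measurements, densities)
        n0 = morphometry.relative_cell_number(dv0, rho0)
        n1 = morphometry.relative_cell_number(dv1, rho1)
        ci = (None, None)
        if self.n_bootstrap:
            ci = self._bootstrap_ci(measurements, densities)
        est = morphometry.estimate_divisions(
            n0, n1, volume_ratio=dv1 / dv0, density_ratio=rho1 / rho0
        )
        est = dataclasses.replace(est, ci_low=ci[0], ci_high=ci[1])
        self.estimate_ = est
        self.n_divisions_ = est.n_divisions
        self.cell_ratio_ = est.cell_ratio
        self.volume_ratio_ = est.volume_ratio
        self.density_ratio_ = est.density_ratio
        self.dv_t0_ = dv0
        self.dv_t1_ = dv1
        self.rho_t0_ = rho0
        self.rho_t1_ = rho1
        self.ci_ = ci
        return self

    def _bootstrap_ci(
        self, measurements: pd.DataFrame, densities: pd.DataFrame
    ) -> Tuple[float, float]:
        rng = np.random.default_rng(self.seed)
        stats = []
        meas_groups = [grp for _, grp in measurements.groupby(["age_days", "sex"])]
        dens_groups = [grp for _, grp in densities.groupby(["age_days", "layer"])]
        for _ in range(self.n_bootstrap):
            m = pd.concat(
                [g.sample(len(g), replace=True, random_state=rng) for g in meas_groups],
                ignore_index=True,
            )
            d = pd.concat(
                [g.sample(len(g), replace=True, random_state=rng) for g in dens_groups],
                ignore_index=True,
            )
            dv0, dv1, rho0, rho1 = self._point_estimate(m, d)
            stats.append(math.log2((dv1 * rho1) / (dv0 * rho0)))
        alpha = 1.0 - self.ci_level
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)


def estimate_division_number(
    measurements: pd.DataFrame,
    densities: pd.DataFrame,
    t0: float = 2,
    t1: float = 50,
    layer: str = "total",
    n_bootstrap: int = 0,
    seed: int = 0,
) -> DivisionEstimate:
    """Functional wrapper over :class:`DivisionNumberEstimator`."""
    est = DivisionNumberEstimator(
        t0=t0, t1=t1, layer=layer, n_bootstrap=n_bootstrap, seed=seed
    ).fit(measurements, densities)
    return est.estimate_


def estimate_divisions_from_snapshots(
    snap0: simulate.Snapshot,
    snap1: simulate.Snapshot,
    section_thickness_um: float = 60.0,
) -> DivisionEstimate:
    """Closed-loop estimate from two simulated snapshots.

    Volumes are the tissue-box volumes; densities are fixed-thickness-section
    areal densities (the same measurement the whole-mount protocol makes), so
    the estimator sees the simulator through the same observables as real data.
    """
    dv0 = snap0.volume_mm3()
    dv1 = snap1.volume_mm3()
    rho0 = quantify.snapshot_areal_density(snap0, section_thickness_um)
    rho1 = quantify.snapshot_areal_density(snap1, section_thickness_um)
    return morphometry.estimate_divisions(
        morphometry.relative_cell_number(dv0, rho0),
        morphometry.relative_cell_number(dv1, rho1),
        volume_ratio=dv1 / dv0,
        density_ratio=rho1 / rho0,
    )


@dataclass(frozen=True)
class FitResult:
    """Grid-search recovery of the simulator division budget."""

    division_rate: float
    objective: float
    grid: Tuple[float, ...]
    objectives: Tuple[float, ...]
    ci_low: Optional[float]
    ci_high: Optional[float]
    seed: int

    def __post_init__(self) -> None:
        if self.division_rate not in self.grid:
            raise ValueError("fitted rate must lie on the evaluated grid")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            raise ValueError("CI bounds must be ordered")


class DivisionRateFitter(BaseEstimator):
    """Simulation-based grid search for the division budget.

    For each grid rate the configured simulation is run ``reps`` times with
    derived seeds, the final labelled cells are clone-called and summarised as
    mean cells-per-clone per compartment, and the replicate-mean summary is
    scored against the observed summary by sum of squared differences.  A
    bootstrap over replicate summaries gives a CI of the argmin.
    """

    def __init__(
        self,
        config: simulate.SimConfig,
        rate_grid: Sequence[float] = (0.8, 1.3, 1.8),
        reps: int = 10,
        calling_params: Optional[quantify.CloneCallingParams] = None,
        n_bootstrap: int = 0,
        seed: int = 0,
    ):
        self.config = config
        self.rate_grid = rate_grid
        self.reps = reps
        self.calling_params = calling_params
        self.n_bootstrap = n_bootstrap
        self.seed = seed

    def _simulate_summary(self, rate: float, rep_seed: int) -> pd.Series:
        cfg = dataclasses.replace(self.config, division_rate=rate, seed=rep_seed)
        snap = simulate.run(cfg, [cfg.end_age_days])[-1]
        return quantify.clone_size_summary(snap.cells, self.calling_params)

    def fit(self, observed_summary: pd.Series):
        grid = tuple(float(r) for r in self.rate_grid)
        if len(grid) == 0:
            raise ValueError("rate grid must be non-empty")
        if int(self.reps) < 1:
            raise ValueError("reps must be >= 1")
        observed = pd.Series(observed_summary).astype(float)
        if observed.empty or not np.isfinite(observed).any():
            raise ValueError("observed clone-size summary is degenerate (no clones)")
        rng = np.random.default_rng(self.seed)
        rep_seeds = rng.integers(0, 2**31 - 1, size=(len(grid), self.reps))
        summaries = []  # per rate: DataFrame reps x compartments
        objectives = []
        for gi, rate in enumerate(grid):
            reps = [
                self._simulate_summary(rate, int(rep_seeds[gi, r]))
                for r in range(self.reps)
            ]
            frame = pd.DataFrame(reps)
            summaries.append(frame)
            mean = frame.mean(axis=0)
            common = observed.index.intersection(mean.index)
            if len(common) == 0:
                raise ValueError("observed summary shares no compartments with simulation")
            objectives.append(float(((mean[common] - observed[common]) ** 2).sum()))
        objectives_arr = np.asarray(objectives)
        best = int(np.argmin(objectives_arr))
        ci = (None, None)
        if self.n_bootstrap:
            picks = []
            for _ in range(self.n_bootstrap):
                objs = []
                for gi in range(len(grid)):
                    frame = summaries[gi]
                    res = frame.sample(len(frame), replace=True, random_state=rng)
                    mean = res.mean(axis=0)
                    common = observed.index.intersection(mean.index)
                    objs.append(float(((mean[common] - observed[common]) ** 2).sum()))
                picks.append(grid[int(np.argmin(objs))])
            lo, hi = np.quantile(picks, [0.025, 0.975])
            ci = (float(lo), float(hi))
        self.result_ = FitResult(
            division_rate=grid[best],
            objective=float(objectives_arr[best]),
            grid=grid,
            objectives=tuple(objectives),
            ci_low=ci[0],
            ci_high=ci[1],
            seed=self.seed,
        )
        self.division_rate_ = self.result_.division_rate
        self.objective_ = self.result_.objective
        return self


def fit_division_rate(
    observed_summary: pd.Series,
    config: simulate.SimConfig,
    rate_grid: Sequence[float],
    reps: int = 10,
    seed: int = 0,
    n_bootstrap: int = 0,
) -> FitResult:
    """Functional wrapper over :class:`DivisionRateFitter`."""
    fitter = DivisionRateFitter(
        config=config,
        rate_grid=rate_grid,
        reps=reps,
        seed=seed,
        n_bootstrap=n_bootstrap,
    ).fit(observed_summary)
    return fitter.result_
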