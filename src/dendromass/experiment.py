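"""Benchmark sweeps: the configuration grid, neighbor sweep and the
comparison of the best kNN configuration against the Schumacher-Hall model.

The grid crosses distance metric x weighting x neighbor count x variable
subset x transform x data size.  Reduced data sizes are drawn once per run
(seeded) and shared by every cell at that size, i.e. they are treated as
fixed reduced datasets, not as a resampling distribution.  All criteria are
computed on the original biomass scale (log-scale predictions are
exponentiated first) so that every cell and the allometric reference are
compared in the same units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allometry import SchumacherHallRegressor, fit_schumacher_hall
from .criteria import CRITERIA_FIELDS, CriteriaSet, compute_criteria, syx_gain
from .data import CANONICAL_SUBSETS, PREDICTORS, TreeDataset, log_transform, subsample
from .distances import METRICS
from .neighbors import CANONICAL_K, WEIGHTINGS, KNNConfig, loocv_predict

DEFAULT_SIZES = (150, 100, 70, 50)


@dataclass(frozen=True)
class ExperimentGrid:
    """The full crossing of benchmark arms; defaults are the canonical sweep."""

    metrics: tuple = METRICS
    weightings: tuple = WEIGHTINGS
    neighbor_counts: tuple = CANONICAL_K
    variable_subsets: tuple = CANONICAL_SUBSETS
    transforms: tuple = ("raw", "log")
    data_sizes: tuple | None = None  # None => (n,) + DEFAULT_SIZES clipped to n
    seed: int = 0

    def resolve_sizes(self, n: int) -> tuple[int, ...]:
        if self.data_sizes is not None:
            # "full" is a sentinel for the complete dataset, whatever its n
            sizes = tuple(n if s == "full" else s for s in self.data_sizes)
        else:
            sizes = (n,) + tuple(s for s in DEFAULT_SIZES if s < n)
        seen, out = set(), []
        for s in sizes:
            if s not in seen:
                seen.add(s)
                out.append(int(s))
        return tuple(out)

    def size(self, n: int) -> int:
        return (len(self.resolve_sizes(n)) * len(self.transforms)
                * len(self.variable_subsets) * len(self.metrics)
                * len(self.weightings) * len(self.neighbor_counts))


def single_dataset_grid(seed: int = 0) -> ExperimentGrid:
    """The full-data untransformed arm: 4 metrics x 2 weightings x 6 k x 4 subsets."""
    return ExperimentGrid(transforms=("raw",), data_sizes=("full",), seed=seed)


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def run_grid(ds: TreeDataset, grid: ExperimentGrid) -> pd.DataFrame:
    """Evaluate every grid cell by LOOCV; one row per cell, enumeration order.

    Per cell: seeded subsample -> optional log transform -> LOOCV kNN ->
    criteria on the original scale (parameter count = number of predictor
    variables).  Infeasible cells (k >= cell n) are marked failed and the
    run continues.  The result is a pure function of (ds, grid).
    """
    ds.validate()
    sizes = grid.resolve_sizes(ds.n)
    if grid.data_sizes is not None and any(s > ds.n for s in sizes):
        raise ValueError(f"requested data size exceeds n={ds.n}")
    reduced = {}
    for i, s in enumerate(sizes):
        reduced[s] = ds if s == ds.n else subsample(ds, s, _child_seed(grid.seed, i))

    rows = []
    for size in sizes:
        ds_s = reduced[size]
        for transform in grid.transforms:
            use_log = transform == "log"
            for subset in grid.variable_subsets:
                for metric in grid.metrics:
                    for weighting in grid.weightings:
                        for k in grid.neighbor_counts:
                            row = {
                                "data_size": size, "transform": transform,
                                "variables": "+".join(subset), "metric": metric,
                                "weighting": weighting, "k": k,
                            }
                            try:
                                with warnings.catch_warnings():
                                    warnings.simplefilter("ignore")
                                    cfg = KNNConfig(
                                        metric=metric, k_neighbors=k,
                                        weighting=weighting, variables=subset,
                                        use_log=use_log)
                                    preds = loocv_predict(ds_s, cfg).back_transformed()
                                    cs = compute_criteria(preds, n_params=len(subset))
                                row["status"] = "ok"
                                row["reason"] = ""
                                row.update(cs.as_dict())
                            except ValueError as exc:
                                row["status"] = "failed"
                                row["reason"] = str(exc)
                                row.update({f: np.nan for f in CRITERIA_FIELDS})
                            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    table["rank_syx"] = np.nan
    table.loc[ok, "rank_syx"] = table.loc[ok, "syx"].rank(method="first")
    return table


def best_row(table: pd.DataFrame, criterion: str = "syx") -> pd.Series:
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise ValueError("no successful grid cells")
    idx = ok[criterion].idxmax() if criterion in ("r2", "r2_adj") else ok[criterion].idxmin()
    return table.loc[idx]


def config_from_row(row: pd.Series) -> KNNConfig:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return KNNConfig(
            metric=row["metric"], k_neighbors=int(row["k"]),
            weighting=row["weighting"],
            variables=tuple(row["variables"].split("+")),
            use_log=row["transform"] == "log")


@dataclass(frozen=True)
class ComparisonReport:
    """Best-kNN vs Schumacher-Hall comparison on one dataset."""

    sh_model: SchumacherHallRegressor
    sh_criteria: CriteriaSet
    knn_criteria: CriteriaSet
    knn_config: KNNConfig
    gains_by_metric: dict          # metric -> Syx gain (%) of kNN over SH
    residual_table: pd.DataFrame   # record_id, actual, per-model predicted/residual


def compare_to_allometry(ds: TreeDataset, best: KNNConfig,
                         sh_residuals: str = "loo") -> ComparisonReport:
    """Compare a kNN configuration with the Schumacher-Hall fit on one dataset.

    The allometric model is fitted to the full data; its criteria use
    leave-one-out (PRESS) residuals by default so both methods are judged
    out-of-sample (``sh_residuals="fit"`` uses in-sample residuals instead).
    Both sets of criteria are computed on the original biomass scale; the
    Syx gain is additionally reported with the metric arm swept, other
    fields of ``best`` held fixed.
    """
    if sh_residuals not in ("loo", "fit"):
        raise ValueError(f"sh_residuals must be 'loo' or 'fit', got {sh_residuals!r}")
    ds.validate()
    sh = fit_schumacher_hall(ds)
    sh_preds = sh.prediction_set(loo=sh_residuals == "loo")
    sh_cs = compute_criteria(sh_preds, n_params=3)

    def knn_cs(cfg: KNNConfig) -> tuple[CriteriaSet, np.ndarray]:
        preds = loocv_predict(ds, cfg).back_transformed()
        return compute_criteria(preds, n_params=len(cfg.variables)), preds.predicted

    best_cs, best_pred = knn_cs(best)
    gains = {}
    for metric in METRICS:
        cs = best_cs if metric == best.metric else knn_cs(replace(best, metric=metric))[0]
        gains[metric] = syx_gain(sh_cs, cs)

    resid = pd.DataFrame({
        "record_id": ds.record_ids,
        "actual": sh_preds.actual,
        "predicted_sh": sh_preds.predicted,
        "residual_sh": sh_preds.actual - sh_preds.predicted,
        "predicted_knn": best_pred,
        "residual_knn": sh_preds.actual - best_pred,
    })
    return ComparisonReport(
        sh_model=sh, sh_criteria=sh_cs, knn_criteria=best_cs, knn_config=best,
        gains_by_metric=gains, residual_table=resid)


def neighbor_sweep(ds: TreeDataset, config: KNNConfig, k_values) -> pd.DataFrame:
    """Criteria as a function of the neighbor count, other fields fixed."""
    k_values = [int(k) for k in k_values]
    if max(k_values) >= ds.n:
        raise ValueError(f"max k {max(k_values)} must be < n={ds.n}")
    rows = []
    for k in k_values:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = replace(config, k_neighbors=k)
            preds = loocv_predict(ds, cfg).back_transformed()
            cs = compute_criteria(preds, n_params=len(cfg.variables))
        row = {"k": k}
        row.update(cs.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
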