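"""Declustered holdout construction, predictive metrics and model comparison.

The holdout is stratified over space and time: strata are the cross of survey
year and a k x k block grid over the domain (default 4 x 4), and within each
nonempty stratum ``round(fraction * stratum size)`` clusters are sampled
without replacement.  This spreads the validation set across space-time
rather than letting it clump where surveys are dense.

Metric conventions: observed prevalence is the raw cluster fraction
``n_stunted / n_examined``; MPE = mean(observed - predicted), so positive MPE
means under-prediction; MAPE is the mean absolute error on the prevalence
scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ClusterRecord, RasterGeometry, ValidationError

__all__ = ["ValidationReport", "split_holdout", "compute_metrics", "compare_models"]


@dataclass
class ValidationReport:
    label: str
    rmse: float
    mpe: float
    mape: float
    pearson_r: float | None
    n_holdout: int

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "RMSE": self.rmse,
            "MPE": self.mpe,
            "MAPE": self.mape,
            "pearson_r": self.pearson_r,
            "n_holdout": self.n_holdout,
        }


def split_holdout(
    clusters: Sequence[ClusterRecord],
    fraction: float = 0.10,
    seed: int = 0,
    geometry: RasterGeometry | None = None,
    n_blocks: int = 4,
) -> tuple[list[ClusterRecord], list[ClusterRecord]]:
    """Space-time declustered split into (training, holdout).

    Strata are year x spatial block on an ``n_blocks x n_blocks`` grid over
    the bounding box of the cluster locations (or the raster extent when a
    geometry is given).
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    clusters = list(clusters)
    xs = np.array([c.x for c in clusters])
    ys = np.array([c.y for c in clusters])
    if geometry is not None:
        xmin, xmax, ymin, ymax = geometry.extent
    else:
        xmin, xmax, ymin, ymax = xs.min(), xs.max(), ys.min(), ys.max()
    bx = np.clip(((xs - xmin) / max(xmax - xmin, 1e-12) * n_blocks).astype(int), 0, n_blocks - 1)
    by = np.clip(((ys - ymin) / max(ymax - ymin, 1e-12) * n_blocks).astype(int), 0, n_blocks - 1)

    strata: dict[tuple, list[int]] = {}
    for i, c in enumerate(clusters):
        strata.setdefault((c.year, bx[i], by[i]), []).append(i)

    rng = np.random.default_rng(seed)
    hold_idx: set[int] = set()
    for key in sorted(strata):
        members = strata[key]
        k = int(round(fraction * len(members)))
        if k > 0:
            hold_idx.update(rng.choice(members, size=k, replace=False).tolist())
    train = [c for i, c in enumerate(clusters) if i not in hold_idx]
    hold = [c for i, c in enumerate(clusters) if i in hold_idx]
    return train, hold


def compute_metrics(
    observed: Sequence[float], predicted: Sequence[float], label: str = "pooled"
) -> ValidationReport:
    """RMSE, MPE, MAPE and Pearson correlation on the prevalence scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValidationError("observed and predicted must be equal-length, nonempty")
    err = obs - pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mpe = float(np.mean(err))
    mape = float(np.mean(np.abs(err)))
    if obs.std() == 0 or pred.std() == 0:
        r = None
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    return ValidationReport(label=label, rmse=rmse, mpe=mpe, mape=mape, pearson_r=r, n_holdout=obs.size)


def compare_models(model1: pd.DataFrame, model2: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-region-year absolute prevalence differences, in percentage points.

    Inputs are regional estimate tables (as from ``aggregate_regions``) keyed
    by (region, year).  Returns the per-key table plus the overall maximum.
    """
    k1 = model1.set_index(["region", "year"])["prevalence"]
    k2 = model2.set_index(["region", "year"])["prevalence"]
    missing = sorted(set(k1.index.tolist()) ^ set(k2.index.tolist()))
    if missing:
        raise ValidationError(f"region-year keys present in only one table: {missing}")
    diff = (k1 - k2).abs() * 100.0
    table = diff.reset_index().rename(columns={"prevalence": "abs_diff_pp"})
    per_year = table.groupby("year")["abs_diff_pp"].max().rename("max_abs_diff_pp")
    table = table.merge(per_year, on="year")
    return table, float(diff.max())
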