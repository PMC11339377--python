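"""Validation of a probability-of-loss surface against observed binary loss.

The protocol is point-based: sample paired (predicted probability, observed
0/1) values at random cell locations, then report threshold-free (AUC) and
thresholded classification metrics at the cut-point that maximises Cohen's
kappa. Note that AUC and the proportion correctly classified are distinct
quantities in general; both are reported and neither stands in for the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster import GridRaster

__all__ = [
    "ValidationResult",
    "sample_points",
    "auc",
    "confusion_at_cutpoint",
    "kappa_optimal_cutpoint",
    "validate_risk",
]


@dataclass
class ValidationResult:
    auc: float
    sensitivity: float
    specificity: float
    pcc: float
    kappa: float
    cutpoint: float
    n_points: int

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "pcc": self.pcc,
            "kappa": self.kappa,
            "cutpoint": self.cutpoint,
            "n_points": self.n_points,
        }


def sample_points(
    pred_raster: GridRaster, truth_raster: GridRaster, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement sample of cells valid in both rasters.

    Returns (pred, obs) arrays of length ``n``; obs is coerced to 0/1
    (loss = 1, retained = 0).
    """
    pred_raster.require_aligned(truth_raster)
    valid = pred_raster.valid_mask() & truth_raster.valid_mask()
    idx = np.flatnonzero(valid.ravel())
    if n > idx.size:
        raise ValueError(f"requested {n} points but only {idx.size} valid cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    pred = pred_raster.values.ravel()[chosen].astype(float)
    obs = (truth_raster.values.ravel()[chosen] > 0).astype(np.int64)
    return pred, obs


def auc(pred: np.ndarray, obs: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count half."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs)
    n_pos = int((obs == 1).sum())
    n_neg = int((obs == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(pred)  # average ranks => ties count half
    r_pos = ranks[obs == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_at_cutpoint(
    pred: np.ndarray, obs: np.ndarray, t: float
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, pcc, kappa) classifying positive iff pred >= t."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs)
    if pred.size == 0:
        raise ValueError("empty input")
    if not 0.0 <= t <= 1.0:
        raise ValueError("cutpoint must lie in [0, 1]")
    pos = pred >= t
    tp = float(np.sum(pos & (obs == 1)))
    fp = float(np.sum(pos & (obs == 0)))
    tn = float(np.sum(~pos & (obs == 0)))
    fn = float(np.sum(~pos & (obs == 1)))
    n = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    pcc = (tp + tn) / n
    # Cohen's kappa from the same 2x2 table
    p_yes = (tp + fp) / n
    p_obs_yes = (tp + fn) / n
    pe = p_yes * p_obs_yes + (1 - p_yes) * (1 - p_obs_yes)
    kappa = (pcc - pe) / (1 - pe) if pe < 1.0 else 0.0
    return sens, spec, pcc, kappa


def kappa_optimal_cutpoint(
    pred: np.ndarray, obs: np.ndarray, grid_step: float = 0.01
) -> ValidationResult:
    """Scan thresholds on a regular grid; report metrics at the kappa argmax.

    Ties are broken toward the smaller threshold. The grid (step 0.01 by
    default) matches the reporting precision of the metrics.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs)
    a = auc(pred, obs)  # also validates both classes present
    best = None
    for t in np.arange(0.0, 1.0 + grid_step / 2, grid_step):
        sens, spec, pcc, kappa = confusion_at_cutpoint(pred, obs, float(t))
        if best is None or kappa > best[0] + 1e-12:
            best = (kappa, float(t), sens, spec, pcc)
    kappa, t, sens, spec, pcc = best
    return ValidationResult(
        auc=a,
        sensitivity=sens,
        specificity=spec,
        pcc=pcc,
        kappa=kappa,
        cutpoint=t,
        n_points=int(pred.size),
    )


def validate_risk(
    pred_raster: GridRaster,
    truth_raster: GridRaster,
    n: int,
    seed: int = 0,
    grid_step: float = 0.01,
) -> ValidationResult:
    """End-to-end validation: sample points, then kappa-optimal metrics."""
    pred, obs = sample_points(pred_raster, truth_raster, n, seed=seed)
    return kappa_optimal_cutpoint(pred, obs, grid_step=grid_step)
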