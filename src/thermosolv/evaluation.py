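"""Accuracy metrics and distributional diagnostics.

Two headline metrics: RMSE of log10 S, and the percentage of predictions
within one log10 unit of the measurement (the upper bound of reported
experimental reproducibility).  Distribution-level diagnostics compare
temperature-gradient samples by the 1-D earth-mover's distance and locate
systematic bias by cumulative residuals along a molecular feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import ExperimentGroup


@dataclass(frozen=True)
class EvalReport:
    n: int
    rmse: float
    pct_within_1: float

    def as_dict(self) -> dict:
        return {"n": self.n, "rmse": self.rmse, "pct_within_1": self.pct_within_1}


def _paired(y: Sequence[float], y_hat: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length and non-empty")
    return y, y_hat


def rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root mean squared error of paired values."""
    y, y_hat = _paired(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def pct_within_one(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Percentage of predictions within 1 log10 unit (boundary included)."""
    y, y_hat = _paired(y, y_hat)
    return float(100.0 * np.mean(np.abs(y - y_hat) <= 1.0))


def evaluate(y: Sequence[float], y_hat: Sequence[float]) -> EvalReport:
    y, y_hat = _paired(y, y_hat)
    return EvalReport(n=len(y), rmse=rmse(y, y_hat), pct_within_1=pct_within_one(y, y_hat))


def pearson_r(a: Sequence[float], b: Sequence[float],
              with_p: bool = False) -> float | tuple[float, float]:
    """Sample Pearson correlation; one-sided p (r > 0) when requested."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(a, b, alternative="greater")
    return (float(res.statistic), float(res.pvalue)) if with_p else float(res.statistic)


def emd(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """1-D earth-mover's distance: integral of |CDF_a - CDF_b|.

    Computed exactly from the raw sorted samples (no binning).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.wasserstein_distance(a, b))


def dataset_gradients(groups: Sequence[ExperimentGroup]) -> np.ndarray:
    """Experimental d log10 S/dT sample: finite differences over every curve.

    Uses the same scheme as the training gradient targets, so model and data
    distributions are directly comparable; single-temperature experiments
    contribute nothing.
    """
    from .model import finite_difference_gradients

    vals: list[float] = []
    for g in groups:
        grads = finite_difference_gradients(g)
        vals.extend(grads[np.isfinite(grads)].tolist())
    return np.array(vals)


def model_gradients(ensemble, groups: Sequence[ExperimentGroup]) -> np.ndarray:
    """Model d log10 S/dT sample at every record of the given experiments."""
    solutes, solvents, temps = [], [], []
    for g in groups:
        for r in g.records:
            solutes.append(g.solute_smiles)
            solvents.append(g.solvent_smiles)
            temps.append(r.temperature)
    return ensemble.predict_gradient(solutes, solvents, temps)


@dataclass(frozen=True)
class GradientCDF:
    """Empirical CDF of a gradient sample (log10/K)."""

    sample: np.ndarray  # sorted

    @classmethod
    def from_sample(cls, values: Sequence[float]) -> "GradientCDF":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("empty gradient sample")
        return cls(sample=np.sort(values))

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        return np.searchsorted(self.sample, np.asarray(x), side="right") / self.sample.size


def cumulative_residuals(
    residuals: Sequence[float], ordering_feature: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Running sum of signed residuals (pred - true) along a feature.

    Points are sorted by the feature ascending (ties keep input order); the
    curve's drift exposes systematic bias localized in feature space, e.g.
    along solute molecular weight or solvent Wildman-Crippen logP.  The last
    running-sum value always equals the plain residual sum.
    """
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(ordering_feature, dtype=float)
    if r.shape != f.shape:
        raise ValueError("residuals and ordering_feature must be equal-length")
    if not np.all(np.isfinite(f)):
        raise ValueError("ordering feature must be finite")
    order = np.argsort(f, kind="stable")
    return f[order], np.cumsum(r[order])
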