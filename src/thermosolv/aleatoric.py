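"""Learning curves against the aleatoric (inter-laboratory) error floor.

Training experiments are randomly downsampled to a ladder of sizes; at each
size a fresh 4-member ensemble is trained per replicate and evaluated on
fixed test sets.  Once mean test RMSE stops improving with more data, the
model has hit either its own ceiling or — if the plateau sits inside the
inter-laboratory variability band — the irreducible noise of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ExperimentGroup
from .evaluation import rmse
from .model import ModelConfig, train_ensemble

logger = logging.getLogger("thermosolv")

DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class LearningCurvePoint:
    n_experiments: int
    replicate_rmses: dict[str, tuple[float, ...]]  # test-set name -> per-replicate RMSE

    def mean_rmse(self, test_set: str) -> float:
        return float(np.mean(self.replicate_rmses[test_set]))

    def sd_rmse(self, test_set: str) -> float:
        vals = self.replicate_rmses[test_set]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def _cell_seed(base_seed: int, size_index: int, replicate_index: int) -> int:
    """Independent, re-derivable seed for one (size, replicate) cell."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(size_index, replicate_index))
    return int(ss.generate_state(1)[0] % (2**31))


def downsample_experiments(
    groups: Sequence[ExperimentGroup], n: int, seed: int
) -> list[ExperimentGroup]:
    """Uniform random subset of n whole experiments (groups never split)."""
    if not 1 <= n <= len(groups):
        raise ValueError(f"n must be in [1, {len(groups)}], got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(groups), size=n, replace=False)
    return [groups[i] for i in sorted(idx)]


def learning_curve(
    groups: Sequence[ExperimentGroup],
    sizes: Sequence[int],
    replicates: int,
    config: ModelConfig,
    test_sets: Mapping[str, Sequence[ExperimentGroup]],
    base_seed: int = 0,
    val_fraction: float = 0.1,
) -> list[LearningCurvePoint]:
    """Test RMSE versus number of training experiments.

    Every (size, replicate) cell draws its own downsample and trains a fresh
    ensemble under an independently derived seed, so any cell can be re-run
    in isolation with identical results.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    test_records = {
        name: [(g.solute_smiles, g.solvent_smiles, r.temperature, r.log_s)
               for g in ts for r in g.records]
        for name, ts in test_sets.items()
    }

    points: list[LearningCurvePoint] = []
    for si, size in enumerate(sizes):
        per_set: dict[str, list[float]] = {name: [] for name in test_sets}
        for rep in range(replicates):
            seed = _cell_seed(base_seed, si, rep)
            subset = downsample_experiments(groups, size, seed=seed)
            try:
                ensemble = train_ensemble(subset, config, val_fraction=val_fraction,
                                          base_seed=seed)
            except Exception as exc:
                logger.error("learning_curve cell (size=%d, rep=%d) failed: %s",
                             size, rep, exc)
                raise
            for name, recs in test_records.items():
                solutes = [r[0] for r in recs]
                solvents = [r[1] for r in recs]
                temps = [r[2] for r in recs]
                truth = [r[3] for r in recs]
                mean, _ = ensemble.predict_batch(solutes, solvents, temps)
                per_set[name].append(rmse(truth, mean))
        points.append(
            LearningCurvePoint(
                n_experiments=size,
                replicate_rmses={k: tuple(v) for k, v in per_set.items()},
            )
        )
        logger.info("learning_curve size=%d: %s", size,
                    {k: round(float(np.mean(v)), 4) for k, v in per_set.items()})
    return points


@dataclass(frozen=True)
class PlateauReport:
    test_set: str
    plateau_size: int  # first size statistically at the final performance
    final_mean_rmse: float
    band: tuple[float, float]
    final_within_band: bool
    crossed_below_band: bool  # whether any mean RMSE fell below the band floor


def plateau_report(
    curve: Sequence[LearningCurvePoint],
    band: tuple[float, float],
    test_set: str | None = None,
) -> PlateauReport:
    """Locate the plateau of a learning curve relative to an aleatoric band.

    The plateau is the first size whose mean RMSE is within one final-size
    standard deviation of the final mean.  The report never claims sub-band
    performance: RMSE below the band floor is flagged, not celebrated, since
    differences inside the noise band are not discernible.
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 learning-curve points")
    if test_set is None:
        test_set = next(iter(curve[0].replicate_rmses))
    final = curve[-1]
    final_mean = final.mean_rmse(test_set)
    final_sd = final.sd_rmse(test_set)
    plateau_size = final.n_experiments
    for p in curve:
        if p.mean_rmse(test_set) <= final_mean + final_sd:
            plateau_size = p.n_experiments
            break
    means = [p.mean_rmse(test_set) for p in curve]
    low, high = band
    return PlateauReport(
        test_set=test_set,
        plateau_size=plateau_size,
        final_mean_rmse=final_mean,
        band=band,
        final_within_band=bool(low <= final_mean <= high),
        crossed_below_band=bool(min(means) < low),
    )


def curve_to_frame(curve: Sequence[LearningCurvePoint]) -> pd.DataFrame:
    """Long-format (size, replicate, test_set, rmse) table for export."""
    rows = []
    for p in curve:
        for name, vals in p.replicate_rmses.items():
            for rep, v in enumerate(vals):
                rows.append({"n_experiments": p.n_experiments, "replicate": rep,
                             "test_set": name, "rmse": v})
    return pd.DataFrame(rows)
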