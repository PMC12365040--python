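import numpy as np
import pytest

import thermosolv as ts
from thermosolv.featurization import (
    assemble_inputs,
    build_schema,
    fit_scaler,
    raw_solution_matrix,
)


@pytest.fixture(scope="session")
def schema():
    return build_schema("rdkit_core")


@pytest.fixture(scope="session")
def small_noiseless():
    """Small noiseless van't Hoff dataset with its ground truth."""
    spec = ts.SyntheticSpec(n_solutes=30, n_solvents=3, n_temperatures=5,
                            noise_sd=0.0, seed=11)
    records, truth = ts.generate(spec)
    return records, truth


@pytest.fixture(scope="session")
def small_groups(small_noiseless):
    records, _ = small_noiseless
    return ts.group_experiments(records)


@pytest.fixture(scope="session")
def tiny_ensemble(small_groups, schema):
    """A cheap trained ensemble for contract tests (not for accuracy checks)."""
    config = ts.ModelConfig(hidden_sizes=(32,), max_epochs=40, patience=10,
                            sobolev_weight=400.0, clamp_T=350.0)
    return ts.train_ensemble(small_groups, config, val_fraction=0.15, base_seed=3)


def held_out_arrays(groups):
    """Flatten experiment groups into aligned (solute, solvent, T, logS) lists."""
    solutes, solvents, temps, y = [], [], [], []
    for g in groups:
        for r in g.records:
            solutes.append(g.solute_smiles)
            solvents.append(g.solvent_smiles)
            temps.append(r.temperature)
            y.append(r.log_s)
    return solutes, solvents, np.array(temps), np.array(y)
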