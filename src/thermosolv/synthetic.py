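"""Download-free synthetic solubility datasets with known ground truth.

Each (solute, solvent) pair follows a van't Hoff law,

    log10 S(T) = a_ij + b_ij * (1000 / T) + noise,

with coefficients linear in five designated descriptors of the actual
molecules (standardized over the drawn set), so a descriptor-based model can
in principle learn them exactly.  The 1000/T parameterization keeps b_ij at
order 1; b_ij is centered at -1.2 (solubility increasing with temperature,
d log10 S/dT around +0.01 per kelvin near room temperature, as for typical
organic solutes).  Molecules are drawn from a shipped library of real
structures: common organic solutes plus substituted benzenes/naphthalenes,
and common laboratory solvents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import SolubilityRecord, canonicalize
from .featurization import build_schema, compute_descriptors

# Descriptors that carry the synthetic structure-property signal.
DESIGNATED_DESCRIPTORS = ("MolWt", "MolLogP", "TPSA", "NumRotatableBonds", "NumHDonors")

# Fixed coefficient-law weights (per standardized designated descriptor).
A0 = 3.0
WA_SOLUTE = np.array([0.55, -0.45, 0.35, 0.20, -0.25])
WA_SOLVENT = np.array([0.25, 0.45, -0.30, 0.10, 0.15])
B0 = -1.2
WB_SOLUTE = np.array([-0.12, 0.10, -0.08, 0.05, 0.06])
WB_SOLVENT = np.array([0.08, -0.10, 0.06, -0.04, 0.05])

_NAMED_SOLUTES = (
    "CC(=O)Nc1ccc(O)cc1",          # paracetamol
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",  # ibuprofen
    "CC(=O)Oc1ccccc1C(=O)O",       # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "c1ccc2ccccc2c1",              # naphthalene
    "c1ccc2cc3ccccc3cc2c1",        # anthracene
    "O=C1c2ccccc2C(=O)c2ccccc21",  # anthraquinone
    "c1ccc2c(c1)ccc1ccccc12",      # phenanthrene
    "c1ccc2c(c1)sc1ccccc12",       # dibenzothiophene
    "OC(=O)c1ccccc1O",             # salicylic acid
    "NC(=O)c1ccccc1",              # benzamide
    "OC(=O)c1ccccc1",              # benzoic acid
    "Nc1ccccc1C(=O)O",             # anthranilic acid
    "O=c1[nH]c(=O)c2[nH]cnc2[nH]1",  # uric acid
    "Nc1ccc(S(N)(=O)=O)cc1",       # sulfanilamide
    "OCC(O)CO",                    # glycerol
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",  # citric acid
    "OC(=O)C(O)C(O)C(=O)O",        # tartaric acid
    "NC(=O)N",                     # urea
    "NC(CO)(CO)CO",                # tris
    "OC1CCCCC1",                   # cyclohexanol
    "O=C1CCCCC1",                  # cyclohexanone
    "C1CCC2CCCCC2C1",              # decalin
    "Cc1ccc2cc(C)ccc2c1",          # 2,6-dimethylnaphthalene
    "O=C(O)CCCCCCCCC",             # decanoic acid
    "CCCCCCCCCCCCO",               # dodecanol
    "NC(Cc1ccccc1)C(=O)O",         # phenylalanine
    "NC(CC(C)C)C(=O)O",            # leucine
    "OC(=O)c1cccnc1",              # nicotinic acid
    "NC(=O)c1cccnc1",              # nicotinamide
    "Oc1ccc2ccccc2c1",             # 2-naphthol
    "Nc1ccc2ccccc2c1",             # 2-naphthylamine
    "O=C1NC(=O)NC(=O)C1",          # barbituric acid
    "CC(=O)NC1C(O)CC(O)(C(=O)O)CC1O",  # sialic-acid-like polyol acid
    "O=C1CC(c2ccccc2)Oc2ccccc21",  # flavanone
    "COc1cc(C=O)ccc1O",            # vanillin
    "CC12CCC(=O)C=C1CCC1C2CCC2(C)C(O)CCC12",  # testosterone-like steroid
    "OCC1OC(O)C(O)C(O)C1O",        # glucose
)

_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "I", "C#N", "[N+](=O)[O-]", "C(=O)O",
    "C(=O)N", "C(=O)C", "C(=O)OC", "OC(C)=O", "S", "SC", "C=C", "CO",
)


def _enumerate_solutes() -> tuple[str, ...]:
    """Library of real structures: named compounds + substituted aromatics."""
    smiles: list[str] = []
    for a in _SUBSTITUENTS:
        smiles.append(f"c1ccccc1{a}")  # monosubstituted benzene
        smiles.append(f"c1ccc2ccccc2c1{a}" if a != "C" else "Cc1ccc2ccccc2c1")
    for i, a in enumerate(_SUBSTITUENTS):
        for b in _SUBSTITUENTS[i:]:
            smiles.append(f"c1cc({a})ccc1{b}")  # disubstituted benzene
    smiles.extend(_NAMED_SOLUTES)
    seen: dict[str, None] = {}
    for smi in smiles:
        try:
            seen.setdefault(canonicalize(smi), None)
        except ValueError:  # defensive: enumeration should always parse
            continue
    return tuple(seen)


SOLVENT_LIBRARY: tuple[str, ...] = tuple(
    canonicalize(s)
    for s in (
        "O",                 # water
        "CO",                # methanol
        "CCO",               # ethanol
        "CCCO",              # 1-propanol
        "CC(C)O",            # isopropanol
        "CCCCO",             # 1-butanol
        "CC(C)=O",           # acetone
        "CCC(C)=O",          # methyl ethyl ketone
        "CC#N",              # acetonitrile
        "CCOC(C)=O",         # ethyl acetate
        "COC(C)=O",          # methyl acetate
        "C1CCOC1",           # tetrahydrofuran
        "O1CCOCC1",          # 1,4-dioxane
        "CCOCC",             # diethyl ether
        "CCCCCC",            # hexane
        "CCCCCCC",           # heptane
        "C1CCCCC1",          # cyclohexane
        "Cc1ccccc1",         # toluene
        "c1ccccc1",          # benzene
        "ClC(Cl)Cl",         # chloroform
        "ClCCl",             # dichloromethane
        "CN(C)C=O",          # DMF
        "CS(C)=O",           # DMSO
        "CC(=O)N(C)C",       # DMAc
        "OCCO",              # ethylene glycol
        "OCCOCCO",           # diethylene glycol
        "CC(O)=O",           # acetic acid
        "CCCCCCCCO",         # 1-octanol
        "Clc1ccccc1",        # chlorobenzene
        "COc1ccccc1",        # anisole
    )
)

SOLUTE_LIBRARY: tuple[str, ...] = _enumerate_solutes()


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise of one synthetic dataset."""

    n_solutes: int = 200
    n_solvents: int = 5
    n_temperatures: int = 5
    temp_range: tuple[float, float] = (280.0, 340.0)
    noise_sd: float = 0.3  # log10 units
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.temp_range
        if not (200.0 < lo < hi < 400.0):
            raise ValueError("temp_range must be increasing and within (200, 400) K")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_solutes < 1 or self.n_solvents < 1 or self.n_temperatures < 1:
            raise ValueError("counts must be positive")
        if self.n_solutes > len(SOLUTE_LIBRARY):
            raise ValueError(f"at most {len(SOLUTE_LIBRARY)} solutes available")
        if self.n_solvents > len(SOLVENT_LIBRARY):
            raise ValueError(f"at most {len(SOLVENT_LIBRARY)} solvents available")


def _designated_features(smiles: Sequence[str]) -> np.ndarray:
    """Standardized designated-descriptor matrix for a set of molecules."""
    schema = build_schema("rdkit_core")
    idx = [schema.index(name) for name in DESIGNATED_DESCRIPTORS]
    mat = np.stack([compute_descriptors(s, schema).values[idx] for s in smiles])
    loc = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (mat - loc) / scale


def generate(spec: SyntheticSpec) -> tuple[list[SolubilityRecord], dict[tuple[str, str], tuple[float, float]]]:
    """Generate records and the per-pair ground-truth (a_ij, b_ij)."""
    rng = np.random.default_rng(spec.seed)
    solutes = [SOLUTE_LIBRARY[i] for i in
               rng.choice(len(SOLUTE_LIBRARY), size=spec.n_solutes, replace=False)]
    solvents = [SOLVENT_LIBRARY[i] for i in
                rng.choice(len(SOLVENT_LIBRARY), size=spec.n_solvents, replace=False)]
    z_solute = _designated_features(solutes)
    z_solvent = _designated_features(solvents)

    temps = np.linspace(*spec.temp_range, spec.n_temperatures)
    records: list[SolubilityRecord] = []
    truth: dict[tuple[str, str], tuple[float, float]] = {}
    for i, solute in enumerate(solutes):
        for j, solvent in enumerate(solvents):
            a = A0 + float(WA_SOLUTE @ z_solute[i] + WA_SOLVENT @ z_solvent[j])
            b = B0 + float(WB_SOLUTE @ z_solute[i] + WB_SOLVENT @ z_solvent[j])
            truth[(solute, solvent)] = (a, b)
            source = f"synthetic:{i}-{j}"
            noise = rng.normal(0.0, spec.noise_sd, size=len(temps)) if spec.noise_sd > 0 \
                else np.zeros(len(temps))
            for T, eps in zip(temps, noise):
                records.append(
                    SolubilityRecord(
                        solute_smiles=solute,
                        solvent_smiles=solvent,
                        temperature=float(T),
                        log_s=float(a + b * (1000.0 / T) + eps),
                        source_id=source,
                    )
                )
    return records, truth


def true_gradient(b: float, temperature: float) -> float:
    """Analytic d log10 S / dT of the noiseless generator: -1000 b / T^2."""
    return -1000.0 * b / temperature**2


def write_truth_csv(truth: dict[tuple[str, str], tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(
        [{"solute_smiles": s, "solvent_smiles": v, "a": a, "b": b}
         for (s, v), (a, b) in truth.items()]
    ).to_csv(path, index=False)


def make_interlab_twin(
    records: Sequence[SolubilityRecord],
    n_groups: int,
    offset_sd: float,
    seed: int,
) -> list[SolubilityRecord]:
    """A second 'laboratory' re-measuring n_groups records with an offset.

    Returns a dataset whose records share (solute, solvent, T) with the
    chosen originals but carry fresh source_ids and log_s shifted by
    Normal(0, offset_sd) — a controlled test bed for duplicate detection
    and inter-laboratory variability statistics.
    """
    if not 0 < n_groups <= len(records):
        raise ValueError(f"n_groups must be in [1, {len(records)}], got {n_groups}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(records), size=n_groups, replace=False)
    twins = []
    for k, idx in enumerate(chosen):
        r = records[idx]
        twins.append(
            SolubilityRecord(
                solute_smiles=r.solute_smiles,
                solvent_smiles=r.solvent_smiles,
                temperature=r.temperature,
                log_s=r.log_s + float(rng.normal(0.0, offset_sd)) if offset_sd > 0 else r.log_s,
                source_id=f"synthetic-twin:{k}",
            )
        )
    return twins
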