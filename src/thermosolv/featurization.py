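"""Fixed molecular descriptors and assembly of solution inputs.

A solution is represented as the concatenation of the solute's descriptor
vector, the solvent's descriptor vector, and the temperature — one scaled
real vector per measurement.  Descriptors are RDKit 2-D descriptors; the
default schema is a curated core subset (fast, rarely undefined) and the
full RDKit set is available as ``rdkit_full``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import rdkit
from rdkit import Chem
from rdkit.Chem import Descriptors

from .data_io import ExperimentGroup, canonicalize

logger = logging.getLogger("thermosolv")

IMPUTATION_VALUE = 0.0  # replaces non-finite raw descriptor values, before scaling

# Curated 2-D descriptors: size/shape, polarity, H-bonding, flexibility,
# electronics.  MolWt and MolLogP (Wildman-Crippen) are required downstream
# as the cumulative-residual ordering features.
CORE_DESCRIPTORS = (
    "MolWt",
    "HeavyAtomCount",
    "MolLogP",
    "MolMR",
    "TPSA",
    "LabuteASA",
    "NumHAcceptors",
    "NumHDonors",
    "NumRotatableBonds",
    "NumAromaticRings",
    "NumSaturatedRings",
    "NumAliphaticRings",
    "RingCount",
    "FractionCSP3",
    "NOCount",
    "NHOHCount",
    "NumHeteroatoms",
    "BalabanJ",
    "BertzCT",
    "HallKierAlpha",
    "Kappa1",
    "Kappa2",
    "Kappa3",
    "Chi0",
    "Chi1",
    "Chi0n",
    "Chi1n",
    "Chi2n",
    "Chi3n",
    "Chi0v",
    "Chi1v",
    "Chi2v",
    "MaxEStateIndex",
    "MinEStateIndex",
    "MaxPartialCharge",
    "MinPartialCharge",
    "NumValenceElectrons",
    "qed",
)

_DESC_FUNCS = dict(Descriptors._descList)


@dataclass(frozen=True)
class DescriptorSchema:
    """An ordered, named set of descriptor functions (fixed length, versioned)."""

    schema_id: str
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def build_schema(name: str = "rdkit_core") -> DescriptorSchema:
    if name == "rdkit_core":
        return DescriptorSchema(schema_id=f"rdkit_core-v1-rdkit{rdkit.__version__}",
                                names=CORE_DESCRIPTORS)
    if name == "rdkit_full":
        return DescriptorSchema(schema_id=f"rdkit_full-v1-rdkit{rdkit.__version__}",
                                names=tuple(n for n, _ in Descriptors._descList))
    raise ValueError(f"unknown descriptor schema {name!r}")


@dataclass(frozen=True)
class DescriptorVector:
    values: np.ndarray  # finite after imputation
    schema_id: str


_desc_cache: dict[tuple[str, str], DescriptorVector] = {}


def compute_descriptors(smiles: str, schema: DescriptorSchema) -> DescriptorVector:
    """Descriptor vector for one molecule, cached by canonical SMILES.

    Raw non-finite values (descriptors undefined for the molecule) are
    replaced by ``IMPUTATION_VALUE`` so downstream algebra stays finite.
    """
    smiles = canonicalize(smiles)
    key = (smiles, schema.schema_id)
    hit = _desc_cache.get(key)
    if hit is not None:
        return hit
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # canonicalize already guards; belt and braces
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    values = np.empty(len(schema))
    for i, name in enumerate(schema.names):
        try:
            v = _DESC_FUNCS[name](mol)
        except Exception:
            v = float("nan")
        values[i] = v if (v is not None and np.isfinite(v)) else IMPUTATION_VALUE
    vec = DescriptorVector(values=values, schema_id=schema.schema_id)
    _desc_cache[key] = vec
    return vec


def prune_schema(schema: DescriptorSchema, smiles_list: Sequence[str],
                 max_nonfinite_fraction: float = 0.5) -> DescriptorSchema:
    """Drop descriptors that are undefined for most of the given molecules."""
    counts = np.zeros(len(schema))
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(canonicalize(smi))
        for i, name in enumerate(schema.names):
            try:
                v = _DESC_FUNCS[name](mol)
            except Exception:
                v = float("nan")
            if v is None or not np.isfinite(v):
                counts[i] += 1
    keep = counts / max(len(smiles_list), 1) <= max_nonfinite_fraction
    if keep.all():
        return schema
    dropped = [n for n, k in zip(schema.names, keep) if not k]
    logger.warning("pruning %d mostly-undefined descriptors: %s", len(dropped), dropped)
    return DescriptorSchema(
        schema_id=schema.schema_id + f"-pruned{len(dropped)}",
        names=tuple(n for n, k in zip(schema.names, keep) if k),
    )


def write_schema_manifest(schema: DescriptorSchema, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"schema_id": schema.schema_id, "rdkit_version": rdkit.__version__,
             "names": list(schema.names)},
            fh, indent=1,
        )


def read_schema_manifest(path: str | Path) -> DescriptorSchema:
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    return DescriptorSchema(schema_id=d["schema_id"], names=tuple(d["names"]))


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalerState:
    """Per-feature standardization fitted on training rows only."""

    location: np.ndarray  # per-feature mean
    scale: np.ndarray  # per-feature sample sd; zero-variance features get 1
    fitted_on: str  # fingerprint of the training rows

    @property
    def temperature_scale(self) -> float:
        """Scale of the temperature feature (last column) for chain-rule use."""
        return float(self.scale[-1])

    def transform(self, rows: np.ndarray) -> np.ndarray:
        return (rows - self.location) / self.scale


def fit_scaler(train_rows: np.ndarray | Sequence[DescriptorVector]) -> ScalerState:
    """Fit per-feature mean/sd on training rows (matrix or descriptor vectors)."""
    if not isinstance(train_rows, np.ndarray):
        if len(train_rows) == 0:
            raise ValueError("cannot fit a scaler on no rows")
        train_rows = np.stack([v.values for v in train_rows])
    if train_rows.ndim != 2 or train_rows.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >=2 rows to fit a scaler")
    location = train_rows.mean(axis=0)
    scale = train_rows.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    fingerprint = f"n={train_rows.shape[0]},d={train_rows.shape[1]},sum={train_rows.sum():.6g}"
    return ScalerState(location=location, scale=scale, fitted_on=fingerprint)


# ---------------------------------------------------------------------------
# Solution inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolutionInput:
    """One network input: scaled solute ⊕ solvent ⊕ temperature, with targets."""

    x: np.ndarray  # scaled, length 2*len(schema)+1
    y: float  # log10 S target
    g: float  # d log10 S / dT target (log10/K); NaN when masked
    solute_smiles: str
    solvent_smiles: str
    temperature: float  # unscaled kelvin (pre-clamp)

    @property
    def gradient_masked(self) -> bool:
        return not np.isfinite(self.g)


def temperature_feature_value(T: np.ndarray | float, kind: str) -> np.ndarray | float:
    """Temperature input feature: raw kelvin, or the van't Hoff axis 1000/T."""
    if kind == "kelvin":
        return T
    if kind == "inverse":
        return 1000.0 / T
    raise ValueError(f"unknown temperature feature {kind!r}")


def temperature_feature_derivative(T: np.ndarray | float, kind: str) -> np.ndarray | float:
    """d(feature)/dT, the chain-rule factor for gradients in log10/K."""
    if kind == "kelvin":
        return np.ones_like(np.asarray(T, dtype=float))
    if kind == "inverse":
        return -1000.0 / np.asarray(T, dtype=float) ** 2
    raise ValueError(f"unknown temperature feature {kind!r}")


def raw_solution_matrix(
    groups: Sequence[ExperimentGroup],
    schema: DescriptorSchema,
    clamp_T: float | None = None,
    temperature_feature: str = "kelvin",
) -> np.ndarray:
    """Unscaled [solute_desc ⊕ solvent_desc ⊕ T-feature] rows, one per record."""
    rows = []
    for g in groups:
        solute = compute_descriptors(g.solute_smiles, schema).values
        solvent = compute_descriptors(g.solvent_smiles, schema).values
        for r in g.records:
            T = min(r.temperature, clamp_T) if clamp_T is not None else r.temperature
            t_feat = temperature_feature_value(T, temperature_feature)
            rows.append(np.concatenate([solute, solvent, [t_feat]]))
    return np.stack(rows)


def assemble_inputs(
    groups: Sequence[ExperimentGroup],
    scaler: ScalerState,
    schema: DescriptorSchema,
    clamp_T: float | None = None,
    temperature_feature: str = "kelvin",
) -> list[SolutionInput]:
    """Build one SolutionInput per record, with finite-difference gradient targets.

    Gradient targets are computed on the unscaled experimental curves before
    any scaling; records from single-temperature experiments get a masked
    (NaN) gradient.  When ``clamp_T`` is set, the temperature feature
    saturates at min(T, clamp_T).
    """
    from .model import finite_difference_gradients  # local import to avoid a cycle

    raw = raw_solution_matrix(groups, schema, clamp_T=clamp_T,
                              temperature_feature=temperature_feature)
    scaled = scaler.transform(raw)
    out: list[SolutionInput] = []
    i = 0
    for g in groups:
        grads = finite_difference_gradients(g)
        for r, grad in zip(g.records, grads):
            out.append(
                SolutionInput(
                    x=scaled[i],
                    y=r.log_s,
                    g=grad,
                    solute_smiles=g.solute_smiles,
                    solvent_smiles=g.solvent_smiles,
                    temperature=r.temperature,
                )
            )
            i += 1
    return out
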