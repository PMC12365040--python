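"""Reading, curation, grouping and splitting of solubility tables.

The unit of everything downstream is the *experiment*: all measurements of
one solute in one solvent from one literature source, across temperature.
Experiments are the atoms of train/validation splitting (so a solute never
leaks across the split), of finite-difference temperature gradients, and of
the downsampling ladder in the aleatoric study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger("thermosolv")

RDLogger.DisableLog("rdApp.*")  # parse failures are reported by us, not rdkit

CELSIUS_OFFSET = 273.15

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolubilityRecord:
    """One solubility measurement: log10 S (mol/L) of a solute in a solvent at T."""

    solute_smiles: str
    solvent_smiles: str
    temperature: float  # kelvin
    log_s: float  # log10 mol/L
    source_id: str

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive kelvin, got {self.temperature}")
        if not np.isfinite(self.log_s):
            raise ValueError(f"log_s must be finite, got {self.log_s}")


@dataclass(frozen=True)
class ExperimentGroup:
    """All records sharing (solute, solvent, source), sorted by temperature."""

    solute_smiles: str
    solvent_smiles: str
    source_id: str
    records: tuple[SolubilityRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("an experiment group needs at least one record")
        temps = [r.temperature for r in self.records]
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ValueError("group temperatures must be strictly increasing")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records])

    @property
    def log_s_values(self) -> np.ndarray:
        return np.array([r.log_s for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DuplicateGroup:
    """Measurements of one (solute, solvent, ~temperature) from >=2 sources."""

    solute_smiles: str
    solvent_smiles: str
    temperature: float  # representative (mean) kelvin
    measurements: tuple[tuple[str, float], ...]  # (source_id, log_s)

    def __post_init__(self) -> None:
        sources = {s for s, _ in self.measurements}
        if len(sources) < 2:
            raise ValueError("a duplicate group needs measurements from >=2 sources")


@dataclass(frozen=True)
class SplitResult:
    train: tuple[ExperimentGroup, ...]
    validation: tuple[ExperimentGroup, ...]
    seed: int

    @property
    def train_solutes(self) -> set[str]:
        return {g.solute_smiles for g in self.train}

    @property
    def validation_solutes(self) -> set[str]:
        return {g.solute_smiles for g in self.validation}


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------

_canon_cache: dict[str, str] = {}


def canonicalize(smiles: str) -> str:
    """Return RDKit's canonical SMILES; same molecule -> same string.

    Raises ValueError naming the offending input if it does not parse.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    cached = _canon_cache.get(smiles)
    if cached is not None:
        return cached
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    out = Chem.MolToSmiles(mol)
    _canon_cache[smiles] = out
    _canon_cache[out] = out
    return out


# ---------------------------------------------------------------------------
# CSV ingestion — dataset dialects
# ---------------------------------------------------------------------------

_DIALECTS: dict | None = None


def dialect_config() -> dict:
    """Column maps for the supported dataset dialects (shipped YAML)."""
    global _DIALECTS
    if _DIALECTS is None:
        path = Path(__file__).with_name("dialects.yaml")
        with open(path, "r", encoding="utf-8") as fh:
            _DIALECTS = yaml.safe_load(fh)
    return _DIALECTS


def _to_kelvin(value: float, unit: str) -> float:
    if unit == "K":
        return float(value)
    if unit == "C":
        return float(value) + CELSIUS_OFFSET
    raise ValueError(f"unknown temperature unit {unit!r}")


def _to_log10_molar(value: float, representation: str) -> float:
    if representation == "log10_molar":
        return float(value)
    if representation == "molar":
        if value <= 0:
            return float("nan")
        return float(np.log10(value))
    raise ValueError(f"unknown solubility representation {representation!r}")


def read_solubility_csv(path: str | Path, dialect: str = "native") -> list[SolubilityRecord]:
    """Read a solubility table into canonical records.

    Rows with unparseable structures, missing temperature, non-finite
    solubility, or multi-component solvents are skipped and counted in the
    log.  Temperatures are converted to kelvin and solubility to log10 mol/L
    according to the dialect's declared units.
    """
    dialects = dialect_config()["dialects"]
    if dialect not in dialects:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(dialects)}")
    spec = dialects[dialect]
    cols = spec["columns"]

    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty input file: {path}")
    required = [c for c in cols.values() if c is not None]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dialect {dialect!r}: missing required columns {missing}")

    records: list[SolubilityRecord] = []
    skipped = {"structure": 0, "temperature": 0, "solubility": 0, "mixture": 0}
    default_T = spec.get("default_temperature_K")
    for row in df.to_dict("records"):  # dicts keep punctuated headers like "T,K"
        raw_solute = row[cols["solute_smiles"]]
        raw_solvent = row[cols["solvent_smiles"]]
        if not isinstance(raw_solute, str) or not isinstance(raw_solvent, str):
            skipped["structure"] += 1
            continue
        if "." in raw_solvent:  # multi-component solvent: out of scope
            skipped["mixture"] += 1
            continue
        try:
            solute = canonicalize(raw_solute)
            solvent = canonicalize(raw_solvent)
        except ValueError:
            skipped["structure"] += 1
            continue
        if cols["temperature"] is None:
            temperature = default_T
        else:
            temperature = row[cols["temperature"]]
            if temperature is None or not np.isfinite(float(temperature)):
                skipped["temperature"] += 1
                continue
            temperature = _to_kelvin(float(temperature), spec["temperature_unit"])
        log_s = _to_log10_molar(float(row[cols["solubility"]]), spec["solubility_representation"])
        if not np.isfinite(log_s):
            skipped["solubility"] += 1
            continue
        source = str(row[cols["source_id"]]) if cols["source_id"] else "unknown"
        records.append(
            SolubilityRecord(
                solute_smiles=solute,
                solvent_smiles=solvent,
                temperature=temperature,
                log_s=log_s,
                source_id=source,
            )
        )
    total_skipped = sum(skipped.values())
    if total_skipped:
        logger.warning(
            "read_solubility_csv(%s, dialect=%s): skipped %d rows (%s)",
            path, dialect, total_skipped,
            ", ".join(f"{k}={v}" for k, v in skipped.items() if v),
        )
    logger.info("read %d records from %s (dialect=%s)", len(records), path, dialect)
    return records


def write_solubility_csv(records: Sequence[SolubilityRecord], path: str | Path) -> None:
    """Write records in the native dialect (the round-trip inverse of reading)."""
    df = pd.DataFrame(
        {
            "solute_smiles": [r.solute_smiles for r in records],
            "solvent_smiles": [r.solvent_smiles for r in records],
            "temperature_K": [r.temperature for r in records],
            "logS": [r.log_s for r in records],
            "source_id": [r.source_id for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_duplicate_report(groups: Sequence[DuplicateGroup], path: str | Path) -> None:
    rows = []
    for i, g in enumerate(groups):
        for source, log_s in g.measurements:
            rows.append(
                {
                    "group": i,
                    "solute_smiles": g.solute_smiles,
                    "solvent_smiles": g.solvent_smiles,
                    "temperature_K": g.temperature,
                    "source_id": source,
                    "logS": log_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Leakage control, grouping, splitting
# ---------------------------------------------------------------------------


def drop_overlapping_solutes(
    train: Sequence[SolubilityRecord],
    *test_sets: Sequence[SolubilityRecord],
) -> list[SolubilityRecord]:
    """Drop training records whose solute occurs in any test set.

    Matching is on canonical solute structure only; shared solvents are fine
    (solvents are few and unavoidable).  May return an empty list.
    """
    test_solutes: set[str] = set()
    for ts in test_sets:
        test_solutes.update(r.solute_smiles for r in ts)
    kept = [r for r in train if r.solute_smiles not in test_solutes]
    n_dropped = len(train) - len(kept)
    if n_dropped:
        logger.warning("dropped %d training records with test-set solutes", n_dropped)
    if not kept:
        logger.warning("drop_overlapping_solutes removed every training record")
    return kept


def group_experiments(records: Sequence[SolubilityRecord]) -> list[ExperimentGroup]:
    """Partition records into experiments keyed by (solute, solvent, source).

    Replicate measurements at the same temperature within one experiment are
    merged to their mean log_s so each (pair, T) has a single target, which
    finite differences require.
    """
    by_key: dict[tuple[str, str, str], list[SolubilityRecord]] = {}
    for r in records:
        by_key.setdefault((r.solute_smiles, r.solvent_smiles, r.source_id), []).append(r)

    groups: list[ExperimentGroup] = []
    n_merged = 0
    for (solute, solvent, source), recs in by_key.items():
        by_temp: dict[float, list[float]] = {}
        for r in recs:
            by_temp.setdefault(r.temperature, []).append(r.log_s)
        merged = []
        for temp in sorted(by_temp):
            vals = by_temp[temp]
            n_merged += len(vals) - 1
            merged.append(
                SolubilityRecord(
                    solute_smiles=solute,
                    solvent_smiles=solvent,
                    temperature=temp,
                    log_s=float(np.mean(vals)),
                    source_id=source,
                )
            )
        groups.append(
            ExperimentGroup(
                solute_smiles=solute,
                solvent_smiles=solvent,
                source_id=source,
                records=tuple(merged),
            )
        )
    if n_merged:
        logger.info("merged %d same-temperature replicate records (mean logS)", n_merged)
    return groups


def split_by_solute(
    groups: Sequence[ExperimentGroup], val_fraction: float, seed: int
) -> SplitResult:
    """Split experiments so no solute appears on both sides.

    Solutes are shuffled with `seed`; the validation side accumulates whole
    solutes until it holds at least `val_fraction` of all records, so it is
    the smallest (by construction, prefix-minimal) solute subset reaching the
    requested share.
    """
    if not 0 < val_fraction < 1:
        raise ValueError(f"val_fraction must be in (0,1), got {val_fraction}")
    by_solute: dict[str, list[ExperimentGroup]] = {}
    for g in groups:
        by_solute.setdefault(g.solute_smiles, []).append(g)
    solutes = sorted(by_solute)
    if len(solutes) < 2:
        raise ValueError("need at least 2 distinct solutes to split by solute")

    n_records = sum(len(g) for g in groups)
    target = val_fraction * n_records
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(solutes))

    val_solutes: set[str] = set()
    val_count = 0
    for idx in order:
        if val_count >= target:
            break
        solute = solutes[idx]
        val_solutes.add(solute)
        val_count += sum(len(g) for g in by_solute[solute])

    train = tuple(g for g in groups if g.solute_smiles not in val_solutes)
    validation = tuple(g for g in groups if g.solute_smiles in val_solutes)
    return SplitResult(train=train, validation=validation, seed=seed)


# ---------------------------------------------------------------------------
# Inter-laboratory duplicates
# ---------------------------------------------------------------------------


def find_interlab_duplicates(
    datasets: Sequence[Sequence[SolubilityRecord]],
    temperature_tolerance: float = 0.1,
) -> list[DuplicateGroup]:
    """Find (solute, solvent, ~T) measured by more than one literature source.

    Records from all datasets are pooled, keyed by (solute, solvent), and
    clustered along temperature by single linkage with the given tolerance.
    Clusters containing >=2 distinct source_ids become DuplicateGroups.
    """
    if temperature_tolerance < 0:
        raise ValueError("temperature_tolerance must be nonnegative")
    pooled: dict[tuple[str, str], list[SolubilityRecord]] = {}
    for ds in datasets:
        for r in ds:
            pooled.setdefault((r.solute_smiles, r.solvent_smiles), []).append(r)

    out: list[DuplicateGroup] = []
    for (solute, solvent), recs in sorted(pooled.items()):
        recs = sorted(recs, key=lambda r: r.temperature)
        # single-linkage chains along temperature
        clusters: list[list[SolubilityRecord]] = []
        for r in recs:
            if clusters and r.temperature - clusters[-1][-1].temperature <= temperature_tolerance:
                clusters[-1].append(r)
            else:
                clusters.append([r])
        for cluster in clusters:
            sources = {r.source_id for r in cluster}
            if len(sources) < 2:
                continue
            out.append(
                DuplicateGroup(
                    solute_smiles=solute,
                    solvent_smiles=solvent,
                    temperature=float(np.mean([r.temperature for r in cluster])),
                    measurements=tuple((r.source_id, r.log_s) for r in cluster),
                )
            )
    return out


def interlab_variability(groups: Sequence[DuplicateGroup]) -> tuple[float, float]:
    """Summarize inter-laboratory spread as (mean_std, rmse), both in log10 units.

    mean_std averages the within-group sample standard deviation (ddof=1)
    over groups.  rmse pools squared log_s differences over every ordered
    cross-source pair of measurements within each group, then takes the root
    of the pooled mean — an error-like analogue of the same spread.
    """
    if not groups:
        raise ValueError("no duplicate groups given")
    stds = []
    sq_diffs: list[float] = []
    for g in groups:
        vals = np.array([v for _, v in g.measurements])
        if len(vals) < 2:
            raise ValueError("every duplicate group needs >=2 measurements")
        stds.append(float(np.std(vals, ddof=1)))
        for i, (src_i, v_i) in enumerate(g.measurements):
            for j, (src_j, v_j) in enumerate(g.measurements):
                if i != j and src_i != src_j:
                    sq_diffs.append((v_i - v_j) ** 2)
    mean_std = float(np.mean(stds))
    rmse = float(np.sqrt(np.mean(sq_diffs))) if sq_diffs else 0.0
    return mean_std, rmse
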