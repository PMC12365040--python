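"""Ingestion, canonicalization, grouping, splitting and duplicate curation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermosolv as ts
from thermosolv.data_io import SolubilityRecord, write_solubility_csv


def rec(solute="CCO", solvent="O", T=298.15, log_s=-1.0, source="a"):
    return SolubilityRecord(
        solute_smiles=ts.canonicalize(solute),
        solvent_smiles=ts.canonicalize(solvent),
        temperature=T,
        log_s=log_s,
        source_id=source,
    )


class TestCanonicalize:
    @pytest.mark.parametrize(
        "a,b",
        [("CCO", "OCC"), ("c1ccccc1", "C1=CC=CC=C1"), ("CC(=O)O", "OC(C)=O")],
    )
    def test_same_molecule_same_string(self, a, b):
        assert ts.canonicalize(a) == ts.canonicalize(b)

    def test_unparseable_raises_naming_input(self):
        with pytest.raises(ValueError, match="C\\("):
            ts.canonicalize("C(")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ts.canonicalize("")

    @given(st.sampled_from(ts.SOLUTE_LIBRARY))
    @settings(max_examples=30, deadline=None)
    def test_idempotent(self, smi):
        once = ts.canonicalize(smi)
        assert ts.canonicalize(once) == once


class TestReadCsv:
    def test_native_roundtrip(self, tmp_path):
        records = [rec(), rec(solute="c1ccccc1", T=310.0, log_s=-2.5, source="b")]
        path = tmp_path / "native.csv"
        write_solubility_csv(records, path)
        back = ts.read_solubility_csv(path, "native")
        assert back == records

    def test_unparseable_row_skipped_and_logged(self, tmp_path, caplog):
        path = tmp_path / "bad.csv"
        path.write_text(
            "solute_smiles,solvent_smiles,temperature_K,logS,source_id\n"
            "CCO,O,298.15,-1.0,a\n"
            "C(,O,298.15,-1.0,a\n"
        )
        with caplog.at_level("WARNING", logger="thermosolv"):
            out = ts.read_solubility_csv(path, "native")
        assert len(out) == 1
        assert "skipped 1 rows" in caplog.text

    def test_solvent_mixture_skipped(self, tmp_path):
        path = tmp_path / "mix.csv"
        path.write_text(
            "solute_smiles,solvent_smiles,temperature_K,logS,source_id\n"
            "CCO,CCO.O,298.15,-1.0,a\n"
            "CCO,O,298.15,-1.0,a\n"
        )
        out = ts.read_solubility_csv(path, "native")
        assert len(out) == 1 and out[0].solvent_smiles == "O"

    def test_molar_dialect_takes_log10(self, tmp_path):
        path = tmp_path / "big.csv"
        path.write_text('SMILES,SMILES_Solvent,"T,K",Solubility,Source\nCCO,O,298.15,0.01,x\n')
        (record,) = ts.read_solubility_csv(path, "bigsoldb")
        assert record.log_s == pytest.approx(-2.0)

    def test_leeds_dialect_constant_temperature(self, tmp_path):
        path = tmp_path / "leeds.csv"
        path.write_text("SMILES,Solvent_SMILES,LogS,Source\nCCO,O,-1.2,y\n")
        (record,) = ts.read_solubility_csv(path, "leeds")
        assert record.temperature == pytest.approx(298.15)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("solute_smiles,solvent_smiles\nCCO,O\n")
        with pytest.raises(ValueError, match="missing required columns"):
            ts.read_solubility_csv(path, "native")

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("a\n1\n")
        with pytest.raises(ValueError, match="unknown dialect"):
            ts.read_solubility_csv(path, "nope")


class TestDropOverlap:
    def test_overlapping_solutes_removed(self):
        train = [rec(solute="CCO"), rec(solute="c1ccccc1")]
        test = [rec(solute="OCC")]  # ethanol written differently
        kept = ts.drop_overlapping_solutes(train, test)
        assert [r.solute_smiles for r in kept] == [ts.canonicalize("c1ccccc1")]

    def test_empty_test_sets_identity(self):
        train = [rec(), rec(solute="C1CCCCC1")]
        assert ts.drop_overlapping_solutes(train) == train

    def test_idempotent_and_order_independent(self):
        train = [rec(solute=s) for s in ("CCO", "CCCO", "c1ccccc1", "CC(C)O")]
        t1 = [rec(solute="CCO")]
        t2 = [rec(solute="c1ccccc1")]
        once = ts.drop_overlapping_solutes(train, t1, t2)
        assert ts.drop_overlapping_solutes(once, t1, t2) == once
        assert ts.drop_overlapping_solutes(train, t2, t1) == once


class TestGroupExperiments:
    def test_one_experiment_sorted(self):
        records = [rec(T=310.0), rec(T=290.0), rec(T=300.0)]
        (group,) = ts.group_experiments(records)
        assert list(group.temperatures) == [290.0, 300.0, 310.0]

    def test_sources_kept_apart(self):
        records = [rec(source="a"), rec(source="b")]
        assert len(ts.group_experiments(records)) == 2

    def test_same_temperature_replicates_averaged(self):
        records = [rec(log_s=-1.0), rec(log_s=-1.2)]
        (group,) = ts.group_experiments(records)
        assert group.records[0].log_s == pytest.approx(-1.1)

    def test_record_count_conserved(self, small_noiseless):
        records, _ = small_noiseless
        groups = ts.group_experiments(records)
        assert sum(len(g) for g in groups) <= len(records)
        assert {(g.solute_smiles, g.solvent_smiles, g.source_id) for g in groups} == {
            (r.solute_smiles, r.solvent_smiles, r.source_id) for r in records
        }


class TestSplitBySolute:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_leak_free_for_any_seed(self, small_groups, seed):
        split = ts.split_by_solute(small_groups, 0.1, seed=seed)
        assert not (split.train_solutes & split.validation_solutes)
        assert len(split.train) + len(split.validation) == len(small_groups)

    def test_deterministic(self, small_groups):
        a = ts.split_by_solute(small_groups, 0.1, seed=7)
        b = ts.split_by_solute(small_groups, 0.1, seed=7)
        assert a == b

    def test_validation_share_close_to_requested(self):
        # balanced: 100 solutes, one single-record experiment each
        records = [rec(solute=s, source="s") for s in ts.SOLUTE_LIBRARY[:100]]
        groups = ts.group_experiments(records)
        split = ts.split_by_solute(groups, 0.05, seed=0)
        frac = sum(len(g) for g in split.validation) / len(records)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_single_solute_errors(self):
        groups = ts.group_experiments([rec()])
        with pytest.raises(ValueError):
            ts.split_by_solute(groups, 0.1, seed=0)


class TestInterlab:
    def test_two_sources_same_conditions_grouped(self):
        a = [rec(source="a")]
        b = [rec(source="b", log_s=-1.5)]
        (dup,) = ts.find_interlab_duplicates([a, b], temperature_tolerance=0.1)
        assert len(dup.measurements) == 2

    def test_same_source_not_a_duplicate(self):
        a = [rec(source="a"), rec(source="a", log_s=-1.5)]
        assert ts.find_interlab_duplicates([a], temperature_tolerance=0.1) == []

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            ts.find_interlab_duplicates([[rec()]], temperature_tolerance=-1.0)

    def test_variability_identical_measurements(self):
        a = [rec(source="a")]
        b = [rec(source="b")]
        dups = ts.find_interlab_duplicates([a, b], 0.1)
        assert ts.interlab_variability(dups) == (0.0, 0.0)

    def test_variability_single_pair(self):
        a = [rec(source="a", log_s=-1.0)]
        b = [rec(source="b", log_s=-1.6)]
        dups = ts.find_interlab_duplicates([a, b], 0.1)
        mean_std, pooled = ts.interlab_variability(dups)
        assert mean_std == pytest.approx(0.6 / np.sqrt(2), abs=1e-4)
        assert pooled == pytest.approx(0.6, abs=1e-10)

    def test_variability_two_groups_pools_pairs(self):
        g1a = [rec(source="a", log_s=0.0)]
        g1b = [rec(source="b", log_s=0.0)]
        g2a = [rec(solute="c1ccccc1", source="a", log_s=-1.0)]
        g2b = [rec(solute="c1ccccc1", source="b", log_s=-1.6)]
        dups = ts.find_interlab_duplicates([g1a + g2a, g1b + g2b], 0.1)
        mean_std, pooled = ts.interlab_variability(dups)
        assert mean_std == pytest.approx(0.2121, abs=1e-4)
        assert pooled == pytest.approx(0.4243, abs=1e-4)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ts.interlab_variability([])
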