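"""Curation pipeline: unit conversion, canonicalization, deduplication."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepsol.curation import (
    CompoundRecord,
    CuratedDataset,
    RDKitBackend,
    SolubilityUnit,
    canonicalize_and_key,
    convert_to_logs,
    curate,
    deduplicate,
    logs_to_value,
    parse_compound_table,
)


@pytest.fixture(scope="module")
def backend():
    return RDKitBackend()


class TestConvertToLogs:
    def test_one_molar_is_zero(self):
        assert convert_to_logs(1.0, SolubilityUnit.MOL_PER_L) == 0.0

    def test_mg_per_ml(self):
        # 1 mg/mL = 1 g/L = 0.01 mol/L at MW 100
        assert convert_to_logs(1.0, SolubilityUnit.MG_PER_ML, 100.0) == pytest.approx(-2.0)

    def test_ug_per_ml(self):
        # 100 ug/mL = 0.1 g/L = 1e-3 mol/L at MW 100
        assert convert_to_logs(100.0, SolubilityUnit.UG_PER_ML, 100.0) == pytest.approx(-3.0)

    def test_zero_value_rejected(self):
        with pytest.raises(ValueError):
            convert_to_logs(0.0, SolubilityUnit.MOL_PER_L)

    def test_mass_unit_without_mw_is_hard_error(self):
        with pytest.raises(ValueError, match="molecular weight"):
            convert_to_logs(1.0, SolubilityUnit.G_PER_L, None)

    @settings(deadline=None, max_examples=100)
    @given(
        value=st.floats(1e-9, 1e4),
        unit=st.sampled_from(list(SolubilityUnit)),
        mw=st.floats(20.0, 1500.0),
    )
    def test_round_trip(self, value, unit, mw):
        log_s = convert_to_logs(value, unit, mw)
        back = logs_to_value(log_s, unit, mw)
        assert math.isclose(back, value, rel_tol=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        v=st.floats(1e-6, 1e3), delta=st.floats(1e-6, 10.0),
        unit=st.sampled_from(list(SolubilityUnit)),
    )
    def test_strictly_increasing_in_value(self, v, delta, unit):
        assert convert_to_logs(v + delta, unit, 250.0) > convert_to_logs(v, unit, 250.0)


class TestParseCompoundTable:
    def _write(self, tmp_path, text, name="t.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_basic_parse(self, tmp_path):
        p = self._write(tmp_path, "id,smiles,solubility,unit\na,CCO,1,mol/L\nb,CC,2,g/L\nc,C,3,mg/L\n")
        ds = parse_compound_table(p)
        assert len(ds.records) == 3
        assert ds.records[2].solubility_unit is SolubilityUnit.MG_PER_L

    def test_negative_value_logged_not_dropped_silently(self, tmp_path):
        p = self._write(tmp_path, "id,smiles,solubility,unit\na,CCO,-1.5,mol/L\n")
        ds = parse_compound_table(p)
        assert not ds.records[0].valid
        reasons = [e for e in ds.provenance_log if e.get("action") == "reject_row"]
        assert len(reasons) == 1 and "negative" in reasons[0]["reason"]

    def test_censored_marker(self, tmp_path):
        p = self._write(tmp_path, "id,smiles,solubility,unit\na,CCO,<0.01,mg/mL\n")
        ds = parse_compound_table(p)
        assert ds.records[0].censored and ds.records[0].solubility_value == 0.01

    def test_missing_column_is_config_error(self, tmp_path):
        p = self._write(tmp_path, "id,smiles,value\na,CCO,1\n")
        with pytest.raises(KeyError, match="solubility"):
            parse_compound_table(p)

    def test_empty_file_explicit_error(self, tmp_path):
        p = self._write(tmp_path, "id,smiles,solubility,unit\n")
        with pytest.raises(ValueError, match="empty"):
            parse_compound_table(p)


class TestCanonicalization:
    def test_same_molecule_same_key(self, backend):
        ds = CuratedDataset(records=[
            CompoundRecord("a", "OCC", 1.0, SolubilityUnit.MOL_PER_L),
            CompoundRecord("b", "CCO", 1.0, SolubilityUnit.MOL_PER_L),
        ])
        canonicalize_and_key(ds, backend)
        a, b = ds.records
        assert a.canonical_smiles == b.canonical_smiles
        assert a.inchikey == b.inchikey and len(a.inchikey) == 27

    def test_kekule_and_aromatic_benzene_agree(self, backend):
        ds = CuratedDataset(records=[
            CompoundRecord("a", "c1ccccc1", 1.0, SolubilityUnit.MOL_PER_L),
            CompoundRecord("b", "C1=CC=CC=C1", 1.0, SolubilityUnit.MOL_PER_L),
        ])
        canonicalize_and_key(ds, backend)
        assert ds.records[0].inchikey == ds.records[1].inchikey

    def test_malformed_smiles_flagged(self, backend):
        ds = CuratedDataset(records=[CompoundRecord("a", "C1CC", 1.0, SolubilityUnit.MOL_PER_L)])
        canonicalize_and_key(ds, backend)
        assert not ds.records[0].valid
        assert any(e["action"] == "reject_smiles" for e in ds.provenance_log)

    def test_mw_computed_and_logs_derived(self, backend):
        ds = CuratedDataset(records=[CompoundRecord("a", "CCO", 46.0, SolubilityUnit.G_PER_L)])
        canonicalize_and_key(ds, backend)
        rec = ds.records[0]
        assert rec.molecular_weight == pytest.approx(46.07, abs=0.1)
        assert rec.log_s == pytest.approx(0.0, abs=0.01)  # ~1 mol/L


class TestDeduplicate:
    def _mk(self, cid, key, log_s):
        return CompoundRecord(cid, "CCO", 1.0, SolubilityUnit.MOL_PER_L,
                              inchikey=key, log_s=log_s, molecular_weight=46.07)

    KEY = "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"

    def test_identical_duplicates_keep_first(self):
        ds = CuratedDataset(records=[self._mk("a", self.KEY, -2.0), self._mk("b", self.KEY, -2.0)])
        out = deduplicate(ds)
        assert [r.compound_id for r in out.records] == ["a"]

    def test_conflicting_duplicates_keep_median(self):
        ds = CuratedDataset(records=[
            self._mk("a", self.KEY, -2.0),
            self._mk("b", self.KEY, -2.4),
            self._mk("c", self.KEY, -3.0),
        ])
        out = deduplicate(ds)
        assert len(out.records) == 1
        assert out.records[0].log_s == pytest.approx(-2.4)
        assert any(e["action"] == "median_logS" for e in out.provenance_log)

    def test_idempotent(self):
        ds = CuratedDataset(records=[
            self._mk("a", self.KEY, -2.0),
            self._mk("b", self.KEY, -2.5),
            self._mk("c", "ZZZZZZZZZZZZZZ-ZZZZZZZZZZ-Z", -1.0),
        ])
        once = deduplicate(ds)
        twice = deduplicate(once)
        assert [(r.compound_id, r.log_s) for r in once.records] == \
               [(r.compound_id, r.log_s) for r in twice.records]

    def test_censored_records_untouched(self):
        cens = CompoundRecord("x", "CCO", 0.01, SolubilityUnit.MG_PER_ML,
                              inchikey=self.KEY, censored=True)
        ds = CuratedDataset(records=[self._mk("a", self.KEY, -2.0), cens])
        out = deduplicate(ds)
        assert len(out.records) == 2


class TestFullPipeline:
    def test_fixture_curates_to_18_records(self, fixture_dir):
        ds = curate(fixture_dir / "fixture_compounds.csv")
        assert len(ds.valid_records) == 18
        assert len(ds.modeling_records) == 17  # one censored record retained but excluded
        assert sum(1 for r in ds.valid_records if r.censored) == 1

    def test_record_count_conservation(self, fixture_dir):
        ds = curate(fixture_dir / "fixture_compounds.csv")
        removed_invalid = sum(1 for e in ds.provenance_log
                              if e["action"] in ("reject_row", "reject_smiles", "reject_conversion"))
        removed_dup = sum(1 for e in ds.provenance_log if e["action"] == "remove_duplicate")
        assert len(ds.valid_records) + removed_invalid + removed_dup == 20

    def test_curated_csv_round_trip(self, fixture_dir, tmp_path):
        from deepsol.curation import read_curated_csv

        ds = curate(fixture_dir / "fixture_compounds.csv")
        out = tmp_path / "curated.csv"
        ds.write_csv(out)
        back = read_curated_csv(out)
        assert len(back.records) == 18
        orig = {r.compound_id: r.log_s for r in ds.modeling_records}
        loaded = {r.compound_id: r.log_s for r in back.modeling_records}
        assert orig.keys() == loaded.keys()
        for k in orig:
            assert loaded[k] == pytest.approx(orig[k], abs=1e-9)
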