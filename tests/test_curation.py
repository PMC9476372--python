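import pytest

from tmsid.curation import (CompoundRecord, classify_structure,
                            count_tms_groups, filter_high_mass,
                            quality_filter, run_curation)
from tmsid.synthetic_data import GeneratorConfig, make_planted_library

from conftest import spec_from_pairs


def rec(smiles, **kw):
    return CompoundRecord(record_id=kw.pop("record_id", "r"), structure=smiles, **kw)


class TestClassifyStructure:
    @pytest.mark.parametrize("smiles,category", [
        ("C[Si](C)(C)[Si](C)(C)C", "si_si_bond"),
        ("C[Si](C)(C)CCCC", "c_si_bond"),
        ("C[Si](C)(C)O[Si](C)(C)C", "o_si_non_hydroxyl_carboxyl"),
        ("C[Si](C)(C)ON=CC", "n_o_si_or_n_n_si"),
        ("C[Si](C)(C)OP(=O)(OC)OC", "p_si_linkage"),
        ("C[Si](C)(C)OC(=CC)C", "rearrangement_tms"),
        ("CC(C)(C)[Si](C)(C)OCC", "tbdms"),
        ("CC(C)(C)[Si](C)(C)OCCO[Si](C)(C)C", "mixed_tms_tbdms"),
        ("Cl[Si](C)(C)C", "derivatization_agent"),
        ("FC(F)(F)C(=O)N(C)[Si](C)(C)C", "derivatization_agent"),
    ])
    def test_exclusion_categories(self, smiles, category):
        assert classify_structure(rec(smiles)) == ("exclude", category)

    @pytest.mark.parametrize("smiles", [
        "C[Si](C)(C)Oc1ccccc1",                            # phenol O-TMS
        "CCCCCCCCO[Si](C)(C)C",                            # aliphatic O-TMS
        "C[Si](C)(C)OC(=O)c1ccccc1",                       # carboxyl O-TMS
        "C[Si](C)(C)NCCc1ccccc1",                          # secondary-amine N-TMS
        "CCCCCCS[Si](C)(C)C",                              # thiol S-TMS
        "CC(C)CC(N[Si](C)(C)C)C(=O)O[Si](C)(C)C",          # amino acid, mixed
    ])
    def test_canonical_tms_motifs_always_retained(self, smiles):
        assert classify_structure(rec(smiles)) == ("retain", None)

    def test_unparsable_structure(self):
        with pytest.raises(ValueError):
            classify_structure(rec("C("))


def test_count_tms_groups():
    assert count_tms_groups(rec("C[Si](C)(C)Oc1ccccc1").mol()) == 1
    assert count_tms_groups(
        rec("C[Si](C)(C)OC(=O)c1ccccc1O[Si](C)(C)C").mol()) == 2
    # silyl on carbon is not a derivatization TMS group
    assert count_tms_groups(rec("C[Si](C)(C)CCCC").mol()) == 0


class TestHighMassFilter:
    def test_thresholds(self):
        records = [rec("C", record_id="a", mw=1050.0),
                   rec("C", record_id="b", mw=575.0),
                   rec("C", record_id="c", mw=1000.0)]
        kept, removed, review = filter_high_mass(records)
        assert {r.record_id for r in removed} == {"a"}
        assert {r.record_id for r in kept} == {"b", "c"}  # ">" keeps 1000
        kept, removed, _ = filter_high_mass(records, mode=">=")
        assert {r.record_id for r in removed} == {"a", "c"}

    def test_missing_mw_needs_review(self):
        kept, removed, review = filter_high_mass([rec("C", mw=None)])
        assert not kept and not removed and len(review) == 1


class TestQualityFilter:
    def _good(self, mw=300.0):
        frags = [(60 + 13 * i, 50.0) for i in range(5)]
        return spec_from_pairs(
            [(73, 999), (147, 400), (mw, 100), (mw + 1, 20), (mw + 10, 1)] + frags,
            mw=mw)

    def test_constructed_spectrum_passes_all_four(self):
        assert quality_filter(self._good(), mw=300.0, n_tms=2).passed

    def test_four_peak_spectrum_fails_fragment_count(self):
        s = spec_from_pairs([(73, 10), (147, 5), (300, 10), (301, 2)], mw=300.0,
                            extra={"AcqMzMax": "800"})
        res = quality_filter(s, mw=300.0, n_tms=1)
        assert res.violations == ["fragment_count"]

    def test_missing_markers_fails(self):
        s = self._good()
        s = spec_from_pairs([(p.mz, p.intensity) for p in s.peaks
                             if p.mz not in (73, 147)], mw=300.0)
        res = quality_filter(s, mw=300.0, n_tms=1)
        assert "tms_markers" in res.violations

    def test_missing_molecular_ion_fails(self):
        s = spec_from_pairs([(73, 999), (147, 10)] +
                            [(60 + 7 * i, 5) for i in range(6)],
                            mw=300.0, extra={"AcqMzMax": "800"})
        res = quality_filter(s, mw=300.0, n_tms=1)
        assert "molecular_ion_isotope" in res.violations

    def test_acquisition_range_metadata_overrides_proxy(self):
        s = spec_from_pairs([(73, 999), (300, 100), (301, 20)] +
                            [(60 + 7 * i, 5) for i in range(5)],
                            mw=300.0, extra={"AcqMzMax": "305"})
        assert "acquisition_range" in quality_filter(s, 300.0, 1).violations
        s2 = spec_from_pairs([(p.mz, p.intensity) for p in s.peaks], mw=300.0,
                             extra={"AcqMzMax": "800"})
        assert "acquisition_range" not in quality_filter(s2, 300.0, 1).violations

    def test_strict_marker_mode(self):
        s = self._good()  # has 73 and 147 only
        assert quality_filter(s, 300.0, n_tms=3, strict_markers=True).violations \
            == ["tms_markers"]  # needs 221 for 3 TMS
        assert quality_filter(s, 300.0, n_tms=2, strict_markers=True).passed


class TestRunCuration:
    def test_planted_toy_library(self):
        """2 siloxanes + 1 overweight + 2 four-peak spectra planted in a
        10-record library: removals match the plan, 5 survive."""
        cfg = GeneratorConfig(master_seed=5)
        records, plan = make_planted_library(
            cfg, {"si_si_bond": 2, "high_mass": 1, "fragment_count": 2},
            n_clean=5, seed=5)
        assert len(records) == 10
        report = run_curation(records)
        assert report.n_input == 10 and report.n_output == 5
        assert report.per_step_removed["step1_structure"] == {"si_si_bond": 2}
        assert report.per_step_removed["step2_high_mass"] == {"high_mass": 1}
        assert report.per_step_removed["step3_quality"] == {"fragment_count": 2}
        assert report.check_conservation()

    def test_all_valid_library_is_noop(self):
        cfg = GeneratorConfig(master_seed=6)
        records, _ = make_planted_library(cfg, {}, n_clean=6, seed=6)
        report = run_curation(records)
        assert report.n_output == report.n_input == 6
        # rerunning curation on its own output removes nothing further
        again = run_curation(report.curated)
        assert again.n_output == again.n_input == 6
        assert all(v == "kept" for v in again.audit.values())

    def test_empty_input(self):
        report = run_curation([])
        assert report.n_input == 0 == report.n_output
        assert report.check_conservation()

    def test_erroneous_entry_inchikey_mismatch(self):
        cfg = GeneratorConfig(master_seed=7)
        records, _ = make_planted_library(cfg, {}, n_clean=2, seed=7)
        records[0].inchikey = "XXXXXXXXXXXXXX-UHFFFAOYSA-N"
        report = run_curation(records)
        assert report.per_step_removed["step1_structure"] == {"erroneous_entry": 1}
        assert report.n_output == 1

    def test_spectra_clamped_in_output(self):
        cfg = GeneratorConfig(master_seed=8)
        records, _ = make_planted_library(cfg, {}, n_clean=4, seed=8)
        report = run_curation(records)
        for r in report.curated:
            assert all(50.0 <= p.mz <= r.mw + 10.0 for p in r.spectrum.peaks)
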