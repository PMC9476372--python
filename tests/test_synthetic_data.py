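import dataclasses

import numpy as np
import pytest

from tmsid.curation import quality_filter
from tmsid.fingerprints import compute_fingerprint
from tmsid.similarity import bin_spectrum, cosine
from tmsid.synthetic_data import (GeneratorConfig, generate_compounds,
                                  make_candidate_set, make_planted_library,
                                  make_replicates, simulate_spectrum,
                                  template_pool, _informative_columns,
                                  _record_from_entry)

CFG = GeneratorConfig(master_seed=0)


def pool_records():
    return [_record_from_entry(e, i)
            for i, e in enumerate(template_pool(CFG.mw_range, CFG.n_tms_range))]


class TestCompounds:
    def test_same_seed_identical(self):
        a = generate_compounds(CFG, 20, np.random.default_rng(9))
        b = generate_compounds(CFG, 20, np.random.default_rng(9))
        assert [r.structure for r in a] == [r.structure for r in b]
        assert [r.record_id for r in a] == [r.record_id for r in b]

    def test_zero_compounds(self):
        assert generate_compounds(CFG, 0) == []

    def test_mw_within_configured_range(self):
        lo, hi = CFG.mw_range
        for r in generate_compounds(CFG, 40, np.random.default_rng(1)):
            assert lo <= r.mw <= hi
            assert CFG.n_tms_range[0] <= r.n_tms <= CFG.n_tms_range[1]

    def test_structures_parse_and_are_unique(self):
        recs = generate_compounds(CFG, 60, np.random.default_rng(2))
        keys = [r.inchikey for r in recs]
        assert len(set(keys)) == len(keys)


class TestSimulateSpectrum:
    def test_noise_free_core_is_seed_independent(self):
        cfg = dataclasses.replace(CFG, intensity_noise_sd=0.0,
                                  peak_dropout_p=0.0, background_peaks=0)
        (rec,) = generate_compounds(cfg, 1, np.random.default_rng(3))
        s1 = simulate_spectrum(rec, cfg, seed=1)
        s2 = simulate_spectrum(rec, cfg, seed=999)
        assert [(p.mz, p.intensity) for p in s1.peaks] == \
               [(p.mz, p.intensity) for p in s2.peaks]

    def test_low_noise_spectra_pass_quality_filter(self):
        """100 draws under the default config all satisfy the four
        spectral-quality criteria (oracle: the quality filter itself)."""
        rng = np.random.default_rng(4)
        recs = generate_compounds(CFG, 20, rng)
        n_pass = 0
        for i in range(100):
            rec = recs[i % len(recs)]
            s = simulate_spectrum(rec, CFG, seed=int(rng.integers(2**31)))
            n_pass += quality_filter(s, rec.mw, rec.n_tms).passed
        assert n_pass == 100

    def test_markers_molecular_ion_present(self):
        rng = np.random.default_rng(5)
        for rec in generate_compounds(CFG, 5, rng):
            s = simulate_spectrum(rec, CFG, seed=7)
            mzs = {p.mz for p in s.peaks}
            assert 73.0 in mzs
            nominal = round(s.exact_mass)
            assert nominal in mzs and nominal + 1 in mzs

    def test_fragments_below_molecular_ion(self):
        cfg = dataclasses.replace(CFG, background_peaks=0)  # clutter may sit anywhere
        rng = np.random.default_rng(6)
        for rec in generate_compounds(cfg, 5, rng):
            s = simulate_spectrum(rec, cfg, seed=8)
            nominal = round(s.exact_mass)
            assert all(p.mz <= nominal + 1 for p in s.peaks
                       if p.mz not in (nominal, nominal + 1.0))


class TestReplicates:
    def test_noise_free_replicates_identical_cosine(self):
        cfg = dataclasses.replace(CFG, intensity_noise_sd=0.0,
                                  peak_dropout_p=0.0, background_peaks=0)
        (rec,) = generate_compounds(cfg, 1, np.random.default_rng(7))
        reps = make_replicates(rec, 4, cfg, seed=0)
        vecs = [bin_spectrum(s) for s in reps]
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                assert cosine(vecs[i], vecs[j]) == pytest.approx(1.0)

    def test_low_noise_reproducibility_single_compound(self):
        (rec,) = generate_compounds(CFG, 1, np.random.default_rng(8))
        reps = make_replicates(rec, 15, CFG, seed=1)
        vecs = [bin_spectrum(s) for s in reps]
        sims = [cosine(vecs[i], vecs[j])
                for i in range(15) for j in range(i + 1, 15)]
        assert min(sims) > 0.95

    def test_high_dropout_exercises_qc_threshold(self):
        cfg = dataclasses.replace(CFG, peak_dropout_p=0.5,
                                  intensity_noise_sd=0.5, background_peaks=20)
        (rec,) = generate_compounds(cfg, 1, np.random.default_rng(9))
        reps = make_replicates(rec, 10, cfg, seed=2)
        vecs = [bin_spectrum(s) for s in reps]
        sims = [cosine(vecs[i], vecs[j])
                for i in range(10) for j in range(i + 1, 10)]
        assert min(sims) < 0.95  # noticeably degraded replicates

    def test_needs_at_least_one(self):
        (rec,) = generate_compounds(CFG, 1)
        with pytest.raises(ValueError):
            make_replicates(rec, 0, CFG)


class TestCandidateSets:
    def test_all_missing_when_p_missing_one(self):
        cfg = dataclasses.replace(CFG, p_missing=1.0, candidates_per_query=10)
        pool = pool_records()
        rng = np.random.default_rng(10)
        for truth in pool[:5]:
            cs = make_candidate_set(truth, pool, cfg, rng)
            assert not cs.contains_true and cs.true_id is None

    def test_truth_present_when_p_missing_zero(self):
        cfg = dataclasses.replace(CFG, candidates_per_query=10)
        pool = pool_records()
        cs = make_candidate_set(pool[3], pool, cfg, np.random.default_rng(11))
        assert cs.contains_true and cs.true_id == pool[3].inchikey
        assert len(cs.candidates) == 10

    def test_decoys_within_similarity_range(self):
        cfg = dataclasses.replace(CFG, candidates_per_query=15)
        pool = pool_records()
        cols = _informative_columns(tuple(r.structure for r in pool))
        truth = pool[7]
        cs = make_candidate_set(truth, pool, cfg, np.random.default_rng(12))
        tb = compute_fingerprint(truth.structure).bits[cols].astype(bool)
        lo, hi = cfg.decoy_similarity_range
        for c in cs.candidates:
            if c.identifier == cs.true_id:
                continue
            cb = compute_fingerprint(c.structure).bits[cols].astype(bool)
            t = (tb & cb).sum() / (tb | cb).sum()
            assert lo <= t <= hi

    def test_infeasible_pool_raises_with_achieved_range(self):
        cfg = dataclasses.replace(CFG, candidates_per_query=50)
        pool = pool_records()[:10]
        with pytest.raises(ValueError, match="decoys available"):
            make_candidate_set(pool[0], pool, cfg, np.random.default_rng(13))


class TestPlantedLibrary:
    def test_plan_echo_and_counts(self):
        records, plan = make_planted_library(
            CFG, {"tbdms": 1, "molecular_ion_isotope": 2}, n_clean=3, seed=3)
        assert len(records) == 6
        assert plan == {"tbdms": 1, "molecular_ion_isotope": 2}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown violation"):
            make_planted_library(CFG, {"nonsense": 1}, n_clean=1, seed=0)
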