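"""Synthetic paired (structure, EI spectrum) data for end-to-end testing.

Reference EI libraries of TMS derivatives are license-restricted, so every
stage of the pipeline is exercised on generated data instead. The
generator emulates the statistical structure the analysis assumes:

* **Compounds** are assembled from a template grammar of TMS-derivatizable
  scaffolds — substituted phenols, bisphenols, aliphatic alcohols and
  polyols, cyclohexanols, amines and amino acids, benzoates — carrying
  1–5 trimethylsilyl groups, with molecular weights inside the range of
  real derivatized test compounds (182–575 Da by default).
* **Spectra** are generated from molecular fingerprints, not from a
  physical fragmentation model: each active fingerprint bit is sent by a
  deterministic hash map to characteristic fragment m/z positions in the
  instrument scan range (m/z 50–800). This is the minimal faithful
  stand-in, because the learnability assumption of the pipeline is
  precisely that spectra carry fingerprint information. On top of the
  fragment map, each spectrum gets the TMS marker ions (m/z 73/147/221/295
  up to the TMS count), the molecular ion and its 13C isotope peak,
  multiplicative lognormal intensity noise, per-peak dropout (structural
  peaks — molecular ion, isotope, markers — are exempt so low-noise
  spectra satisfy the quality criteria by construction), and uniform
  background clutter. Fragment-map collisions (two bits hashing to one
  bin) are allowed; they create realistic ambiguity.
* **Candidate sets** contain decoys drawn at a controlled Tanimoto
  similarity to the truth, with an optional fraction of queries whose set
  omits the truth ("missing").

Everything is deterministic under ``master_seed``: identical configs give
bit-identical bundles.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .curation import CompoundRecord
from .fingerprints import compute_fingerprint
from .iokr import Candidate, CandidateSet
from .spectra_io import Peak, Spectrum

__all__ = [
    "GeneratorConfig",
    "SyntheticBundle",
    "TestQuery",
    "generate_compounds",
    "simulate_spectrum",
    "make_replicates",
    "make_candidate_set",
    "make_benchmark",
    "make_planted_library",
    "template_pool",
]

TMS = "[Si](C)(C)C"
OTMS = "O[Si](C)(C)C"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the synthetic benchmark.

    The defaults define the reference benchmark conditions: 300 training
    compounds, 50 test queries (60% of which also appear in training,
    mirroring the presence-in-training split of real evaluations), 15
    replicate acquisitions per test compound pool, 50 candidates per
    query with decoys at Tanimoto <= 0.4 to the truth, and low noise
    (lognormal sd 0.05, 2% peak dropout, 3 background peaks).
    """

    n_train: int = 300
    n_test: int = 50
    overlap_fraction: float = 0.6
    n_tms_range: tuple[int, int] = (1, 5)
    fragment_map_seed: int = 7
    peaks_per_bit: int = 1
    intensity_noise_sd: float = 0.05
    peak_dropout_p: float = 0.02
    background_peaks: int = 3
    candidates_per_query: int = 50
    decoy_similarity_range: tuple[float, float] = (0.0, 0.4)
    p_missing: float = 0.0
    max_candidates: int = 400
    n_replicates: int = 3
    mw_range: tuple[float, float] = (182.0, 575.0)
    mz_min: float = 50.0
    mz_max: float = 800.0
    fragment_mz_max: float = 180.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.overlap_fraction, self.peak_dropout_p, self.p_missing):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.n_train, self.n_test, self.background_peaks,
               self.candidates_per_query, self.peaks_per_bit) < 0:
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# template grammar
# ---------------------------------------------------------------------------

_AR_SUBS = ["", "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "Cl", "F", "Br", "OC", "CCCC"]


def _sub(r: str) -> str:
    return f"({r})" if r else ""


def _enumerate_templates():
    """Yield (smiles, class_label) for the scaffold grammar; labels follow
    the six structural TMS classes (attachment-moiety based)."""
    # substituted phenols: one aromatic O-TMS
    for r1, r2 in itertools.product(_AR_SUBS, repeat=2):
        yield f"c1c{_sub(r1)}cc{_sub(r2)}cc1{OTMS}", "phenyl_O_TMS"
    # naphthols
    for r in _AR_SUBS:
        yield f"c1ccc2cc{_sub(r)}c({OTMS})cc2c1", "phenyl_O_TMS"
    # benzoates (carboxyl O-TMS on an aromatic acid)
    for r in _AR_SUBS:
        yield f"C[Si](C)(C)OC(=O)c1ccc{_sub(r)}cc1", "phenyl_O_TMS"
    # salicylate-type: carboxyl + phenol O-TMS (2 TMS)
    for r in _AR_SUBS:
        yield (f"C[Si](C)(C)OC(=O)c1cc{_sub(r)}ccc1{OTMS}", "other_poly_TMS")
    # catechol/hydroquinone-type di-O-TMS
    for r in _AR_SUBS:
        yield f"c1c{_sub(r)}cc({OTMS})c({OTMS})c1", "other_poly_TMS"
        yield f"c1c{_sub(r)}c({OTMS})cc({OTMS})c1", "other_poly_TMS"
    # bisphenols and related
    for link in ["C(C)(C)", "C(C)(CC)", "S(=O)(=O)", "C(=O)", "CC", "C(CC)(CC)"]:
        for r in ["", "C", "Cl", "F"]:
            yield (f"c1cc({OTMS})cc{_sub(r)}c1{link}c1ccc({OTMS})cc1",
                   "bisphenol_TMS")
    # aliphatic alcohols and diols
    for k in range(7, 22):
        yield "C" * k + OTMS, "aliphatic_O_TMS"
    for k in range(4, 16):
        yield f"C[Si](C)(C)OC" + "C" * k + OTMS, "aliphatic_O_TMS"
    for k in range(6, 18):
        yield f"CC(C{OTMS})C" + "C" * k, "aliphatic_O_TMS"
    # phenylalkyl alcohols
    for k in range(2, 8):
        for r in ["", "C", "Cl", "OC"]:
            yield f"c1cc{_sub(r)}ccc1" + "C" * k + OTMS, "aliphatic_O_TMS"
    # cyclohexanols / non-aromatic ring O-TMS
    for r in ["", "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C"]:
        yield f"C1CC{_sub(r)}CCC1{OTMS}", "nonaromatic_ring_O_TMS"
        yield f"C1C{_sub(r)}CC(C(C)C)CC1{OTMS}", "nonaromatic_ring_O_TMS"
    # polyols (sugar-like, 3-5 O-TMS)
    for k in range(3, 6):
        core = "C[Si](C)(C)OC" + f"C({OTMS})" * k + "C" + OTMS
        yield core, "other_poly_TMS"
    # amines: mono N-TMS
    for k in range(8, 20):
        yield "C" * k + f"N{TMS}", "mono_N_TMS"
    for k in range(2, 7):
        for r in ["", "C", "Cl", "OC"]:
            yield f"c1cc{_sub(r)}ccc1" + "C" * k + f"N{TMS}", "mono_N_TMS"
    for r1, r2 in itertools.product(["", "C", "CC", "Cl", "OC"], repeat=2):
        yield f"c1c{_sub(r1)}cc{_sub(r2)}cc1N{TMS}", "mono_N_TMS"
    # amino acids: N-TMS + carboxyl O-TMS (mixed N,O)
    for side in ["C", "CC", "CC(C)C", "CCC", "Cc1ccccc1", "CCCC", "C(C)CC",
                 f"CC({OTMS})", f"Cc1ccc({OTMS})cc1"]:
        yield f"{side}C(N{TMS})C(=O)O{TMS}", "other_poly_TMS"
    # thiophenols (S-TMS on thiol)
    for r in ["", "C", "CC", "Cl", "CCC"]:
        yield f"c1cc{_sub(r)}ccc1S{TMS}", "other_poly_TMS"
    # trisubstituted phenols
    for r1, r2, r3 in itertools.product(["C", "CC", "Cl", "OC", "C(C)C"], repeat=3):
        yield f"c1{_sub(r1)}c{_sub(r2)}cc{_sub(r3)}c1{OTMS}", "phenyl_O_TMS"
    # mono aliphatic acids (carboxyl O-TMS)
    for k in range(7, 19):
        yield "C" * k + f"C(=O)O{TMS}", "aliphatic_O_TMS"
    # dicarboxylic acids, di-O-TMS
    for k in range(2, 13):
        yield f"C[Si](C)(C)OC(=O)" + "C" * k + f"C(=O)O{TMS}", "other_poly_TMS"
    # hydroxy acids (alpha-hydroxy, 2 TMS)
    for k in range(3, 13):
        yield f"C" * k + f"C(O{TMS})C(=O)O{TMS}", "other_poly_TMS"
    # phenylacetic / cinnamic acids
    for r in _AR_SUBS:
        yield f"c1cc{_sub(r)}ccc1CC(=O)O{TMS}", "phenyl_O_TMS"
        yield f"c1cc{_sub(r)}ccc1/C=C/C(=O)O{TMS}", "phenyl_O_TMS"
    # benzyl alcohols
    for r1, r2 in itertools.product(["", "C", "Cl", "OC", "CC"], repeat=2):
        yield f"c1c{_sub(r1)}cc{_sub(r2)}cc1C{OTMS}", "aliphatic_O_TMS"
    # secondary alcohols
    for k in range(5, 16):
        yield f"CC(O{TMS})" + "C" * k, "aliphatic_O_TMS"
    # diamines / amino alcohols
    for k in range(4, 12):
        yield f"C[Si](C)(C)NC" + "C" * k + f"CO{TMS}", "other_poly_TMS"
    # N-TMS anilides of long acids (secondary amine-TMS)
    for k in range(6, 14):
        yield "C" * k + f"CN{TMS}", "mono_N_TMS"
    # hydroxypyridines / quinolinols (heteroaromatic O-TMS)
    for r in ["", "C", "CC", "Cl", "Br", "OC", "CCC", "C(C)C"]:
        yield f"c1c{_sub(r)}cnc(c1){OTMS}", "phenyl_O_TMS"
        yield f"c1c{_sub(r)}cc2ncccc2c1{OTMS}", "phenyl_O_TMS"
        yield f"c1c{_sub(r)}oc(c1)C(=O)O{TMS}", "phenyl_O_TMS"
        yield f"c1c{_sub(r)}sc(c1)C(=O)O{TMS}", "phenyl_O_TMS"
    # nitro- and dinitro-phenols
    for r in ["", "C", "Cl", "OC", "CC", "Br", "CCC"]:
        yield f"c1c{_sub(r)}cc([N+](=O)[O-])cc1{OTMS}", "phenyl_O_TMS"
        yield (f"c1c([N+](=O)[O-])cc{_sub(r)}c([N+](=O)[O-])c1{OTMS}",
               "phenyl_O_TMS")
    # polyfluorinated alcohols
    for k in range(4, 12):
        yield "FC(F)(F)" + "C" * k + OTMS, "aliphatic_O_TMS"
        yield "FC(F)(F)C(F)(F)" + "C" * k + OTMS, "aliphatic_O_TMS"
    # hydroxylated benzophenones
    for r in ["", "C", "Cl", "OC", "CC"]:
        yield (f"c1cc{_sub(r)}ccc1C(=O)c1ccc({OTMS})cc1", "phenyl_O_TMS")
        yield (f"c1cc{_sub(r)}ccc1C(=O)c1ccc({OTMS})cc1{OTMS}", "other_poly_TMS")
    # pyranose-like ring polyols (non-aromatic ring, 3-4 O-TMS)
    for r in ["C", "CC", f"C{OTMS}", "CCC", "C(C)C", ""]:
        yield (f"C1OC{_sub(r)}C({OTMS})C({OTMS})C1{OTMS}",
               "nonaromatic_ring_O_TMS")
    # decalin / fused-ring alcohols
    for r in ["", "C", "CC", "CCC", "C(C)C", "CCCC"]:
        yield f"C1CC{_sub(r)}C2CCCCC2C1{OTMS}", "nonaromatic_ring_O_TMS"
        yield f"CC12CCC{_sub(r)}CC1CCCC2{OTMS}", "nonaromatic_ring_O_TMS"
    # ketone-bearing alcohols (keto acids / ketols)
    for k in range(4, 12):
        yield "C" * k + f"C(=O)CC(=O)O{TMS}", "aliphatic_O_TMS"
        yield "CC(=O)" + "C" * k + OTMS, "aliphatic_O_TMS"
    # ether-linked diols
    for k in range(2, 8):
        yield (f"C[Si](C)(C)OC" + "C" * k + "OC" + "C" * k + OTMS,
               "other_poly_TMS")
    # indolyl alcohols
    for r in ["", "C", "CC", "Cl", "OC"]:
        yield f"c1c{_sub(r)}cc2c(c1)[nH]cc2CC{OTMS}", "aliphatic_O_TMS"
    # long-chain ester alcohols
    for k in range(3, 10):
        yield ("CCCCC(=O)OC" + "C" * k + OTMS, "aliphatic_O_TMS")


@lru_cache(maxsize=4)
def template_pool(mw_range: tuple[float, float] = (182.0, 575.0),
                  n_tms_range: tuple[int, int] = (1, 5)) -> tuple:
    """The deduplicated, M_w- and TMS-count-filtered compound pool, as a
    tuple of ``(canonical_smiles, class_label, mw, exact_mass, formula,
    inchikey, n_tms)`` entries sorted by InChIKey (deterministic)."""
    from .curation import count_tms_groups

    seen = {}
    for smi, label in _enumerate_templates():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        mw = Descriptors.MolWt(mol)
        if not (mw_range[0] <= mw <= mw_range[1]):
            continue
        n_tms = count_tms_groups(mol)
        if not (n_tms_range[0] <= n_tms <= n_tms_range[1]):
            continue
        ik = Chem.MolToInchiKey(mol)
        if not ik or ik in seen:
            continue
        seen[ik] = (
            Chem.MolToSmiles(mol), label, mw, Descriptors.ExactMolWt(mol),
            Chem.rdMolDescriptors.CalcMolFormula(mol), ik, n_tms,
        )
    return tuple(seen[k] for k in sorted(seen))


def _record_from_entry(entry, idx: int) -> CompoundRecord:
    smi, label, mw, _exact, formula, ik, n_tms = entry
    return CompoundRecord(
        record_id=f"SYN{idx:04d}", structure=smi, inchikey=ik,
        formula=formula, mw=mw, n_tms=n_tms, class_label=label)


def generate_compounds(cfg: GeneratorConfig, n: int | None = None,
                       rng: np.random.Generator | None = None) -> list[CompoundRecord]:
    """Draw n distinct compounds from the template pool (deterministic per
    seed)."""
    if n is None:
        n = cfg.n_train
    if rng is None:
        rng = np.random.default_rng(cfg.master_seed)
    pool = template_pool(cfg.mw_range, cfg.n_tms_range)
    if not pool:
        raise ValueError("template pool is empty under the given config")
    if n > len(pool):
        raise ValueError(f"requested {n} compounds but pool holds {len(pool)}")
    idx = rng.choice(len(pool), size=n, replace=False)
    return [_record_from_entry(pool[i], i) for i in idx]


# ---------------------------------------------------------------------------
# spectrum simulation
# ---------------------------------------------------------------------------

def _bit_hash(bit: int, rep: int, seed: int) -> int:
    key = f"{bit}:{rep}:{seed}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big")


def _fragment_map(active_bits: np.ndarray, cfg: GeneratorConfig):
    """Deterministic (m/z, base intensity) fragment list for active bits.

    Fragments land in [mz_min, fragment_mz_max); the cap sits below the
    lightest molecular weight in the compound universe, since EI fragment
    ions cannot outweigh the molecular ion — and it keeps the training
    library's m/z-range clamp ([50, M_w + 10]) information-neutral.
    Marker bins (73/147/221/295) are never produced, so the TMS markers
    stay unambiguous. Collisions merge by intensity sum.
    """
    span = int(cfg.fragment_mz_max - cfg.mz_min)
    frags: list[tuple[float, float]] = []
    markers = {73.0, 147.0, 221.0, 295.0}
    for b in active_bits:
        for r in range(cfg.peaks_per_bit):
            h = _bit_hash(int(b), r, cfg.fragment_map_seed)
            mz = float(cfg.mz_min + (h % span))
            if mz in markers:
                mz += 1.0
            # fragments stay minor relative to the TMS marker base peak,
            # as in real silyl-derivative EI spectra
            inten = 0.08 + 0.22 * ((h >> 32) % 1000) / 999.0
            frags.append((mz, inten))
    return frags


def _carbon_count(structure: str) -> int:
    mol = Chem.MolFromSmiles(structure)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)


def _pool_informative_columns(cfg: GeneratorConfig) -> np.ndarray:
    pool = template_pool(cfg.mw_range, cfg.n_tms_range)
    return _informative_columns(tuple(e[0] for e in pool))


def simulate_spectrum(c: CompoundRecord, cfg: GeneratorConfig,
                      seed: int = 0) -> Spectrum:
    """Simulate one EI spectrum of a compound.

    The deterministic core (fragment map, markers, molecular-ion cluster)
    does not depend on *seed*; noise, dropout and background do. Fragment
    peaks encode the compound's *distinctive* fingerprint bits — bits
    constant across the generator's compound universe describe the shared
    silyl chemistry, which the spectrum already carries as the TMS marker
    ions, so mapping them to fragments would only flood every spectrum
    with identical peaks.
    """
    fp = compute_fingerprint(c.structure)
    active = np.intersect1d(np.flatnonzero(fp.bits),
                            _pool_informative_columns(cfg))
    frags = _fragment_map(active, cfg)
    mol_exact = Descriptors.ExactMolWt(Chem.MolFromSmiles(c.structure))
    nominal = float(round(mol_exact))

    rng = np.random.default_rng(seed)
    peaks: dict[float, float] = {}
    # fragment components: noisy, droppable one ion species at a time
    # (bin collisions merge by sum afterwards, so a dropout event only
    # removes one component of a shared bin)
    for mz, inten in sorted(frags):
        if rng.random() < cfg.peak_dropout_p:
            continue
        noisy = inten * float(np.exp(rng.normal(0.0, cfg.intensity_noise_sd))) \
            if cfg.intensity_noise_sd > 0 else inten
        peaks[mz] = peaks.get(mz, 0.0) + noisy
    # structural peaks: markers, molecular ion, isotope (dropout-exempt)
    marker_base = {73.0: 1.5, 147.0: 1.0, 221.0: 0.5, 295.0: 0.25}
    for i in range(min(c.n_tms or 0, 4)):
        mz = (73.0, 147.0, 221.0, 295.0)[i]
        inten = marker_base[mz]
        if cfg.intensity_noise_sd > 0:
            inten *= float(np.exp(rng.normal(0.0, cfg.intensity_noise_sd)))
        peaks[mz] = peaks.get(mz, 0.0) + inten
    m_int = 0.4
    iso_int = m_int * 0.011 * _carbon_count(c.structure)
    for mz, inten in ((nominal, m_int), (nominal + 1.0, iso_int)):
        if cfg.intensity_noise_sd > 0:
            inten *= float(np.exp(rng.normal(0.0, cfg.intensity_noise_sd)))
        peaks[mz] = peaks.get(mz, 0.0) + inten
    # uniform clutter
    for _ in range(cfg.background_peaks):
        mz = float(int(rng.uniform(cfg.mz_min, cfg.mz_max)))
        peaks[mz] = peaks.get(mz, 0.0) + float(rng.uniform(0.005, 0.05))

    top = max(peaks.values())
    plist = [Peak(mz, round(999.0 * peaks[mz] / top, 4)) for mz in sorted(peaks)]
    return Spectrum(
        peaks=plist, name=c.record_id, inchikey=c.inchikey, formula=c.formula,
        mw=c.mw, exact_mass=mol_exact, library_id=c.record_id,
        extra={"AcqMzMin": f"{cfg.mz_min:g}", "AcqMzMax": f"{cfg.mz_max:g}"},
    )


def make_replicates(c: CompoundRecord, n: int, cfg: GeneratorConfig,
                    seed: int = 0) -> list[Spectrum]:
    """n independent replicate acquisitions of one compound."""
    if n < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    return [simulate_spectrum(c, cfg, seed=int(rng.integers(2**31)))
            for _ in range(n)]


# ---------------------------------------------------------------------------
# candidate sets and the full benchmark
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _informative_columns(key: tuple) -> np.ndarray:
    """Fingerprint columns that vary across a compound pool; bits constant
    over the whole candidate universe carry no discriminating signal and
    are excluded from decoy-similarity control."""
    fps = np.stack([compute_fingerprint(smi).bits for smi in key])
    return np.flatnonzero(~(fps == fps[0]).all(axis=0))


def _informative_tanimoto(truth_bits: np.ndarray, pool_bits: np.ndarray,
                          cols: np.ndarray) -> np.ndarray:
    a = truth_bits[cols].astype(bool)
    B = pool_bits[:, cols].astype(bool)
    inter = (B & a).sum(axis=1)
    union = (B | a).sum(axis=1)
    return np.where(union > 0, inter / np.maximum(union, 1), 1.0)


def make_candidate_set(
    truth: CompoundRecord,
    pool: list[CompoundRecord],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> CandidateSet:
    """Decoy candidate set for one query, at controlled structural
    similarity to the truth (Tanimoto over the pool's informative
    fingerprint bits); candidate fingerprints are unmasked."""
    if rng is None:
        rng = np.random.default_rng(cfg.master_seed)
    lo, hi = cfg.decoy_similarity_range
    pool_key = tuple(r.structure for r in pool)
    cols = _informative_columns(pool_key)
    pool_bits = np.stack([compute_fingerprint(r.structure).bits for r in pool])
    t_all = _informative_tanimoto(compute_fingerprint(truth.structure).bits,
                                  pool_bits, cols)
    sims = []
    eligible = []
    for r, t in zip(pool, t_all):
        if r.inchikey == truth.inchikey:
            continue
        sims.append(float(t))
        if lo <= t <= hi:
            eligible.append(r)
    n_decoys = min(cfg.candidates_per_query, cfg.max_candidates) - 1
    if len(eligible) < n_decoys:
        achieved = (min(sims), max(sims)) if sims else (None, None)
        raise ValueError(
            f"only {len(eligible)} decoys available in Tanimoto range "
            f"[{lo}, {hi}] for '{truth.record_id}' "
            f"(pool similarity span {achieved})")
    picked = [eligible[i] for i in rng.choice(len(eligible), n_decoys, replace=False)]
    contains_true = bool(rng.random() >= cfg.p_missing)
    members = list(picked) + ([truth] if contains_true else [])
    candidates = [
        Candidate(r.inchikey or r.record_id, r.structure,
                  compute_fingerprint(r.structure))
        for r in members
    ]
    return CandidateSet(
        query_id=truth.record_id, candidates=candidates,
        contains_true=contains_true,
        true_id=(truth.inchikey or truth.record_id) if contains_true else None)


@dataclass
class TestQuery:
    record: CompoundRecord
    replicates: list[Spectrum]
    in_training: bool

    @property
    def query_spectrum(self) -> Spectrum:
        return self.replicates[0]


@dataclass
class SyntheticBundle:
    """A complete synthetic study: training pairs, replicated test queries,
    candidate sets and ground-truth labels."""

    config: GeneratorConfig
    train_records: list[CompoundRecord]
    test_queries: list[TestQuery]
    candidate_sets: dict[str, CandidateSet]
    truth: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        h = hashlib.sha1()
        for r in self.train_records:
            h.update(r.structure.encode())
            for p in r.spectrum.peaks:
                h.update(f"{p.mz:.4f}:{p.intensity:.4f};".encode())
        for q in self.test_queries:
            h.update(q.record.structure.encode())
            h.update(b"1" if q.in_training else b"0")
            for s in q.replicates:
                for p in s.peaks:
                    h.update(f"{p.mz:.4f}:{p.intensity:.4f};".encode())
            cs = self.candidate_sets[q.record.record_id]
            h.update(",".join(c.identifier for c in cs.candidates).encode())
        return h.hexdigest()


def make_benchmark(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate the full synthetic study under the config's master seed."""
    rng = np.random.default_rng(cfg.master_seed)
    pool_entries = template_pool(cfg.mw_range, cfg.n_tms_range)
    n_pool = len(pool_entries)
    n_overlap = int(round(cfg.overlap_fraction * cfg.n_test))
    n_new = cfg.n_test - n_overlap
    if cfg.n_train + n_new > n_pool:
        raise ValueError(
            f"pool ({n_pool}) too small for n_train={cfg.n_train} plus "
            f"{n_new} held-out test compounds")

    idx = rng.choice(n_pool, size=cfg.n_train + n_new, replace=False)
    train_idx, new_idx = idx[:cfg.n_train], idx[cfg.n_train:]
    train_records = [_record_from_entry(pool_entries[i], i) for i in train_idx]
    overlap_pick = rng.choice(cfg.n_train, size=n_overlap, replace=False)
    test_records = (
        [(train_records[i], True) for i in overlap_pick]
        + [(_record_from_entry(pool_entries[i], i), False) for i in new_idx]
    )

    for r in train_records:
        r.spectrum = simulate_spectrum(r, cfg, seed=int(rng.integers(2**31)))

    decoy_pool = [_record_from_entry(e, i) for i, e in enumerate(pool_entries)]
    queries, cand_sets, truth_rows = [], {}, []
    for rec, in_training in test_records:
        reps = make_replicates(rec, cfg.n_replicates, cfg,
                               seed=int(rng.integers(2**31)))
        cs = make_candidate_set(rec, decoy_pool, cfg, rng)
        queries.append(TestQuery(rec, reps, in_training))
        cand_sets[rec.record_id] = cs
        truth_rows.append({
            "query_id": rec.record_id, "true_id": rec.inchikey,
            "in_training": in_training, "class_label": rec.class_label,
            "cluster_label": rec.class_label,
            "contains_true": cs.contains_true,
        })

    truth = {
        "config": asdict(cfg),
        "queries": truth_rows,
    }
    return SyntheticBundle(cfg, train_records, queries, cand_sets, truth)


def write_bundle(bundle: SyntheticBundle, directory) -> None:
    """Serialize a bundle: training.msp, test.msp, structures.tsv,
    candidates.tsv, truth.json."""
    import os

    from .spectra_io import write_msp

    os.makedirs(directory, exist_ok=True)
    write_msp([r.spectrum for r in bundle.train_records],
              os.path.join(directory, "training.msp"))
    test_spectra = []
    for q in bundle.test_queries:
        for i, s in enumerate(q.replicates):
            from dataclasses import replace as _rep
            test_spectra.append(_rep(s, name=f"{q.record.record_id}_rep{i}"))
    write_msp(test_spectra, os.path.join(directory, "test.msp"))
    with open(os.path.join(directory, "structures.tsv"), "w") as fh:
        fh.write("record_id\tsmiles\tinchikey\tformula\tmw\tn_tms\tclass_label\n")
        seen = set()
        for r in itertools.chain(bundle.train_records,
                                 (q.record for q in bundle.test_queries)):
            if r.record_id in seen:
                continue
            seen.add(r.record_id)
            fh.write(f"{r.record_id}\t{r.structure}\t{r.inchikey}\t{r.formula}"
                     f"\t{r.mw:.2f}\t{r.n_tms}\t{r.class_label}\n")
    with open(os.path.join(directory, "candidates.tsv"), "w") as fh:
        fh.write("query_id\tcandidate_id\tsmiles\tis_true\n")
        for qid, cs in bundle.candidate_sets.items():
            for c in cs.candidates:
                is_true = int(cs.contains_true and c.identifier == cs.true_id)
                fh.write(f"{qid}\t{c.identifier}\t{c.structure}\t{is_true}\n")
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=1)


# ---------------------------------------------------------------------------
# planted violations (curation-report testing)
# ---------------------------------------------------------------------------

def make_planted_library(
    cfg: GeneratorConfig,
    plan: dict[str, int],
    n_clean: int = 5,
    seed: int = 0,
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """A toy library of clean records plus planted curation violations.

    ``plan`` maps a violation kind to a count; supported kinds:
    ``si_si_bond``, ``tbdms``, ``high_mass``, ``fragment_count``,
    ``tms_markers``, ``molecular_ion_isotope``. Returns the records and an
    echo of the plan (the expected per-rule removal counts).
    """
    rng = np.random.default_rng(seed)
    clean = generate_compounds(cfg, n_clean + sum(plan.values()), rng)
    for r in clean:
        r.spectrum = simulate_spectrum(r, cfg, seed=int(rng.integers(2**31)))
    records = clean[:n_clean]
    donors = clean[n_clean:]
    d = 0
    for kind, count in plan.items():
        for _ in range(count):
            rec = donors[d]
            d += 1
            if kind == "si_si_bond":
                rec.structure = "C[Si](C)(C)[Si](C)(C)C"
                rec.inchikey = None
                rec.n_tms = 2
            elif kind == "tbdms":
                rec.structure = "CC(C)(C)[Si](C)(C)OCCCCCCCC"
                rec.inchikey = None
            elif kind == "high_mass":
                rec.mw = 1200.0
            elif kind == "fragment_count":
                nominal = round(rec.spectrum.exact_mass)
                keep = [p for p in rec.spectrum.peaks
                        if abs(p.mz - 73) <= 0.5 or abs(p.mz - 147) <= 0.5
                        or abs(p.mz - nominal) <= 0.5
                        or abs(p.mz - nominal - 1) <= 0.5]
                rec.spectrum = Spectrum(
                    peaks=keep, name=rec.spectrum.name, mw=rec.mw,
                    exact_mass=rec.spectrum.exact_mass,
                    extra=dict(rec.spectrum.extra))
            elif kind == "tms_markers":
                keep = [p for p in rec.spectrum.peaks
                        if all(abs(p.mz - m) > 0.5 for m in (73, 147, 221, 295))]
                rec.spectrum = Spectrum(
                    peaks=keep, name=rec.spectrum.name, mw=rec.mw,
                    exact_mass=rec.spectrum.exact_mass,
                    extra=dict(rec.spectrum.extra))
            elif kind == "molecular_ion_isotope":
                nominal = round(rec.spectrum.exact_mass)
                keep = [p for p in rec.spectrum.peaks
                        if abs(p.mz - nominal) > 0.5 and abs(p.mz - nominal - 1) > 0.5]
                rec.spectrum = Spectrum(
                    peaks=keep, name=rec.spectrum.name, mw=rec.mw,
                    exact_mass=rec.spectrum.exact_mass,
                    extra=dict(rec.spectrum.extra))
            else:
                raise ValueError(f"unknown violation kind '{kind}'")
            records.append(rec)
    return records, dict(plan)
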