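"""Three-step curation of a TMS-derivative spectral training library.

Raw silyl-derivative libraries pulled from a reference EI collection mix
genuine trimethylsilyl (TMS) derivatization products with chemically
irrelevant Si-containing material. Curation proceeds in a fixed order:

1. **Structural triage** — thirteen exclusion categories (siloxanes,
   stray C–Si bonds, O/N/S–Si bonds outside the canonical
   hydroxyl/carboxyl-, amine- and thiol-TMS motifs, N–O–Si / N–N–Si,
   phosphorus–silicon linkages, rearrangement (enol-type) TMS products,
   TBDMS and mixed TMS/TBDMS derivatives, derivatization reagents,
   inorganic backbones, heavy-metal compounds), plus an erroneous-entry
   check (recorded InChIKey vs. the structure's own InChIKey skeleton).
2. **High-mass cut** — derivatives with M_w above 1000 Da (above the
   working linear range of common GC–MS mass analyzers).
3. **Spectral quality** — four criteria: acquisition up to at least
   M_w + 10; presence of the molecular ion and its 13C isotope peak;
   at least one TMS marker fragment (m/z 73/147/221/295); at least five
   fragment-ion peaks.

A final m/z-range clamp to [50, M_w + 10] is applied to the survivors.
Every removal names exactly one triggering rule (first match wins) and the
report reconciles counts exactly. The original triage was manual; here
each category is an explicit, auditable rule so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .fingerprints import parse_structure
from .spectra_io import Spectrum, clamp_mz_range

__all__ = [
    "CompoundRecord",
    "CurationReport",
    "QualityResult",
    "EXCLUSION_CATEGORIES",
    "count_tms_groups",
    "classify_structure",
    "filter_high_mass",
    "quality_filter",
    "run_curation",
]

#: ordered category labels; classification tries them in this order
EXCLUSION_CATEGORIES = [
    "si_si_bond",
    "c_si_bond",
    "o_si_non_hydroxyl_carboxyl",
    "n_si_non_amine",
    "n_o_si_or_n_n_si",
    "s_si_non_thiol",
    "p_si_linkage",
    "rearrangement_tms",
    "tbdms",
    "mixed_tms_tbdms",
    "derivatization_agent",
    "inorganic",
    "heavy_metal",
]

_TMS_MARKERS = (73.0, 147.0, 221.0, 295.0)


@dataclass
class CompoundRecord:
    """A structure + identity bundle linked to its EI spectrum."""

    record_id: str
    structure: str
    inchikey: str | None = None
    formula: str | None = None
    mw: float | None = None
    n_tms: int | None = None
    spectrum: Spectrum | None = None
    class_label: str | None = None

    def mol(self) -> Chem.Mol:
        return parse_structure(self.structure)

    def __post_init__(self) -> None:
        if self.n_tms is None:
            try:
                self.n_tms = count_tms_groups(self.mol())
            except ValueError:
                self.n_tms = None


# ---------------------------------------------------------------------------
# silyl-group bookkeeping
# ---------------------------------------------------------------------------

def _is_methyl(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() == 6 and atom.GetDegree() == 1 and atom.GetTotalNumHs() == 3


def _silyl_kind(si: Chem.Atom) -> str | None:
    """Classify a silicon atom: 'tms' (three methyls + one hetero/any bond),
    'tbdms' (two methyls + tert-butyl), else None."""
    if si.GetAtomicNum() != 14:
        return None
    nbrs = list(si.GetNeighbors())
    methyls = [a for a in nbrs if _is_methyl(a)]
    rest = [a for a in nbrs if a not in methyls]
    # the attachment atom must be a heteroatom: a silyl group bonded to
    # carbon is a stray C-Si bond, not a derivatization product
    if len(nbrs) == 4 and len(methyls) == 3 and rest[0].GetAtomicNum() != 6:
        return "tms"
    if len(nbrs) == 4 and len(methyls) == 2:
        tbu = [
            a for a in rest
            if a.GetAtomicNum() == 6 and a.GetDegree() == 4
            and sum(_is_methyl(n) for n in a.GetNeighbors()) == 3
        ]
        other = [a for a in rest if a not in tbu]
        if tbu and other and other[0].GetAtomicNum() != 6:
            return "tbdms"
    return None


def count_tms_groups(mol: Chem.Mol) -> int:
    """Number of intact trimethylsilyl groups in a structure."""
    return sum(1 for a in mol.GetAtoms() if _silyl_kind(a) == "tms")


def _silyl_member_atoms(mol: Chem.Mol) -> set[int]:
    """Atom indices belonging to intact TMS/TBDMS groups (Si + its carbons)."""
    members: set[int] = set()
    for a in mol.GetAtoms():
        kind = _silyl_kind(a)
        if kind is None:
            continue
        members.add(a.GetIdx())
        for n in a.GetNeighbors():
            if n.GetAtomicNum() == 6:
                members.add(n.GetIdx())
                if kind == "tbdms" and n.GetDegree() == 4:
                    members.update(m.GetIdx() for m in n.GetNeighbors()
                                   if _is_methyl(m))
    return members


_ALLOWED_Z = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53}  # H B C N O F Si P S Cl Br I

_AGENT_SMARTS = [
    # residual silylation reagents: MSTFA/BSTFA cores, TMCS, HMDS
    "FC(F)(F)C(=O)[#7][Si]",
    "FC(F)(F)C(O[Si])=[#7]",
    "Cl[Si]([CH3])([CH3])[CH3]",
    "[Si][NX3H1][Si]",
]
_AGENT_QUERIES = [Chem.MolFromSmarts(s) for s in _AGENT_SMARTS]


def _has_bond(mol, z1, z2) -> bool:
    for b in mol.GetBonds():
        zs = {b.GetBeginAtom().GetAtomicNum(), b.GetEndAtom().GetAtomicNum()}
        if zs == {z1, z2} or (z1 == z2 and zs == {z1}):
            return True
    return False


def classify_structure(record: CompoundRecord):
    """Assign a record to the first matching exclusion category.

    Returns ``("retain", None)`` or ``("exclude", category)``. A structure
    whose only silicon chemistry is O-TMS on hydroxyl/carboxyl, N-TMS on a
    primary/secondary amine, or S-TMS on a thiol is always retained.
    """
    mol = record.mol()
    silyl_atoms = _silyl_member_atoms(mol)
    has_tms = any(_silyl_kind(a) == "tms" for a in mol.GetAtoms())
    has_tbdms = any(_silyl_kind(a) == "tbdms" for a in mol.GetAtoms())

    # 1. Si-Si bonds
    if _has_bond(mol, 14, 14):
        return ("exclude", "si_si_bond")

    # 2. C-Si bonds outside intact TMS/TBDMS groups (every silyl group
    #    necessarily contains C-Si; only stray ones are disqualifying)
    for b in mol.GetBonds():
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        zs = {a1.GetAtomicNum(), a2.GetAtomicNum()}
        if zs == {6, 14}:
            if a1.GetIdx() not in silyl_atoms or a2.GetIdx() not in silyl_atoms:
                return ("exclude", "c_si_bond")

    # 3. O-Si other than hydroxyl/carboxyl-TMS: the O must bridge Si and a
    #    carbon; O-Si with a second Si, a lone O, etc. is disqualifying
    #    (O bonded to N is deferred to category 5).
    for b in mol.GetBonds():
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if {a1.GetAtomicNum(), a2.GetAtomicNum()} != {8, 14}:
            continue
        o = a1 if a1.GetAtomicNum() == 8 else a2
        others = [n for n in o.GetNeighbors() if n.GetAtomicNum() != 14]
        if any(n.GetAtomicNum() in (7, 15) for n in others):
            continue  # N-O-Si and P-O-Si belong to categories 5 and 7
        if len(others) != 1 or others[0].GetAtomicNum() != 6:
            return ("exclude", "o_si_non_hydroxyl_carboxyl")

    # 4. N-Si other than primary/secondary-amine TMS: every non-Si heavy
    #    neighbor of the N must be carbon, and the N carries at most two Si
    for b in mol.GetBonds():
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if {a1.GetAtomicNum(), a2.GetAtomicNum()} != {7, 14}:
            continue
        n = a1 if a1.GetAtomicNum() == 7 else a2
        non_si = [x for x in n.GetNeighbors() if x.GetAtomicNum() != 14]
        n_si = sum(1 for x in n.GetNeighbors() if x.GetAtomicNum() == 14)
        if any(x.GetAtomicNum() not in (6,) for x in non_si) or n_si > 2:
            if any(x.GetAtomicNum() in (7, 8) for x in non_si):
                continue  # N-O-Si / N-N-Si, category 5
            return ("exclude", "n_si_non_amine")

    # 5. N-O-Si and N-N-Si linkages
    for patt in ("[#7][#8][Si]", "[#7][#7][Si]"):
        if mol.HasSubstructMatch(Chem.MolFromSmarts(patt)):
            return ("exclude", "n_o_si_or_n_n_si")

    # 6. S-Si other than thiol-TMS
    for b in mol.GetBonds():
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if {a1.GetAtomicNum(), a2.GetAtomicNum()} != {16, 14}:
            continue
        s = a1 if a1.GetAtomicNum() == 16 else a2
        others = [x for x in s.GetNeighbors() if x.GetAtomicNum() != 14]
        if len(others) != 1 or others[0].GetAtomicNum() != 6:
            return ("exclude", "s_si_non_thiol")

    # 7. phosphorus-silicon linkages: P-Si or P-(O/N/S)-Si
    if _has_bond(mol, 15, 14) or mol.HasSubstructMatch(
            Chem.MolFromSmarts("[#15][#7,#8,#16][Si]")):
        return ("exclude", "p_si_linkage")

    # 8. rearrangement products: enol-type O-TMS on a non-aromatic sp2 carbon
    if mol.HasSubstructMatch(Chem.MolFromSmarts("[CX3;!$(C=O)](=[CX3])[OX2][Si]")):
        return ("exclude", "rearrangement_tms")

    # 9/10. TBDMS and mixed silylation
    if has_tbdms and has_tms:
        return ("exclude", "mixed_tms_tbdms")
    if has_tbdms:
        return ("exclude", "tbdms")

    # 11. residual derivatization agents
    if any(mol.HasSubstructMatch(q) for q in _AGENT_QUERIES):
        return ("exclude", "derivatization_agent")

    # 12. inorganic: no carbon skeleton outside the silyl groups
    skeleton_c = [a for a in mol.GetAtoms()
                  if a.GetAtomicNum() == 6 and a.GetIdx() not in silyl_atoms]
    if not skeleton_c:
        return ("exclude", "inorganic")

    # 13. heavy metals / elements outside the organic set
    if any(a.GetAtomicNum() not in _ALLOWED_Z for a in mol.GetAtoms()):
        return ("exclude", "heavy_metal")

    return ("retain", None)


# ---------------------------------------------------------------------------
# steps 2 and 3
# ---------------------------------------------------------------------------

def filter_high_mass(records, threshold: float = 1000.0, mode: str = ">"):
    """Split records by molecular weight against the high-mass cut-off.

    Returns ``(kept, removed, needs_review)``; records without a known M_w
    land in *needs_review* rather than being silently kept. ``mode`` is
    ``">"`` (strict, the default) or ``">="``.
    """
    if mode not in (">", ">="):
        raise ValueError("mode must be '>' or '>='")
    kept, removed, needs_review = [], [], []
    for r in records:
        if r.mw is None:
            needs_review.append(r)
        elif (r.mw > threshold) if mode == ">" else (r.mw >= threshold):
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed, needs_review


@dataclass
class QualityResult:
    passed: bool
    violations: list[str]


def _nominal_mass(mw: float, exact_mass: float | None) -> float:
    return round(exact_mass if exact_mass is not None else mw)


def _has_peak_near(spectrum: Spectrum, target: float, tol: float = 0.5) -> bool:
    return any(abs(p.mz - target) <= tol for p in spectrum.peaks)


def _acq_mz_max(spectrum: Spectrum) -> float | None:
    for key, value in spectrum.extra.items():
        if key.lower().replace(" ", "").replace("_", "") in ("acqmzmax", "acquisitionmzmax"):
            try:
                return float(value)
            except ValueError:
                return None
    return None


def quality_filter(
    spectrum: Spectrum,
    mw: float,
    n_tms: int,
    tol: float = 0.5,
    strict_markers: bool = False,
) -> QualityResult:
    """Evaluate the four spectral-quality criteria; all violations reported.

    1. acquisition range reaches M_w + 10 (an ``AcqMzMax`` metadata field is
       used when present, otherwise the maximum observed peak m/z serves as
       a proxy);
    2. molecular ion at the nominal mass plus its 13C isotope peak at +1 Da,
       each within ±0.5 Da (unit-resolution EI data);
    3. at least one TMS marker fragment among m/z 73/147/221/295 (strict
       mode demands the marker for min(n_tms, 4) TMS groups);
    4. at least five fragment-ion peaks outside the molecular-ion cluster.
    """
    violations = []
    nominal = _nominal_mass(mw, spectrum.exact_mass)

    upper = _acq_mz_max(spectrum)
    if upper is None:
        upper = max((p.mz for p in spectrum.peaks), default=0.0)
    if upper < mw + 10.0:
        violations.append("acquisition_range")

    if not (_has_peak_near(spectrum, nominal, tol)
            and _has_peak_near(spectrum, nominal + 1.0, tol)):
        violations.append("molecular_ion_isotope")

    if strict_markers:
        required = _TMS_MARKERS[min(max(n_tms, 1), 4) - 1]
        ok = _has_peak_near(spectrum, required, tol)
    else:
        ok = any(_has_peak_near(spectrum, m, tol) for m in _TMS_MARKERS)
    if not ok:
        violations.append("tms_markers")

    fragments = [p for p in spectrum.peaks
                 if not (abs(p.mz - nominal) <= tol or abs(p.mz - (nominal + 1)) <= tol)]
    if len(fragments) < 5:
        violations.append("fragment_count")

    return QualityResult(passed=not violations, violations=violations)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

@dataclass
class CurationReport:
    """Per-step audit of a curation run; counts always reconcile."""

    n_input: int
    per_step_removed: dict[str, dict[str, int]]
    n_output: int
    audit: dict[str, str]  # record_id -> "kept" or the removing rule
    curated: list[CompoundRecord] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(sum(rules.values()) for rules in self.per_step_removed.values())

    def check_conservation(self) -> bool:
        return self.n_input == self.n_output + self.n_removed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "per_step_removed": self.per_step_removed,
            "n_output": self.n_output,
            "audit": self.audit,
        }


def _structure_matches_inchikey(record: CompoundRecord) -> bool:
    if record.inchikey is None:
        return True
    try:
        derived = Chem.MolToInchiKey(record.mol())
    except Exception:
        return False
    # stereochemistry is ignored, so compare the connectivity block only
    return bool(derived) and derived.split("-")[0] == record.inchikey.split("-")[0]


def run_curation(
    records: list[CompoundRecord],
    mass_threshold: float = 1000.0,
    mass_mode: str = ">",
    strict_markers: bool = False,
    clamp_low: float = 50.0,
) -> CurationReport:
    """Run the full three-step curation plus the final m/z-range clamp.

    Individual bad records are routed to the report, never abort the run.
    The curated survivors (spectra clamped to [clamp_low, M_w + 10]) are in
    ``report.curated``.
    """
    audit: dict[str, str] = {}
    per_step: dict[str, dict[str, int]] = {
        "step1_structure": {}, "step2_high_mass": {}, "step3_quality": {},
    }

    def _remove(step: str, rule: str, rec: CompoundRecord) -> None:
        per_step[step][rule] = per_step[step].get(rule, 0) + 1
        audit[rec.record_id] = rule

    survivors = []
    for rec in records:
        try:
            verdict, category = classify_structure(rec)
        except ValueError:
            _remove("step1_structure", "unparsable_structure", rec)
            continue
        if verdict == "exclude":
            _remove("step1_structure", category, rec)
            continue
        if not _structure_matches_inchikey(rec):
            _remove("step1_structure", "erroneous_entry", rec)
            continue
        survivors.append(rec)

    kept, removed, needs_review = filter_high_mass(survivors, mass_threshold, mass_mode)
    for rec in removed:
        _remove("step2_high_mass", "high_mass", rec)
    for rec in needs_review:
        _remove("step2_high_mass", "missing_mw_needs_review", rec)

    survivors = []
    for rec in kept:
        if rec.spectrum is None:
            _remove("step3_quality", "missing_spectrum", rec)
            continue
        result = quality_filter(rec.spectrum, rec.mw, rec.n_tms or 0,
                                strict_markers=strict_markers)
        if result.passed:
            survivors.append(rec)
        else:
            _remove("step3_quality", result.violations[0], rec)

    curated = []
    for rec in survivors:
        clamped = clamp_mz_range(rec.spectrum, low=clamp_low, high=rec.mw + 10.0)
        curated.append(CompoundRecord(
            record_id=rec.record_id, structure=rec.structure,
            inchikey=rec.inchikey, formula=rec.formula, mw=rec.mw,
            n_tms=rec.n_tms, spectrum=clamped, class_label=rec.class_label))
        audit[rec.record_id] = "kept"

    report = CurationReport(
        n_input=len(records), per_step_removed=per_step,
        n_output=len(curated), audit=audit, curated=curated)
    assert report.check_conservation()
    return report
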