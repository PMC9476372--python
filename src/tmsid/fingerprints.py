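"""Molecular fingerprints: four concatenated families plus column masking.

A structure is described by four binary fingerprint families, concatenated
in a fixed block order:

    substructure (307) | maccs (166) | pubchem (881) | klekota_roth (4860)

for 6,214 bits in total. Columns that are constant over a training set, or
duplicates of an earlier column, are removed with a :class:`ColumnMask`
built once on the training fingerprints and applied to every candidate.

The MACCS block is RDKit's implementation with the unused padding key 0
dropped, giving the canonical 166 keys. The other three families are
synthetic stand-ins for the original CDK definitions (which are not
redistributable here): deterministic, versioned pattern enumerations —
curated functional-group SMARTS, element/ring count thresholds, and
bonded-element chain patterns — at exactly the published family sizes.
Bit-level parity with CDK is therefore not a contract; block lengths,
purity (bits are a function of the structure only) and stability under
SMILES canonicalization are.

Stereochemistry is ignored throughout: EI mass spectra do not distinguish
stereoisomers, so structures are stripped of stereo marks before matching.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FAMILIES",
    "TOTAL_BITS",
    "FingerprintVector",
    "ColumnMask",
    "parse_structure",
    "compute_block",
    "concatenate",
    "compute_fingerprint",
    "build_mask",
    "apply_mask",
    "tanimoto",
    "export_pattern_files",
]

#: fixed block order and lengths
FAMILIES = (
    ("substructure", 307),
    ("maccs", 166),
    ("pubchem", 881),
    ("klekota_roth", 4860),
)
TOTAL_BITS = sum(n for _, n in FAMILIES)  # 6214

_ORGANIC = ["C", "N", "O", "S", "P", "Si", "F", "Cl", "Br", "I"]


# ---------------------------------------------------------------------------
# pattern enumeration
#
# Descriptors are tuples:
#   ("smarts", pattern)            bit = structure has a substructure match
#   ("count", symbol, t)           bit = #atoms of element symbol >= t  ("H" counts all hydrogens)
#   ("ring", size, t)              bit = #rings of that size >= t
#   ("aromring", t)                bit = #aromatic rings >= t
# ---------------------------------------------------------------------------

_CURATED_GROUPS = [
    "[OX2H]", "[OX2H][CX4]", "[OX2H]c", "[CX3]=[OX1]", "[CX3H1]=O",
    "[#6][CX3](=O)[#6]", "[CX3](=O)[OX2H1]", "[CX3](=O)[OX2][#6]",
    "[CX3](=O)[NX3]", "[NX3;H2][CX4]", "[NX3;H1]([CX4])[CX4]",
    "[NX3]([CX4])([CX4])[CX4]", "[NX3]c", "[N+](=O)[O-]", "C#N",
    "[SX2H]", "[#16X2]([#6])[#6]", "[#16X4](=O)(=O)", "[#16X3]=O",
    "[OX2]([#6])[#6]", "[OX2](c)[CX4]", "[Si]([CH3])([CH3])[CH3]",
    "[OX2][Si]([CH3])([CH3])[CH3]", "[NX3][Si]([CH3])([CH3])[CH3]",
    "[SX2][Si]([CH3])([CH3])[CH3]", "C(=O)O[Si]", "[Si][Si]", "[Si]O[Si]",
    "c1ccccc1", "c1ccc2ccccc2c1", "[cX3][Cl]", "[cX3][F]", "[CX4][F]",
    "[CX4][Cl]", "[CX4]([F])([F])[F]", "[OX2H][CX3]=[CX3]",
    "[NX3H1]c1ccccc1", "[nX2]", "[nX3H1]", "[oX2]", "[sX2]",
    "O=C1OC=CC1", "O=c1ccocc1", "[CX3]=[CX3]", "[CX2]#[CX2]",
    "[CH3]", "[CH2]", "[CX4H1]", "[CX4]([CX4])([CX4])[CX4]",
    "[OX2H][CX4H2]", "[OX2H][CX4H1]", "[OX2H][CX4H0]",
]


def _padding_stream():
    """Infinite deterministic stream of element-count threshold bits."""
    for t in itertools.count(1):
        for sym in ["H", "C", "N", "O", "S", "Si", "Cl", "F", "Br", "P"]:
            yield ("count", sym, t)


def _fill(sections: list, target: int) -> list:
    out = list(sections)
    seen = set(map(repr, out))
    if len(out) > target:
        raise AssertionError(f"family over-full: {len(out)} > {target}")
    for desc in _padding_stream():
        if len(out) == target:
            break
        if repr(desc) not in seen:
            out.append(desc)
            seen.add(repr(desc))
    return out


def _substructure_family() -> list:
    descs = [("smarts", s) for s in _CURATED_GROUPS]
    # bonded element pairs over the organic set, per bond order
    for a, b in itertools.combinations_with_replacement(_ORGANIC, 2):
        za, zb = Chem.Atom(a).GetAtomicNum(), Chem.Atom(b).GetAtomicNum()
        for bond in ("-", "=", "#", "~"):
            descs.append(("smarts", f"[#{za}]{bond}[#{zb}]"))
    for size in range(3, 9):
        descs.append(("ring", size, 1))
    return _fill(descs, 307)


_PUBCHEM_COUNTS = {
    "H": (2, 4, 8, 16, 32), "C": (2, 4, 8, 16, 32), "N": (1, 2, 4, 8),
    "O": (1, 2, 4, 8, 16), "S": (1, 2, 4, 8), "P": (1, 2, 4),
    "Si": (1, 2, 4), "F": (1, 2, 4), "Cl": (1, 2, 4, 8), "Br": (1, 2, 4),
    "I": (1, 2), "B": (1,), "Na": (1,), "K": (1,), "Li": (1,), "Ca": (1,),
}


def _pubchem_family() -> list:
    descs = []
    for sym, thresholds in _PUBCHEM_COUNTS.items():
        for t in thresholds:
            descs.append(("count", sym, t))
    for size in range(3, 13):
        for t in (1, 2, 3, 4):
            descs.append(("ring", size, t))
    for t in (1, 2, 3, 4):
        descs.append(("aromring", t))
    for a, b in itertools.combinations_with_replacement(_ORGANIC, 2):
        za, zb = Chem.Atom(a).GetAtomicNum(), Chem.Atom(b).GetAtomicNum()
        for bond in ("-", "=", "#", "~"):
            descs.append(("smarts", f"[#{za}]{bond}[#{zb}]"))
    # simple atom neighborhoods: center with two bonded neighbors
    centers = ["C", "N", "O", "S", "P", "Si"]
    neigh = ["C", "N", "O", "S", "Si", "F", "Cl", "Br"]
    for c in centers:
        zc = Chem.Atom(c).GetAtomicNum()
        for a, b in itertools.combinations_with_replacement(neigh, 2):
            za, zb = Chem.Atom(a).GetAtomicNum(), Chem.Atom(b).GetAtomicNum()
            descs.append(("smarts", f"[#{zc}](~[#{za}])~[#{zb}]"))
    return _fill(descs, 881)


# H-count- and ring-aware atom alphabet: specific local environments keep
# the bits discriminative between structurally related derivatives
_KR_ATOMS = [
    "CH3", "CH2;!R", "CH2;R", "CH1;!R", "CH1;R", "CH0", "cH1", "cH0",
    "NH2", "NH1", "NH0", "n", "OH1", "OH0;!R", "OH0;R", "o",
    "SH1", "SH0", "Si", "F", "Cl", "Br", "I", "P",
]
_KR_BONDS = ["-", "=", "#", "~"]
_KR_MIDS = ["CH2", "CH1", "CH0", "cH1", "cH0", "NH0", "OH0", "Si"]


def _kr_atom(sym: str) -> str:
    return f"[{sym}]"


def _klekota_roth_family() -> list:
    """Bonded-chain enumeration over an H-count/ring-specific atom
    alphabet: all length-2 chains, then length-3 chains in deterministic
    product order up to the published family size (4,860)."""
    descs = []
    for a, b in itertools.product(_KR_ATOMS, _KR_ATOMS):
        for bond in _KR_BONDS:
            descs.append(("smarts", f"{_kr_atom(a)}{bond}{_kr_atom(b)}"))
    for a, m, b in itertools.product(_KR_ATOMS, _KR_MIDS, _KR_ATOMS):
        if len(descs) >= 4860:
            break
        descs.append(("smarts", f"{_kr_atom(a)}-{_kr_atom(m)}-{_kr_atom(b)}"))
        if len(descs) < 4860:
            descs.append(("smarts", f"{_kr_atom(a)}~{_kr_atom(m)}~{_kr_atom(b)}"))
    return _fill(descs, 4860)


_FAMILY_BUILDERS = {
    "substructure": _substructure_family,
    "pubchem": _pubchem_family,
    "klekota_roth": _klekota_roth_family,
}

_SMARTS_ELEM_CACHE: dict[str, tuple] = {}


@lru_cache(maxsize=None)
def _compiled_family(family: str):
    """Descriptors with pre-compiled SMARTS queries and element prescreens."""
    descs = _FAMILY_BUILDERS[family]()
    compiled = []
    for d in descs:
        if d[0] == "smarts":
            q = Chem.MolFromSmarts(d[1])
            if q is None:
                raise AssertionError(f"invalid bundled SMARTS: {d[1]}")
            elems = frozenset(
                a.GetAtomicNum() for a in q.GetAtoms() if a.GetAtomicNum() > 0
            )
            compiled.append(("smarts", q, elems, d[1]))
        else:
            compiled.append(d)
    return compiled


# ---------------------------------------------------------------------------
# structure handling and bit evaluation
# ---------------------------------------------------------------------------

def parse_structure(structure: str) -> Chem.Mol:
    """Parse a SMILES or InChI string; stereochemistry is discarded."""
    text = structure.strip()
    mol = Chem.MolFromInchi(text) if text.startswith("InChI=") else Chem.MolFromSmiles(text)
    if mol is None:
        raise ValueError(f"unparsable structure: {structure!r}")
    Chem.RemoveStereochemistry(mol)
    return mol


def canonical_smiles(structure: str) -> str:
    return Chem.MolToSmiles(parse_structure(structure))


def _element_counts(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        h += atom.GetTotalNumHs()
    counts["H"] = counts.get("H", 0) + h
    return counts


def _ring_size_counts(mol: Chem.Mol) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for ring in mol.GetRingInfo().AtomRings():
        sizes[len(ring)] = sizes.get(len(ring), 0) + 1
    return sizes


def _n_aromatic_rings(mol: Chem.Mol) -> int:
    return sum(
        1
        for ring in mol.GetRingInfo().BondRings()
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
    )


def _eval_descriptors(mol: Chem.Mol, compiled) -> np.ndarray:
    counts = _element_counts(mol)
    rings = _ring_size_counts(mol)
    n_arom = _n_aromatic_rings(mol)
    mol_elems = frozenset(a.GetAtomicNum() for a in mol.GetAtoms())
    bits = np.zeros(len(compiled), dtype=np.uint8)
    for i, d in enumerate(compiled):
        kind = d[0]
        if kind == "smarts":
            _, q, elems, _ = d
            if elems <= mol_elems and mol.HasSubstructMatch(q):
                bits[i] = 1
        elif kind == "count":
            bits[i] = counts.get(d[1], 0) >= d[2]
        elif kind == "ring":
            bits[i] = rings.get(d[1], 0) >= d[2]
        else:  # aromring
            bits[i] = n_arom >= d[1]
    return bits


def compute_block(structure, family: str) -> np.ndarray:
    """Binary vector of one family for a structure (SMILES/InChI/Mol)."""
    lengths = dict(FAMILIES)
    if family not in lengths:
        raise ValueError(f"unknown fingerprint family '{family}'")
    mol = structure if isinstance(structure, Chem.Mol) else parse_structure(structure)
    if family == "maccs":
        keys = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; key 0 is padding
        bits = np.array([keys.GetBit(i) for i in range(1, 167)], dtype=np.uint8)
    else:
        bits = _eval_descriptors(mol, _compiled_family(family))
    assert bits.size == lengths[family]
    return bits


@dataclass
class FingerprintVector:
    """Concatenated binary fingerprint, optionally column-masked."""

    bits: np.ndarray
    masked: bool = False
    mask_id: str | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        if not self.masked and self.bits.size != TOTAL_BITS:
            raise ValueError(
                f"unmasked fingerprint must have {TOTAL_BITS} bits, got {self.bits.size}")


def concatenate(blocks: dict[str, np.ndarray]) -> FingerprintVector:
    """Concatenate one vector per family in the fixed block order."""
    missing = [f for f, _ in FAMILIES if f not in blocks]
    if missing:
        raise ValueError(f"missing fingerprint block(s): {missing}")
    parts = []
    for fam, n in FAMILIES:
        b = np.asarray(blocks[fam], dtype=np.uint8)
        if b.size != n:
            raise ValueError(f"block '{fam}' has length {b.size}, expected {n}")
        parts.append(b)
    return FingerprintVector(np.concatenate(parts))


@lru_cache(maxsize=16384)
def _fingerprint_bits_cached(canonical: str) -> bytes:
    mol = Chem.MolFromSmiles(canonical)
    blocks = {fam: compute_block(mol, fam) for fam, _ in FAMILIES}
    return concatenate(blocks).bits.tobytes()


def compute_fingerprint(structure: str) -> FingerprintVector:
    """Full 6,214-bit fingerprint of a SMILES/InChI structure (cached by
    canonical SMILES, so isomorphic inputs share one computation)."""
    bits = np.frombuffer(
        _fingerprint_bits_cached(canonical_smiles(structure)), dtype=np.uint8
    ).copy()
    return FingerprintVector(bits)


# ---------------------------------------------------------------------------
# column mask
# ---------------------------------------------------------------------------

@dataclass
class ColumnMask:
    """Retained-column selection built on a training fingerprint matrix.

    ``removed`` maps column index -> rule ("constant" or "duplicate").
    """

    retained: np.ndarray
    removed: dict[int, str] = field(default_factory=dict)
    mask_id: str = ""

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=int)
        if not self.mask_id:
            h = hashlib.sha1(self.retained.tobytes())
            self.mask_id = h.hexdigest()[:16]

    @property
    def n_retained(self) -> int:
        return self.retained.size


def build_mask(training_fps: list[FingerprintVector]) -> ColumnMask:
    """Drop constant columns, then all but the lowest-index member of each
    group of identical columns, over the training set."""
    if len(training_fps) < 2:
        raise ValueError("build_mask needs at least two fingerprints")
    lengths = {fp.bits.size for fp in training_fps}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
    M = np.stack([fp.bits for fp in training_fps])  # n x p
    removed: dict[int, str] = {}
    constant = (M == M[0]).all(axis=0)
    seen: dict[bytes, int] = {}
    retained = []
    for j in range(M.shape[1]):
        if constant[j]:
            removed[j] = "constant"
            continue
        key = M[:, j].tobytes()
        if key in seen:
            removed[j] = "duplicate"
        else:
            seen[key] = j
            retained.append(j)
    return ColumnMask(np.array(retained, dtype=int), removed)


def apply_mask(fp: FingerprintVector, mask: ColumnMask) -> FingerprintVector:
    """Project a fingerprint onto the mask's retained columns."""
    if fp.masked:
        raise ValueError("fingerprint is already masked; re-masking rejected")
    if mask.retained.size and mask.retained.max() >= fp.bits.size:
        raise ValueError("mask layout does not match fingerprint length")
    if len(mask.removed) + mask.n_retained != fp.bits.size:
        raise ValueError("mask layout does not match fingerprint length")
    return FingerprintVector(fp.bits[mask.retained], masked=True, mask_id=mask.mask_id)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Jaccard/Tanimoto similarity of two binary fingerprints."""
    if a.bits.size != b.bits.size:
        raise ValueError("fingerprint lengths differ")
    inter = int(np.sum((a.bits == 1) & (b.bits == 1)))
    union = int(np.sum((a.bits == 1) | (b.bits == 1)))
    return inter / union if union else 1.0


def export_pattern_files(directory) -> None:
    """Write each synthetic family's descriptor list as a plain-text file
    (one descriptor per line) for audit."""
    import os

    os.makedirs(directory, exist_ok=True)
    for fam in _FAMILY_BUILDERS:
        with open(os.path.join(directory, f"{fam}.patterns.txt"), "w") as fh:
            fh.write(f"# {fam} fingerprint descriptors (synthetic stand-in set)\n")
            for d in _FAMILY_BUILDERS[fam]():
                if d[0] == "smarts":
                    fh.write(f"smarts\t{d[1]}\n")
                else:
                    fh.write("\t".join(str(x) for x in d) + "\n")
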