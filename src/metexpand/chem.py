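"""Structure handling: parsing, canonicalization and elemental accounting.

Molecules enter the workflow as MDL molfiles (V2000) or SMILES strings and
are reduced to a *constitutional* representation: all stereo descriptors
(wedges, atom parity, double-bond geometry) are stripped before the
canonical key is computed, because the network generator treats
stereoisomers as a single compound.  The canonical key is RDKit's canonical
SMILES of the stereo-stripped molecule under RDKit's default aromaticity
model; it is the deduplication key for every downstream stage.  Tautomers
are *not* merged: distinct tautomers keep distinct keys.

Inputs must be single-fragment.  Intramolecular charges are accepted
(quaternary protoberberinium alkaloids are legitimate pathway
intermediates); multi-fragment input (salts, mixtures) is rejected rather
than split.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

from .errors import ChemistryError, ParseError

RDLogger.DisableLog("rdApp.*")  # errors are re-raised as package exceptions

#: formats accepted by :func:`parse_structure`
FORMATS = ("smiles", "molfile")


@dataclass(frozen=True)
class FilterSpec:
    """Minimal elemental composition a compound must contain.

    Defaults are the 1-benzylisoquinoline scaffold minimum: at least 16
    carbon, 13 hydrogen and 1 nitrogen atoms.
    """

    min_c: int = 16
    min_h: int = 13
    min_n: int = 1

    def __post_init__(self) -> None:
        if min(self.min_c, self.min_h, self.min_n) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class Molecule:
    """An immutable parsed structure.

    Attributes
    ----------
    name:
        Free-text label; purely descriptive (an ``(S)-`` prefix in a name is
        a label only — the structure itself carries no stereochemistry).
    canonical_key:
        Stereo-stripped canonical SMILES; the identity of the compound
        throughout the package.
    element_counts:
        Element symbol -> count, with implicit hydrogens materialized.
        ``C``, ``H`` and ``N`` are always present (possibly 0).
    """

    name: str
    canonical_key: str
    element_counts: dict[str, int]
    source: str = field(compare=False, repr=False, default="")
    source_format: str = field(compare=False, repr=False, default="smiles")

    @property
    def mol(self) -> Chem.Mol:
        """The RDKit molecule (rebuilt from the canonical key)."""
        return Chem.MolFromSmiles(self.canonical_key)

    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)

    def to_smiles(self) -> str:
        return self.canonical_key

    def to_molfile(self) -> str:
        return Chem.MolToMolBlock(self.mol)


def strip_stereo_key(mol: Chem.Mol) -> str:
    """Canonical SMILES of *mol* with every stereo descriptor removed."""
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return Chem.MolToSmiles(flat)


def element_counts(mol: Chem.Mol) -> dict[str, int]:
    """Per-element atom counts with valence-completed hydrogens."""
    counts: dict[str, int] = {"C": 0, "H": 0, "N": 0}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        counts["H"] += atom.GetTotalNumHs()
    return counts


def _raise_chemistry_problems(mol: Chem.Mol) -> None:
    problems = Chem.DetectChemistryProblems(mol)
    for p in problems:
        if p.GetType() == "AtomValenceException":
            atom = mol.GetAtomWithIdx(p.GetAtomIdx())
            raise ChemistryError(
                f"impossible valence at atom {p.GetAtomIdx()} ({atom.GetSymbol()}): {p.Message()}"
            )
    if problems:
        raise ChemistryError("; ".join(p.Message() for p in problems))


def mol_from_source(text: str, fmt: str) -> Chem.Mol:
    """Parse *text* in format *fmt* into a sanitized RDKit molecule."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if not text or not text.strip():
        raise ParseError(f"empty {fmt} document")
    if fmt == "smiles":
        token = text.strip().split()[0]
        mol = Chem.MolFromSmiles(token, sanitize=False)
        if mol is None:
            raise ParseError(f"unparseable SMILES token {token!r}")
    else:
        if "V3000" in text:
            raise ParseError("V3000 connection tables are not supported (V2000 only)")
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if mol is None:
            # locate the counts line for a helpful message
            lines = text.splitlines()
            hint = lines[3] if len(lines) > 3 else "<truncated header>"
            raise ParseError(f"unparseable molfile (counts line: {hint!r})")
        mol = Chem.RemoveHs(mol, sanitize=False)
    _raise_chemistry_problems(mol)
    Chem.SanitizeMol(mol)
    return mol


def parse_structure(text: str, fmt: str = "smiles", name: str = "") -> Molecule:
    """Parse a structure document into a :class:`Molecule`.

    Raises :class:`ParseError` on malformed input, :class:`ChemistryError`
    on valence-impossible structures or multi-fragment input.
    """
    mol = mol_from_source(text, fmt)
    n_frags = len(Chem.GetMolFrags(mol))
    if n_frags != 1:
        raise ChemistryError(
            f"expected a single-fragment structure, got {n_frags} fragments "
            "(salts/mixtures are rejected, not split)"
        )
    return Molecule(
        name=name or _name_from_source(text, fmt),
        canonical_key=strip_stereo_key(mol),
        element_counts=element_counts(mol),
        source=text,
        source_format=fmt,
    )


def _name_from_source(text: str, fmt: str) -> str:
    if fmt == "molfile":
        first = text.splitlines()[0].strip()
        return first
    parts = text.strip().split(None, 1)
    return parts[1].strip() if len(parts) > 1 else ""


def from_rdkit(mol: Chem.Mol, name: str = "") -> Molecule:
    """Wrap an in-memory RDKit molecule (used for rule products)."""
    key = strip_stereo_key(mol)
    return Molecule(name=name, canonical_key=key, element_counts=element_counts(mol), source=key)


def passes_filter(m: Molecule, spec: FilterSpec | None = None) -> bool:
    """True iff *m* contains at least the composition required by *spec*."""
    spec = spec or FilterSpec()
    ec = m.element_counts
    return (
        ec.get("C", 0) >= spec.min_c
        and ec.get("H", 0) >= spec.min_h
        and ec.get("N", 0) >= spec.min_n
    )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def counts_from_formula(formula: str) -> dict[str, int]:
    """Parse a Hill formula like ``C21H25NO4`` into element counts.

    Charge suffixes (``+``/``-``) are ignored.  Convenience for tests and
    table readers.
    """
    counts: dict[str, int] = {"C": 0, "H": 0, "N": 0}
    for sym, num in _FORMULA_TOKEN.findall(formula):
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    return counts
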