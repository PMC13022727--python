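"""Atom-mapped molecules, reactions, and the marker-atom dialect.

Molecules are plain RDKit ``Mol`` objects.  An *abstracted* molecule is a
``Mol`` in which each removed leaving substructure is represented by an
attachment-point pseudo-atom (atomic number 0) bonded to the core atom.
The pseudo-atom's isotope field encodes the marker class and multiplicity:

====================  =======================================
isotope               meaning
====================  =======================================
``1`` .. ``4``        single marker of class HET / C(+) / C(-) / C(0)
``m*10 + c``          class ``c`` with multiplicity ``m`` > 1
====================  =======================================

Multiplicity counts attachment bond orders: a carbonyl oxygen that leaves
contributes 2 to its core atom's marker, the same as two single-bonded
leaving neighbors of equal class.  Core atoms that lost a neighbor or a
hydrogen have their hydrogen count pinned explicitly so that the
abstracted form is self-contained in SMILES.

The on-disk reaction record format is tab-separated::

    document_id <TAB> record_id <TAB> reactants>agents>products

Agents between the two ``>`` separators are discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


class MarkerClass(IntEnum):
    """Polarity class of an abstracted leaving substructure.

    The class records the electronegativity relationship between the core
    atom and the first atom of the removed substructure: heteroatom cores
    collapse to a single HET class, carbon cores are split into
    electrophilic C(+), nucleophilic C(-), and neutral carbon attachments.
    """

    HET = 1
    C_PLUS = 2
    C_MINUS = 3
    C_NEUTRAL = 4

    @property
    def token(self) -> str:
        return _MARKER_TOKENS[self]


_MARKER_TOKENS = {
    MarkerClass.HET: "HET",
    MarkerClass.C_PLUS: "C(+)",
    MarkerClass.C_MINUS: "C(-)",
    MarkerClass.C_NEUTRAL: "C(0)",
}

#: Pauling electronegativities for the elements handled by the abstraction
#: heuristics.  Carbon is the reference value.
PAULING_EN: dict[str, float] = {
    "H": 2.20,
    "Li": 0.98,
    "B": 2.04,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "F": 3.98,
    "Na": 0.93,
    "Mg": 1.31,
    "Al": 1.61,
    "Si": 1.90,
    "P": 2.19,
    "S": 2.58,
    "Cl": 3.16,
    "K": 0.82,
    "Ca": 1.00,
    "Zn": 1.65,
    "Cu": 1.90,
    "Fe": 1.83,
    "Se": 2.55,
    "Br": 2.96,
    "Sn": 1.96,
    "I": 2.66,
    "Pd": 2.20,
}

#: Default half-width of the neutral band around carbon, in Pauling units.
EN_THRESHOLD = 0.1


class ReactionParseError(ValueError):
    """A reaction record could not be parsed into molecules."""


class RecordSkip(Exception):
    """Record is well-formed but should be skipped (e.g. zero products)."""


def marker_isotope(cls: MarkerClass, multiplicity: int = 1) -> int:
    if multiplicity < 1:
        raise ValueError("marker multiplicity must be >= 1")
    return int(cls) if multiplicity == 1 else multiplicity * 10 + int(cls)


def parse_marker_isotope(isotope: int) -> tuple[MarkerClass, int]:
    if isotope < 10:
        return MarkerClass(isotope), 1
    return MarkerClass(isotope % 10), isotope // 10


def is_marker(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() == 0 and atom.GetIsotope() > 0


def iter_markers(mol: Chem.Mol) -> Iterator[tuple[int, MarkerClass, int]]:
    """Yield ``(core_atom_idx, marker_class, multiplicity)`` per marker atom."""
    for atom in mol.GetAtoms():
        if is_marker(atom):
            cls, mult = parse_marker_isotope(atom.GetIsotope())
            nbrs = atom.GetNeighbors()
            if len(nbrs) != 1:
                raise ValueError("marker atom must have exactly one core neighbor")
            yield nbrs[0].GetIdx(), cls, mult


def has_markers(mol: Chem.Mol) -> bool:
    return any(is_marker(a) for a in mol.GetAtoms())


@dataclass
class MappedReaction:
    """A single-product atom-mapped reaction from one document record."""

    reactants: list[Chem.Mol]
    product: Chem.Mol
    document_id: str = ""
    record_id: str = ""

    def smiles(self) -> str:
        lhs = ".".join(Chem.MolToSmiles(m) for m in self.reactants)
        return f"{lhs}>>{Chem.MolToSmiles(self.product)}"


@dataclass
class MappingReport:
    """Validation report for the atom mapping of one reaction."""

    missing_product_maps: list[int] = field(default_factory=list)
    duplicate_maps: list[int] = field(default_factory=list)
    orphan_product_atoms: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.missing_product_maps
            or self.duplicate_maps
            or self.orphan_product_atoms
        )

    def entries(self) -> list[str]:
        out = []
        for idx in self.missing_product_maps:
            out.append(f"incomplete mapping: product atom {idx} has no map number")
        for num in self.duplicate_maps:
            out.append(f"duplicate map: map number {num} repeated within a molecule")
        for idx in self.orphan_product_atoms:
            out.append(f"orphan product atom: atom {idx} map absent from reactants")
        return out


def _parse_part(smiles: str, what: str, record_id: str) -> list[Chem.Mol]:
    if not smiles:
        return []
    mols = []
    for frag in smiles.split("."):
        mol = Chem.MolFromSmiles(frag)
        if mol is None:
            raise ReactionParseError(
                f"record {record_id!r}: unparseable {what} SMILES {frag!r}"
            )
        mols.append(mol)
    return mols


def parse_mapped_reaction(
    reaction_smiles: str,
    document_id: str = "",
    record_id: str = "",
    multiproduct: str = "largest",
) -> MappedReaction:
    """Parse a ``reactants>agents>products`` record into a :class:`MappedReaction`.

    Agents are discarded.  Multi-product records keep only the largest
    product by heavy-atom count (``multiproduct='largest'``) or raise
    :class:`RecordSkip` (``multiproduct='reject'``).
    """
    parts = reaction_smiles.strip().split(">")
    if len(parts) == 2:
        lhs, rhs = parts
        agents = ""
    elif len(parts) == 3:
        lhs, agents, rhs = parts
    else:
        raise ReactionParseError(
            f"record {record_id!r}: expected 'reactants>agents>products'"
        )
    del agents
    reactants = _parse_part(lhs, "reactant", record_id)
    products = _parse_part(rhs, "product", record_id)
    if not products:
        raise RecordSkip(f"record {record_id!r}: zero products")
    if len(products) > 1:
        if multiproduct == "reject":
            raise RecordSkip(f"record {record_id!r}: {len(products)} products")
        products.sort(key=lambda m: m.GetNumHeavyAtoms(), reverse=True)
    return MappedReaction(
        reactants=reactants,
        product=products[0],
        document_id=document_id,
        record_id=record_id,
    )


def validate_mapping(rxn: MappedReaction) -> MappingReport:
    """Report missing, duplicated, and orphan atom-map numbers."""
    report = MappingReport()
    reactant_maps: set[int] = set()
    for mol in rxn.reactants + [rxn.product]:
        seen: set[int] = set()
        for atom in mol.GetAtoms():
            num = atom.GetAtomMapNum()
            if num > 0:
                if num in seen:
                    report.duplicate_maps.append(num)
                seen.add(num)
        if mol is not rxn.product:
            reactant_maps |= seen
    for atom in rxn.product.GetAtoms():
        if is_marker(atom):
            continue
        num = atom.GetAtomMapNum()
        if num == 0:
            report.missing_product_maps.append(atom.GetIdx())
        elif num not in reactant_maps:
            report.orphan_product_atoms.append(atom.GetIdx())
    return report


def strip_maps(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy of *mol* with all atom-map numbers cleared."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def canonical_serialize(mol: Chem.Mol) -> str:
    """Canonical SMILES of a molecule, ignoring atom-map numbers.

    Marker pseudo-atoms (class and multiplicity, via the isotope field)
    and pinned hydrogen counts are part of the canonical form, so two
    abstracted molecules compare equal iff their core graphs and marker
    annotations agree.
    """
    return Chem.MolToSmiles(strip_maps(mol))


def normalize_pins(mol: Chem.Mol) -> Chem.Mol | None:
    """Clear hydrogen pinning wherever the implicit count would be identical.

    Abstraction and template application both pin explicit hydrogen
    counts on atoms they touch; pins that agree with the implicit value
    RDKit would assign anyway are redundant and would make otherwise
    equal molecules serialize differently.  Returns a sanitized copy
    keeping only load-bearing pins, or ``None`` if the molecule cannot
    be sanitized at all.
    """
    out = Chem.RWMol(mol)
    pinned = []
    for atom in out.GetAtoms():
        if atom.GetNoImplicit():
            pinned.append((atom.GetIdx(), atom.GetTotalNumHs()))
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
    result = out.GetMol()
    try:
        Chem.SanitizeMol(result)
    except Exception:
        # retry keeping the pins; some are load-bearing (open valences)
        result = Chem.Mol(mol)
        try:
            Chem.SanitizeMol(result)
            return result
        except Exception:
            return None
    changed = [
        (idx, h) for idx, h in pinned if result.GetAtomWithIdx(idx).GetTotalNumHs() != h
    ]
    for idx, h in changed:
        atom = result.GetAtomWithIdx(idx)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(h)
    if changed:
        Chem.SanitizeMol(result)
    return result


def canonical_atom_alignment(mol_a: Chem.Mol, mol_b: Chem.Mol) -> list[int]:
    """Atom-index mapping from *mol_a* onto the isomorphic *mol_b*.

    Both molecules must have identical map-stripped canonical SMILES; the
    alignment is derived from canonical atom ranks and is therefore an
    actual graph isomorphism (up to automorphism for symmetric atoms).
    """
    ra = list(Chem.CanonicalRankAtoms(strip_maps(mol_a), breakTies=True))
    rb = list(Chem.CanonicalRankAtoms(strip_maps(mol_b), breakTies=True))
    if sorted(ra) != sorted(rb) or mol_a.GetNumAtoms() != mol_b.GetNumAtoms():
        raise ValueError("molecules are not isomorphic")
    inv_b = {rank: idx for idx, rank in enumerate(rb)}
    return [inv_b[rank] for rank in ra]


def map_index(mol: Chem.Mol) -> dict[int, int]:
    """Map-number -> atom-index lookup for one molecule."""
    return {
        a.GetAtomMapNum(): a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0
    }


_RECORD_RE = re.compile(r"^([^\t]*)\t([^\t]*)\t(.+)$")


def read_reaction_records(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(document_id, record_id, reaction_smiles)`` from a corpus file."""
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            match = _RECORD_RE.match(line)
            if match is None:
                raise ReactionParseError(f"{path}:{line_no}: malformed record line")
            yield match.group(1), match.group(2), match.group(3)


def write_reaction_records(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as handle:
        for document_id, record_id, smiles in records:
            handle.write(f"{document_id}\t{record_id}\t{smiles}\n")
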