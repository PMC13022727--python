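"""Synthon abstraction: markers for leaving substructures, higher-level routes.

Leaving substructures identified by atom provenance are removed and
replaced by polarity-classed markers on their core attachment atoms.
Heteroatom cores collapse to a single HET class; carbon cores are split
by the Pauling electronegativity of the attached leaving atom relative
to carbon: C(+) for more electronegative attachments (halides,
triflates, ...), C(-) for less electronegative ones (boronates,
stannanes, hydrogens of C-H nucleophile equivalents), and C(0) within a
neutral band.  Reactions whose abstracted principal reactant equals
their abstracted product ("tactical" steps: leaving-group FGIs,
protections) are removed from the higher-level route; the route graph
reconnects automatically because both endpoints share one abstracted
form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from rdkit import Chem

from retrostrat.chem import (
    EN_THRESHOLD,
    PAULING_EN,
    MappedReaction,
    MarkerClass,
    canonical_serialize,
    marker_isotope,
    normalize_pins,
)
from retrostrat.routes import AtomProvenance, MoleculeProvenance, Route

log = logging.getLogger(__name__)


class AbstractionError(ValueError):
    pass


def classify_marker(
    core_symbol: str,
    leaving_symbol: str,
    table: dict[str, float] | None = None,
    threshold: float = EN_THRESHOLD,
) -> MarkerClass:
    """Polarity class of a leaving attachment on *core_symbol*.

    Heteroatom cores always give HET.  For carbon cores the class follows
    the sign of ``EN(leaving) - EN(C)`` outside the ``threshold`` band.
    """
    table = PAULING_EN if table is None else table
    if core_symbol != "C":
        return MarkerClass.HET
    try:
        delta = table[leaving_symbol] - table["C"]
    except KeyError as exc:
        raise AbstractionError(f"element {exc} missing from electronegativity table")
    if delta > threshold:
        return MarkerClass.C_PLUS
    if delta < -threshold:
        return MarkerClass.C_MINUS
    return MarkerClass.C_NEUTRAL


def abstract_molecule(
    mol: Chem.Mol,
    prov: MoleculeProvenance,
    table: dict[str, float] | None = None,
    threshold: float = EN_THRESHOLD,
) -> Chem.Mol | None:
    """Replace leaving substructures of *mol* by markers on core atoms.

    Returns ``None`` when every atom is leaving (spectator reagent).  A
    molecule with an empty leaving set and no lost hydrogens is returned
    structurally unchanged.  Core atoms that lost a neighbor or hydrogen
    get their hydrogen count pinned to the retained value.
    """
    n = mol.GetNumAtoms()
    leaving = [i for i in range(n) if not prov.core[i]]
    if len(leaving) == n:
        return None

    # accumulate marker multiplicities per (core atom, class)
    markers: dict[tuple[int, MarkerClass], int] = {}
    touched: set[int] = set()
    leaving_set = set(leaving)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if (a.GetIdx() in leaving_set) == (b.GetIdx() in leaving_set):
            continue
        core_atom, leave_atom = (a, b) if b.GetIdx() in leaving_set else (b, a)
        cls = classify_marker(
            core_atom.GetSymbol(), leave_atom.GetSymbol(), table, threshold
        )
        order = max(1, int(bond.GetBondTypeAsDouble()))
        key = (core_atom.GetIdx(), cls)
        markers[key] = markers.get(key, 0) + order
        touched.add(core_atom.GetIdx())
    for idx in range(n):
        if not prov.core[idx]:
            continue
        atom = mol.GetAtomWithIdx(idx)
        lost_h = atom.GetTotalNumHs() - prov.core_h[idx]
        if lost_h > 0:
            cls = classify_marker(atom.GetSymbol(), "H", table, threshold)
            key = (idx, cls)
            markers[key] = markers.get(key, 0) + lost_h
            touched.add(idx)

    out = Chem.RWMol(mol)
    for (core_idx, cls), mult in sorted(markers.items()):
        midx = out.AddAtom(Chem.Atom(0))
        out.GetAtomWithIdx(midx).SetIsotope(marker_isotope(cls, mult))
        out.AddBond(core_idx, midx, Chem.BondType.SINGLE)
    for idx in touched:
        atom = out.GetAtomWithIdx(idx)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(prov.core_h[idx])
        if atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED and any(
            nb.GetIdx() in leaving_set for nb in mol.GetAtomWithIdx(idx).GetNeighbors()
        ):
            # stereo descriptor references a removed neighbor
            log.warning("dropping chiral tag on atom %d during abstraction", idx)
            atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for idx in sorted(leaving, reverse=True):
        out.RemoveAtom(idx)
    result = out.GetMol()
    try:
        Chem.SanitizeMol(result)
    except Exception as exc:
        raise AbstractionError(f"abstracted molecule failed sanitization: {exc}")
    result = normalize_pins(result)
    if result is None:  # pragma: no cover - sanitized above
        raise AbstractionError("abstracted molecule failed pin normalization")
    return result


@dataclass
class AbstractedReaction:
    """One route step after abstraction; spectator reactants removed."""

    reactants: list[Chem.Mol]
    product: Chem.Mol
    document_id: str = ""
    record_id: str = ""

    @property
    def reactant_smiles(self) -> tuple[str, ...]:
        return tuple(sorted(canonical_serialize(m) for m in self.reactants))

    @property
    def product_smiles(self) -> str:
        return canonical_serialize(self.product)

    def smiles(self) -> str:
        lhs = ".".join(Chem.MolToSmiles(m) for m in self.reactants)
        return f"{lhs}>>{Chem.MolToSmiles(self.product)}"


def abstract_reaction(
    rxn: MappedReaction,
    prov: AtomProvenance,
    table: dict[str, float] | None = None,
    threshold: float = EN_THRESHOLD,
) -> AbstractedReaction:
    """Abstract both sides of one route step under route provenance."""
    product = abstract_molecule(
        rxn.product, prov.molecules[(rxn.record_id, "p")], table, threshold
    )
    if product is None:
        raise AbstractionError(f"record {rxn.record_id}: product fully leaving")
    reactants = []
    for i, mol in enumerate(rxn.reactants):
        abst = abstract_molecule(mol, prov.molecules[(rxn.record_id, i)], table, threshold)
        if abst is not None:
            reactants.append(abst)
    return AbstractedReaction(
        reactants=reactants,
        product=product,
        document_id=rxn.document_id,
        record_id=rxn.record_id,
    )


def is_tactical(rxn: AbstractedReaction) -> bool:
    """A step that only transforms leaving substructures.

    True iff exactly one reactant contributes core atoms and its
    abstracted form equals the abstracted product.
    """
    if len(rxn.reactants) != 1:
        return False
    return canonical_serialize(rxn.reactants[0]) == canonical_serialize(rxn.product)


@dataclass
class HigherLevelRoute:
    """Route after abstraction with tactical steps removed."""

    document_id: str
    target: str
    steps: list[AbstractedReaction]
    depth: int
    n_reactions: int
    removed_records: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.steps


def build_higher_level_route(
    route: Route,
    prov: AtomProvenance,
    table: dict[str, float] | None = None,
    threshold: float = EN_THRESHOLD,
) -> HigherLevelRoute:
    """Abstract a route and drop its tactical steps.

    Tactical endpoints merge because both carry one abstracted canonical
    form; depth and reaction count are recomputed on the remaining DAG.
    """
    steps: list[AbstractedReaction] = []
    removed: list[str] = []
    seen_pairs: set[tuple[str, tuple[str, ...]]] = set()
    for rxn in route.reactions:
        abst = abstract_reaction(rxn, prov, table, threshold)
        if is_tactical(abst):
            removed.append(rxn.record_id)
            continue
        key = (abst.product_smiles, abst.reactant_smiles)
        if key in seen_pairs:
            removed.append(rxn.record_id)
            continue
        seen_pairs.add(key)
        steps.append(abst)
    depth = _hl_depth(steps, route.target)
    return HigherLevelRoute(
        document_id=route.document_id,
        target=route.target,
        steps=steps,
        depth=depth,
        n_reactions=len(steps),
        removed_records=removed,
    )


def _hl_depth(steps: list[AbstractedReaction], target: str) -> int:
    produced = {s.product_smiles: s for s in steps}
    cache: dict[str, int] = {}

    def mol_depth(smiles: str) -> int:
        if smiles in cache:
            return cache[smiles]
        step = produced.get(smiles)
        if step is None:
            cache[smiles] = 0
            return 0
        cache[smiles] = 0
        value = 1 + max((mol_depth(s) for s in step.reactant_smiles), default=0)
        cache[smiles] = value
        return value

    return mol_depth(target)


@dataclass
class DatasetEntry:
    """One unique reactant/product pair with its precedents."""

    product: str
    reactants: tuple[str, ...]
    example: AbstractedReaction  # mapped example reaction for template extraction
    precedents: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.precedents)

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        return (self.product, self.reactants)


@dataclass
class CuratedDataset:
    """Deduplicated reaction dataset (higher-level or original space)."""

    entries: list[DatasetEntry]
    excluded: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def write_jsonl(self, path) -> None:
        with open(path, "w") as handle:
            for e in self.entries:
                handle.write(
                    json.dumps(
                        {
                            "product": e.product,
                            "reactants": list(e.reactants),
                            "example": e.example.smiles(),
                            "precedents": e.precedents,
                            "count": e.count,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )


def curate_dataset(
    hl_routes: list[HigherLevelRoute],
    exclusions: list[tuple[str, tuple[str, ...]]] | None = None,
) -> CuratedDataset:
    """Deduplicate higher-level steps into unique reactant/product pairs.

    ``exclusions`` lists benchmark pairs to withhold (compared on
    canonical product and sorted reactant strings).
    """
    excluded_keys = {(p, tuple(r)) for p, r in (exclusions or [])}
    by_key: dict[tuple[str, tuple[str, ...]], DatasetEntry] = {}
    n_excluded = 0
    for route in hl_routes:
        for step in route.steps:
            key = (step.product_smiles, step.reactant_smiles)
            if key in excluded_keys:
                n_excluded += 1
                continue
            entry = by_key.get(key)
            if entry is None:
                by_key[key] = entry = DatasetEntry(
                    product=key[0], reactants=key[1], example=step
                )
            entry.precedents.append(f"{route.document_id}:{step.record_id}")
    entries = sorted(by_key.values(), key=lambda e: e.key)
    return CuratedDataset(entries=entries, excluded=n_excluded)


def concrete_reaction(rxn: MappedReaction, prov: AtomProvenance) -> AbstractedReaction:
    """Route step kept in the original (concrete) space.

    No markers are installed; reactants contributing no atoms to the
    product are still dropped so that pairs are comparable across
    documents.
    """
    pmap = {a.GetAtomMapNum() for a in rxn.product.GetAtoms() if a.GetAtomMapNum() > 0}
    reactants = [
        mol
        for mol in rxn.reactants
        if any(a.GetAtomMapNum() in pmap for a in mol.GetAtoms())
    ]
    return AbstractedReaction(
        reactants=[Chem.Mol(m) for m in reactants],
        product=Chem.Mol(rxn.product),
        document_id=rxn.document_id,
        record_id=rxn.record_id,
    )


def concrete_route(route: Route, prov: AtomProvenance) -> HigherLevelRoute:
    """Original-space counterpart of :func:`build_higher_level_route`."""
    steps = [concrete_reaction(rxn, prov) for rxn in route.reactions]
    return HigherLevelRoute(
        document_id=route.document_id,
        target=route.target,
        steps=steps,
        depth=route.depth,
        n_reactions=route.n_reactions,
    )
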