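"""Retrosynthetic templates: extraction, application, consolidation.

A template is a retro rewrite rule ``product_pattern >> precursor_patterns``
in a SMARTS dialect whose atoms carry exact hydrogen counts and charges,
and whose attachment-point pseudo-atoms (``[c#0]`` with a class/multiplicity
isotope) make the rules marker-aware.  Extraction takes the atoms changed
by the reaction plus ``radius`` bonds of context (carbonyl-type
double-bonded O/N/S neighbors are always completed); application runs the
rule with RDKit's reaction machinery and re-normalizes hydrogen pinning so
outputs are comparable with curated abstracted molecules.

Consolidation follows the "most general recovering template" rule: all
extracted candidates (the context template and its radius-0
generalization) are applied to every reaction product, and each reaction
is assigned the recovering template with the widest coverage over the
training reactions, ties broken by fewer pattern atoms, then
lexicographic SMARTS.
"""

from __future__ import annotations

import ast
import hashlib
import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import AllChem

from retrostrat.abstraction import AbstractedReaction, DatasetEntry
from retrostrat.chem import canonical_serialize, is_marker, map_index, normalize_pins

log = logging.getLogger(__name__)


class TemplateError(ValueError):
    pass


@dataclass
class RetroTemplate:
    """A retro rewrite rule with bookkeeping for consolidation."""

    template_id: str
    smarts: str  # "product_pattern>>precursor.patterns"
    radius: int
    n_pattern_atoms: int
    precedent_count: int = 0
    _rxn: object = field(default=None, repr=False, compare=False)
    _query: object = field(default=None, repr=False, compare=False)

    @property
    def product_pattern(self) -> str:
        return self.smarts.split(">>")[0]

    @property
    def rxn(self):
        if self._rxn is None:
            self._rxn = AllChem.ReactionFromSmarts(self.smarts)
            self._rxn.Initialize()
        return self._rxn

    @property
    def query(self) -> Chem.Mol:
        if self._query is None:
            self._query = Chem.MolFromSmarts(self.product_pattern)
        return self._query


def _charge_token(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    return sign if abs(charge) == 1 else f"{sign}{abs(charge)}"


def _atom_symbol(atom: Chem.Atom, mapno: int) -> str:
    if atom.GetAtomicNum() == 0:
        return f"[{atom.GetIsotope()}#0]"
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    token = f"{sym}H{atom.GetTotalNumHs()}{_charge_token(atom.GetFormalCharge())}"
    return f"[{token}:{mapno}]" if mapno > 0 else f"[{token}]"


def _emit_fragment(
    mol: Chem.Mol, atoms: list[int], mapnos: dict[int, int]
) -> str:
    symbols = [""] * mol.GetNumAtoms()
    for idx in atoms:
        symbols[idx] = _atom_symbol(mol.GetAtomWithIdx(idx), mapnos.get(idx, 0))
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=atoms,
        atomSymbols=symbols,
        allBondsExplicit=True,
        canonical=True,
    )


def _neighbor_signature(atom: Chem.Atom, effective_map: dict[int, int]):
    """Hashable summary of one atom's bonding environment for change detection."""
    mapped = []
    unmapped = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        order = bond.GetBondTypeAsDouble()
        num = effective_map.get(nbr.GetIdx(), 0)
        if num > 0:
            mapped.append((num, order))
        elif is_marker(nbr):
            unmapped.append(("marker", nbr.GetIsotope(), order))
        else:
            unmapped.append(("atom", nbr.GetSymbol(), order))
    return (
        tuple(sorted(mapped)),
        tuple(sorted(unmapped)),
        atom.GetTotalNumHs(),
        atom.GetFormalCharge(),
    )


def _effective_maps(mol: Chem.Mol, product_maps: set[int]) -> dict[int, int]:
    """Atom idx -> map number, zeroing maps that do not appear in the product."""
    out = {}
    for atom in mol.GetAtoms():
        num = atom.GetAtomMapNum()
        out[atom.GetIdx()] = num if num in product_maps else 0
    return out


def extract_template(rxn: AbstractedReaction, radius: int = 1) -> RetroTemplate:
    """Extract the retro template of one reaction.

    Raises :class:`TemplateError` for null transformations (no changed
    atoms).  The returned template applied to ``rxn.product`` recovers
    ``rxn.reactants`` (checked by the caller/tests, not here).
    """
    product = rxn.product
    pmap = map_index(product)
    product_maps = set(pmap)
    p_eff = {a.GetIdx(): a.GetAtomMapNum() for a in product.GetAtoms()}

    # locate each mapped product atom in the reactants
    r_atoms: dict[int, tuple[int, int]] = {}  # map -> (reactant idx, atom idx)
    r_effs = []
    for ri, reactant in enumerate(rxn.reactants):
        eff = _effective_maps(reactant, product_maps)
        r_effs.append(eff)
        for atom in reactant.GetAtoms():
            num = eff[atom.GetIdx()]
            if num > 0:
                r_atoms[num] = (ri, atom.GetIdx())

    changed_maps = set()
    for num, pidx in pmap.items():
        patom = product.GetAtomWithIdx(pidx)
        loc = r_atoms.get(num)
        if loc is None:
            changed_maps.add(num)
            continue
        ratom = rxn.reactants[loc[0]].GetAtomWithIdx(loc[1])
        if _neighbor_signature(patom, p_eff) != _neighbor_signature(
            ratom, r_effs[loc[0]]
        ):
            changed_maps.add(num)
    if not changed_maps:
        raise TemplateError(f"record {rxn.record_id}: null transformation")

    # product-side selection: changed atoms + radius context
    selected = {pmap[m] for m in changed_maps}
    frontier = set(selected)
    for _ in range(radius):
        nxt = set()
        for idx in frontier:
            for nbr in product.GetAtomWithIdx(idx).GetNeighbors():
                if nbr.GetIdx() not in selected and not is_marker(nbr):
                    nxt.add(nbr.GetIdx())
        selected |= nxt
        frontier = nxt
    _complete_selection(product, selected)
    # markers riding on selected atoms must appear on both template sides
    for idx in list(selected):
        for nbr in product.GetAtomWithIdx(idx).GetNeighbors():
            if is_marker(nbr):
                selected.add(nbr.GetIdx())

    selected_maps = {p_eff[i] for i in selected if p_eff[i] > 0}

    # canonical map renumbering from the product fragment's canonical order
    prod_atoms = sorted(selected)
    Chem.MolFragmentToSmiles(product, atomsToUse=prod_atoms, canonical=True)
    order = ast.literal_eval(product.GetProp("_smilesAtomOutputOrder"))
    renumber: dict[int, int] = {}
    for pos, idx in enumerate(order):
        old = p_eff[idx]
        if old > 0:
            renumber[old] = pos + 1
    prod_mapnos = {i: renumber.get(p_eff[i], 0) for i in prod_atoms}
    product_pattern = _emit_fragment(product, prod_atoms, prod_mapnos)

    precursor_patterns = []
    for ri, reactant in enumerate(rxn.reactants):
        eff = r_effs[ri]
        atoms = {
            a.GetIdx()
            for a in reactant.GetAtoms()
            if eff[a.GetIdx()] in selected_maps and eff[a.GetIdx()] > 0
        }
        if not atoms:
            continue  # reactant untouched by the pattern (spectator fragment)
        # flood-fill attached unmapped atoms (markers and leaving groups)
        stack = list(atoms)
        while stack:
            idx = stack.pop()
            for nbr in reactant.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j not in atoms and eff[j] == 0:
                    atoms.add(j)
                    stack.append(j)
        mapnos = {i: renumber.get(eff[i], 0) for i in atoms}
        precursor_patterns.append(_emit_fragment(reactant, sorted(atoms), mapnos))
    if not precursor_patterns:
        raise TemplateError(f"record {rxn.record_id}: no precursor patterns")
    precursor_patterns.sort()

    smarts = f"{product_pattern}>>{'.'.join(precursor_patterns)}"
    template_id = "T" + hashlib.sha1(smarts.encode()).hexdigest()[:12]
    return RetroTemplate(
        template_id=template_id,
        smarts=smarts,
        radius=radius,
        n_pattern_atoms=len(prod_atoms),
    )


def _complete_selection(mol: Chem.Mol, selected: set[int]) -> None:
    """Close the selection over multiple bonds.

    Unsaturation at the reaction center is part of its chemical identity
    (an sp carbon is not a CF3 carbon), so atoms double/triple-bonded to
    a selected atom are pulled in transitively.
    """
    while True:
        extra = set()
        for idx in selected:
            for bond in mol.GetAtomWithIdx(idx).GetBonds():
                nbr = bond.GetOtherAtom(mol.GetAtomWithIdx(idx))
                if (
                    nbr.GetIdx() not in selected
                    and not bond.GetIsAromatic()
                    and bond.GetBondTypeAsDouble() >= 2
                ):
                    extra.add(nbr.GetIdx())
        if not extra:
            return
        selected |= extra


def apply_template(
    template: RetroTemplate, product: Chem.Mol
) -> list[tuple[tuple[str, ...], tuple[Chem.Mol, ...]]]:
    """Apply a retro template to a product molecule.

    Returns one ``(sorted canonical SMILES tuple, mols)`` entry per
    distinct precursor set; an empty list when the pattern does not
    embed.  Candidate sets that fail sanitization are dropped.
    """
    if not product.HasSubstructMatch(template.query):
        return []
    try:
        outcomes = template.rxn.RunReactants((product,))
    except Exception:
        return []
    results: dict[tuple[str, ...], tuple[Chem.Mol, ...]] = {}
    for mols in outcomes:
        smis = []
        fixed = []
        ok = True
        for mol in mols:
            norm = normalize_pins(mol)
            if norm is None:
                ok = False
                break
            fixed.append(norm)
            smis.append(canonical_serialize(norm))
        if not ok:
            continue
        key = tuple(sorted(smis))
        results.setdefault(key, tuple(fixed))
    return sorted(results.items())


def template_recovers(template: RetroTemplate, entry: DatasetEntry) -> bool:
    """Does the template regenerate the recorded reactants of *entry*?"""
    for smis, _ in apply_template(template, entry.example.product):
        if smis == entry.reactants:
            return True
    return False


@dataclass
class TemplateLibrary:
    """Consolidated templates plus the reaction -> template assignment."""

    templates: dict[str, RetroTemplate]
    assignment: dict[tuple[str, tuple[str, ...]], str]
    unassigned: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.templates)

    def template_for(self, entry_key) -> RetroTemplate | None:
        tid = self.assignment.get(entry_key)
        return self.templates[tid] if tid else None

    def sorted_templates(self) -> list[RetroTemplate]:
        return sorted(self.templates.values(), key=lambda t: t.template_id)

    def write_jsonl(self, path) -> None:
        import json

        with open(path, "w") as handle:
            for t in self.sorted_templates():
                handle.write(
                    json.dumps(
                        {
                            "template_id": t.template_id,
                            "smarts": t.smarts,
                            "radius": t.radius,
                            "precedent_count": t.precedent_count,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )


def extract_all_templates(
    entries: list[DatasetEntry], radius: int = 1, extra_radii: tuple[int, ...] = (0,)
) -> tuple[dict[str, RetroTemplate], dict[tuple[str, tuple[str, ...]], list[str]]]:
    """Extract per-entry templates at the context radius and generalizations.

    Returns the unique template pool and, per entry, the ids of the
    templates extracted from that entry (its own candidates).
    """
    pool: dict[str, RetroTemplate] = {}
    own: dict[tuple[str, tuple[str, ...]], list[str]] = {}
    for entry in entries:
        ids = []
        for r in (radius, *extra_radii):
            try:
                tpl = extract_template(entry.example, radius=r)
            except TemplateError as exc:
                log.debug("extraction failed: %s", exc)
                continue
            pool.setdefault(tpl.template_id, tpl)
            ids.append(tpl.template_id)
        own[entry.key] = ids
    return pool, own


def consolidate_templates(
    entries: list[DatasetEntry],
    radius: int = 1,
) -> TemplateLibrary:
    """Assign each reaction the most general template that recovers it.

    Generality is measured as coverage: the number of training reactions
    a template recovers.  Every extracted candidate (radius and radius-0
    forms) competes; unique-template count after assignment is at most
    the number before.
    """
    pool, own = extract_all_templates(entries, radius=radius)
    recovering: dict[tuple[str, tuple[str, ...]], list[str]] = {e.key: [] for e in entries}
    coverage: dict[str, int] = {tid: 0 for tid in pool}
    templates = sorted(pool.values(), key=lambda t: t.template_id)
    for entry in entries:
        for tpl in templates:
            if template_recovers(tpl, entry):
                recovering[entry.key].append(tpl.template_id)
                coverage[tpl.template_id] += 1

    assignment: dict[tuple[str, tuple[str, ...]], str] = {}
    unassigned = []
    for entry in entries:
        candidates = recovering[entry.key]
        if not candidates:
            log.warning("no recovering template for %s", entry.key)
            unassigned.append(entry.key)
            continue
        best = min(
            candidates,
            key=lambda tid: (
                -coverage[tid],
                pool[tid].n_pattern_atoms,
                pool[tid].smarts,
            ),
        )
        assignment[entry.key] = best

    kept: dict[str, RetroTemplate] = {}
    for entry in entries:
        tid = assignment.get(entry.key)
        if tid is None:
            continue
        tpl = kept.setdefault(tid, pool[tid])
        tpl.precedent_count += entry.count
    return TemplateLibrary(templates=kept, assignment=assignment, unassigned=unassigned)
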