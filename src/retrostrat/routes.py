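"""Per-document reaction networks, multistep route extraction, atom provenance.

A document's records form a bipartite directed graph of molecule and
reaction nodes.  Terminal products (sink molecules) seed routes: each
route is the ancestor DAG of one sink, limited to ``max_depth`` reaction
steps.  Atom provenance follows atom-map numbers backwards from the
target; atoms whose lineage never reaches the target are *leaving*.
Hydrogens lost along the way are tracked per core atom as a retained
("core") hydrogen count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

from retrostrat.chem import (
    MappedReaction,
    canonical_atom_alignment,
    canonical_serialize,
    map_index,
    validate_mapping,
)

log = logging.getLogger(__name__)


class ProvenanceError(ValueError):
    """Atom lineage through a route is broken (invalid mapping)."""


@dataclass
class ReactionNetwork:
    """Molecule/reaction graph of one document, acyclic after pruning."""

    document_id: str
    graph: nx.DiGraph
    reactions: dict[str, MappedReaction]

    def molecule_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "mol"]

    def sink_molecules(self) -> list[str]:
        out = []
        for node, data in self.graph.nodes(data=True):
            if data["kind"] != "mol":
                continue
            if self.graph.out_degree(node) == 0 and self.graph.in_degree(node) > 0:
                out.append(data["smiles"])
        return out


@dataclass
class Route:
    """A multistep route: DAG of reactions with a single sink (the target)."""

    document_id: str
    target: str
    reactions: list[MappedReaction]  # topologically ordered, target step first
    depth: int
    n_reactions: int
    #: canonical SMILES -> record_id of the reaction producing that molecule
    produced_by: dict[str, str] = field(default_factory=dict)


@dataclass
class MoleculeProvenance:
    """Per-atom core/leaving labels for one molecule occurrence."""

    core: list[bool]
    core_h: list[int]  # hydrogens on each atom that are retained to the target

    def leaving_atoms(self) -> list[int]:
        return [i for i, c in enumerate(self.core) if not c]


@dataclass
class AtomProvenance:
    """Provenance for every molecule occurrence of one route.

    Keys are ``(record_id, role)`` with role ``"p"`` for the product or the
    integer reactant position.
    """

    route: Route
    molecules: dict[tuple[str, object], MoleculeProvenance]


def _mol_node(smiles: str) -> tuple[str, str]:
    return ("mol", smiles)


def _rxn_node(record_id: str) -> tuple[str, str]:
    return ("rxn", record_id)


def build_network(
    records: list[MappedReaction], document_id: str | None = None
) -> ReactionNetwork:
    """Assemble the per-document network, deduplicated and acyclic.

    Duplicate reactant/product pairs collapse to one edge (earliest
    record).  Self-loops (product among its own reactants) are dropped.
    Cycles are broken by discarding the latest participating record, by
    ``record_id`` order.
    """
    if document_id is None:
        document_id = records[0].document_id if records else ""
    graph = nx.DiGraph()
    reactions: dict[str, MappedReaction] = {}
    seen_pairs: set[tuple[tuple[str, ...], str]] = set()
    for rxn in sorted(records, key=lambda r: r.record_id):
        product = canonical_serialize(rxn.product)
        reactant_smis = tuple(sorted(canonical_serialize(m) for m in rxn.reactants))
        if product in reactant_smis:
            log.debug("%s: self-loop removed", rxn.record_id)
            continue
        pair = (reactant_smis, product)
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        node = _rxn_node(rxn.record_id)
        graph.add_node(node, kind="rxn")
        graph.add_node(_mol_node(product), kind="mol", smiles=product)
        graph.add_edge(node, _mol_node(product))
        for smi in reactant_smis:
            graph.add_node(_mol_node(smi), kind="mol", smiles=smi)
            graph.add_edge(_mol_node(smi), node)
        reactions[rxn.record_id] = rxn
    # cycle pruning: drop the latest record of each remaining cycle
    while True:
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            break
        rxn_ids = sorted(
            {n[1] for edge in cycle for n in edge[:2] if n[0] == "rxn"}
        )
        victim = rxn_ids[-1]
        log.debug("%s: removed to break cycle", victim)
        graph.remove_node(_rxn_node(victim))
        reactions.pop(victim, None)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return ReactionNetwork(document_id=document_id, graph=graph, reactions=reactions)


def extract_routes(net: ReactionNetwork, max_depth: int = 10) -> list[Route]:
    """One route per terminal product, truncated at ``max_depth`` steps."""
    routes = []
    for target in sorted(net.sink_molecules()):
        route = _route_for_target(net, target, max_depth)
        if route is not None:
            routes.append(route)
    return routes


def _route_for_target(
    net: ReactionNetwork, target: str, max_depth: int
) -> Route | None:
    # backwards BFS over reaction nodes, keyed by minimum step depth
    graph = net.graph
    depths: dict[str, int] = {}  # record_id -> min depth from target
    frontier = [(target, 0)]
    seen_mols = {target}
    while frontier:
        mol_smiles, mol_depth = frontier.pop()
        for rxn_node in graph.predecessors(_mol_node(mol_smiles)):
            record_id = rxn_node[1]
            step_depth = mol_depth + 1
            if step_depth > max_depth:
                continue
            if record_id in depths and depths[record_id] <= step_depth:
                continue
            depths[record_id] = step_depth
            for mol_node in graph.predecessors(rxn_node):
                smi = graph.nodes[mol_node]["smiles"]
                if smi not in seen_mols:
                    seen_mols.add(smi)
                    frontier.append((smi, step_depth))
    if not depths:
        return None
    ordered = sorted(depths, key=lambda rid: (depths[rid], rid))
    reactions = [net.reactions[rid] for rid in ordered]
    produced_by = {}
    for rxn in reactions:
        produced_by.setdefault(canonical_serialize(rxn.product), rxn.record_id)
    depth = _longest_linear_sequence(reactions, target)
    return Route(
        document_id=net.document_id,
        target=target,
        reactions=reactions,
        depth=depth,
        n_reactions=len(reactions),
        produced_by=produced_by,
    )


def _longest_linear_sequence(reactions: list[MappedReaction], target: str) -> int:
    """Longest root-to-leaf reaction count of a route DAG."""
    produced = {canonical_serialize(r.product): r for r in reactions}

    depth_cache: dict[str, int] = {}

    def mol_depth(smiles: str) -> int:
        if smiles in depth_cache:
            return depth_cache[smiles]
        rxn = produced.get(smiles)
        if rxn is None:
            depth_cache[smiles] = 0
            return 0
        depth_cache[smiles] = 0  # cycle guard; DAG by construction
        value = 1 + max(
            (mol_depth(canonical_serialize(m)) for m in rxn.reactants), default=0
        )
        depth_cache[smiles] = value
        return value

    return mol_depth(target)


def route_union_edges(routes: list[Route]) -> set[str]:
    """Record ids covered by a set of routes (for coverage checks)."""
    return {rxn.record_id for route in routes for rxn in route.reactions}


def trace_provenance(route: Route) -> AtomProvenance:
    """Label every atom of every molecule occurrence core/leaving.

    Processing order follows the route DAG from the target towards the
    starting materials.  For each reaction, the product occurrence's
    labels are copied from the occurrence where that molecule is consumed
    downstream (or from the target itself), then pushed onto the
    reactants through the atom map.  The retained-hydrogen count of a
    core atom is ``min`` over its forward lineage, so hydrogens removed
    at any later step count as leaving attachments even if a hydrogen is
    re-installed afterwards.
    """
    molecules: dict[tuple[str, object], MoleculeProvenance] = {}
    # first consumer of each molecule (record_id, reactant index)
    consumer: dict[str, tuple[str, int]] = {}
    for rxn in route.reactions:
        for i, mol in enumerate(rxn.reactants):
            smi = canonical_serialize(mol)
            consumer.setdefault(smi, (rxn.record_id, i))

    for rxn in route.reactions:  # already ordered target-first
        report = validate_mapping(rxn)
        if not report.ok:
            raise ProvenanceError(
                f"route {route.document_id}/{route.target}: record "
                f"{rxn.record_id} has mapping violations: {report.entries()}"
            )
        product = rxn.product
        prod_smiles = canonical_serialize(product)
        if prod_smiles == route.target:
            prod_prov = MoleculeProvenance(
                core=[True] * product.GetNumAtoms(),
                core_h=[a.GetTotalNumHs() for a in product.GetAtoms()],
            )
        else:
            where = consumer.get(prod_smiles)
            if where is None:
                raise ProvenanceError(
                    f"route {route.document_id}/{route.target}: intermediate "
                    f"{prod_smiles} is never consumed"
                )
            down = molecules.get((where[0], where[1]))
            if down is None:
                raise ProvenanceError(
                    f"route {route.document_id}/{route.target}: provenance for "
                    f"{prod_smiles} not yet available (route order broken)"
                )
            down_mol = None
            for r in route.reactions:
                if r.record_id == where[0]:
                    down_mol = r.reactants[where[1]]
                    break
            perm = canonical_atom_alignment(product, down_mol)
            prod_prov = MoleculeProvenance(
                core=[down.core[j] for j in perm],
                core_h=[down.core_h[j] for j in perm],
            )
        molecules[(rxn.record_id, "p")] = prod_prov

        pmap = map_index(product)
        for i, reactant in enumerate(rxn.reactants):
            core = []
            core_h = []
            for atom in reactant.GetAtoms():
                num = atom.GetAtomMapNum()
                if num > 0 and num in pmap:
                    pidx = pmap[num]
                    if prod_prov.core[pidx]:
                        core.append(True)
                        core_h.append(min(atom.GetTotalNumHs(), prod_prov.core_h[pidx]))
                        continue
                core.append(False)
                core_h.append(0)
            molecules[(rxn.record_id, i)] = MoleculeProvenance(core=core, core_h=core_h)
    return AtomProvenance(route=route, molecules=molecules)
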