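"""Per-document networks, route extraction, and atom provenance."""

import pytest

from retrostrat.chem import canonical_serialize, parse_mapped_reaction
from retrostrat.routes import (
    build_network,
    extract_routes,
    route_union_edges,
    trace_provenance,
)


def _rxn(smiles, rid, doc="D"):
    return parse_mapped_reaction(smiles, doc, rid)


# demethylation -> acylation -> hydrolysis chain on methanol-derived core
CHAIN = [
    _rxn("C[O:1][CH3:2]>>[OH:1][CH3:2]", "r1"),
    _rxn("[OH:1][CH3:2].[CH3:3][C:4](=[O:5])Cl>>[CH3:2][O:1][C:4](=[O:5])[CH3:3]", "r2"),
    _rxn("[CH3:2][O:1][C:4](=[O:5])[CH3:3]>>[OH:1][C:4](=[O:5])[CH3:3]", "r3"),
]


class TestNetwork:
    def test_chain_network_node_and_edge_counts(self):
        net = build_network(CHAIN, "D")
        mols = net.molecule_nodes()
        rxns = [n for n, d in net.graph.nodes(data=True) if d["kind"] == "rxn"]
        assert len(mols) == 5
        assert len(rxns) == 3

    def test_duplicate_pair_collapses_to_one_edge(self):
        dup = _rxn("C[O:1][CH3:2]>>[OH:1][CH3:2]", "r9")
        net = build_network(CHAIN + [dup], "D")
        rxns = [n for n, d in net.graph.nodes(data=True) if d["kind"] == "rxn"]
        assert len(rxns) == 3
        assert "r9" not in net.reactions  # earlier record wins

    def test_two_cycle_keeps_earlier_record(self):
        fwd = _rxn("C[O:1][CH3:2]>>[OH:1][CH3:2]", "r1")
        back = _rxn("[OH:1][CH3:2].CI>>C[O:1][CH3:2]", "r2")
        net = build_network([fwd, back], "D")
        assert "r1" in net.reactions
        assert "r2" not in net.reactions

    def test_empty_input_gives_empty_network(self):
        net = build_network([], "D")
        assert not net.reactions


class TestExtractRoutes:
    def test_chain_route_depth(self):
        routes = extract_routes(build_network(CHAIN, "D"))
        assert len(routes) == 1
        (route,) = routes
        assert route.depth == 3
        assert route.n_reactions == 3
        assert route.target == "CC(=O)O"

    def test_convergent_route_depth_matches_bruteforce(self):
        # branch A: three steps building a butyl fragment; branch B: two
        # steps building an aminopropyl fragment; one final junction step
        reactions = [
            _rxn("[CH3:1][CH3:2].[CH3:3]Br>>[CH3:1][CH2:2][CH3:3]", "a1"),
            _rxn("[CH3:1][CH2:2][CH3:3].[CH3:4]Br>>[CH3:1][CH2:2][CH2:3][CH3:4]", "a2"),
            _rxn(
                "[CH3:1][CH2:2][CH2:3][CH3:4].[OH2:5]>>"
                "[CH3:1][CH2:2][CH2:3][CH2:4][OH:5]",
                "a3",
            ),
            _rxn("[NH3:1].[CH3:2]Br>>[NH2:1][CH3:2]", "b1"),
            _rxn("[NH2:1][CH3:2].[CH3:3]Br>>[NH:1]([CH3:2])[CH3:3]", "b2"),
            _rxn(
                "[CH3:1][CH2:2][CH2:3][CH2:4][OH:5].[NH:6]([CH3:7])[CH3:8]>>"
                "[CH3:1][CH2:2][CH2:3][CH2:4][O:5][N:6]([CH3:7])[CH3:8]",
                "c1",
            ),
        ]
        routes = extract_routes(build_network(reactions, "D"))
        assert len(routes) == 1
        (route,) = routes

        # brute-force longest path over the explicit DAG
        produced = {canonical_serialize(r.product): r for r in route.reactions}

        def longest(smiles):
            rxn = produced.get(smiles)
            if rxn is None:
                return 0
            return 1 + max(longest(canonical_serialize(m)) for m in rxn.reactants)

        assert route.depth == longest(route.target) == 4
        assert route.n_reactions == 6

    def test_isolated_molecule_yields_no_route(self):
        net = build_network([], "D")
        assert extract_routes(net) == []

    def test_tree_network_routes_cover_all_edges(self):
        routes = extract_routes(build_network(CHAIN, "D"))
        assert route_union_edges(routes) == {"r1", "r2", "r3"}


class TestProvenance:
    def test_suzuki_toy_route_leaving_atoms(self):
        # oracle: follow map numbers by hand -- Br and B(OH)2 never appear
        # in the biaryl target, every ring atom does
        coupling = _rxn(
            "Br[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1."
            "OB(O)[c:7]1[cH:8][cH:9][cH:10][cH:11][cH:12]1>>"
            "[c:1]1(-[c:7]2[cH:8][cH:9][cH:10][cH:11][cH:12]2)"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
            "r1",
        )
        routes = extract_routes(build_network([coupling], "D"))
        prov = trace_provenance(routes[0])
        halide = prov.molecules[("r1", 0)]
        boronate = prov.molecules[("r1", 1)]
        rxn = routes[0].reactions[0]
        for mp, mol in ((halide, rxn.reactants[0]), (boronate, rxn.reactants[1])):
            for atom in mol.GetAtoms():
                expected_core = atom.GetAtomMapNum() > 0
                assert mp.core[atom.GetIdx()] == expected_core
        assert prov.molecules[("r1", "p")].core == [True] * 12

    def test_all_atoms_retained_means_no_leaving(self):
        iso = _rxn("[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][OH:3].[OH2:9]", "r1")
        routes = extract_routes(build_network([iso], "D"))
        # degenerate: single self-preserving record forms no route (self-loop)
        assert routes == []
        add = _rxn("[CH2:1]=[CH2:2].[OH2:3]>>[CH3:1][CH2:2][OH:3]", "r2")
        routes = extract_routes(build_network([add], "D"))
        prov = trace_provenance(routes[0])
        assert prov.molecules[("r2", 0)].leaving_atoms() == []
        assert prov.molecules[("r2", 1)].leaving_atoms() == []

    def test_hydroxyl_to_triflate_oxygen_is_leaving(self):
        # OH -> OTf -> coupled away: the phenol O and the whole OTf are
        # leaving in their respective intermediates
        fgi = _rxn(
            "[OH:13][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1."
            "Cl[S:14](=[O:15])(=[O:16])[C:17]([F:18])([F:19])[F:20]>>"
            "[c:1]1([O:13][S:14](=[O:15])(=[O:16])[C:17]([F:18])([F:19])[F:20])"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
            "r2",
        )
        coupling = _rxn(
            "O=S(=O)(O[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1)C(F)(F)F."
            "OB(O)[c:7]1[cH:8][cH:9][cH:10][cH:11][cH:12]1>>"
            "[c:1]1(-[c:7]2[cH:8][cH:9][cH:10][cH:11][cH:12]2)"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
            "r1",
        )
        routes = extract_routes(build_network([coupling, fgi], "D"))
        assert len(routes) == 1
        prov = trace_provenance(routes[0])
        phenol = prov.molecules[("r2", 0)]
        rxn2 = next(r for r in routes[0].reactions if r.record_id == "r2")
        o_idx = next(
            a.GetIdx() for a in rxn2.reactants[0].GetAtoms() if a.GetSymbol() == "O"
        )
        assert not phenol.core[o_idx], "phenol oxygen never reaches the target"
        triflate_prod = prov.molecules[("r2", "p")]
        n_leaving = len(triflate_prod.leaving_atoms())
        assert n_leaving == 8  # O + SO2CF3

    def test_generated_routes_conserve_core_multisets(self, provenance_corpus):
        """Core atoms of any intermediate map onto target atoms (map-count check)."""
        from retrostrat.chem import map_index

        corpus = provenance_corpus
        by_doc = {}
        for d, rid, smi in corpus.iter_records():
            by_doc.setdefault(d, []).append((rid, smi))
        doc_id = corpus.routes[0].document_id
        recs = [parse_mapped_reaction(s, doc_id, r) for r, s in by_doc[doc_id]]
        route = extract_routes(build_network(recs, doc_id))[0]
        prov = trace_provenance(route)
        for rxn in route.reactions:
            pmap = map_index(rxn.product)
            prod_prov = prov.molecules[(rxn.record_id, "p")]
            for i, reactant in enumerate(rxn.reactants):
                mp = prov.molecules[(rxn.record_id, i)]
                for atom in reactant.GetAtoms():
                    if not mp.core[atom.GetIdx()]:
                        continue
                    # a core reactant atom maps to a core product atom
                    pidx = pmap[atom.GetAtomMapNum()]
                    assert prod_prov.core[pidx]
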