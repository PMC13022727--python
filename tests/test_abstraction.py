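"""Marker classification, molecule abstraction, and tactical-step removal."""

import pytest
from rdkit import Chem

from retrostrat.abstraction import (
    AbstractionError,
    abstract_molecule,
    abstract_reaction,
    build_higher_level_route,
    classify_marker,
    curate_dataset,
    is_tactical,
)
from retrostrat.chem import MarkerClass, canonical_serialize, parse_mapped_reaction
from retrostrat.routes import MoleculeProvenance, build_network, extract_routes, trace_provenance


class TestClassifyMarker:
    @pytest.mark.parametrize(
        "core,leaving,expected",
        [
            ("C", "Br", MarkerClass.C_PLUS),   # halide partner: electrophilic C
            ("C", "Cl", MarkerClass.C_PLUS),
            ("C", "I", MarkerClass.C_PLUS),
            ("C", "O", MarkerClass.C_PLUS),    # triflate-type oxygen
            ("C", "B", MarkerClass.C_MINUS),   # boron partner: nucleophilic C
            ("C", "Si", MarkerClass.C_MINUS),
            ("C", "H", MarkerClass.C_MINUS),   # C-H nucleophile equivalents
            ("C", "C", MarkerClass.C_NEUTRAL),
            ("O", "C", MarkerClass.HET),       # heteroatom cores collapse
            ("N", "C", MarkerClass.HET),
            ("N", "H", MarkerClass.HET),
            ("S", "Cl", MarkerClass.HET),
        ],
    )
    def test_polarity_classes(self, core, leaving, expected):
        assert classify_marker(core, leaving) == expected

    def test_missing_element_is_configuration_error(self):
        with pytest.raises(AbstractionError):
            classify_marker("C", "Xx", table={"C": 2.55})


def _abstract(smiles, leaving_symbols=(), core_h_override=None):
    mol = Chem.MolFromSmiles(smiles)
    core = [a.GetSymbol() not in leaving_symbols for a in mol.GetAtoms()]
    core_h = [
        (core_h_override or {}).get(i, a.GetTotalNumHs()) if core[i] else 0
        for i, a in enumerate(mol.GetAtoms())
    ]
    out = abstract_molecule(mol, MoleculeProvenance(core=core, core_h=core_h))
    return canonical_serialize(out) if out is not None else None


class TestAbstractMolecule:
    def test_acyl_equivalents_share_one_form(self):
        # acid, ester, and acyl chloride with the leaving O/OMe/Cl removed
        # all become the same acyl cation equivalent
        chloride = _abstract("CC(=O)Cl", ("Cl",))
        mol = Chem.MolFromSmiles("CC(=O)OC")
        # for the ester both oxygens of the ester group: only the O-C(sp3)
        # oxygen and its methyl leave
        core = [True, True, True, False, False]
        prov = MoleculeProvenance(
            core=core,
            core_h=[m.GetTotalNumHs() if c else 0
                    for m, c in zip(mol.GetAtoms(), core)],
        )
        ester = canonical_serialize(abstract_molecule(mol, prov))
        # acid: only the hydroxyl O leaves, not the carbonyl O
        mol2 = Chem.MolFromSmiles("CC(=O)O")
        core2 = [True, True, True, False]
        prov2 = MoleculeProvenance(
            core=core2,
            core_h=[m.GetTotalNumHs() if c else 0
                    for m, c in zip(mol2.GetAtoms(), core2)],
        )
        acid = canonical_serialize(abstract_molecule(mol2, prov2))
        assert chloride == ester == acid == "[2*]C(C)=O"

    def test_halide_and_triflate_share_one_aryl_form(self):
        bromide = _abstract("Brc1ccccc1", ("Br",))
        mol = Chem.MolFromSmiles("O=S(=O)(Oc1ccccc1)C(F)(F)F")
        core = [a.GetIsAromatic() for a in mol.GetAtoms()]
        prov = MoleculeProvenance(
            core=core,
            core_h=[a.GetTotalNumHs() if c else 0
                    for a, c in zip(mol.GetAtoms(), core)],
        )
        triflate = canonical_serialize(abstract_molecule(mol, prov))
        assert bromide == triflate == "[2*]c1ccccc1"

    def test_empty_leaving_set_is_identity(self):
        assert _abstract("CC(=O)Nc1ccccc1") == "CC(=O)Nc1ccccc1"

    def test_fully_leaving_molecule_is_spectator(self):
        assert _abstract("ClS(Cl)=O", ("Cl", "S", "O")) is None

    def test_lost_hydrogen_becomes_het_marker_on_nitrogen(self):
        # amine N retains one of two hydrogens: HET marker, pinned H
        out = _abstract("CN", (), {1: 1})
        assert out == "[1*]NC"

    def test_abstracting_marker_free_abstracted_mol_is_idempotent(self):
        first = Chem.MolFromSmiles(_abstract("Brc1ccccc1", ("Br",)))
        prov = MoleculeProvenance(
            core=[True] * first.GetNumAtoms(),
            core_h=[a.GetTotalNumHs() for a in first.GetAtoms()],
        )
        again = abstract_molecule(first, prov)
        assert canonical_serialize(again) == canonical_serialize(first)


def _route_from(smiles_records):
    recs = [parse_mapped_reaction(s, "D", f"r{i}") for i, s in enumerate(smiles_records)]
    routes = extract_routes(build_network(recs, "D"))
    assert len(routes) == 1
    return routes[0]


class TestTactical:
    def test_hydroxyl_to_triflate_is_tactical(self):
        route = _route_from([
            "O=S(=O)(O[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1)C(F)(F)F."
            "OB(O)[c:7]1[cH:8][cH:9][cH:10][cH:11][cH:12]1>>"
            "[c:1]1(-[c:7]2[cH:8][cH:9][cH:10][cH:11][cH:12]2)"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
            "[OH:13][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1."
            "Cl[S:14](=[O:15])(=[O:16])[C:17]([F:18])([F:19])[F:20]>>"
            "[c:1]1([O:13][S:14](=[O:15])(=[O:16])[C:17]([F:18])([F:19])[F:20])"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
        ])
        prov = trace_provenance(route)
        fgi = next(r for r in route.reactions if r.record_id == "r1")
        assert is_tactical(abstract_reaction(fgi, prov))

    def test_core_bond_forming_coupling_is_not_tactical(self):
        route = _route_from([
            "Br[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1."
            "OB(O)[c:7]1[cH:8][cH:9][cH:10][cH:11][cH:12]1>>"
            "[c:1]1(-[c:7]2[cH:8][cH:9][cH:10][cH:11][cH:12]2)"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
        ])
        prov = trace_provenance(route)
        assert not is_tactical(abstract_reaction(route.reactions[0], prov))

    def test_ester_hydrolysis_with_retained_oxygen_is_not_tactical(self):
        # the acid O-H is concrete in the product, so both sides differ
        route = _route_from([
            "[CH3:2][O:1][C:4](=[O:5])[CH3:3]>>[OH:1][C:4](=[O:5])[CH3:3]",
        ])
        prov = trace_provenance(route)
        assert not is_tactical(abstract_reaction(route.reactions[0], prov))


class TestHigherLevelRoute:
    def test_fgi_detour_collapses_by_one_step(self):
        # FGI + coupling: two records in, one higher-level step out
        route = _route_from([
            "O=S(=O)(O[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1)C(F)(F)F."
            "OB(O)[c:7]1[cH:8][cH:9][cH:10][cH:11][cH:12]1>>"
            "[c:1]1(-[c:7]2[cH:8][cH:9][cH:10][cH:11][cH:12]2)"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
            "[OH:13][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1."
            "Cl[S:14](=[O:15])(=[O:16])[C:17]([F:18])([F:19])[F:20]>>"
            "[c:1]1([O:13][S:14](=[O:15])(=[O:16])[C:17]([F:18])([F:19])[F:20])"
            "[cH:2][cH:3][cH:4][cH:5][cH:6]1",
        ])
        prov = trace_provenance(route)
        hl = build_higher_level_route(route, prov)
        assert route.n_reactions == 2
        assert hl.n_reactions == 1
        assert hl.depth == 1
        assert hl.removed_records == ["r1"]

    def test_route_without_leaving_atoms_is_unchanged(self):
        route = _route_from([
            "[CH2:1]=[CH2:2].[OH2:3]>>[CH3:1][CH2:2][OH:3]",
        ])
        prov = trace_provenance(route)
        hl = build_higher_level_route(route, prov)
        assert hl.n_reactions == route.n_reactions == 1
        assert hl.depth == route.depth


class TestCurate:
    def test_dedup_matches_planted_strategy_count(self):
        # a low-diversity corpus repeats strategies across documents; the
        # deduplicated pair set must equal the planted distinct strategies
        from retrostrat.corpus import CorpusSpec, generate_corpus
        from retrostrat.pipeline import curate

        corpus = generate_corpus(
            CorpusSpec(
                n_documents=30,
                families=("amide", "biaryl"),
                max_decorations=0,
                p_tactical=0.0,
                seed=9,
            )
        )
        result = curate(list(corpus.iter_records()), space="higher")
        assert len(result.dataset) == len(corpus.unique_strategies())
        assert any(e.count > 1 for e in result.dataset.entries)

    def test_exclusion_list_removes_pairs(self, world):
        entry = world.higher.dataset.entries[0]
        ds = curate_dataset(world.higher.hl_routes, exclusions=[entry.key])
        keys = {e.key for e in ds.entries}
        assert entry.key not in keys
        assert ds.excluded > 0

    def test_no_duplicate_pairs(self, world):
        keys = [e.key for e in world.higher.dataset.entries]
        assert len(keys) == len(set(keys))
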