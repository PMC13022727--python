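"""Buyables matching and multistep tree search."""

import pytest
from rdkit import Chem

from retrostrat.planner import (
    BuyablesCatalog,
    SearchConfig,
    load_buyables,
    match_buyables,
    run_search,
    route_stats,
    success_rate,
)


class TestLoadBuyables:
    def test_duplicates_collapse(self, tmp_path):
        p = tmp_path / "stock.txt"
        p.write_text("CCO\nc1ccccc1\nOCC\nCC(C)O\nCCN\n")
        cat = load_buyables(p)
        assert len(cat) == 4  # CCO and OCC are one molecule

    def test_empty_file(self, tmp_path):
        p = tmp_path / "stock.txt"
        p.write_text("")
        assert len(load_buyables(p)) == 0

    def test_csv_metadata_retained(self, tmp_path):
        p = tmp_path / "stock.csv"
        p.write_text("smiles,price\nCCO,12\nc1ccccc1,3\n")
        cat = load_buyables(p)
        assert cat.metadata[Chem.CanonSmiles("CCO")]["price"] == "12"

    def test_unparseable_lines_skipped(self, tmp_path):
        p = tmp_path / "stock.txt"
        p.write_text("CCO\nnot-a-smiles\nCCN\n")
        cat = load_buyables(p)
        assert len(cat) == 2
        assert cat.skipped == 1


class TestMatchBuyables:
    def test_aryl_electrophile_matches_halides_and_triflate_not_boronate(self):
        cat = BuyablesCatalog.from_smiles([
            "Brc1ccccc1", "Clc1ccccc1",
            "O=S(=O)(Oc1ccccc1)C(F)(F)F", "OB(O)c1ccccc1",
        ])
        query = Chem.MolFromSmiles("[2*]c1ccccc1")
        matches = set(match_buyables(query, cat, "substructure"))
        assert Chem.CanonSmiles("Brc1ccccc1") in matches
        assert Chem.CanonSmiles("Clc1ccccc1") in matches
        assert Chem.CanonSmiles("O=S(=O)(Oc1ccccc1)C(F)(F)F") in matches
        assert Chem.CanonSmiles("OB(O)c1ccccc1") not in matches

    def test_aryl_nucleophile_matches_only_boronate(self):
        cat = BuyablesCatalog.from_smiles(["Brc1ccccc1", "OB(O)c1ccccc1"])
        query = Chem.MolFromSmiles("[3*]c1ccccc1")
        assert match_buyables(query, cat, "substructure") == [
            Chem.CanonSmiles("OB(O)c1ccccc1")
        ]

    def test_het_marked_amine_matches_free_amine_via_hydrogen(self):
        cat = BuyablesCatalog.from_smiles(["C1CCNCC1"])
        query = Chem.MolFromSmiles("[1*]N1CCCCC1")
        assert match_buyables(query, cat, "substructure") == ["C1CCNCC1"]

    def test_hydrogen_does_not_satisfy_carbon_markers(self):
        cat = BuyablesCatalog.from_smiles(["c1ccccc1"])
        query = Chem.MolFromSmiles("[2*]c1ccccc1")
        assert match_buyables(query, cat, "substructure") == []

    def test_exact_mode_requires_identity(self):
        cat = BuyablesCatalog.from_smiles(["Brc1ccccc1"])
        assert match_buyables(Chem.MolFromSmiles("Brc1ccccc1"), cat, "exact")
        assert not match_buyables(Chem.MolFromSmiles("Clc1ccccc1"), cat, "exact")

    def test_marker_free_molecule_requires_exact_match_in_substructure_mode(self):
        cat = BuyablesCatalog.from_smiles(["Cc1ccccc1"])
        probe = Chem.MolFromSmiles("c1ccccc1")  # substructure but not equal
        assert match_buyables(probe, cat, "substructure") == []

    def test_match_cap_and_smallest_first(self):
        # twelve electronegative substituents of increasing size, all
        # satisfying an aryl C(+) marker
        groups = ["F", "Cl", "Br", "I", "OC", "OCC", "OCCC", "OCCCC",
                  "OCCCCC", "OC(C)C", "OCC(C)C", "OS(=O)(=O)C(F)(F)F"]
        stock = [f"c1ccccc1{g}" for g in groups]
        cat = BuyablesCatalog.from_smiles(stock)
        query = Chem.MolFromSmiles("[2*]c1ccccc1")
        matches = match_buyables(query, cat, "substructure", max_matches=10)
        assert len(matches) == 10
        sizes = [Chem.MolFromSmiles(s).GetNumHeavyAtoms() for s in matches]
        assert sizes == sorted(sizes)


class TestRunSearch:
    def test_buyable_target_is_zero_step_success(self, world):
        clf = world.trained_higher.classifier
        smi = world.stock_exact.smiles[0]
        result = run_search(smi, clf, world.stock_exact,
                            SearchConfig(max_iterations=10))
        assert result.success
        assert result.routes[0].n_reactions == 0
        assert result.routes[0].depth == 0

    def test_unparseable_target_raises(self, world):
        with pytest.raises(ValueError):
            run_search("][", world.trained_higher.classifier, world.stock_exact)

    def test_emitted_routes_terminate_in_buyable_matches(self, world):
        clf = world.trained_higher.classifier
        target = world.corpus.routes[0].target
        result = run_search(
            target, clf, world.stock_exact,
            SearchConfig(max_iterations=300, max_depth=8, expansion_width=50,
                         mode="substructure"),
        )
        assert result.success
        for route in result.routes:
            assert route.leaves
            for smiles, matches in route.leaves.items():
                node = result.graph.chem[smiles]
                assert node.terminal
                assert matches == node.buyable_matches
                assert matches or smiles in world.stock_exact

    def test_route_steps_revalidate_by_template_application(self, world):
        from retrostrat.templates import apply_template

        clf = world.trained_higher.classifier
        library = world.trained_higher.library
        target = world.corpus.routes[1].target
        result = run_search(
            target, clf, world.stock_exact,
            SearchConfig(max_iterations=300, max_depth=8, expansion_width=50,
                         mode="substructure"),
        )
        assert result.success
        for route in result.routes[:5]:
            for step in route.steps:
                tpl = library.templates[step.template_id]
                product = result.graph.chem[step.product].mol
                outcomes = [s for s, _ in apply_template(tpl, product)]
                assert step.precursors in outcomes


class TestStats:
    def test_success_rate_arithmetic(self, world):
        clf = world.trained_higher.classifier
        targets = [r.target for r in world.corpus.routes[:4]]
        cfg = SearchConfig(max_iterations=200, max_depth=8,
                           expansion_width=50, mode="substructure",
                           stop_on_solve=True)
        results = [run_search(t, clf, world.stock_exact, cfg) for t in targets]
        n = sum(r.success for r in results)
        assert success_rate(results) == pytest.approx(100.0 * n / 4)
        stats = route_stats(results)
        assert len(stats) == 4
        for s, r in zip(stats, results):
            if r.success:
                assert s["depth"] == min(rt.depth for rt in r.routes)

    def test_empty_results_rate(self):
        assert success_rate([]) == 0.0
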