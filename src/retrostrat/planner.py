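"""Multistep retrosynthetic tree search over abstracted intermediates.

The planner runs a Monte Carlo tree search (select -> expand -> update)
from a target molecule.  Expansion proposes precursors through the
template-relevance model; chemical nodes are deduplicated graph-wide by
canonical SMILES.  A node terminates the search when it matches the
buyables catalog -- exactly (original mode) or by marker-aware
substructure search (higher-level mode), where a buyable satisfies an
abstracted query if the core graph embeds and every marker position is
filled either by an implicit hydrogen (HET markers on heteroatoms only)
or by a substituent whose attachment atom satisfies the marker's
electronegativity class.

Selection uses a PUCT-style score (value + c * prior * sqrt(N_parent) /
(1 + N)) with the model's template probability as prior; the value of a
chemical node is the fraction of its expansions resolved to buyables.
Search completeness does not depend on the value function: each
iteration expands exactly one new node, so with enough iterations the
reachable space within ``max_depth`` is enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from retrostrat.abstraction import classify_marker
from retrostrat.chem import (
    EN_THRESHOLD,
    MarkerClass,
    canonical_serialize,
    has_markers,
    is_marker,
    parse_marker_isotope,
)
from retrostrat.relevance import TemplateClassifier, rank_precursors


@dataclass
class BuyablesCatalog:
    """Deduplicated building-block stock with a substructure prescreen."""

    smiles: list[str]  # canonical
    metadata: dict[str, dict] = field(default_factory=dict)
    _mols: list[Chem.Mol] = field(default_factory=list, repr=False)
    _fps: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not self._mols:
            self._mols = [Chem.MolFromSmiles(s) for s in self.smiles]
            self._fps = [Chem.PatternFingerprint(m) for m in self._mols]
        self._exact = set(self.smiles)

    def __len__(self) -> int:
        return len(self.smiles)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._exact

    @staticmethod
    def from_smiles(smiles_list, metadata=None) -> "BuyablesCatalog":
        seen: dict[str, None] = {}
        meta_out = {}
        skipped = 0
        for i, smi in enumerate(smiles_list):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                skipped += 1
                continue
            can = Chem.MolToSmiles(mol)
            seen.setdefault(can, None)
            if metadata is not None and smi in metadata:
                meta_out[can] = metadata[smi]
        cat = BuyablesCatalog(smiles=list(seen), metadata=meta_out)
        cat.skipped = skipped
        return cat


def load_buyables(path) -> BuyablesCatalog:
    """Read a stock file: plain SMILES lines or CSV with a ``smiles`` column."""
    smiles, metadata = [], {}
    with open(path) as fh:
        first = fh.readline()
        if not first:
            return BuyablesCatalog(smiles=[])
        if "," in first and "smiles" in first.lower():
            import csv

            fh.seek(0)
            reader = csv.DictReader(fh)
            smi_col = next(c for c in reader.fieldnames if c.lower() == "smiles")
            for row in reader:
                smi = row[smi_col].strip()
                if smi:
                    smiles.append(smi)
                    metadata[smi] = {k: v for k, v in row.items() if k != smi_col}
        else:
            for line in [first] + fh.readlines():
                line = line.strip()
                if line and not line.startswith("#"):
                    smiles.append(line)
    return BuyablesCatalog.from_smiles(smiles, metadata)


def _core_query(mol: Chem.Mol):
    """Bare core graph of an abstracted molecule plus marker requirements.

    Returns ``(query mol, markers, expected_h)`` where ``markers`` maps
    query atom index -> {MarkerClass: multiplicity} and ``expected_h``
    gives the abstracted hydrogen count per query atom.
    """
    markers: dict[int, dict[MarkerClass, int]] = {}
    doomed = []
    for atom in mol.GetAtoms():
        if is_marker(atom):
            cls, mult = parse_marker_isotope(atom.GetIsotope())
            core = atom.GetNeighbors()[0].GetIdx()
            markers.setdefault(core, {})
            markers[core][cls] = markers[core].get(cls, 0) + mult
            doomed.append(atom.GetIdx())
    expected_h = {}
    out = Chem.RWMol(mol)
    for idx in sorted(doomed, reverse=True):
        out.RemoveAtom(idx)
    # index shift: heavy core atoms keep relative order
    shift = {}
    removed = sorted(doomed)
    for old in range(mol.GetNumAtoms()):
        if old in doomed:
            continue
        shift[old] = old - sum(1 for d in removed if d < old)
    query = out.GetMol()
    for old, new in shift.items():
        expected_h[new] = mol.GetAtomWithIdx(old).GetTotalNumHs()
    new_markers = {shift[i]: m for i, m in markers.items()}
    for atom in query.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetAtomMapNum(0)
    Chem.SanitizeMol(query)
    return query, new_markers, expected_h


def _embedding_satisfies(
    query, markers, expected_h, buyable: Chem.Mol, match: tuple[int, ...],
    table=None, threshold: float = EN_THRESHOLD,
) -> bool:
    match_set = set(match)
    inverse = {b: q for q, b in enumerate(match)}
    for qi, bi in enumerate(match):
        aq = query.GetAtomWithIdx(qi)
        ab = buyable.GetAtomWithIdx(bi)
        needed = dict(markers.get(qi, {}))
        # extra bonds: neighbors outside the embedding, or ring-closing
        # bonds not present in the query
        budget_used: dict[MarkerClass, int] = {}
        ok = True
        for bond in ab.GetBonds():
            nbr = bond.GetOtherAtom(ab)
            order = max(1, int(bond.GetBondTypeAsDouble()))
            if nbr.GetIdx() in match_set:
                if query.GetBondBetweenAtoms(qi, inverse[nbr.GetIdx()]) is None:
                    ok = False  # extra bond inside the embedding
                    break
                continue
            cls = classify_marker(aq.GetSymbol(), nbr.GetSymbol(), table, threshold)
            budget_used[cls] = budget_used.get(cls, 0) + order
        if not ok:
            return False
        h_extra = ab.GetTotalNumHs() - expected_h[qi]
        if h_extra < 0:
            return False
        if h_extra > 0:
            # implicit hydrogens may stand in for HET markers only
            if aq.GetSymbol() == "C":
                return False
            budget_used[MarkerClass.HET] = (
                budget_used.get(MarkerClass.HET, 0) + h_extra
            )
        if budget_used != needed:
            return False
    return True


def match_buyables(
    mol: Chem.Mol,
    catalog: BuyablesCatalog,
    mode: str = "substructure",
    max_matches: int = 10,
    table=None,
    threshold: float = EN_THRESHOLD,
) -> list[str]:
    """Buyables matching one (possibly abstracted) molecule.

    Exact mode and marker-free molecules use set membership of the
    canonical string.  In substructure mode a marker-bearing query
    matches any buyable whose graph contains the core with compatible
    substituents at every marker position.  At most ``max_matches``
    matches are returned, smallest buyables first.
    """
    smiles = canonical_serialize(mol)
    if mode == "exact" or not has_markers(mol):
        return [smiles] if smiles in catalog else []
    query, markers, expected_h = _core_query(mol)
    qfp = Chem.PatternFingerprint(query)
    candidates = []
    for smi, bmol, bfp in zip(catalog.smiles, catalog._mols, catalog._fps):
        if bmol.GetNumHeavyAtoms() < query.GetNumHeavyAtoms():
            continue
        if (qfp & bfp).GetNumOnBits() != qfp.GetNumOnBits():
            continue
        # uniquify=False: symmetric embeddings differ in which core atom
        # lands on which marker position, and only some satisfy the classes
        for match in bmol.GetSubstructMatches(query, uniquify=False, maxMatches=256):
            if _embedding_satisfies(
                query, markers, expected_h, bmol, match, table, threshold
            ):
                candidates.append((bmol.GetNumHeavyAtoms(), smi))
                break
    candidates.sort()
    return [smi for _, smi in candidates[:max_matches]]


# ---------------------------------------------------------------------------
# search graph


@dataclass
class ChemNode:
    smiles: str
    mol: Chem.Mol
    depth: int
    expanded: bool = False
    terminal: bool = False
    buyable_matches: list[str] = field(default_factory=list)
    visits: int = 0
    value_sum: float = 0.0
    solved: bool = False
    exhausted: bool = False
    children: list[int] = field(default_factory=list)  # rxn ids
    parents: list[int] = field(default_factory=list)

    @property
    def value(self) -> float:
        if self.solved:
            return 1.0
        return self.value_sum / self.visits if self.visits else 0.0


@dataclass
class RxnNode:
    rxn_id: int
    parent: str  # product smiles
    template_id: str
    prior: float
    precursors: tuple[str, ...]
    visits: int = 0
    solved: bool = False
    exhausted: bool = False


@dataclass
class SearchConfig:
    max_iterations: int = 200
    max_depth: int = 6
    expansion_width: int = 25
    exploration_const: float = 1.4
    mode: str = "substructure"  # or "exact"
    max_routes: int = 32
    max_buyable_matches: int = 10
    stop_on_solve: bool = False
    seed: int = 0


@dataclass
class SearchGraph:
    root: str
    chem: dict[str, ChemNode] = field(default_factory=dict)
    rxns: dict[int, RxnNode] = field(default_factory=dict)


@dataclass
class RouteStep:
    product: str
    template_id: str
    precursors: tuple[str, ...]


@dataclass
class PlanRoute:
    steps: list[RouteStep]
    leaves: dict[str, list[str]]  # terminal smiles -> buyable matches
    depth: int
    n_reactions: int


@dataclass
class PlanResult:
    target: str
    success: bool
    iterations: int
    routes: list[PlanRoute]
    graph: SearchGraph

    def best_depth(self) -> int | None:
        return min((r.depth for r in self.routes), default=None)

    def best_n_reactions(self) -> int | None:
        return min((r.n_reactions for r in self.routes), default=None)


class _Search:
    def __init__(self, target: Chem.Mol, model: TemplateClassifier,
                 catalog: BuyablesCatalog, config: SearchConfig):
        self.model = model
        self.catalog = catalog
        self.config = config
        self.graph = SearchGraph(root=canonical_serialize(target))
        self._next_rxn = itertools.count()
        self._add_chem(target, depth=0)

    def _add_chem(self, mol: Chem.Mol, depth: int) -> ChemNode:
        smiles = canonical_serialize(mol)
        node = self.graph.chem.get(smiles)
        if node is not None:
            node.depth = min(node.depth, depth)
            return node
        node = ChemNode(smiles=smiles, mol=mol, depth=depth)
        matches = match_buyables(
            mol, self.catalog, self.config.mode, self.config.max_buyable_matches
        )
        if matches:
            node.terminal = True
            node.solved = True
            node.buyable_matches = matches
        self.graph.chem[smiles] = node
        return node

    # -- selection ---------------------------------------------------------

    def _expandable(self, node: ChemNode) -> bool:
        return (
            not node.expanded
            and not node.terminal
            and not node.exhausted
            and node.depth < self.config.max_depth
        )

    def _select(self) -> list[str] | None:
        """Path of chem smiles from root to an expandable node."""
        return self._dfs(self.graph.root, [])

    def _dfs(self, smiles: str, path: list[str]) -> list[str] | None:
        node = self.graph.chem[smiles]
        if smiles in path:
            return None
        if self._expandable(node):
            return path + [smiles]
        if not node.expanded or node.terminal:
            # dead leaf: beyond depth limit, or terminal
            if not node.terminal:
                node.exhausted = True
            return None
        live = [
            self.graph.rxns[r] for r in node.children
            if not self.graph.rxns[r].exhausted
        ]
        live.sort(key=lambda r: (-self._puct(node, r), r.rxn_id))
        for rxn in live:
            precursors = sorted(
                rxn.precursors,
                key=lambda s: (self.graph.chem[s].solved, self.graph.chem[s].visits),
            )
            for smi in precursors:
                child = self.graph.chem[smi]
                if child.terminal or child.exhausted:
                    continue
                found = self._dfs(smi, path + [smiles])
                if found is not None:
                    return found
            if all(
                self.graph.chem[s].terminal or self.graph.chem[s].exhausted
                for s in rxn.precursors
            ):
                rxn.exhausted = True
        if all(self.graph.rxns[r].exhausted for r in node.children):
            node.exhausted = True
        return None

    def _puct(self, parent: ChemNode, rxn: RxnNode) -> float:
        q = float(np.mean([self.graph.chem[s].value for s in rxn.precursors]))
        u = (
            self.config.exploration_const
            * rxn.prior
            * math.sqrt(max(1, parent.visits))
            / (1 + rxn.visits)
        )
        return q + u

    # -- expansion / update ------------------------------------------------

    def _expand(self, path: list[str]) -> None:
        smiles = path[-1]
        node = self.graph.chem[smiles]
        node.expanded = True
        proposals = rank_precursors(
            self.model, node.mol, self.config.expansion_width
        )
        ancestors = set(path)
        n_new = n_solved = 0
        for template, precursor_smis, score in proposals:
            if any(p in ancestors for p in precursor_smis):
                continue  # loop guard
            if precursor_smis == (smiles,):
                continue
            results = dict(
                (s, m)
                for s, m in zip(precursor_smis, _mols_for(precursor_smis))
                if m is not None
            )
            if len(results) != len(precursor_smis):
                continue
            rxn_id = next(self._next_rxn)
            rxn = RxnNode(
                rxn_id=rxn_id,
                parent=smiles,
                template_id=template.template_id,
                prior=score,
                precursors=tuple(sorted(precursor_smis)),
            )
            self.graph.rxns[rxn_id] = rxn
            node.children.append(rxn_id)
            for p_smi, p_mol in results.items():
                child = self._add_chem(p_mol, node.depth + 1)
                child.parents.append(rxn_id)
                n_new += 1
                n_solved += child.solved
            rxn.solved = all(self.graph.chem[s].solved for s in rxn.precursors)
        if not node.children:
            node.exhausted = True
        reward = n_solved / n_new if n_new else 0.0
        for smi in path:
            n = self.graph.chem[smi]
            n.visits += 1
            n.value_sum += reward
        self._propagate_solved(node)

    def _propagate_solved(self, start: ChemNode) -> None:
        work = [start.smiles]
        while work:
            smiles = work.pop()
            node = self.graph.chem[smiles]
            was = node.solved
            node.solved = node.terminal or any(
                self.graph.rxns[r].solved for r in node.children
            )
            changed_rxns = []
            for rid in node.parents:
                rxn = self.graph.rxns[rid]
                rsolved = all(self.graph.chem[s].solved for s in rxn.precursors)
                if rsolved != rxn.solved:
                    rxn.solved = rsolved
                    changed_rxns.append(rxn)
            if node.solved != was or changed_rxns:
                for rxn in changed_rxns:
                    work.append(rxn.parent)

    # -- driver ------------------------------------------------------------

    def run(self) -> PlanResult:
        cfg = self.config
        root = self.graph.chem[self.graph.root]
        iterations = 0
        if not root.terminal:
            for iterations in range(1, cfg.max_iterations + 1):
                path = self._select()
                if path is None:
                    break
                self._expand(path)
                if cfg.stop_on_solve and root.solved:
                    break
        routes = self._extract_routes()
        return PlanResult(
            target=self.graph.root,
            success=root.solved,
            iterations=iterations,
            routes=routes,
            graph=self.graph,
        )

    def _extract_routes(self) -> list[PlanRoute]:
        cfg = self.config
        memo: dict[str, list] = {}

        def expand_routes(smiles: str, seen: frozenset) -> list[tuple]:
            """Each route: (steps tuple, leaves frozenset)."""
            node = self.graph.chem[smiles]
            if node.terminal:
                return [((), frozenset([smiles]))]
            if smiles in seen:
                return []
            out = []
            for rid in node.children:
                rxn = self.graph.rxns[rid]
                if not rxn.solved:
                    continue
                sub = [
                    expand_routes(p, seen | {smiles}) for p in rxn.precursors
                ]
                if any(not s for s in sub):
                    continue
                for combo in itertools.islice(
                    itertools.product(*sub), cfg.max_routes
                ):
                    steps = (
                        RouteStep(
                            product=smiles,
                            template_id=rxn.template_id,
                            precursors=rxn.precursors,
                        ),
                    )
                    leaves = frozenset()
                    for s, l in combo:
                        steps = steps + s
                        leaves = leaves | l
                    out.append((steps, leaves))
                if len(out) >= cfg.max_routes:
                    break
            return out[: cfg.max_routes]

        root = self.graph.chem[self.graph.root]
        if not root.solved:
            return []
        if root.terminal:
            return [
                PlanRoute(
                    steps=[],
                    leaves={root.smiles: root.buyable_matches},
                    depth=0,
                    n_reactions=0,
                )
            ]
        raw = expand_routes(self.graph.root, frozenset())
        routes = []
        for steps, leaves in raw[: cfg.max_routes]:
            depth = _route_depth(steps, self.graph.root)
            routes.append(
                PlanRoute(
                    steps=list(steps),
                    leaves={
                        s: self.graph.chem[s].buyable_matches for s in sorted(leaves)
                    },
                    depth=depth,
                    n_reactions=len(steps),
                )
            )
        routes.sort(key=lambda r: (r.depth, r.n_reactions))
        return routes


def _route_depth(steps, target: str) -> int:
    produced = {}
    for step in steps:
        produced.setdefault(step.product, step)

    cache: dict[str, int] = {}

    def depth(smiles: str) -> int:
        if smiles in cache:
            return cache[smiles]
        step = produced.get(smiles)
        if step is None:
            cache[smiles] = 0
            return 0
        cache[smiles] = 0
        value = 1 + max((depth(p) for p in step.precursors), default=0)
        cache[smiles] = value
        return value

    return depth(target)


def _mols_for(smiles_tuple):
    return [Chem.MolFromSmiles(s) for s in smiles_tuple]


def run_search(
    target,
    model: TemplateClassifier,
    catalog: BuyablesCatalog,
    config: SearchConfig | None = None,
) -> PlanResult:
    """Plan routes for one target (SMILES string or Mol)."""
    if isinstance(target, str):
        mol = Chem.MolFromSmiles(target)
        if mol is None:
            raise ValueError(f"unparseable target SMILES {target!r}")
    else:
        mol = target
    return _Search(mol, model, catalog, config or SearchConfig()).run()


def success_rate(results: list[PlanResult]) -> float:
    """Percent of targets with at least one terminating route."""
    if not results:
        return 0.0
    return 100.0 * sum(r.success for r in results) / len(results)


def route_stats(results: list[PlanResult]) -> list[dict]:
    out = []
    for r in results:
        out.append(
            {
                "target": r.target,
                "success": r.success,
                "depth": r.best_depth(),
                "n_reactions": r.best_n_reactions(),
                "n_routes": len(r.routes),
                "iterations": r.iterations,
            }
        )
    return out


def compare_modes(results_a, results_b) -> list[dict]:
    """Per-target deltas of best depth/reaction count (A minus B)."""
    by_target = {r.target: r for r in results_b}
    out = []
    for ra in results_a:
        rb = by_target.get(ra.target)
        if rb is None or not (ra.success and rb.success):
            continue
        out.append(
            {
                "target": ra.target,
                "delta_depth": ra.best_depth() - rb.best_depth(),
                "delta_n_reactions": ra.best_n_reactions() - rb.best_n_reactions(),
            }
        )
    return out


def write_routes_json(results: list[PlanResult], path) -> None:
    payload = []
    for r in results:
        payload.append(
            {
                "target": r.target,
                "success": r.success,
                "iterations": r.iterations,
                "routes": [
                    {
                        "depth": route.depth,
                        "n_reactions": route.n_reactions,
                        "steps": [
                            {
                                "product": s.product,
                                "template_id": s.template_id,
                                "precursors": list(s.precursors),
                            }
                            for s in route.steps
                        ],
                        "buyable_matches": route.leaves,
                    }
                    for route in r.routes
                ],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
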