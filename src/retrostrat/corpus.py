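"""Synthetic patent-like reaction corpus with planted ground truth.

Each generated document contains the atom-mapped records of one multistep
route.  Targets are assembled forward from aryl/amine/alkyl fragment
pools through scaffold-building joins (sulfonamide, amide, ester, benzyl
ether, N-benzylation, thioether, aryl alkynylation/vinylation, biaryl
coupling); the route is then derived by a fixed, structure-determined
decomposition priority, so identical molecules always decompose the same
way.  With probability ``p_tactical`` a route is given one tactical
detour: a leaving-group FGI (aryl halide <- triflate <- phenol, or acid
-> acyl chloride) or a silyl protection/deprotection pair on a phenol.

Atom maps are constructed during generation via persistent per-atom ids
("gids"), so the planted leaving-atom sets and retained-hydrogen counts
are exact by construction, not inferred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from rdkit import Chem

from retrostrat.chem import write_reaction_records

# ---------------------------------------------------------------------------
# fragment pools

ARYL_CORES = [
    "c1ccccc1",
    "c1ccncc1",
    "c1cccnc1",
    "c1ccc2ccccc2c1",
    "c1ccsc1",
    "c1ccoc1",
]

#: substituents attached to aromatic CH positions (none may contain a
#: disconnectable feature)
ARYL_DECORATIONS = ["F", "C", "OC", "C(F)(F)F"]

AMINES = ["CN", "CCN", "CNC", "C1CCNCC1", "C1CCNC1", "C1COCCN1"]

ALKYLS = ["C", "CC", "CCC", "CC(C)C"]

SCAFFOLD_FAMILIES = (
    "sulfonamide",
    "amide",
    "ester",
    "benzyl_ether",
    "n_benzylation",
    "thioether",
    "alkyne",
    "vinyl",
    "arylamination",
    "biaryl",
)

#: scaffold families whose retro-split orientation is determined by the
#: product structure alone (a symmetric biaryl disconnection proposes
#: both polarity orientations, so it is excluded here)
UNAMBIGUOUS_FAMILIES = tuple(f for f in SCAFFOLD_FAMILIES if f != "biaryl")

#: decomposition priority: first matching feature is split first
_FEATURES = [
    ("sulfonamide", "[NX3:1]-[SX4:2](=O)=O"),
    ("amide", "[NX3:1]-[CX3:2](=O)-[#6]"),
    ("ester", "[CX4:1]-[OX2:2]-[CX3:3](=O)-[#6]"),
    ("benzyl_ether", "[c:1]-[OX2:2]-[CH2:3]-[c:4]"),
    ("n_benzylation", "[NX3:1]-[CH2:2]-[c:3]"),
    ("thioether", "[c:1]-[SX2:2]-[CH2:3]"),
    ("alkyne", "[c:1]-[CX2:2]#[CX2:3]"),
    ("vinyl", "[c:1]-[CH1:2]=[CH1:3]"),
    ("arylamination", "[NX3:1]-[c:2]"),
    ("biaryl", "[c:1]-[c:2]"),
]

_FEATURE_QUERIES = [(fam, Chem.MolFromSmarts(sma)) for fam, sma in _FEATURES]

# leaving-group recipes (first atom is the attachment atom)
_LG = {
    "Br": "Br",
    "Cl": "Cl",
    "I": "I",
    "F": "F",
    "OH": "O",
    "OMe": "OC",
    "OTf": "OS(=O)(=O)C(F)(F)F",
    "B(OH)2": "B(O)O",
    "Bpin": "B1OC(C)(C)C(C)(C)O1",
    "TBS": "[Si](C)(C)C(C)(C)C",
    "TIPS": "[Si](C(C)C)(C(C)C)C(C)C",
    "Boc": "C(=O)OC(C)(C)C",
    "Ac": "C(C)=O",
}


@dataclass
class CorpusSpec:
    """Conditions of one synthetic corpus; same spec + seed => same bytes."""

    n_documents: int = 100
    families: tuple[str, ...] = SCAFFOLD_FAMILIES
    p_tactical: float = 0.3
    min_steps: int = 2
    max_steps: int = 4
    max_decorations: int = 2
    seed: int = 0


@dataclass
class GeneratedRecord:
    record_id: str
    family: str
    tactical: bool
    product: Chem.Mol  # generator mol with gid props, no maps
    reactants: list[Chem.Mol]
    smiles: str = ""
    #: role ("p" or reactant index, as str) -> {"leaving": [...], "core_h": {...}}
    provenance: dict = field(default_factory=dict)


@dataclass
class LeafInfo:
    smiles: str
    kind: str
    variant: str | None
    reagent: bool = False


@dataclass
class GeneratedRoute:
    document_id: str
    target: str  # canonical SMILES
    records: list[GeneratedRecord]
    leaves: list[LeafInfo]
    depth: int = 0
    n_reactions: int = 0
    hl_depth: int = 0
    hl_n_reactions: int = 0
    tactical_records: list[str] = field(default_factory=list)
    strategy_keys: list[str] = field(default_factory=list)


@dataclass
class SyntheticCorpus:
    spec: CorpusSpec
    routes: list[GeneratedRoute]

    def iter_records(self):
        for route in self.routes:
            for rec in route.records:
                yield route.document_id, rec.record_id, rec.smiles

    def write(self, path) -> None:
        write_reaction_records(path, self.iter_records())

    def unique_strategies(self) -> set[str]:
        return {k for route in self.routes for k in route.strategy_keys}

    def ground_truth(self) -> dict:
        docs = {}
        for route in self.routes:
            docs[route.document_id] = {
                "target": route.target,
                "depth": route.depth,
                "n_reactions": route.n_reactions,
                "hl_depth": route.hl_depth,
                "hl_n_reactions": route.hl_n_reactions,
                "tactical_records": route.tactical_records,
                "records": [
                    {
                        "record_id": rec.record_id,
                        "family": rec.family,
                        "tactical": rec.tactical,
                        "provenance": rec.provenance,
                    }
                    for rec in route.records
                ],
                "leaves": [
                    {
                        "smiles": leaf.smiles,
                        "kind": leaf.kind,
                        "variant": leaf.variant,
                        "reagent": leaf.reagent,
                    }
                    for leaf in route.leaves
                ],
            }
        return {
            "documents": docs,
            "n_unique_strategies": len(self.unique_strategies()),
        }

    def write_ground_truth(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.ground_truth(), handle, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# gid bookkeeping


class _Gids:
    def __init__(self) -> None:
        self.next = 1

    def tag(self, mol: Chem.Mol) -> Chem.Mol:
        for atom in mol.GetAtoms():
            atom.SetIntProp("gid", self.next)
            self.next += 1
        return mol


def _gid(atom: Chem.Atom) -> int:
    return atom.GetIntProp("gid")


def _gids(mol: Chem.Mol) -> frozenset[int]:
    return frozenset(_gid(a) for a in mol.GetAtoms())


def _sanitize(mol: Chem.Mol) -> Chem.Mol:
    Chem.SanitizeMol(mol)
    return mol


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - pool entries are valid
        raise ValueError(f"bad pool SMILES {smiles!r}")
    return mol


def _attach(mol: Chem.Mol, idx: int, recipe: str, gids: _Gids,
            bond: Chem.BondType = Chem.BondType.SINGLE) -> tuple[Chem.Mol, int]:
    """Attach a recipe fragment (first atom binds) to atom *idx* of *mol*."""
    frag = gids.tag(_parse(recipe))
    n0 = mol.GetNumAtoms()
    out = Chem.RWMol(Chem.CombineMols(mol, frag))
    out.AddBond(idx, n0, bond)
    return _sanitize(out.GetMol()), n0


# ---------------------------------------------------------------------------
# target assembly


def _aromatic_ch_atoms(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _nh_atoms(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "N" and a.GetTotalNumHs() >= 1 and not a.GetIsAromatic()
    ]


def _build_aryl(rng, gids: _Gids, spec: CorpusSpec,
                force_oh: bool = False) -> tuple[Chem.Mol, int]:
    mol = gids.tag(_parse(rng.choice(ARYL_CORES)))
    n_dec = rng.randint(0, spec.max_decorations)
    decorations = [rng.choice(ARYL_DECORATIONS) for _ in range(n_dec)]
    if force_oh:
        decorations.append("O")
    for dec in decorations:
        sites = _aromatic_ch_atoms(mol)
        if len(sites) <= 1:
            break
        mol, _ = _attach(mol, rng.choice(sites), dec, gids)
    return mol, -1  # attachment chosen later


def _pick_attachment(rng, mol: Chem.Mol) -> int | None:
    sites = _aromatic_ch_atoms(mol)
    return rng.choice(sites) if sites else None


def _join(rng, gids: _Gids, spec: CorpusSpec, current: Chem.Mol,
          family: str) -> Chem.Mol | None:
    """Forward scaffold join of *current* with a fresh partner fragment."""
    if family != "n_benzylation" and not _aromatic_ch_atoms(current):
        return None

    def aryl():
        mol, _ = _build_aryl(rng, gids, spec)
        return mol

    if family in ("sulfonamide", "amide"):
        partner = gids.tag(_parse(rng.choice(AMINES)))
        p_site = _nh_atoms(partner)[0]
        c_site = _pick_attachment(rng, current)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        if family == "sulfonamide":
            linker = gids.tag(_parse("S(=O)=O"))
            n1 = out.GetNumAtoms()
            out = Chem.RWMol(Chem.CombineMols(out.GetMol(), linker))
            out.AddBond(c_site, n1, Chem.BondType.SINGLE)
            out.AddBond(n1, n0 + p_site, Chem.BondType.SINGLE)
        else:
            linker = gids.tag(_parse("C=O"))
            n1 = out.GetNumAtoms()
            out = Chem.RWMol(Chem.CombineMols(out.GetMol(), linker))
            out.AddBond(c_site, n1, Chem.BondType.SINGLE)
            out.AddBond(n1, n0 + p_site, Chem.BondType.SINGLE)
        return _sanitize(out.GetMol())

    if family == "ester":
        partner = gids.tag(_parse(rng.choice(ALKYLS)))
        c_site = _pick_attachment(rng, current)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        linker = gids.tag(_parse("C(=O)O"))
        n1 = out.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(out.GetMol(), linker))
        out.AddBond(c_site, n1, Chem.BondType.SINGLE)  # c-C(=O)
        out.AddBond(n1 + 2, n0, Chem.BondType.SINGLE)  # O-alkyl
        return _sanitize(out.GetMol())

    if family == "benzyl_ether":
        partner = aryl()
        c_site = _pick_attachment(rng, current)
        p_site = _pick_attachment(rng, partner)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        linker = gids.tag(_parse("OC"))  # O-CH2
        n1 = out.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(out.GetMol(), linker))
        out.AddBond(c_site, n1, Chem.BondType.SINGLE)
        out.AddBond(n1 + 1, n0 + p_site, Chem.BondType.SINGLE)
        return _sanitize(out.GetMol())

    if family == "n_benzylation":
        # only N sites with no existing CH2 neighbor: the retro-split of
        # the installed benzylic bond must be the unique N-CH2 bond
        def no_ch2(i):
            return not any(
                n.GetSymbol() == "C"
                and not n.GetIsAromatic()
                and n.GetTotalNumHs() == 2
                for n in current.GetAtomWithIdx(i).GetNeighbors()
            )

        sites = [i for i in _nh_atoms(current) if no_ch2(i)]
        if not sites:
            return None
        partner = aryl()
        p_site = _pick_attachment(rng, partner)
        n_site = rng.choice(sites)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        linker = gids.tag(_parse("C"))
        n1 = out.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(out.GetMol(), linker))
        out.AddBond(n_site, n1, Chem.BondType.SINGLE)
        out.AddBond(n1, n0 + p_site, Chem.BondType.SINGLE)
        return _sanitize(out.GetMol())

    if family == "thioether":
        partner = aryl()
        c_site = _pick_attachment(rng, current)
        p_site = _pick_attachment(rng, partner)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        linker = gids.tag(_parse("SC"))  # S-CH2
        n1 = out.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(out.GetMol(), linker))
        out.AddBond(c_site, n1, Chem.BondType.SINGLE)
        out.AddBond(n1 + 1, n0 + p_site, Chem.BondType.SINGLE)
        return _sanitize(out.GetMol())

    if family in ("alkyne", "vinyl"):
        partner = gids.tag(_parse(rng.choice(ALKYLS)))
        c_site = _pick_attachment(rng, current)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        linker = gids.tag(_parse("C#C" if family == "alkyne" else "C=C"))
        n1 = out.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(out.GetMol(), linker))
        out.AddBond(c_site, n1, Chem.BondType.SINGLE)
        out.AddBond(n1 + 1, n0, Chem.BondType.SINGLE)
        return _sanitize(out.GetMol())

    if family == "arylamination":
        partner = gids.tag(_parse(rng.choice(AMINES)))
        p_site = _nh_atoms(partner)[0]
        c_site = _pick_attachment(rng, current)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        out.AddBond(c_site, n0 + p_site, Chem.BondType.SINGLE)
        return _sanitize(out.GetMol())

    if family == "biaryl":
        partner = aryl()
        c_site = _pick_attachment(rng, current)
        p_site = _pick_attachment(rng, partner)
        n0 = current.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(current, partner))
        out.AddBond(c_site, n0 + p_site, Chem.BondType.SINGLE)
        return _sanitize(out.GetMol())

    raise ValueError(f"unknown family {family!r}")


def _assemble_target(rng, gids: _Gids, spec: CorpusSpec,
                     force_phenol: bool) -> Chem.Mol:
    current, _ = _build_aryl(rng, gids, spec, force_oh=force_phenol)
    families = [f for f in spec.families if f in SCAFFOLD_FAMILIES]
    if not families:
        raise ValueError("family list contains no scaffold families")
    n_steps = min(rng.randint(spec.min_steps, spec.max_steps), len(families))
    # each family joins at most once per route, so every recorded product
    # determines its own decomposition unambiguously
    order = rng.sample(families, len(families))
    done = 0
    for fam in order:
        if done >= n_steps:
            break
        joined = _join(rng, gids, spec, current, fam)
        if joined is None:
            continue
        current = joined
        done += 1
    return current


# ---------------------------------------------------------------------------
# priority decomposition


def _find_feature(mol: Chem.Mol):
    """Highest-priority disconnectable feature, deterministically chosen."""
    ranks = None
    for family, query in _FEATURE_QUERIES:
        matches = mol.GetSubstructMatches(query)
        if family == "biaryl":
            matches = tuple(
                m
                for m in matches
                if not mol.GetBondBetweenAtoms(m[0], m[1]).IsInRing()
            )
        if not matches:
            continue
        if ranks is None:
            ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
        best = min(matches, key=lambda m: tuple(ranks[i] for i in m))
        return family, best
    return None


def _break_and_split(
    mol: Chem.Mol,
    bond_atoms: tuple[int, int],
    attachments: list[tuple[int, str]],
    gids: _Gids,
) -> list[Chem.Mol]:
    """Break one bond and attach leaving groups; return sanitized fragments."""
    out = Chem.RWMol(mol)
    out.RemoveBond(*bond_atoms)
    offset = {}
    for site, recipe in attachments:
        if not recipe:
            continue
        frag = gids.tag(_parse(_LG[recipe]))
        n0 = out.GetNumAtoms()
        out = Chem.RWMol(Chem.CombineMols(out.GetMol(), frag))
        out.AddBond(site, n0, Chem.BondType.SINGLE)
        offset[site] = n0
    whole = out.GetMol()
    _sanitize(whole)
    frags = Chem.GetMolFrags(whole, asMols=True, sanitizeFrags=True)
    return list(frags)


def _split_record(mol: Chem.Mol, family: str, match: tuple[int, ...],
                  rng, gids: _Gids) -> tuple[list[tuple[Chem.Mol, str]], dict]:
    """Retro-split one feature; returns (fragment, leaf-kind) pairs and info.

    ``info`` records which leaving-group recipe went where, for detour
    planting and buyable-variant construction.
    """
    info: dict = {"family": family}
    if family == "sulfonamide":
        n_idx, s_idx = match[0], match[1]
        frags = _break_and_split(mol, (n_idx, s_idx), [(s_idx, "Cl")], gids)
        kinds = _kinds_by_membership(frags, {n_idx: "amine", s_idx: "sulfonyl"}, mol)
        info["lg"] = {"sulfonyl": "Cl"}
    elif family == "amide":
        n_idx, c_idx = match[0], match[1]
        lg = rng.choice(["Cl", "OH"])
        frags = _break_and_split(mol, (n_idx, c_idx), [(c_idx, lg)], gids)
        kinds = _kinds_by_membership(frags, {n_idx: "amine", c_idx: "acyl"}, mol)
        info["lg"] = {"acyl": lg}
    elif family == "ester":
        o_idx, c_idx = match[1], match[2]
        lg = rng.choice(["Cl", "OH"])
        frags = _break_and_split(mol, (o_idx, c_idx), [(c_idx, lg)], gids)
        kinds = _kinds_by_membership(frags, {o_idx: "alcohol", c_idx: "acyl"}, mol)
        info["lg"] = {"acyl": lg}
    elif family == "benzyl_ether":
        o_idx, c_idx = match[1], match[2]
        lg = rng.choice(["Br", "Cl"])
        frags = _break_and_split(mol, (o_idx, c_idx), [(c_idx, lg)], gids)
        kinds = _kinds_by_membership(
            frags, {o_idx: "phenol", c_idx: "benzyl_halide"}, mol
        )
        info["lg"] = {"benzyl_halide": lg}
    elif family == "n_benzylation":
        n_idx, c_idx = match[0], match[1]
        lg = rng.choice(["Br", "Cl"])
        frags = _break_and_split(mol, (n_idx, c_idx), [(c_idx, lg)], gids)
        kinds = _kinds_by_membership(
            frags, {n_idx: "amine", c_idx: "benzyl_halide"}, mol
        )
        info["lg"] = {"benzyl_halide": lg}
    elif family == "thioether":
        s_idx, c_idx = match[1], match[2]
        lg = rng.choice(["Br", "Cl"])
        frags = _break_and_split(mol, (s_idx, c_idx), [(c_idx, lg)], gids)
        kinds = _kinds_by_membership(
            frags, {s_idx: "thiol", c_idx: "benzyl_halide"}, mol
        )
        info["lg"] = {"benzyl_halide": lg}
    elif family == "arylamination":
        n_idx, c_idx = match[0], match[1]
        lg = rng.choice(["Br", "Cl"])
        frags = _break_and_split(mol, (n_idx, c_idx), [(c_idx, lg)], gids)
        kinds = _kinds_by_membership(frags, {n_idx: "amine", c_idx: "aryl_halide"}, mol)
        info["lg"] = {"aryl_halide": lg}
    elif family in ("alkyne", "vinyl"):
        ar_idx, c_idx = match[0], match[1]
        lg = rng.choice(["Br", "Cl"])
        frags = _break_and_split(
            mol, (ar_idx, c_idx), [(ar_idx, lg), (c_idx, "B(OH)2")], gids
        )
        kinds = _kinds_by_membership(
            frags, {ar_idx: "aryl_halide", c_idx: "boronate"}, mol
        )
        info["lg"] = {"aryl_halide": lg, "boronate": "B(OH)2"}
    elif family == "biaryl":
        a_idx, b_idx = match[0], match[1]
        lg = rng.choice(["Br", "Cl"])
        frags = _break_and_split(
            mol, (a_idx, b_idx), [(a_idx, lg), (b_idx, "B(OH)2")], gids
        )
        kinds = _kinds_by_membership(
            frags, {a_idx: "aryl_halide", b_idx: "boronate"}, mol
        )
        info["lg"] = {"aryl_halide": lg, "boronate": "B(OH)2"}
    else:  # pragma: no cover
        raise ValueError(f"unknown family {family!r}")
    parts = [(frag, kind, site) for frag, (kind, site) in zip(frags, kinds)]
    return parts, info


def _kinds_by_membership(frags, role_by_atom: dict[int, str],
                         parent: Chem.Mol) -> list[tuple[str, int | None]]:
    """Per fragment: role of the inherited split atom and that atom's gid."""
    gid_roles = {_gid(parent.GetAtomWithIdx(i)): r for i, r in role_by_atom.items()}
    out = []
    for frag in frags:
        kind, site = "", None
        for atom in frag.GetAtoms():
            role = gid_roles.get(_gid(atom))
            if role:
                kind, site = role, _gid(atom)
                break
        out.append((kind, site))
    return out


# ---------------------------------------------------------------------------
# route generation

_VARIANT_RULES = {
    # kind -> (mode, recipe): "swap" replaces the leaving group, "cap"
    # attaches a protecting group at the functional atom
    "aryl_halide": ("swap", "I"),
    "benzyl_halide": ("swap", "I"),
    "boronate": ("swap", "Bpin"),
    "acyl": ("swap", "OMe"),
    "sulfonyl": ("swap", "F"),
    "amine": ("cap", "Boc"),
    "phenol": ("cap", "TIPS"),
    "alcohol": ("cap", "TIPS"),
    "thiol": ("cap", "Ac"),
    "fgi_phenol": ("swap", "I"),
}


class _RouteBuilder:
    """Builds one document: records, leaves, detour, ground truth."""

    def __init__(self, document_id: str, rng, spec: CorpusSpec):
        self.document_id = document_id
        self.rng = rng
        self.spec = spec
        self.gids = _Gids()
        self.records: list[GeneratedRecord] = []
        self.leaves: list[tuple[Chem.Mol, str, dict]] = []  # mol, kind, lg info
        self.n_rec = 0

    def next_record_id(self) -> str:
        self.n_rec += 1
        return f"{self.document_id}-r{self.n_rec:02d}"

    # -- construction ------------------------------------------------------

    def build(self) -> GeneratedRoute:
        rng = self.rng
        detour = None
        if rng.random() < self.spec.p_tactical:
            detour = rng.choice(["fgi_halide", "fgi_acyl", "protection"])
        force_phenol = detour == "protection"
        target = _assemble_target(rng, self.gids, self.spec, force_phenol)
        self.target = target
        self.target_gids = _gids(target)

        root = target
        deprot_extra = None
        if detour == "protection":
            prot = self._protect_phenol(target)
            if prot is None:
                detour = rng.choice(["fgi_halide", "fgi_acyl"])
            else:
                root, deprot_extra = prot

        self._decompose(root, kind="")

        if deprot_extra is not None:
            self.records.append(deprot_extra)
            self._plant_protection_record()
        elif detour in ("fgi_halide", "fgi_acyl"):
            order = (
                [self._plant_halide_fgi, self._plant_acyl_fgi]
                if detour == "fgi_halide"
                else [self._plant_acyl_fgi, self._plant_halide_fgi]
            )
            for plant in order:
                if plant():
                    break

        return self._emit()

    def _decompose(self, mol: Chem.Mol, kind: str, lg_info: dict | None = None):
        found = _find_feature(mol)
        if found is None:
            self.leaves.append((mol, kind, lg_info or {}))
            return
        family, match = found
        parts, info = _split_record(mol, family, match, self.rng, self.gids)
        rec = GeneratedRecord(
            record_id=self.next_record_id(),
            family=family,
            tactical=False,
            product=mol,
            reactants=[m for m, _, _ in parts],
        )
        self.records.append(rec)
        for frag, frag_kind, site in parts:
            self._decompose(
                frag, frag_kind, {"lg": info.get("lg", {}), "site_gid": site}
            )

    # -- detours -----------------------------------------------------------

    def _protect_phenol(self, target: Chem.Mol):
        """Silyl-protect the planted phenol; returns (protected root, deprot record)."""
        oh = [
            a.GetIdx()
            for a in target.GetAtoms()
            if a.GetSymbol() == "O"
            and a.GetTotalNumHs() == 1
            and a.GetDegree() == 1
            and a.GetNeighbors()[0].GetIsAromatic()
        ]
        if not oh:
            return None
        self._prot_o_gid = _gid(target.GetAtomWithIdx(oh[0]))
        gid0 = self.gids.next
        prot, _ = _attach(Chem.Mol(target), oh[0], _LG["TBS"], self.gids)
        self._prot_tbs_gids = list(range(gid0, self.gids.next))
        deprot = GeneratedRecord(
            record_id=self.next_record_id(),
            family="deprotection",
            tactical=False,
            product=target,
            reactants=[prot],
        )
        return prot, deprot

    def _plant_protection_record(self) -> None:
        """Tactical silylation record at the leaf carrying the protected O."""
        tbs = set(self._prot_tbs_gids)
        idx = None
        for i, (mol, kind, info) in enumerate(self.leaves):
            if tbs & set(_gids(mol)):
                idx = i
                break
        if idx is None:  # pragma: no cover - leaf must exist
            return
        leaf, kind, info = self.leaves[idx]
        bare = Chem.RWMol(leaf)
        for j in sorted(
            (a.GetIdx() for a in leaf.GetAtoms() if _gid(a) in tbs), reverse=True
        ):
            bare.RemoveAtom(j)
        bare = _sanitize(bare.GetMol())
        tbscl = _parse("Cl[Si](C)(C)C(C)(C)C")
        tbscl.GetAtomWithIdx(0).SetIntProp("gid", self.gids.next)
        self.gids.next += 1
        for i in range(1, tbscl.GetNumAtoms()):
            tbscl.GetAtomWithIdx(i).SetIntProp("gid", self._prot_tbs_gids[i - 1])
        rec = GeneratedRecord(
            record_id=self.next_record_id(),
            family="protection",
            tactical=True,
            product=leaf,
            reactants=[bare, tbscl],
        )
        self.records.append(rec)
        self.leaves[idx] = (bare, "phenol", {**info, "site_gid": self._prot_o_gid})
        self.leaves.append((tbscl, "reagent", {}))

    def _consumer_product_gids(self, mol: Chem.Mol) -> frozenset[int]:
        g = _gids(mol)
        for rec in self.records:
            for r in rec.reactants:
                if _gids(r) == g:
                    return _gids(rec.product)
        return frozenset()

    def _plant_halide_fgi(self) -> bool:
        # eligible: an aromatic-bound Br/Cl on a leaf that leaves in the
        # very next step (absent from the consuming record's product);
        # pool decorations use F only, so it is a planted leaving group
        idx = site = None
        for i, (mol, kind, _) in enumerate(self.leaves):
            if kind == "reagent":
                continue
            downstream = self._consumer_product_gids(mol)
            for a in mol.GetAtoms():
                if (
                    a.GetSymbol() in ("Br", "Cl")
                    and a.GetNeighbors()[0].GetIsAromatic()
                    and _gid(a) not in downstream
                ):
                    idx, site = i, a.GetIdx()
                    break
            if idx is not None:
                break
        if idx is None:
            return False
        leaf, kind, info = self.leaves[idx]
        core_idx = leaf.GetAtomWithIdx(site).GetNeighbors()[0].GetIdx()
        bare = Chem.RWMol(leaf)
        bare.RemoveAtom(site)
        bare = _sanitize(bare.GetMol())
        # core atom indices shift only for atoms after `site`
        def shifted(i):
            return i - 1 if i > site else i
        triflate, o_idx = _attach(Chem.Mol(bare), shifted(core_idx), _LG["OTf"], self.gids)
        phenol = Chem.RWMol(Chem.Mol(bare))
        o_atom = Chem.Atom(8)
        new_o = phenol.AddAtom(o_atom)
        phenol.AddBond(shifted(core_idx), new_o, Chem.BondType.SINGLE)
        phenol = _sanitize(phenol.GetMol())
        phenol.GetAtomWithIdx(new_o).SetIntProp(
            "gid", _gid(triflate.GetAtomWithIdx(o_idx))
        )
        # TfCl reagent shares the gids of the triflate tail
        tfcl = _parse("ClS(=O)(=O)C(F)(F)F")
        tfcl.GetAtomWithIdx(0).SetIntProp("gid", self.gids.next)
        self.gids.next += 1
        for i in range(1, tfcl.GetNumAtoms()):
            tfcl.GetAtomWithIdx(i).SetIntProp(
                "gid", _gid(triflate.GetAtomWithIdx(o_idx + i))
            )
        # swap the coupling reactant and retire the old leaf
        self._replace_reactant(leaf, triflate)
        rec = GeneratedRecord(
            record_id=self.next_record_id(),
            family="fgi_triflation",
            tactical=True,
            product=triflate,
            reactants=[phenol, tfcl],
        )
        self.records.append(rec)
        o_gid = _gid(triflate.GetAtomWithIdx(o_idx))
        self.leaves[idx] = (phenol, "fgi_phenol", {**info, "site_gid": o_gid})
        self.leaves.append((tfcl, "reagent", {}))
        return True

    def _plant_acyl_fgi(self) -> bool:
        idx = lg = lg_atom = None
        for i, (mol, kind, _) in enumerate(self.leaves):
            if kind == "reagent":
                continue
            downstream = self._consumer_product_gids(mol)
            for symbol, name in (("O", "OH"), ("Cl", "Cl")):
                j = self._acyl_lg_atom(mol, symbol, exclude_gids=downstream)
                if j is not None:
                    idx, lg, lg_atom = i, name, j
                    break
            if idx is not None:
                break
        if idx is None:
            return False
        leaf, kind, info = self.leaves[idx]
        if lg == "OH":
            # coupling used the acid; detour routes it through the chloride
            acid = leaf
            chloride, cl_gid = self._swap_acyl_lg(leaf, lg_atom, "Cl")
            self._replace_reactant(leaf, chloride)
            coupling_reactant = chloride
        else:
            coupling_reactant = leaf
            cl_gid = _gid(leaf.GetAtomWithIdx(lg_atom))
            acid, _ = self._swap_acyl_lg(leaf, lg_atom, "OH")
        socl2 = _parse("ClS(Cl)=O")
        for a in socl2.GetAtoms():
            a.SetIntProp("gid", self.gids.next)
            self.gids.next += 1
        socl2.GetAtomWithIdx(0).SetIntProp("gid", cl_gid)
        rec = GeneratedRecord(
            record_id=self.next_record_id(),
            family="fgi_acyl_chloride",
            tactical=True,
            product=coupling_reactant,
            reactants=[acid, socl2],
        )
        self.records.append(rec)
        self.leaves[idx] = (acid, kind, {**info, "lg": {"acyl": "OH"}})
        self.leaves.append((socl2, "reagent", {}))
        return True

    def _acyl_lg_atom(
        self, mol: Chem.Mol, symbol: str, exclude_gids: frozenset = frozenset()
    ) -> int | None:
        for a in mol.GetAtoms():
            if a.GetSymbol() != symbol or _gid(a) in exclude_gids:
                continue
            nb = a.GetNeighbors()
            if len(nb) == 1 and nb[0].GetSymbol() == "C":
                if any(
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetOtherAtom(nb[0]).GetSymbol() == "O"
                    for b in nb[0].GetBonds()
                ):
                    if symbol == "O" and a.GetTotalNumHs() != 1:
                        continue
                    return a.GetIdx()
        return None

    def _swap_acyl_lg(
        self, mol: Chem.Mol, lg_idx: int, new_lg: str
    ) -> tuple[Chem.Mol, int]:
        """Replace the acyl leaving atom at *lg_idx*; returns (mol, new LG gid)."""
        c_idx = mol.GetAtomWithIdx(lg_idx).GetNeighbors()[0].GetIdx()
        out = Chem.RWMol(mol)
        out.RemoveAtom(lg_idx)
        out = _sanitize(out.GetMol())
        c_new = c_idx - 1 if c_idx > lg_idx else c_idx
        out, new_idx = _attach(out, c_new, _LG[new_lg], self.gids)
        return out, _gid(out.GetAtomWithIdx(new_idx))

    def _replace_reactant(self, old: Chem.Mol, new: Chem.Mol) -> None:
        old_g = _gids(old)
        for rec in self.records:
            for i, r in enumerate(rec.reactants):
                if _gids(r) == old_g:
                    rec.reactants[i] = new
                    return

    # -- ground truth ------------------------------------------------------

    def _emit(self) -> GeneratedRoute:
        records = self.records
        target = self.target
        target_smiles = Chem.MolToSmiles(Chem.Mol(target))

        produced = {_gids(r.product): r for r in records}
        consumer: dict[frozenset, tuple[GeneratedRecord, int]] = {}
        for rec in records:
            for i, r in enumerate(rec.reactants):
                consumer.setdefault(_gids(r), (rec, i))

        # depth of each record from the target
        depth_of: dict[str, int] = {}

        def rec_depth(rec: GeneratedRecord) -> int:
            if rec.record_id in depth_of:
                return depth_of[rec.record_id]
            g = _gids(rec.product)
            if g == self.target_gids:
                d = 1
            else:
                c = consumer.get(g)
                d = rec_depth(c[0]) + 1 if c else 1
            depth_of[rec.record_id] = d
            return d

        for rec in records:
            rec_depth(rec)

        # longest linear sequence over the record DAG
        def mol_depth(g: frozenset) -> int:
            rec = produced.get(g)
            if rec is None:
                return 0
            return 1 + max((mol_depth(_gids(r)) for r in rec.reactants), default=0)

        depth = mol_depth(self.target_gids)

        # provenance ground truth (same semantics the miner must recover)
        core_h: dict[tuple[str, object], dict[int, int]] = {}
        is_core: dict[tuple[str, object], list[bool]] = {}
        for rec in sorted(records, key=lambda r: depth_of[r.record_id]):
            g = _gids(rec.product)
            if g == self.target_gids:
                ch = {
                    a.GetIdx(): a.GetTotalNumHs() for a in rec.product.GetAtoms()
                }
                co = [True] * rec.product.GetNumAtoms()
            else:
                c = consumer[g]
                down_key = (c[0].record_id, c[1])
                down_mol = c[0].reactants[c[1]]
                by_gid_h = {}
                by_gid_core = {}
                for a in down_mol.GetAtoms():
                    by_gid_h[_gid(a)] = core_h[down_key].get(a.GetIdx(), 0)
                    by_gid_core[_gid(a)] = is_core[down_key][a.GetIdx()]
                ch = {}
                co = []
                for a in rec.product.GetAtoms():
                    co.append(by_gid_core[_gid(a)])
                    ch[a.GetIdx()] = by_gid_h[_gid(a)]
            key = (rec.record_id, "p")
            core_h[key] = ch
            is_core[key] = co

            ph_by_gid = {
                _gid(a): ch[a.GetIdx()] for a in rec.product.GetAtoms() if co[a.GetIdx()]
            }
            for i, r in enumerate(rec.reactants):
                rch = {}
                rco = []
                for a in r.GetAtoms():
                    gid = _gid(a)
                    if gid in ph_by_gid:
                        rco.append(True)
                        rch[a.GetIdx()] = min(a.GetTotalNumHs(), ph_by_gid[gid])
                    else:
                        rco.append(False)
                        rch[a.GetIdx()] = 0
                rkey = (rec.record_id, i)
                core_h[rkey] = rch
                is_core[rkey] = rco

        # higher-level metrics: abstracted-node identity = core gids plus
        # retained-H and leaving-attachment counts (distinguishes e.g. a
        # free phenol from its abstracted protected form)
        def node_key(rec_id: str, role, mol: Chem.Mol) -> frozenset:
            co = is_core[(rec_id, role)]
            ch = core_h[(rec_id, role)]
            items = []
            for a in mol.GetAtoms():
                i = a.GetIdx()
                if not co[i]:
                    continue
                lost_h = a.GetTotalNumHs() - ch[i]
                leav = sum(
                    int(b.GetBondTypeAsDouble())
                    for b in a.GetBonds()
                    if not co[b.GetOtherAtom(a).GetIdx()]
                )
                items.append((_gid(a), ch[i], lost_h + leav))
            return frozenset(items)

        hl_edges: dict[frozenset, list[frozenset]] = {}
        hl_steps = set()
        for rec in records:
            if rec.tactical:
                continue
            pnode = node_key(rec.record_id, "p", rec.product)
            rnodes = [
                node_key(rec.record_id, i, r) for i, r in enumerate(rec.reactants)
            ]
            rnodes = [n for n in rnodes if n]
            step_key = (pnode, frozenset(rnodes))
            if step_key in hl_steps:
                continue
            hl_steps.add(step_key)
            hl_edges[pnode] = rnodes

        hl_cache: dict[frozenset, int] = {}

        def hl_mol_depth(node: frozenset) -> int:
            if node in hl_cache:
                return hl_cache[node]
            hl_cache[node] = 0  # cycle guard; DAG expected
            children = hl_edges.get(node)
            value = (
                0 if not children else 1 + max(hl_mol_depth(c) for c in children)
            )
            hl_cache[node] = value
            return value

        target_rec = produced[self.target_gids]
        hl_depth = hl_mol_depth(node_key(target_rec.record_id, "p", target_rec.product))
        hl_n = len(hl_steps)

        # emission: mapped SMILES + ground truth in parsed atom order
        strategy_keys = []
        for rec in records:
            gid2map = {}
            prod = Chem.Mol(rec.product)
            for j, atom in enumerate(prod.GetAtoms()):
                atom.SetAtomMapNum(j + 1)
                gid2map[_gid(atom)] = j + 1
            reactant_copies = []
            for r in rec.reactants:
                rc = Chem.Mol(r)
                for atom in rc.GetAtoms():
                    atom.SetAtomMapNum(gid2map.get(_gid(atom), 0))
                reactant_copies.append(rc)
            parts = []
            prov = {}
            for role, mol_c, orig in (
                [("p", prod, rec.product)]
                + [(i, rc, rec.reactants[i]) for i, rc in enumerate(reactant_copies)]
            ):
                smi = Chem.MolToSmiles(mol_c)
                import ast as _ast

                order = _ast.literal_eval(mol_c.GetProp("_smilesAtomOutputOrder"))
                key = (rec.record_id, role)
                leaving = [
                    pos
                    for pos, oi in enumerate(order)
                    if not is_core[key][oi]
                ]
                ch = {
                    str(pos): core_h[key][oi]
                    for pos, oi in enumerate(order)
                    if is_core[key][oi]
                }
                prov[str(role)] = {"leaving": sorted(leaving), "core_h": ch}
                parts.append(smi)
            rec.smiles = ".".join(parts[1:]) + ">>" + parts[0]
            rec.provenance = prov
            if not rec.tactical:
                strategy_keys.append(self._strategy_key(rec))

        leaves = [
            LeafInfo(
                smiles=Chem.MolToSmiles(mol),
                kind=kind,
                variant=self._variant(mol, kind, info),
                reagent=(kind == "reagent"),
            )
            for mol, kind, info in self.leaves
        ]

        return GeneratedRoute(
            document_id=self.document_id,
            target=Chem.MolToSmiles(Chem.Mol(target)),
            records=records,
            leaves=leaves,
            depth=depth,
            n_reactions=len(records),
            hl_depth=hl_depth,
            hl_n_reactions=hl_n,
            tactical_records=[r.record_id for r in records if r.tactical],
            strategy_keys=strategy_keys,
        )

    def _strip_leaving(self, mol: Chem.Mol) -> str | None:
        out = Chem.RWMol(mol)
        doomed = sorted(
            (a.GetIdx() for a in mol.GetAtoms() if _gid(a) not in self.target_gids),
            reverse=True,
        )
        if len(doomed) == mol.GetNumAtoms():
            return None
        for idx in doomed:
            out.RemoveAtom(idx)
        result = out.GetMol()
        try:
            Chem.SanitizeMol(result)
        except Exception:
            return Chem.MolToSmiles(result, canonical=True)
        return Chem.MolToSmiles(result)

    def _strategy_key(self, rec: GeneratedRecord) -> str:
        prod = self._strip_leaving(rec.product)
        parts = sorted(
            s
            for s in (self._strip_leaving(r) for r in rec.reactants)
            if s is not None
        )
        return f"{rec.family}|{'.'.join(parts)}>>{prod}"

    def _variant(self, mol: Chem.Mol, kind: str, info: dict) -> str | None:
        rule = _VARIANT_RULES.get(kind)
        if rule is None:
            return None
        mode, recipe = rule
        gids = _Gids()  # throwaway ids for variant building
        work = Chem.Mol(mol)
        site_atom = self._site_atom(work, kind, info)
        if site_atom is None:
            return None
        if mode == "cap":
            capped, _ = _attach(work, site_atom, _LG[recipe], gids)
            return Chem.MolToSmiles(capped)
        # swap: remove the leaving group at the site, attach the variant
        site, doomed = self._lg_atoms(work, kind, site_atom)
        if site is None:
            return None
        out = Chem.RWMol(work)
        for idx in sorted(doomed, reverse=True):
            out.RemoveAtom(idx)
        shift = sum(1 for d in doomed if d < site)
        bare = _sanitize(out.GetMol())
        swapped, _ = _attach(bare, site - shift, _LG[recipe], gids)
        return Chem.MolToSmiles(swapped)

    def _site_atom(self, mol: Chem.Mol, kind: str, info: dict) -> int | None:
        """Atom index of the leaf's reacting site, by planted gid."""
        site_gid = info.get("site_gid")
        if site_gid is not None:
            for a in mol.GetAtoms():
                if _gid(a) == site_gid:
                    return a.GetIdx()
        # fallback: structural scan (single-site leaves)
        if kind in ("amine", "phenol", "alcohol", "thiol"):
            symbol = {"amine": "N", "phenol": "O", "alcohol": "O", "thiol": "S"}[kind]
            for a in mol.GetAtoms():
                if a.GetSymbol() == symbol and a.GetTotalNumHs() >= 1:
                    return a.GetIdx()
            return None
        if kind in ("aryl_halide", "benzyl_halide"):
            for a in mol.GetAtoms():
                if a.GetSymbol() in ("Br", "Cl", "I"):
                    nb = a.GetNeighbors()[0]
                    if (kind == "aryl_halide") == nb.GetIsAromatic():
                        return nb.GetIdx()
            return None
        if kind == "boronate":
            for a in mol.GetAtoms():
                if a.GetSymbol() == "B":
                    core = [n for n in a.GetNeighbors() if n.GetSymbol() != "O"]
                    if core:
                        return core[0].GetIdx()
            return None
        if kind == "acyl":
            for sym in ("O", "Cl"):
                idx = self._acyl_lg_atom(mol, sym)
                if idx is not None:
                    return mol.GetAtomWithIdx(idx).GetNeighbors()[0].GetIdx()
            return None
        if kind == "sulfonyl":
            for a in mol.GetAtoms():
                if a.GetSymbol() == "S" and any(
                    n.GetSymbol() == "Cl" for n in a.GetNeighbors()
                ):
                    return a.GetIdx()
            return None
        if kind == "fgi_phenol":
            for a in mol.GetAtoms():
                if (
                    a.GetSymbol() == "O"
                    and a.GetTotalNumHs() == 1
                    and a.GetDegree() == 1
                    and a.GetNeighbors()[0].GetIsAromatic()
                ):
                    return a.GetIdx()
            return None
        return None

    def _lg_atoms(self, mol: Chem.Mol, kind: str, site: int):
        """(core attachment atom, leaving atom indices) for swap variants.

        ``site`` is the split-bond atom the leaf inherited: the core
        carbon for halide/boronate/acyl kinds, the S for sulfonyl, the
        leaving O itself for FGI phenols.
        """
        atom = mol.GetAtomWithIdx(site)
        if kind in ("aryl_halide", "benzyl_halide"):
            for n in atom.GetNeighbors():
                if n.GetSymbol() in ("Br", "Cl", "I"):
                    return site, [n.GetIdx()]
        elif kind == "boronate":
            for b in atom.GetNeighbors():
                if b.GetSymbol() == "B":
                    doomed = [b.GetIdx()] + [
                        n.GetIdx() for n in b.GetNeighbors() if n.GetSymbol() == "O"
                    ]
                    return site, doomed
        elif kind == "acyl":
            for n in atom.GetNeighbors():
                if n.GetSymbol() == "Cl" and n.GetDegree() == 1:
                    return site, [n.GetIdx()]
                if (
                    n.GetSymbol() == "O"
                    and n.GetDegree() == 1
                    and n.GetTotalNumHs() == 1
                ):
                    return site, [n.GetIdx()]
        elif kind == "sulfonyl":
            for n in atom.GetNeighbors():
                if n.GetSymbol() == "Cl":
                    return site, [n.GetIdx()]
        elif kind == "fgi_phenol":
            # site is the phenol O; the variant halogenates its carbon
            core = atom.GetNeighbors()[0].GetIdx()
            return core, [site]
        return None, []


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate a corpus of ``spec.n_documents`` single-route documents."""
    import random

    if not spec.families:
        raise ValueError("family list must not be empty")
    rng = random.Random(spec.seed)
    routes = []
    for d in range(spec.n_documents):
        doc_rng = random.Random(rng.randrange(2**31))
        builder = _RouteBuilder(f"DOC{d:05d}", doc_rng, spec)
        routes.append(builder.build())
    return SyntheticCorpus(spec=spec, routes=routes)


def make_buyables(corpus: SyntheticCorpus, variant_expansion: bool = False) -> list[str]:
    """Buyable stock from route leaves.

    With ``variant_expansion`` every proper leaf is replaced by a
    different functional-group variant of the same abstracted form
    (reagents are omitted), producing an adversarial stock for
    exact-match termination.
    """
    out = []
    for route in corpus.routes:
        for leaf in route.leaves:
            if variant_expansion:
                if leaf.variant is not None:
                    out.append(leaf.variant)
            else:
                out.append(leaf.smiles)
    # canonical dedup, stable order
    seen = {}
    for smi in out:
        mol = Chem.MolFromSmiles(smi)
        can = Chem.MolToSmiles(mol)
        seen.setdefault(can, None)
    return list(seen)
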