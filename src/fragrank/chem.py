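"""Molecular structure parsing and metabolite-graph construction.

A *metabolite graph* is the condensation of a small molecule obtained by
deleting every breakable bond: mass spectrometry is assumed to cleave only
N-C, O-C and C-C single bonds (the only frequent single bonds that do not
involve a hydrogen atom), so the connected components that remain after
deleting those bonds become nodes, and each deleted bond becomes a labelled
edge.  Aromatic systems are kekulized first, so a benzene ring contributes
three breakable single C-C bonds and three intact C=C units.

Structure input goes through :mod:`rdkit`; monoisotopic masses come from the
embedded constants table below so that results do not depend on the toolkit
version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# ---------------------------------------------------------------------------
# Constants

#: Monoisotopic atomic masses in Da (IUPAC/CODATA, 6 decimals).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "B": 11.009305,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "F": 18.998403,
    "Na": 22.989770,
    "Si": 27.976927,
    "P": 30.973762,
    "S": 31.972071,
    "Cl": 34.968853,
    "K": 38.963707,
    "Se": 79.916522,
    "Br": 78.918338,
    "I": 126.904473,
}

#: Mass of a proton in Da (charge carrier for [M+H]+ style adducts).
PROTON_MASS = 1.007276

#: Bond-type labels considered breakable by default.
DEFAULT_BREAKABLE: frozenset[str] = frozenset({"NC", "OC", "CC"})

#: Optional extra cleavable bond labels (off by default; marginal gain).
EXTRA_BOND_TYPES: frozenset[str] = frozenset({"SC", "OP", "PC"})

_PAIR_LABEL: dict[frozenset[str], str] = {
    frozenset({"N", "C"}): "NC",
    frozenset({"O", "C"}): "OC",
    frozenset({"C"}): "CC",
    frozenset({"S", "C"}): "SC",
    frozenset({"O", "P"}): "OP",
    frozenset({"P", "C"}): "PC",
}


class ParseError(ValueError):
    """A structure record could not be parsed; carries the record id."""

    def __init__(self, molecule_id: str, message: str):
        super().__init__(f"{molecule_id}: {message}")
        self.molecule_id = molecule_id


class UnsupportedElementError(ParseError):
    """The record contains an element without a monoisotopic mass entry."""


class DisconnectedMoleculeError(ValueError):
    """Multi-fragment record: split it into one record per component."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Molecule:
    """A small molecule with implicit hydrogens resolved.

    ``atoms`` holds ``(element symbol, attached hydrogen count)`` per heavy
    atom; ``bonds`` holds ``(i, j, order)`` with order one of ``single``,
    ``double``, ``triple`` (aromatic bonds are kekulized away on parse).
    """

    id: str
    atoms: tuple[tuple[str, int], ...]
    bonds: tuple[tuple[int, int, str], ...]
    monoisotopic_mass: float

    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    def atom_mass(self, i: int) -> float:
        sym, nh = self.atoms[i]
        return MONOISOTOPIC_MASS[sym] + nh * MONOISOTOPIC_MASS["H"]


@dataclass(frozen=True)
class MetaboliteNode:
    atoms: frozenset[int]
    mass: float


@dataclass(frozen=True)
class MetaboliteEdge:
    """A deleted breakable bond between two metabolite-graph nodes.

    ``hetero`` is the node index holding the heteroatom of an N-C/O-C bond
    (None for symmetric bonds such as C-C); the rearrangement rule table uses
    it to decide which fragment side gains the migrating hydrogen.
    """

    u: int
    v: int
    bond_type: str
    hetero: int | None = None

    def other(self, node: int) -> int:
        return self.v if node == self.u else self.u


@dataclass(frozen=True)
class MetaboliteGraph:
    molecule_id: str
    nodes: tuple[MetaboliteNode, ...]
    edges: tuple[MetaboliteEdge, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def total_mass(self) -> float:
        return sum(n.mass for n in self.nodes)

    def adjacency_masks(self) -> list[int]:
        """Per-node bitmask of neighbouring nodes (parallel edges collapse)."""
        adj = [0] * len(self.nodes)
        for e in self.edges:
            adj[e.u] |= 1 << e.v
            adj[e.v] |= 1 << e.u
        return adj


# ---------------------------------------------------------------------------
# Parsing


def _mol_from_record(record: str, molecule_id: str) -> Chem.Mol:
    text = record.strip()
    if not text:
        raise ParseError(molecule_id, "empty structure record")
    if "\n" in record or "V2000" in record or "V3000" in record:
        mol = Chem.MolFromMolBlock(record, sanitize=True, removeHs=True)
        dialect = "MOL"
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
        dialect = "SMILES"
    if mol is None:
        raise ParseError(molecule_id, f"unparseable {dialect} record")
    return mol


def _canonical_kekulized(mol: Chem.Mol) -> Chem.Mol:
    # Renumber atoms canonically before kekulization so the single/double
    # assignment in resonant rings is a function of the structure, not of
    # the input atom order.
    order = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    perm = [0] * len(order)
    for src, rank in enumerate(order):
        perm[rank] = src
    mol = Chem.RenumberAtoms(mol, perm)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
}


def parse_molecule(record: str, molecule_id: str) -> Molecule:
    """Parse a SMILES string or MOL block into a :class:`Molecule`.

    Implicit hydrogens are resolved, aromatic rings are deterministically
    kekulized, and the monoisotopic mass is computed from the embedded
    constants table.

    Raises
    ------
    ParseError
        If the record is empty or syntactically invalid.
    UnsupportedElementError
        If an element has no entry in :data:`MONOISOTOPIC_MASS`.
    """
    mol = _canonical_kekulized(_mol_from_record(record, molecule_id))
    atoms: list[tuple[str, int]] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in MONOISOTOPIC_MASS:
            raise UnsupportedElementError(
                molecule_id, f"element {sym!r} has no monoisotopic mass entry"
            )
        atoms.append((sym, atom.GetTotalNumHs()))
    bonds: list[tuple[int, int, str]] = []
    for bond in mol.GetBonds():
        order = _BOND_ORDER.get(bond.GetBondType())
        if order is None:
            raise ParseError(
                molecule_id, f"unsupported bond type {bond.GetBondType()}"
            )
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), order))
    mass = sum(
        MONOISOTOPIC_MASS[sym] + nh * MONOISOTOPIC_MASS["H"] for sym, nh in atoms
    )
    return Molecule(
        id=molecule_id,
        atoms=tuple(atoms),
        bonds=tuple(sorted(bonds)),
        monoisotopic_mass=mass,
    )


# ---------------------------------------------------------------------------
# Metabolite graph


def _bond_label(a: str, b: str) -> str | None:
    return _PAIR_LABEL.get(frozenset({a, b}))


def breakable_bonds(
    mol: Molecule, breakable: Iterable[str] = DEFAULT_BREAKABLE
) -> list[tuple[int, int, str]]:
    """Single bonds between the allowed element pairs, as (i, j, label)."""
    allowed = set(breakable)
    out = []
    for i, j, order in mol.bonds:
        if order != "single":
            continue
        label = _bond_label(mol.atoms[i][0], mol.atoms[j][0])
        if label in allowed:
            out.append((i, j, label))
    return out


def build_metabolite_graph(
    mol: Molecule, breakable: Iterable[str] = DEFAULT_BREAKABLE
) -> MetaboliteGraph:
    """Delete all breakable bonds and condense the molecule.

    The connected components remaining after deletion become the graph's
    nodes (each carrying the summed monoisotopic mass of its atoms plus their
    hydrogens); every deleted bond becomes exactly one labelled edge.

    Raises
    ------
    DisconnectedMoleculeError
        If the input record encodes more than one connected structure.
    """
    n = mol.n_heavy_atoms
    cut = breakable_bonds(mol, breakable)
    cut_set = {(i, j) for i, j, _ in cut}

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, j, _ in mol.bonds:
        if (i, j) not in cut_set:
            union(i, j)

    roots = sorted({find(i) for i in range(n)})
    comp_index = {r: k for k, r in enumerate(roots)}
    members: list[set[int]] = [set() for _ in roots]
    for i in range(n):
        members[comp_index[find(i)]].add(i)

    nodes = tuple(
        MetaboliteNode(
            atoms=frozenset(ms), mass=sum(mol.atom_mass(i) for i in ms)
        )
        for ms in members
    )
    edges = []
    for i, j, label in cut:
        u = comp_index[find(i)]
        v = comp_index[find(j)]
        hetero: int | None = None
        if mol.atoms[i][0] in ("N", "O", "P", "S"):
            hetero = u
        elif mol.atoms[j][0] in ("N", "O", "P", "S"):
            hetero = v
        edges.append(MetaboliteEdge(u=u, v=v, bond_type=label, hetero=hetero))

    graph = MetaboliteGraph(
        molecule_id=mol.id, nodes=nodes, edges=tuple(edges)
    )
    if not _is_connected(graph):
        raise DisconnectedMoleculeError(
            f"{mol.id}: record encodes a disconnected structure; "
            "split it into one record per component"
        )
    return graph


def _is_connected(g: MetaboliteGraph) -> bool:
    if g.n_nodes == 0:
        return False
    adj = g.adjacency_masks()
    full = (1 << g.n_nodes) - 1
    seen = 1
    frontier = 1
    while frontier:
        nxt = 0
        v = frontier
        while v:
            low = (v & -v).bit_length() - 1
            nxt |= adj[low]
            v &= v - 1
        frontier = nxt & ~seen
        seen |= nxt
    return seen == full


# ---------------------------------------------------------------------------
# Readers / writers


def read_smiles_tsv(path) -> list[Molecule]:
    """Read a two-column TSV (id, SMILES); header line optional."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {ln}", "expected 'id<TAB>smiles'")
            mol_id, smiles = parts[0], parts[1]
            if ln == 1 and smiles.lower() in ("smiles", "structure"):
                continue
            out.append(parse_molecule(smiles, mol_id))
    return out


def read_sdf(path) -> list[Molecule]:
    """Read a multi-record SDF file; record ids from the title line."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"record {k}", "unparseable SDF record")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record-{k}"
        out.append(parse_molecule(Chem.MolToMolBlock(mol), name or f"record-{k}"))
    return out


def metabolite_graph_to_json(g: MetaboliteGraph) -> str:
    """Serialize a metabolite graph for debugging / inspection."""
    return json.dumps(
        {
            "molecule_id": g.molecule_id,
            "nodes": [
                {"atoms": sorted(n.atoms), "mass": round(n.mass, 6)}
                for n in g.nodes
            ],
            "edges": [
                {"u": e.u, "v": e.v, "bond_type": e.bond_type, "hetero": e.hetero}
                for e in g.edges
            ],
        },
        indent=2,
    )
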