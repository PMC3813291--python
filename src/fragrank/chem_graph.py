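"""Molecular graph data model and anonymous-graph canonicalization.

Molecules are held as simple attributed graphs: heavy atoms as vertices
(element, formal charge, implicit hydrogen count), bonds as edges with a
Kekulé bond order plus an aromaticity flag.  Parsing from SMILES and SDF is
delegated to RDKit and the result converted into this lightweight model so
that downstream dissection logic owns its own data.

The *anonymous* view of a molecule drops every atom and bond attribute and
keeps only topology; two molecules share an anonymous graph exactly when
their heavy-atom skeletons are isomorphic.  Canonical hashing of anonymous
graphs uses Weisfeiler–Lehman colour refinement with an
individualization–refinement search, so equal hashes hold if and only if the
graphs are isomorphic (not merely WL-equivalent).
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("fragrank")

#: Elements accepted by the parser (organic subset plus hydrogen).
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
)


class SmilesParseError(ValueError):
    """Raised for a malformed SMILES string; carries the offending position."""

    def __init__(self, text: str, position: int | None, detail: str):
        self.text = text
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"cannot parse SMILES {text!r}{where}: {detail}")


class UnsupportedElementError(ValueError):
    """Raised when a structure contains an element outside the organic subset."""

    def __init__(self, element: str, position: int | None = None):
        self.element = element
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"unsupported element {element!r}{where}")


class SdfFormatError(ValueError):
    """Raised for a malformed or truncated SDF record; carries the record index."""

    def __init__(self, index: int, detail: str):
        self.index = index
        super().__init__(f"SDF record {index}: {detail}")


@dataclass
class Atom:
    """A heavy atom: element symbol, formal charge, implicit H count.

    ``pi_marker`` counts "dot pairs": π electron pairs left behind when a
    multiply-bonded neighbour was cut away during scaffold extraction.  It is
    0 for freshly parsed molecules.
    """

    element: str
    formal_charge: int = 0
    implicit_h: int = 0
    pi_marker: int = 0
    aromatic: bool = False


@dataclass
class Bond:
    i: int
    j: int
    order: int = 1  # Kekulé order: 1, 2 or 3
    aromatic: bool = False


@dataclass
class MolecularGraph:
    """Attributed molecular graph with 0-based atom indexing."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    identifier: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) has out-of-range atom index")
            if b.i == b.j:
                raise ValueError(f"self-bond on atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond between atoms {key}")
            seen.add(key)
        for idx, a in enumerate(self.atoms):
            if a.implicit_h < 0:
                raise ValueError(f"atom {idx}: negative implicit hydrogen count")
            if a.pi_marker < 0:
                raise ValueError(f"atom {idx}: negative pi marker")

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        return adj

    def bond_between(self, i: int, j: int) -> Bond | None:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b
        return None

    def to_networkx(self) -> nx.Graph:
        """Attributed networkx view (element/charge on nodes, order on edges)."""
        g = nx.Graph()
        for idx, a in enumerate(self.atoms):
            g.add_node(idx, element=a.element, charge=a.formal_charge,
                       aromatic=a.aromatic)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order, aromatic=b.aromatic)
        return g

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            identifier=self.identifier,
        )

    def molecular_formula(self) -> str:
        """Hill-order molecular formula including implicit hydrogens."""
        counts: dict[str, int] = {}
        n_h = 0
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
            n_h += a.implicit_h
        parts: list[str] = []
        if "C" in counts:
            parts.append("C" + (str(counts.pop("C")) if counts["C"] != 1 else ""))
            if n_h:
                parts.append("H" + (str(n_h) if n_h != 1 else ""))
            n_h = 0
        elif n_h:
            counts["H"] = counts.get("H", 0) + n_h
            n_h = 0
        for el in sorted(counts):
            c = counts[el]
            parts.append(el + (str(c) if c != 1 else ""))
        return "".join(parts)


@dataclass(frozen=True)
class AnonymousGraph:
    """Pure topology: node count, undirected edge list, canonical hash."""

    num_nodes: int
    edges: tuple[tuple[int, int], ...]
    hash: str

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.num_nodes))
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# Parsing (RDKit-backed)
# ---------------------------------------------------------------------------

_SMILES_TOKEN = re.compile(
    r"Cl|Br|[BCNOPSFI]|[bcnops]|\[[^\]]*\]|[0-9]|%[0-9]{2}"
    r"|[().=#:\-+/\\*~@]"
)
_BRACKET_ELEMENT = re.compile(r"\[(?:[0-9]+)?([A-Z][a-z]?|[a-z]{1,2})")


def _prescan_smiles(text: str) -> None:
    """Lexical scan: reject unknown tokens / elements with a position."""
    pos = 0
    while pos < len(text):
        m = _SMILES_TOKEN.match(text, pos)
        if m is None:
            raise SmilesParseError(text, pos, f"unexpected character {text[pos]!r}")
        tok = m.group(0)
        if tok.startswith("["):
            if not tok.endswith("]"):
                raise SmilesParseError(text, pos, "unclosed bracket atom")
            em = _BRACKET_ELEMENT.match(tok)
            if em is None:
                raise SmilesParseError(text, pos, f"bad bracket atom {tok!r}")
            sym = em.group(1)
            sym_norm = sym.capitalize() if sym.islower() else sym
            if sym_norm not in ALLOWED_ELEMENTS:
                raise UnsupportedElementError(sym_norm, pos)
        pos = m.end()


def _from_rdkit(mol: Chem.Mol, identifier: str = "") -> MolecularGraph:
    """Convert an RDKit molecule (explicit Hs removed) into a MolecularGraph."""
    mol = Chem.RemoveHs(mol)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            raise UnsupportedElementError(atom.GetSymbol())
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=False)
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            implicit_h=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
        )
        for a in kek.GetAtoms()
    ]
    bonds = []
    for b in kek.GetBonds():
        order = int(round(b.GetBondTypeAsDouble()))
        if order not in (1, 2, 3):
            raise ValueError(f"unsupported bond order {b.GetBondType()}")
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, b.GetIsAromatic())
        )
    return MolecularGraph(atoms=atoms, bonds=bonds, identifier=identifier)


def parse_smiles(text: str, identifier: str = "") -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Implicit hydrogens are filled by standard valence; aromaticity is taken
    from rings written in aromatic (lowercase) form; internal bond orders are
    Kekulized.  Stereochemistry is accepted on input but discarded.

    Raises
    ------
    SmilesParseError
        For malformed input, naming the offending position where the lexer
        can locate it.
    UnsupportedElementError
        For elements outside the organic subset (B, C, N, O, P, S, halogens).
    """
    if not text or not text.strip():
        raise SmilesParseError(text, 0, "empty string")
    text = text.strip()
    _prescan_smiles(text)
    mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise SmilesParseError(text, None, "rejected by sanitization/grammar")
    return _from_rdkit(mol, identifier=identifier)


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read a .smi file: one SMILES per line, optional tab-separated id."""
    mols = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            mols.append(parse_smiles(smiles, identifier=ident))
    return mols


def read_sdf(path) -> list[MolecularGraph]:
    """Read a V2000 SDF/MOL file; explicit hydrogens are folded into
    implicit counts.  An empty file yields an empty list (with a warning)."""
    with open(path) as fh:
        if not fh.read().strip():
            logger.warning("SDF file %s contained no records", path)
            return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    mols = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise SdfFormatError(idx, "unreadable or truncated record")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{idx}"
        mols.append(_from_rdkit(mol, identifier=name or f"record{idx}"))
    if not mols:
        logger.warning("SDF file %s contained no records", path)
    return mols


# ---------------------------------------------------------------------------
# Anonymous graphs and canonical hashing
# ---------------------------------------------------------------------------

def _refine(n: int, adj: list[set[int]], colors: list[int]) -> list[int]:
    """WL colour refinement to a stable partition; colours are rank-normalized
    each round so they are comparable across search branches."""
    while True:
        sigs = [
            (colors[v], tuple(sorted(colors[u] for u in adj[v])))
            for v in range(n)
        ]
        rank = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [rank[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _interchangeable(adj: list[set[int]], u: int, v: int) -> bool:
    # twins (adjacent or not) are swapped by an automorphism
    return (adj[u] - {v}) == (adj[v] - {u})


def _canonical_edges(n: int, edges) -> tuple[tuple[int, int], ...]:
    """Canonical edge list via individualization–refinement search.

    The minimum over all discrete leaves of the refinement tree is a true
    canonical form, so two graphs yield equal results iff isomorphic.  Twin
    vertices (identical neighbourhoods) are branched only once, which keeps
    highly symmetric inputs — stars, isolated vertices — tractable.
    """
    if n == 0:
        return ()
    adj: list[set[int]] = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    best: list[tuple[tuple[int, int], ...] | None] = [None]

    def search(colors: list[int]) -> None:
        cells: dict[int, list[int]] = {}
        for v, c in enumerate(colors):
            cells.setdefault(c, []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            # discrete: colors is a permutation of 0..n-1
            lab = colors
            cand = tuple(
                sorted(
                    (min(lab[u], lab[v]), max(lab[u], lab[v]))
                    for u in range(n)
                    for v in adj[u]
                    if u < v
                )
            )
            if best[0] is None or cand < best[0]:
                best[0] = cand
            return
        reps: list[int] = []
        for v in target:
            if any(_interchangeable(adj, v, r) for r in reps):
                continue
            reps.append(v)
        for v in reps:
            nxt = list(colors)
            nxt[v] = n  # fresh maximal colour
            search(_refine(n, adj, nxt))

    search(_refine(n, adj, [0] * n))
    assert best[0] is not None
    return best[0]


def canonical_hash(num_nodes: int, edges) -> str:
    """Deterministic, relabel-invariant hash of an unlabelled graph.

    Equal hashes iff the graphs are isomorphic (exact canonicalization, not
    a WL sketch).  Intended for molecule-sized graphs (≤ ~100 nodes).
    """
    canon = _canonical_edges(num_nodes, list(edges))
    payload = f"{num_nodes}|" + ";".join(f"{u}-{v}" for u, v in canon)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def anonymize(mol: MolecularGraph) -> AnonymousGraph:
    """Drop all atom/bond attributes, keeping topology, and attach the
    canonical hash."""
    edges = tuple(sorted((min(b.i, b.j), max(b.i, b.j)) for b in mol.bonds))
    return AnonymousGraph(
        num_nodes=mol.num_atoms,
        edges=edges,
        hash=canonical_hash(mol.num_atoms, edges),
    )


def write_hashes_tsv(path, mols: list[MolecularGraph]) -> None:
    """Write (id, canonical anonymous-graph hash) rows as TSV."""
    with open(path, "w") as fh:
        fh.write("id\thash\n")
        for m in mols:
            fh.write(f"{m.identifier}\t{anonymize(m).hash}\n")
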