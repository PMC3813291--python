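"""Hierarchical dissection of molecules into ring systems, linkers, side
chains, scaffolds and graph frameworks.

The hierarchy runs: molecule → atom roles (ring / linker / side chain) →
scaffold (the induced subgraph on ring + linker atoms, with atom types and
bond orders retained and "dot pair" π markers where multiple bonds were cut)
→ framework (the scaffold with every attribute discarded, i.e. pure
topology).

Role definitions
----------------
* RING — atoms lying on at least one cycle.  Cycles sharing at least one
  atom (fused or spiro) belong to one *ring system*.
* LINKER — non-ring atoms on the (unique, since non-ring regions are
  acyclic) paths connecting two different ring systems, together with any
  atom attached to such a path atom by a double or triple bond.  Functional
  groups riding on linkers — carbonyl oxygens and the like — are therefore
  kept with the linker rather than stripped as side chains.
* SIDE_CHAIN — every remaining atom.
"""

from __future__ import annotations

import enum
import itertools
import json
import logging
from dataclasses import dataclass

import networkx as nx

from .chem_graph import (
    AnonymousGraph,
    Atom,
    Bond,
    MolecularGraph,
    anonymize,
)

logger = logging.getLogger("fragrank")


class AtomRole(enum.Enum):
    RING = "RING"
    LINKER = "LINKER"
    SIDE_CHAIN = "SIDE_CHAIN"


class EmptyScaffoldError(ValueError):
    """Raised when scaffold extraction is attempted on an acyclic molecule."""


@dataclass(frozen=True)
class RingSystem:
    """A maximal set of cycles pairwise connected through shared atoms."""

    atoms: frozenset[int]
    ring_count: int


@dataclass
class DissectionResult:
    roles: list[AtomRole]
    ring_systems: list[RingSystem]
    scaffold: MolecularGraph
    framework: AnonymousGraph
    side_chain_fragments: list[MolecularGraph]
    linker_fragments: list[MolecularGraph]


def _ring_edges(mol: MolecularGraph) -> set[tuple[int, int]]:
    """Edges on at least one cycle = non-bridge edges."""
    g = mol.to_networkx()
    bridges = {frozenset(e) for e in nx.bridges(g)}
    return {
        (min(b.i, b.j), max(b.i, b.j))
        for b in mol.bonds
        if frozenset((b.i, b.j)) not in bridges
    }


def perceive_ring_systems(mol: MolecularGraph) -> list[RingSystem]:
    """Partition the cyclic part of a molecule into ring systems.

    Two cycles sharing one atom or more (fused, bridged or spiro) merge into
    a single system.  Acyclic molecules yield an empty list.  The ring count
    of a system is its cyclomatic number.
    """
    redges = _ring_edges(mol)
    sub = nx.Graph()
    sub.add_edges_from(redges)
    systems = []
    for comp in nx.connected_components(sub):
        n_edges = sum(1 for (u, v) in redges if u in comp and v in comp)
        systems.append(
            RingSystem(atoms=frozenset(comp), ring_count=n_edges - len(comp) + 1)
        )
    systems.sort(key=lambda s: min(s.atoms))
    return systems


def classify_atoms(
    mol: MolecularGraph, systems: list[RingSystem] | None = None
) -> list[AtomRole]:
    """Assign every atom exactly one role (RING, LINKER, SIDE_CHAIN).

    Non-ring atoms form trees hanging off the ring systems; within a tree
    that touches two or more distinct ring systems, the unique paths between
    its attachment points are linker paths.  Atoms double- or triple-bonded
    to a linker-path atom are linkers too (functional groups are retained);
    singly-bonded branches off a linker are side chains.
    """
    if systems is None:
        systems = perceive_ring_systems(mol)
    n = mol.num_atoms
    sys_of: dict[int, int] = {}
    for si, s in enumerate(systems):
        for a in s.atoms:
            sys_of[a] = si
    roles = [
        AtomRole.RING if i in sys_of else AtomRole.SIDE_CHAIN for i in range(n)
    ]
    if len(systems) >= 2:
        g = mol.to_networkx()
        nonring = g.subgraph([v for v in g if v not in sys_of])
        for comp in nx.connected_components(nonring):
            # attachment points: component atoms adjacent to a ring system
            attach: list[tuple[int, int]] = []
            for v in comp:
                for u in g.neighbors(v):
                    if u in sys_of:
                        attach.append((v, sys_of[u]))
            touched = {si for (_, si) in attach}
            if len(touched) < 2:
                continue
            core: set[int] = set()
            tree = nonring.subgraph(comp)
            for (a, sa), (b, sb) in itertools.combinations(attach, 2):
                if sa == sb:
                    continue
                core.update(nx.shortest_path(tree, a, b))
            for v in core:
                roles[v] = AtomRole.LINKER
            # retained functional groups: multiple bonds off the path
            for b in mol.bonds:
                if b.order >= 2:
                    for v, u in ((b.i, b.j), (b.j, b.i)):
                        if v in core and roles[u] == AtomRole.SIDE_CHAIN:
                            roles[u] = AtomRole.LINKER
    return roles


def _induced_fragment(
    mol: MolecularGraph, keep: list[int], identifier: str
) -> MolecularGraph:
    """Induced subgraph on ``keep``; hydrogens and π markers are adjusted at
    cut bonds so that valence stays consistent: a cut single bond becomes an
    implicit hydrogen, a cut double (triple) bond becomes one hydrogen plus
    one (two) dot-pair markers on the kept atom."""
    keep_set = set(keep)
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [
        Atom(
            element=mol.atoms[i].element,
            formal_charge=mol.atoms[i].formal_charge,
            implicit_h=mol.atoms[i].implicit_h,
            pi_marker=mol.atoms[i].pi_marker,
            aromatic=mol.atoms[i].aromatic,
        )
        for i in keep
    ]
    bonds = []
    for b in mol.bonds:
        ins_i, ins_j = b.i in keep_set, b.j in keep_set
        if ins_i and ins_j:
            bonds.append(Bond(remap[b.i], remap[b.j], b.order, b.aromatic))
        elif ins_i or ins_j:
            kept = remap[b.i] if ins_i else remap[b.j]
            atoms[kept].implicit_h += 1
            if b.order >= 2:
                atoms[kept].pi_marker += b.order - 1
                if b.order == 3:
                    logger.warning(
                        "%s: triple-bond cut at atom %d; pi marker set to 2",
                        mol.identifier, keep[kept],
                    )
    return MolecularGraph(atoms=atoms, bonds=bonds, identifier=identifier)


def extract_scaffold(
    mol: MolecularGraph, roles: list[AtomRole] | None = None
) -> MolecularGraph:
    """Simplified structure: the induced subgraph on ring + linker atoms.

    Atom types, charges and bond orders are retained.  For every removed
    side-chain atom that was multiply bonded to a kept atom, the kept atom
    gains a π "dot pair" marker preserving its sp² (sp) character; implicit
    hydrogens are adjusted so valence stays consistent.
    """
    if roles is None:
        roles = classify_atoms(mol)
    keep = [i for i, r in enumerate(roles) if r is not AtomRole.SIDE_CHAIN]
    if not keep:
        raise EmptyScaffoldError(
            f"{mol.identifier or 'molecule'}: acyclic input has no scaffold"
        )
    return _induced_fragment(mol, keep, identifier=f"{mol.identifier}|scaffold")


def extract_framework(scaffold: MolecularGraph) -> AnonymousGraph:
    """Graph framework: the scaffold with atom types, hybridizations,
    charges and bond orders all discarded; canonical hash attached."""
    if scaffold.num_atoms == 0:
        raise EmptyScaffoldError("cannot take the framework of an empty scaffold")
    return anonymize(scaffold)


def _role_fragments(
    mol: MolecularGraph, roles: list[AtomRole], role: AtomRole, tag: str
) -> list[MolecularGraph]:
    g = mol.to_networkx()
    sub = g.subgraph([i for i, r in enumerate(roles) if r is role])
    frags = []
    for k, comp in enumerate(sorted(nx.connected_components(sub), key=min)):
        frags.append(
            _induced_fragment(mol, sorted(comp), f"{mol.identifier}|{tag}{k}")
        )
    return frags


def dissect(mol: MolecularGraph) -> DissectionResult:
    """Full hierarchical dissection of one molecule."""
    systems = perceive_ring_systems(mol)
    if not systems:
        raise EmptyScaffoldError(
            f"{mol.identifier or 'molecule'}: no ring system found"
        )
    roles = classify_atoms(mol, systems)
    scaffold = extract_scaffold(mol, roles)
    return DissectionResult(
        roles=roles,
        ring_systems=systems,
        scaffold=scaffold,
        framework=extract_framework(scaffold),
        side_chain_fragments=_role_fragments(mol, roles, AtomRole.SIDE_CHAIN, "sc"),
        linker_fragments=_role_fragments(mol, roles, AtomRole.LINKER, "lk"),
    )


def group_by_framework(mols: list[MolecularGraph]) -> dict[str, list[str]]:
    """Partition molecules by the canonical hash of their graph framework.

    Groups are ordered by descending member count, then lexicographic hash;
    members keep input order.
    """
    groups: dict[str, list[str]] = {}
    for mol in mols:
        h = dissect(mol).framework.hash
        groups.setdefault(h, []).append(mol.identifier)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return dict(ordered)


def dissection_to_dict(mol: MolecularGraph, result: DissectionResult) -> dict:
    """JSON-serializable report for one molecule's dissection."""
    return {
        "id": mol.identifier,
        "roles": [r.value for r in result.roles],
        "ring_systems": [sorted(s.atoms) for s in result.ring_systems],
        "scaffold_formula": result.scaffold.molecular_formula(),
        "scaffold_atoms": result.scaffold.num_atoms,
        "pi_markers": sum(a.pi_marker for a in result.scaffold.atoms),
        "framework_hash": result.framework.hash,
        "n_side_chains": len(result.side_chain_fragments),
        "n_linkers": len(result.linker_fragments),
    }


def write_dissection_json(path, mols: list[MolecularGraph]) -> None:
    records = [dissection_to_dict(m, dissect(m)) for m in mols]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def write_frameworks_tsv(path, mols: list[MolecularGraph]) -> None:
    groups = group_by_framework(mols)
    with open(path, "w") as fh:
        fh.write("hash\tcount\tmembers\n")
        for h, members in groups.items():
            fh.write(f"{h}\t{len(members)}\t{','.join(members)}\n")
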