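"""Molecular descriptors: heavy atom count, molecular weight, hydrogen-bond
donors/acceptors, rotatable bonds, and the rotatable-bond selection filter.

Definitions used here (documented, deterministic):

* HAC — number of non-hydrogen atoms.  π "dot pair" markers on scaffold
  atoms are electrons, not atoms, and are never counted.
* MW — sum of average atomic masses (IUPAC 2021, rounded to 3 decimals)
  including implicit hydrogens, in daltons.
* HBD — number of hydrogens borne by nitrogen or oxygen.
* HBA — number of N and O atoms, excluding positively charged atoms and
  pyrrole-type nitrogens (an aromatic N–H in a five-membered ring, whose
  lone pair is part of the π system).
* RotB — non-ring single bonds between two non-terminal heavy atoms,
  excluding amide C–N bonds (the usual convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .chem_graph import MolecularGraph

#: Average atomic masses in Da (IUPAC 2021, 3 decimals).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "B": 10.811,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.065,
    "Cl": 35.453,
    "Br": 79.904,
    "I": 126.904,
}


class UnknownMassError(ValueError):
    def __init__(self, element: str):
        self.element = element
        super().__init__(f"no average mass tabulated for element {element!r}")


@dataclass(frozen=True)
class DescriptorSet:
    """The descriptor panel used for fragment selection and ranking."""

    hac: int
    mw: float
    hbd: int
    hba: int
    rotb: int


def heavy_atom_count(mol: MolecularGraph) -> int:
    return mol.num_atoms


def molecular_weight(mol: MolecularGraph) -> float:
    """Average molecular weight in daltons, implicit hydrogens included."""
    total = 0.0
    for a in mol.atoms:
        if a.element not in ATOMIC_MASS:
            raise UnknownMassError(a.element)
        total += ATOMIC_MASS[a.element] + a.implicit_h * ATOMIC_MASS["H"]
    return round(total, 2)


def hbd_count(mol: MolecularGraph) -> int:
    return sum(a.implicit_h for a in mol.atoms if a.element in ("N", "O"))


def _atoms_in_5rings(mol: MolecularGraph) -> set[int]:
    g = mol.to_networkx()
    out: set[int] = set()
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) == 5:
            out.update(cycle)
    return out


def hba_count(mol: MolecularGraph) -> int:
    five_ring = _atoms_in_5rings(mol)
    n = 0
    for i, a in enumerate(mol.atoms):
        if a.element not in ("N", "O") or a.formal_charge > 0:
            continue
        pyrrole_type = (
            a.element == "N" and a.aromatic and a.implicit_h >= 1 and i in five_ring
        )
        if not pyrrole_type:
            n += 1
    return n


def _is_amide_cn(mol: MolecularGraph, i: int, j: int) -> bool:
    for c, nitro in ((i, j), (j, i)):
        if mol.atoms[c].element == "C" and mol.atoms[nitro].element == "N":
            for b in mol.bonds:
                if b.order == 2 and c in (b.i, b.j):
                    other = b.j if b.i == c else b.i
                    if mol.atoms[other].element == "O":
                        return True
    return False


def rotatable_bond_count(mol: MolecularGraph) -> int:
    g = mol.to_networkx()
    bridges = {frozenset(e) for e in nx.bridges(g)}
    degree = dict(g.degree())
    n = 0
    for b in mol.bonds:
        if b.order != 1 or b.aromatic:
            continue
        if frozenset((b.i, b.j)) not in bridges:
            continue  # ring bond
        if degree[b.i] < 2 or degree[b.j] < 2:
            continue  # terminal atom
        if _is_amide_cn(mol, b.i, b.j):
            continue
        n += 1
    return n


def compute_descriptors(mol: MolecularGraph) -> DescriptorSet:
    return DescriptorSet(
        hac=heavy_atom_count(mol),
        mw=molecular_weight(mol),
        hbd=hbd_count(mol),
        hba=hba_count(mol),
        rotb=rotatable_bond_count(mol),
    )


def filter_by_rotb(
    mols: list[MolecularGraph], threshold: int = 10
) -> tuple[list[MolecularGraph], list[MolecularGraph]]:
    """Keep molecules with at most ``threshold`` rotatable bonds.

    The default of 10 is the fragment-selection gate applied after
    dissection into simplified structures ("10 or less rotatable bonds").
    """
    kept, discarded = [], []
    for m in mols:
        (kept if rotatable_bond_count(m) <= threshold else discarded).append(m)
    return kept, discarded


def write_descriptors_tsv(path, mols: list[MolecularGraph]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tHAC\tMW\tHBD\tHBA\tRotB\n")
        for m in mols:
            d = compute_descriptors(m)
            fh.write(
                f"{m.identifier}\t{d.hac}\t{d.mw:.1f}\t{d.hbd}\t{d.hba}\t{d.rotb}\n"
            )
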