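"""Synthetic molecule libraries with known ground truth, plus packaged
reference tables.

The generator runs the dissection hierarchy in reverse: it assembles
molecules from ring-system, linker and side-chain templates, recording the
role of every atom and the template each came from.  Binding free energies
are simulated from an additive per-template contribution model with
Gaussian noise, so both the atom-role classifier and the efficiency
pipeline can be validated against construction bookkeeping.

The default template set echoes the scaffold families of the reference
inhibitor collection (aryl rings, fused bicycles, pyrimidinone, piperazine;
methylene and amide linkers; small polar side chains).  What the generator
does *not* emulate: 3D geometry, realistic docking-pose energetics,
stereochemistry, tautomers.

Packaged fixtures carry the reference descriptor table (83 entries,
ligand/fragment HAC, HBD, HBA, MW) and the three-ligand isophthalamide
comparison table (experimental IC50, docked BE, printed LE/BEI); the one
internally inconsistent LE cell is flagged as an erratum.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import logging
import random
from dataclasses import dataclass, field

import pandas as pd

from .chem_graph import Atom, Bond, MolecularGraph, parse_smiles
from .dissection import AtomRole
from .efficiency import BindingRecord

logger = logging.getLogger("fragrank")

_FIXTURE_SHA256 = {
    "reference_descriptors.tsv": "c427df63eb9a93f01f522fa41eff0ea9d6a3dc38bfbc51e3dd679ee1241e72dd",
    "reference_binding.tsv": "bfe069f3696c9742d738e8105f7ded4d83ca458945160aa7059eba7ccc7472b3",
}


@dataclass(frozen=True)
class Template:
    """One building block: a parsed graph, attachment atom indices, and its
    additive binding-energy contribution in kcal/mol."""

    name: str
    smiles: str
    energy: float
    attach: tuple[int, ...] = ()  # preferred attachment atoms (linkers: ends)

    def graph(self) -> MolecularGraph:
        return parse_smiles(self.smiles, identifier=self.name)


@dataclass
class TemplateSpec:
    """Building blocks and assembly rules for the generator."""

    ring_templates: list[Template]
    linker_templates: list[Template]
    side_chain_templates: list[Template]
    max_rings: int = 3
    max_side_chains: int = 4
    p_linker: float = 0.7  # chance a ring junction goes through a linker

    def __post_init__(self) -> None:
        from .dissection import perceive_ring_systems

        if not self.ring_templates:
            raise ValueError("need at least one ring template")
        for t in self.ring_templates:
            if not perceive_ring_systems(t.graph()):
                raise ValueError(f"ring template {t.name} has no cycle")
        for t in self.side_chain_templates:
            if perceive_ring_systems(t.graph()):
                raise ValueError(f"side-chain template {t.name} is cyclic")


def default_template_spec() -> TemplateSpec:
    """Rings, linkers and side chains echoing the families seen in the
    reference inhibitor set; energies are per-template contributions."""
    return TemplateSpec(
        ring_templates=[
            Template("benzene", "c1ccccc1", -1.8),
            Template("pyridine", "c1ccncc1", -2.0),
            Template("quinoline", "c1ccc2ncccc2c1", -2.9),
            Template("pyrimidinone", "O=c1cc[nH]cn1", -2.5),
            Template("piperazine", "C1CNCCN1", -1.6),
        ],
        linker_templates=[
            Template("methylene", "C", -0.4, attach=(0, 0)),
            Template("acetamide", "CC(N)=O", -0.9, attach=(0, 2)),
        ],
        side_chain_templates=[
            Template("methyl", "C", -0.3),
            Template("hydroxyl", "O", -0.5),
            Template("amino", "N", -0.4),
            Template("glycolamide_ether", "OCC(N)=O", -0.7),
        ],
    )


@dataclass
class GroundTruth:
    """Per-molecule assembly bookkeeping."""

    roles: dict[str, list[AtomRole]] = field(default_factory=dict)
    templates: dict[str, list[str]] = field(default_factory=dict)
    energies: dict[str, list[float]] = field(default_factory=dict)

    def true_delta_g(self, mol_id: str) -> float:
        return sum(self.energies[mol_id])


def _attachable(mol: MolecularGraph, atoms: list[int]) -> list[int]:
    return [i for i in atoms if mol.atoms[i].implicit_h >= 1]


def _merge(
    dest: MolecularGraph, src: MolecularGraph
) -> tuple[MolecularGraph, int]:
    """Disjoint union; returns the merged graph and the index offset of
    ``src`` atoms."""
    offset = dest.num_atoms
    atoms = [*(a for a in dest.copy().atoms), *(a for a in src.copy().atoms)]
    bonds = [Bond(b.i, b.j, b.order, b.aromatic) for b in dest.bonds]
    bonds += [Bond(b.i + offset, b.j + offset, b.order, b.aromatic)
              for b in src.bonds]
    return MolecularGraph(atoms=atoms, bonds=bonds,
                          identifier=dest.identifier), offset


def _bond_consuming_h(mol: MolecularGraph, i: int, j: int) -> None:
    for idx in (i, j):
        if mol.atoms[idx].implicit_h < 1:
            raise ValueError(
                f"atom {idx} ({mol.atoms[idx].element}) has no free valence"
            )
        mol.atoms[idx].implicit_h -= 1
    mol.bonds.append(Bond(i, j, 1, False))


def _ring_template_roles(g: MolecularGraph) -> list[AtomRole]:
    """True roles of a ring template's atoms: cycle members are RING, any
    exocyclic appendage (e.g. a ring C=O oxygen) is SIDE_CHAIN."""
    from .dissection import perceive_ring_systems

    in_ring: set[int] = set()
    for s in perceive_ring_systems(g):
        in_ring.update(s.atoms)
    return [
        AtomRole.RING if i in in_ring else AtomRole.SIDE_CHAIN
        for i in range(g.num_atoms)
    ]


def _assemble_one(
    spec: TemplateSpec, rng: random.Random, mol_id: str
) -> tuple[MolecularGraph, list[AtomRole], list[str], list[float]]:
    names: list[str] = []
    energies: list[float] = []
    n_rings = rng.randint(1, spec.max_rings)

    first = rng.choice(spec.ring_templates)
    mol = first.graph()
    mol.identifier = mol_id
    roles: list[AtomRole] = _ring_template_roles(mol)
    ring_atom_lists: list[list[int]] = [
        [i for i, r in enumerate(roles) if r is AtomRole.RING]
    ]
    names.append(first.name)
    energies.append(first.energy)

    for _ in range(n_rings - 1):
        ring_t = rng.choice(spec.ring_templates)
        prev_atoms = _attachable(mol, ring_atom_lists[-1])
        if not prev_atoms:
            break
        anchor = rng.choice(prev_atoms)
        if rng.random() < spec.p_linker:
            link_t = rng.choice(spec.linker_templates)
            lg = link_t.graph()
            mol, off = _merge(mol, lg)
            roles += [AtomRole.LINKER] * lg.num_atoms
            a_in, a_out = link_t.attach
            _bond_consuming_h(mol, anchor, a_in + off)
            junction = a_out + off
            names.append(link_t.name)
            energies.append(link_t.energy)
        else:
            junction = anchor
        rg = ring_t.graph()
        rg_roles = _ring_template_roles(rg)
        mol, off = _merge(mol, rg)
        roles += rg_roles
        new_ring_atoms = [
            off + k for k, r in enumerate(rg_roles) if r is AtomRole.RING
        ]
        target = rng.choice(_attachable(mol, new_ring_atoms))
        _bond_consuming_h(mol, junction, target)
        ring_atom_lists.append(new_ring_atoms)
        names.append(ring_t.name)
        energies.append(ring_t.energy)

    n_side = rng.randint(0, spec.max_side_chains)
    scaffold_atoms = [i for i, r in enumerate(roles) if r is AtomRole.RING]
    for _ in range(n_side):
        side_t = rng.choice(spec.side_chain_templates)
        sites = _attachable(mol, scaffold_atoms)
        if not sites:
            break
        site = rng.choice(sites)
        sg = side_t.graph()
        mol, off = _merge(mol, sg)
        roles += [AtomRole.SIDE_CHAIN] * sg.num_atoms
        _bond_consuming_h(mol, site, off)
        names.append(side_t.name)
        energies.append(side_t.energy)
    return mol, roles, names, energies


def generate_library(
    spec: TemplateSpec | None = None, n: int = 100, seed: int = 0
) -> tuple[list[MolecularGraph], GroundTruth]:
    """Assemble ``n`` molecules from templates, fully reproducibly.

    Each molecule carries 1–3 ring systems, optional linkers between them
    and 0–4 side chains; every atom's role and source template is recorded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or default_template_spec()
    rng = random.Random(seed)
    mols: list[MolecularGraph] = []
    gt = GroundTruth()
    for k in range(n):
        mol_id = f"synth{k:04d}"
        mol, roles, names, energies = _assemble_one(spec, rng, mol_id)
        mols.append(mol)
        gt.roles[mol_id] = roles
        gt.templates[mol_id] = names
        gt.energies[mol_id] = energies
    return mols, gt


def simulate_binding(
    gt: GroundTruth, noise_sd: float = 0.25, seed: int = 0
) -> list[BindingRecord]:
    """Additive per-template energies plus Gaussian noise; ΔG clamped
    below zero (a docked pose never reports an unfavourable energy here)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = random.Random(seed)
    records = []
    for mol_id in gt.energies:
        dg = gt.true_delta_g(mol_id)
        if noise_sd > 0:
            dg += rng.gauss(0.0, noise_sd)
        records.append(
            BindingRecord(id=mol_id, delta_g=min(dg, -0.01), source="simulated")
        )
    return records


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

class FixtureChecksumError(RuntimeError):
    pass


def _load_fixture(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("fragrank.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureChecksumError(
            f"{name}: checksum {digest} != expected {_FIXTURE_SHA256[name]}"
        )
    import io

    return pd.read_csv(io.BytesIO(raw), sep="\t")


def load_reference_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the packaged reference tables.

    Returns ``(descriptors, binding)``: the 83-entry ligand/fragment
    descriptor table and the isophthalamide comparison table (IC50s as
    printed, including one range; ``le_erratum`` marks the LE cell that is
    inconsistent with its own BE/HAC).  Internal inconsistencies in the
    printed source (e.g. a fragment MW exceeding its ligand MW) are logged
    as warnings, never fatal.
    """
    desc = _load_fixture("reference_descriptors.tsv")
    binding = _load_fixture("reference_binding.tsv")
    if len(desc) != 83:
        raise FixtureChecksumError(f"descriptor table has {len(desc)} rows, not 83")
    bad = desc[desc.mw_fragment > desc.mw_ligand]
    for pdb in bad.pdb:
        logger.warning(
            "descriptor table: %s fragment MW exceeds ligand MW (as printed)", pdb
        )
    return desc, binding


def parse_ic50(text: str) -> float | tuple[float, float]:
    """Parse an IC50 cell: a number, or a printed range like ``15-80``."""
    text = str(text).strip()
    if "-" in text[1:]:
        lo, hi = text.split("-", 1)
        return (float(lo), float(hi))
    return float(text)


def write_library(mols, gt: GroundTruth, smi_path, truth_path, energies_path,
                  noise_sd: float = 0.25, seed: int = 0) -> None:
    """Persist a generated library: SMILES-free atom-table serialization is
    out of scope, so molecules are written as id + formula + framework-ready
    edge list alongside the ground truth JSON and simulated energies TSV."""
    import json

    with open(smi_path, "w") as fh:
        for m in mols:
            edges = ";".join(f"{b.i}-{b.j}:{b.order}" for b in m.bonds)
            atoms = ",".join(
                f"{a.element}{'+' if a.formal_charge > 0 else ''}"
                f"{'h' + str(a.implicit_h) if a.implicit_h else ''}"
                for a in m.atoms
            )
            fh.write(f"{m.identifier}\t{m.molecular_formula()}\t{atoms}\t{edges}\n")
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "roles": {k: [r.value for r in v] for k, v in gt.roles.items()},
                "templates": gt.templates,
                "energies": gt.energies,
            },
            fh,
            indent=1,
        )
    records = simulate_binding(gt, noise_sd=noise_sd, seed=seed)
    with open(energies_path, "w") as fh:
        fh.write("id\tdelta_g_kcal_mol\n")
        for r in records:
            fh.write(f"{r.id}\t{r.delta_g:.4f}\n")
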