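# Methods

## Dissection model

A molecule is an attributed graph over heavy atoms; hydrogens are implicit
counts filled by standard valence at parse time (RDKit performs SMILES/SDF
parsing and sanitization; aromatic rings are Kekulized internally so every
bond carries a definite order of 1, 2 or 3, with the aromatic flag kept for
descriptor logic). Stereochemistry is accepted on input and ignored
throughout — all comparisons here are constitutional.

**Ring systems.** An atom is a ring atom iff it lies on a cycle, detected as
an endpoint of a non-bridge edge. Ring systems are connected components of
the subgraph of ring atoms and ring bonds; consequently cycles sharing one
atom (spiro) or more (fused/bridged) merge into one system. The per-system
ring count is the cyclomatic number.

**Roles.** Removing ring atoms leaves a forest, so between any two
attachment points of a non-ring tree the connecting path is unique. Atoms on
a path between attachments of two *different* ring systems are linkers;
atoms double- or triple-bonded to a linker-path atom are linkers as well
(carbonyls and similar functional groups are deliberately kept with the
linker — no elimination of functional groups), one bond deep. Everything
else that is not a ring atom is a side chain, including branches hanging off
linkers by single bonds and exocyclic double-bonded atoms on rings (e.g. a
ring C=O oxygen): the retention rule is defined for linkers only.

**Scaffold and dot pairs.** The scaffold is the induced subgraph on ring ∪
linker atoms. Cutting a single bond to a removed side-chain atom adds one
implicit hydrogen to the kept atom; cutting a double (triple) bond adds one
hydrogen plus a π marker of 1 (2) — the "dot pair" recording the π electrons
so the sp² (sp) character of the kept atom is not lost. Markers are integer
atom attributes, not phantom atoms, so HAC and MW of a scaffold are
unaffected by them. With this accounting, σ-valence plus markers always
reproduces standard valence. A triple-bond cut is additionally logged, as no
reference case exercises it.

**Framework and canonical hashing.** The framework drops every attribute of
the scaffold, keeping pure topology. Hashes come from a true canonical form:
Weisfeiler–Lehman colour refinement followed by individualization–refinement
search over non-singleton colour cells, taking the lexicographically
smallest relabelled edge list over all discrete leaves; twin vertices
(identical neighbourhoods) are branched only once, since swapping them is an
automorphism. Unlike a plain WL sketch, equal hashes therefore hold iff the
graphs are isomorphic; the test suite verifies this against networkx VF2 on
thousands of random-graph pairs, including regular counterexamples to WL
(e.g. the Petersen graph). The search is exponential in the worst case but
molecule-sized inputs (≤ ~100 nodes, bounded degree) resolve in
milliseconds.

## Descriptors

HAC counts non-hydrogen atoms. MW sums average atomic masses (IUPAC 2021,
three decimals: C 12.011, H 1.008, N 14.007, O 15.999, S 32.065 …) including
implicit hydrogens; reported to 0.1 Da in tables. The reference tables were
produced with a proprietary descriptor package that defines no HBD/HBA
convention, so explicit rules are adopted: HBD = hydrogens on N or O;
HBA = N/O atoms that are not positively charged and not pyrrole-type
(aromatic N–H in a five-membered ring, whose lone pair is in the π system).
Rotatable bonds are non-ring single bonds between two non-terminal heavy
atoms, excluding amide C–N — the common convention; the ≤10 gate it feeds is
coarse enough to be insensitive to the convention at fragment scale.
Reference HBD/HBA cells are used as test fixtures only where the fragment
identity is unambiguous; several printed cells are internally questionable
(one fragment MW even exceeds its parent ligand's) and are logged as
warnings on load, never treated as fatal.

## Efficiency indices

pKi = −ΔG/(ln 10·R·T). R is taken as 1.987 cal·mol⁻¹·K⁻¹ and T = 298.15 K,
giving the conversion factor c = 1.3641 kcal/mol; this choice of rounding is
deliberate, because back-solving c from the three reference (BE, BEI, MW)
triples brackets it in (1.3638, 1.3641] — the bundled tables were evidently
computed with c ≈ 1.364, and the slightly finer R = 1.9872 would shift one
BEI off its printed value at two decimals. LE = −ΔG/HAC; BEI = pKi/MW(kDa).
One printed reference LE (0.423 computed vs 0.377 printed for the
3L58-derived fragment) cannot be reproduced from its own BE and HAC; the
fixture marks the cell as an erratum and the package always reports the
computed value.

Normalization is min–max to [0, 1] per series. Binding energies are
normalized on |ΔG| so that stronger binding maps to 1 in all three series
(the alternative — preserving sign — merely flips the BE curve; the
magnitude convention makes the curves comparable). A constant series is a
degenerate-range error rather than silently all-zero. ΔE = BEI_norm −
LE_norm is largest in magnitude for fragments whose per-heavy-atom mass
deviates most from the C/N/O norm, e.g. two-sulfur fragments.

Experimental IC50s are used for rank comparison only, never converted to
pKi (no Cheng–Prusoff inputs are available). An IC50 printed as a range is
an interval: it outranks a point value only when the bounds are decisive,
otherwise midpoints decide and the order is flagged approximate. The LE tie
tolerance defaults to 0.005, the resolution at which two reference LEs are
printed as equivalent.

## Synthetic data

The generator assembles molecules from templates: ring systems (benzene,
pyridine, a fused quinoline-type bicycle, pyrimidinone, piperazine), linkers
(methylene; an amide-bearing chain) and acyclic side chains (methyl,
hydroxyl, amino, a glycolamide ether standing in for longer polar chains) —
echoing the scaffold families of the reference inhibitor set. Each molecule
draws 1–3 rings joined through linkers (probability 0.7) or direct bonds,
plus 0–4 side chains on ring atoms; attachments consume implicit hydrogens,
so valence stays consistent by construction. Roles and source templates are
recorded per atom at assembly; since assembly and classification implement
the same role semantics from opposite directions, exact round-trip recovery
is the core end-to-end test of the dissection code. Binding energies are
additive per-template contributions (−0.3 to −2.9 kcal/mol) plus Gaussian
noise (default SD 0.25 kcal/mol, a realistic per-pose docking jitter),
clamped below zero. The generator emulates 2D constitution and an additive
energy model only — no geometry, poses, stereochemistry or non-additive
interactions — so passing tests demonstrate algorithmic correctness, not
docking realism. All randomness flows through explicit seeds; there is no
global random state.

Default problem sizes in the test suite — 200 molecules × 3 seeds for role
recovery, n = 500 at noise 0.25 for ordinary-least-squares recovery of the
template energies (within 3 standard errors), 1,000 random ≤12-node graphs
for hash/oracle agreement — are chosen so the whole suite runs in seconds
while keeping the statistical checks well-powered.

## Pipeline

Two entry modes: *structure mode* (molecules in, full dissection, scaffold
descriptors, rotatable-bond filter, scoring) and *table mode* (descriptor +
binding tables in, scoring only), because printed studies often ship tables
without machine-readable structures. Stage counts are conserved (parsed =
kept + discarded; each kept id scored once); any stage failure aborts with
the stage name. Data inconsistencies in reference fixtures are WARNING-level
log events, never fatal. Outputs are TSV/JSON plus a run log.

## Known limitations

- Aromaticity is taken from the input notation (rings written lowercase);
  no independent aromaticity perception model.
- The framework canonicalization has no worst-case polynomial bound; it is
  intended for molecule-scale graphs, not adversarial regular graphs at
  large n.
- Isostere pairing applies exactly one tabulated swap; multi-site isosterism
  and steric/electronic scoring of the swap are out of scope.
- HBD/HBA follow the documented rules above; other conventions (e.g.
  counting donor *atoms* rather than hydrogens) will differ on polyprotic
  groups.
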