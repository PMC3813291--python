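"""Structured comparisons between molecules and their scores: priority
orders, constitutional-isomer grouping, isostere pairing, and side-chain
effect reports.

Scores may be plain numbers or ``(lo, hi)`` intervals (an IC50 reported as a
range).  An interval beats a point value outright only when its upper bound
lies below it (for smaller-is-better metrics); otherwise midpoints decide
and the order is flagged approximate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .chem_graph import MolecularGraph

Score = float | tuple[float, float]


def _interval(v: Score) -> tuple[float, float]:
    if isinstance(v, tuple):
        lo, hi = v
        return (min(lo, hi), max(lo, hi))
    return (v, v)


def _midpoint(v: Score) -> float:
    lo, hi = _interval(v)
    return (lo + hi) / 2.0


@dataclass
class PriorityOrder:
    """A ranking of ids by one metric, best first."""

    metric: str
    ordered: list[tuple[str, float]]  # (id, effective score), best first
    tie_groups: list[list[str]]
    approximate: bool = False

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.ordered]

    def as_string(self) -> str:
        """E.g. ``"2P83>1W51≈3L58"``."""
        parts = [self.ordered[0][0]]
        tied = {
            frozenset((g[k], g[k + 1]))
            for g in self.tie_groups
            for k in range(len(g) - 1)
        }
        for prev, cur in zip(self.ids, self.ids[1:]):
            sep = "≈" if any({prev, cur} <= t or frozenset((prev, cur)) == t
                             for t in tied) else ">"
            parts.append(sep + cur)
        return "".join(parts)


def priority_order(
    scores: dict[str, Score],
    larger_is_better: bool = True,
    tolerance: float = 0.0,
    metric: str = "score",
) -> PriorityOrder:
    """Stable sort of ids by score, best first, with tie groups.

    Ids whose effective scores differ by less than ``tolerance`` are chained
    into a tie group and joined with "≈" in the rendered order.  Interval
    scores are ranked by midpoint; if any interval comparison is not
    decisive (the intervals overlap), the order is flagged approximate.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 ids to rank")
    ids = list(scores)
    eff = {i: _midpoint(scores[i]) for i in ids}
    sign = -1.0 if larger_is_better else 1.0
    # stable sort on effective score (sign folds in the direction)
    ordered_ids = sorted(ids, key=lambda i: sign * eff[i])
    approximate = False
    for a, b in itertools.combinations(ids, 2):
        ia, ib = _interval(scores[a]), _interval(scores[b])
        if (ia[0] != ia[1] or ib[0] != ib[1]) and ia[0] <= ib[1] and ib[0] <= ia[1]:
            approximate = True  # overlapping intervals: midpoints decided
    tie_groups: list[list[str]] = []
    current = [ordered_ids[0]]
    for prev, cur in zip(ordered_ids, ordered_ids[1:]):
        if abs(eff[cur] - eff[prev]) < tolerance:
            current.append(cur)
        else:
            if len(current) > 1:
                tie_groups.append(current)
            current = [cur]
    if len(current) > 1:
        tie_groups.append(current)
    return PriorityOrder(
        metric=metric,
        ordered=[(i, eff[i]) for i in ordered_ids],
        tie_groups=tie_groups,
        approximate=approximate,
    )


# ---------------------------------------------------------------------------
# Structure-level comparisons
# ---------------------------------------------------------------------------

def _node_match(a, b) -> bool:
    return a["element"] == b["element"] and a["charge"] == b["charge"]


def _edge_match(a, b) -> bool:
    if a["aromatic"] or b["aromatic"]:
        return a["aromatic"] == b["aromatic"]
    return a["order"] == b["order"]


def attributed_isomorphic(m1: MolecularGraph, m2: MolecularGraph) -> bool:
    """Graph isomorphism respecting element, charge and bond order
    (aromatic bonds match aromatic bonds regardless of Kekulé order)."""
    return nx.is_isomorphic(
        m1.to_networkx(), m2.to_networkx(),
        node_match=_node_match, edge_match=_edge_match,
    )


def detect_constitutional_isomers(
    mols: list[MolecularGraph],
) -> tuple[list[list[str]], list[tuple[str, str]]]:
    """Group constitutional isomers: same molecular formula, different
    connectivity.

    Returns ``(groups, duplicates)``: each group lists one representative id
    per distinct connectivity sharing a formula (only formulas with at least
    two connectivities form a group); ``duplicates`` lists id pairs that are
    outright isomorphic and therefore not isomers of each other.
    """
    by_formula: dict[str, list[MolecularGraph]] = {}
    for m in mols:
        by_formula.setdefault(m.molecular_formula(), []).append(m)
    groups: list[list[str]] = []
    duplicates: list[tuple[str, str]] = []
    for formula in sorted(by_formula):
        members = by_formula[formula]
        classes: list[list[MolecularGraph]] = []
        for m in members:
            for cls in classes:
                if attributed_isomorphic(m, cls[0]):
                    cls.append(m)
                    duplicates.append((cls[0].identifier, m.identifier))
                    break
            else:
                classes.append([m])
        if len(classes) >= 2:
            groups.append([cls[0].identifier for cls in classes])
    return groups, duplicates


@dataclass(frozen=True)
class IsostereRule:
    """One allowed atom swap, e.g. pyrrole NH ↔ thiophene S."""

    name: str
    from_element: str
    to_element: str
    aromatic_only: bool = True
    requires_h: bool = False  # source atom must bear >=1 H
    five_ring_only: bool = False


DEFAULT_ISOSTERE_RULES: tuple[IsostereRule, ...] = (
    IsostereRule("NH<->S in 5-rings", "N", "S", aromatic_only=True,
                 requires_h=True, five_ring_only=True),
    IsostereRule("S<->NH in 5-rings", "S", "N", aromatic_only=True,
                 requires_h=False, five_ring_only=True),
    IsostereRule("CH<->N aromatic", "C", "N", aromatic_only=True,
                 requires_h=True),
    IsostereRule("N<->CH aromatic", "N", "C", aromatic_only=True,
                 requires_h=False),
)


def _five_ring_atoms(g: nx.Graph) -> set[int]:
    out: set[int] = set()
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) == 5:
            out.update(cycle)
    return out


def _element_graph(m: MolecularGraph) -> nx.Graph:
    """Graph keyed by element and bond aromaticity/order only (hydrogens
    and charges ignored: the swap itself changes the hydrogen count)."""
    g = nx.Graph()
    for idx, a in enumerate(m.atoms):
        g.add_node(idx, element=a.element)
    for b in m.bonds:
        g.add_edge(b.i, b.j, aromatic=b.aromatic, order=b.order)
    return g


def pair_isosteres(
    mols: list[MolecularGraph],
    rules: tuple[IsostereRule, ...] = DEFAULT_ISOSTERE_RULES,
) -> list[tuple[str, str, str]]:
    """Find pairs of molecules whose heavy-atom graphs become isomorphic
    after exactly one tabulated atom swap.

    Returns ``(id_a, id_b, rule name)`` triples; symmetric and independent
    of input order (pairs are reported with ids in input order).
    """
    em = lambda a, b: a["element"] == b["element"]
    ee = lambda a, b: (a["aromatic"] == b["aromatic"]
                       and (a["aromatic"] or a["order"] == b["order"]))
    pairs: list[tuple[str, str, str]] = []
    graphs = [_element_graph(m) for m in mols]
    for (ia, ma), (ib, mb) in itertools.combinations(enumerate(mols), 2):
        if ma.num_atoms != mb.num_atoms:
            continue
        found: str | None = None
        for src, dst, gsrc in ((ma, mb, graphs[ia]), (mb, ma, graphs[ib])):
            if found:
                break
            five = _five_ring_atoms(gsrc)
            for rule in rules:
                if found:
                    break
                for idx, atom in enumerate(src.atoms):
                    if atom.element != rule.from_element:
                        continue
                    if rule.aromatic_only and not atom.aromatic:
                        continue
                    if rule.requires_h and atom.implicit_h < 1:
                        continue
                    if rule.five_ring_only and idx not in five:
                        continue
                    variant = gsrc.copy()
                    variant.nodes[idx]["element"] = rule.to_element
                    if nx.is_isomorphic(
                        variant, _element_graph(dst), node_match=em, edge_match=ee
                    ):
                        found = rule.name
                        break
        if found:
            pairs.append((ma.identifier, mb.identifier, found))
    return pairs


@dataclass
class ComparisonReport:
    """Experimental vs fragment-score priority orders for a set of parent
    ligands sharing one simplified structure."""

    ids: list[str]
    relation: str
    experimental_order: PriorityOrder
    metric_orders: dict[str, PriorityOrder]
    discordant: dict[str, bool] = field(default_factory=dict)

    @property
    def any_discordant(self) -> bool:
        return any(self.discordant.values())


def side_chain_effect_report(
    parent_ic50: dict[str, Score],
    fragment_metrics: dict[str, dict[str, float]],
    le_tolerance: float = 0.005,
) -> ComparisonReport:
    """Compare the experimental potency order of parent ligands with the
    docked-fragment BE/LE/BEI orders of their shared simplified structure.

    ``fragment_metrics`` maps id → {"BE": ΔG, "LE": ..., "BEI": ...}.  A
    metric is flagged discordant when its ranking (ties collapsed) differs
    from the experimental one — potency driven by side chains is invisible
    to the side-chain-free fragments.
    """
    if len(parent_ic50) < 2:
        raise ValueError("need at least 2 parent ligands to compare")
    exp = priority_order(parent_ic50, larger_is_better=False, metric="IC50")
    orders: dict[str, PriorityOrder] = {}
    discordant: dict[str, bool] = {}
    for metric, larger, tol in (
        ("BE", False, 0.0),  # more negative energy binds better
        ("LE", True, le_tolerance),
        ("BEI", True, 0.0),
    ):
        scores = {i: m[metric] for i, m in fragment_metrics.items()}
        po = priority_order(scores, larger_is_better=larger, tolerance=tol,
                            metric=metric)
        orders[metric] = po
        discordant[metric] = po.ids != exp.ids
    return ComparisonReport(
        ids=sorted(parent_ic50),
        relation="parent_fragment",
        experimental_order=exp,
        metric_orders=orders,
        discordant=discordant,
    )
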