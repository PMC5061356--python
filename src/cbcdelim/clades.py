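"""CBC clade delimitation, subclade profiling, and parsimony event mapping.

A *CBC clade* is a maximal set of taxa with zero CBCs between every pair of
members — a maximal clique of the zero-CBC graph.  With a single CBC site
(the common situation in closely related species complexes) the zero-CBC
relation is transitive and the cliques partition the taxa; when it is not,
the overlapping cliques are returned with a warning rather than silently
merged.  Within a clade, taxa sharing identical profiles of hCBC / non-CBC /
other paired changes and structural deletions form *subclades* — candidate
reproductively isolated lineages.  Events are placed on the branches of a
rooted input tree by small parsimony (uniform-cost Sankoff, equivalent to
Fitch counts), with every minimal placement reported and flagged when it is
not forced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import networkx as nx

from .errors import ValidationError
from .io import Alignment
from .structure import PairedColumnMap
from .substitutions import (
    CBC, HCBC, INDEL, NONCBC, OTHER_PAIRED, CbcMatrix, PairState,
    SubstitutionEvent, classify_transition, transition_subtype,
)
from .structure import roman

MONOPHYLETIC = "monophyletic"
PARAPHYLETIC = "paraphyletic"
POLYPHYLETIC = "polyphyletic"

_INF = float("inf")


@dataclass(frozen=True)
class CbcClade:
    """Maximal taxon set with no CBC between any two members."""

    members: FrozenSet[str]
    defining_states: Mapping = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Subclade:
    """Within-clade group sharing one profile of structural changes."""

    members: FrozenSet[str]
    clade_index: int
    label: str
    diagnostic_events: Tuple[SubstitutionEvent, ...] = ()


def cbc_clades(m: CbcMatrix, events: Sequence[SubstitutionEvent] = ()) -> List[CbcClade]:
    """Maximal cliques of the zero-CBC graph, largest and earliest first.

    If the zero-CBC relation is transitive the cliques partition the taxa;
    otherwise overlapping cliques are returned and a warning is issued.
    """
    g = nx.Graph()
    g.add_nodes_from(m.taxa)
    for a_idx, a in enumerate(m.taxa):
        for b in m.taxa[a_idx + 1:]:
            if m.count(a, b) == 0:
                g.add_edge(a, b)
    order = {t: k for k, t in enumerate(m.taxa)}
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (min(order[t] for t in c), -len(c), sorted(c)))

    covered: Dict[str, int] = {}
    overlapping = False
    for k, c in enumerate(cliques):
        for t in c:
            if t in covered:
                overlapping = True
            covered[t] = k
    if overlapping:
        warnings.warn(
            "zero-CBC relation is not transitive: returned CBC cliques overlap",
            stacklevel=2,
        )

    cbc_sites: Dict[Tuple[int, ...], Dict[str, str]] = {}
    for ev in events:
        if ev.category == CBC and isinstance(ev.between[0], frozenset):
            site = cbc_sites.setdefault(ev.site, {})
            for taxon in ev.between[0]:
                site[taxon] = ev.from_state
            for taxon in ev.between[1]:
                site[taxon] = ev.to_state

    out = []
    for c in cliques:
        defining = {}
        for site, states in cbc_sites.items():
            vals = {states[t] for t in c if t in states}
            if len(vals) == 1:
                defining[site] = vals.pop()
        out.append(CbcClade(members=c, defining_states=defining))
    return out


def _profile_states(events: Sequence[SubstitutionEvent]):
    """Per-site taxon→state maps for subclade profiling.

    Uses paired-site events of the structure-preserving/disrupting kinds
    (hCBC, nonCBC, other_paired) plus paired-site indels; loop variation
    (category ``single``) never splits a subclade.
    """
    site_state: Dict[Tuple[str, Tuple[int, ...]], Dict[str, str]] = {}
    profile_cats = {HCBC, NONCBC, OTHER_PAIRED}
    subs = [e for e in events
            if e.category in profile_cats and len(e.site) == 2
            and isinstance(e.between[0], frozenset)]
    indels = [e for e in events
              if e.category == INDEL and len(e.site) == 2
              and isinstance(e.between[0], frozenset)]
    for ev in subs:
        d = site_state.setdefault((ev.region, ev.site), {})
        for taxon in ev.between[0]:
            d[taxon] = ev.from_state
        for taxon in ev.between[1]:
            d[taxon] = ev.to_state
    for ev in indels:
        d = site_state.setdefault((ev.region, ev.site), {})
        for taxon in ev.between[1]:
            d[taxon] = ev.to_state
        for taxon in ev.between[0]:
            # only fill taxa no substitution event already assigned
            d.setdefault(taxon, ev.from_state)
    return site_state, subs + indels


def subclades(clades: Sequence[CbcClade], events: Sequence[SubstitutionEvent],
              tree: Optional[dendropy.Tree] = None) -> List[Subclade]:
    """Group each CBC clade's members by their structural-change profile.

    Subclades are numbered I, II, … across clades, following tree tip order
    when a tree is supplied and sorted taxon ids otherwise.
    """
    site_state, profile_events = _profile_states(events)
    if tree is not None:
        ref_order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    else:
        ref_order = sorted({t for c in clades for t in c.members})
    pos = {t: k for k, t in enumerate(ref_order)}

    out: List[Subclade] = []
    for ci, clade in enumerate(clades):
        sites = sorted(site_state)
        groups: Dict[Tuple, List[str]] = {}
        for taxon in clade.members:
            prof = tuple(site_state[s].get(taxon, "") for s in sites)
            groups.setdefault(prof, []).append(taxon)
        ordered = sorted(groups.values(),
                         key=lambda ts: min(pos.get(t, len(pos)) for t in ts))
        for members in ordered:
            mset = frozenset(members)
            diag = tuple(
                ev for ev in profile_events
                if frozenset(ev.between[0]) & clade.members == mset
                or frozenset(ev.between[1]) & clade.members == mset
            )
            out.append(Subclade(members=mset, clade_index=ci,
                                label=roman(len(out) + 1),
                                diagnostic_events=diag))
    return out


# ---------------------------------------------------------------------------
# small-parsimony mapping of pair-state characters onto a rooted tree
# ---------------------------------------------------------------------------

@dataclass
class EdgeEventMap:
    """Events placed on tree edges by uniform-cost small parsimony.

    ``assignments`` maps (parent_label, child_label) edges to the events of
    one canonical most-parsimonious reconstruction; an event is flagged
    ``ambiguous`` when another reconstruction of equal length avoids that
    edge.  ``alternative_placements`` lists, per site, edges that carry the
    change in *some* reconstruction but not the canonical one.
    ``site_lengths`` gives the parsimony length of each mapped site.
    """

    assignments: Dict[Tuple[str, str], List[SubstitutionEvent]]
    site_lengths: Dict[Tuple[int, ...], int]
    alternative_placements: Dict[Tuple[int, ...], List[Tuple[str, str]]]

    @property
    def events(self) -> List[SubstitutionEvent]:
        return [ev for evs in self.assignments.values() for ev in evs]

    def n_changes(self, site: Tuple[int, ...]) -> int:
        return sum(1 for evs in self.assignments.values()
                   for ev in evs if ev.site == site)


def _node_label(node: dendropy.Node, index: Mapping) -> str:
    if node.is_leaf():
        return node.taxon.label
    return f"node{index[id(node)]}"


def map_events_to_tree(aln: Alignment, pcm: PairedColumnMap,
                       tree: dendropy.Tree) -> EdgeEventMap:
    """Optimise every paired-site character on the rooted tree and classify
    the state changes on its edges.

    Per site the character alphabet is the set of observed gap-free pair
    states; taxa with a gapped or N state are treated as missing data.  Per
    site the number of change edges in the reported reconstruction equals the
    Fitch parsimony length.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not tips <= set(aln.ids):
        missing = sorted(tips - set(aln.ids))
        raise ValidationError(f"tree tips not in alignment: {missing}")

    index = {id(n): k for k, n in enumerate(tree.preorder_node_iter())}
    assignments: Dict[Tuple[str, str], List[SubstitutionEvent]] = {}
    site_lengths: Dict[Tuple[int, ...], int] = {}
    alternatives: Dict[Tuple[int, ...], List[Tuple[str, str]]] = {}

    for cp in pcm.paired_cols:
        ci, cj = cp
        tip_state = {}
        for taxon in tips:
            row = aln.row(taxon)
            s = row[ci - 1] + row[cj - 1]
            tip_state[taxon] = None if ("-" in s or "N" in s) else s
        observed = sorted({s for s in tip_state.values() if s is not None})
        if len(observed) < 2:
            continue
        k = len(observed)
        sidx = {s: a for a, s in enumerate(observed)}

        down: Dict[int, List[float]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                s = tip_state[node.taxon.label]
                down[id(node)] = [0.0] * k if s is None else [
                    0.0 if a == sidx[s] else _INF for a in range(k)
                ]
            else:
                costs = [0.0] * k
                for child in node.child_nodes():
                    dc = down[id(child)]
                    best = min(dc)
                    for a in range(k):
                        costs[a] += min(dc[a], best + 1.0)
                down[id(node)] = costs

        root = tree.seed_node
        length = int(min(down[id(root)]))
        site_lengths[cp] = length

        # cost of the tree outside each node's subtree, given the node's state
        above: Dict[int, List[float]] = {id(root): [0.0] * k}
        for node in tree.preorder_node_iter():
            if node is root and node.parent_node is None:
                pass
            children = node.child_nodes()
            for child in children:
                r = _edge_rest_costs(node, child, above, down, k)
                above[id(child)] = [
                    min(r[a] + (0.0 if a == b else 1.0) for a in range(k))
                    for b in range(k)
                ]

        # canonical reconstruction: min state at root, children follow parent
        state_of: Dict[int, int] = {}
        root_costs = down[id(root)]
        state_of[id(root)] = min(range(k), key=lambda a: (root_costs[a], a))
        for node in tree.preorder_node_iter():
            pa = state_of[id(node)]
            for child in node.child_nodes():
                dc = down[id(child)]
                state_of[id(child)] = min(
                    range(k),
                    key=lambda b: (dc[b] + (0.0 if b == pa else 1.0),
                                   b != pa, b),
                )

        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                r = _edge_rest_costs(node, child, above, down, k)
                dc = down[id(child)]
                min_same = min(r[a] + dc[a] for a in range(k))
                min_change = min(
                    (r[a] + 1.0 + dc[b]
                     for a in range(k) for b in range(k) if a != b),
                    default=_INF,
                )
                pa, chs = state_of[id(node)], state_of[id(child)]
                edge = (_node_label(node, index), _node_label(child, index))
                if pa != chs:
                    a_state, b_state = observed[pa], observed[chs]
                    cat = classify_transition(PairState(*a_state), PairState(*b_state))
                    sub = transition_subtype(PairState(*a_state), PairState(*b_state))
                    assignments.setdefault(edge, []).append(SubstitutionEvent(
                        region=pcm.region_label, site=cp,
                        helix_label=pcm.helix_of_pair[cp], category=cat,
                        from_state=a_state, to_state=b_state, between=edge,
                        subtype=sub, ambiguous=(min_same <= length),
                    ))
                elif min_change <= length:
                    alternatives.setdefault(cp, []).append(edge)

    return EdgeEventMap(assignments=assignments, site_lengths=site_lengths,
                        alternative_placements=alternatives)


def _edge_rest_costs(node: dendropy.Node, child: dendropy.Node,
                     above: Mapping, down: Mapping, k: int) -> List[float]:
    """Cost of the whole tree minus child's subtree, given node's state."""
    rest = list(above[id(node)])
    for sib in node.child_nodes():
        if sib is child:
            continue
        ds = down[id(sib)]
        best = min(ds)
        for a in range(k):
            rest[a] += min(ds[a], best + 1.0)
    return rest


def check_monophyly(members: Iterable[str], tree: dendropy.Tree) -> str:
    """Classify a taxon set on a rooted tree.

    *monophyletic* — the set is exactly the tip set of one clade;
    *paraphyletic* — the set is a clade's tips minus the tips of one clade
    nested inside it; *polyphyletic* — anything else.
    """
    members = frozenset(members)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not members <= tips:
        raise ValidationError(f"taxa not in tree: {sorted(members - tips)}")

    tipsets: Dict[int, FrozenSet[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = frozenset([node.taxon.label])
        else:
            tipsets[id(node)] = frozenset().union(
                *(tipsets[id(c)] for c in node.child_nodes())
            )
    all_sets = set(tipsets.values())
    if members in all_sets:
        return MONOPHYLETIC
    for node in tree.preorder_node_iter():
        ts = tipsets[id(node)]
        if not members < ts:
            continue
        complement = ts - members
        for desc in node.preorder_iter():
            if desc is node:
                continue
            if tipsets[id(desc)] == complement:
                return PARAPHYLETIC
    return POLYPHYLETIC
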