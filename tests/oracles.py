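"""Independent oracles the implementation is checked against.

Everything here is coded from the definitions alone — exhaustive enumeration,
brute-force minimisation, explicit rule tables — and never calls the code
paths it validates.
"""

from functools import lru_cache
from itertools import product

WATSON_CRICK = {"AU", "UA", "GC", "CG"}
GU_WOBBLE = {"GU", "UG"}


def pair_class(state: str) -> str:
    if state in WATSON_CRICK:
        return "canonical"
    if state in GU_WOBBLE:
        return "wobble"
    return "noncanonical"


def transition_table():
    """Explicit 16x16 lookup of gap-free pair-state transition categories.

    Built case by case from the three definitions: CBC = both strands mutate,
    canonical to canonical; hCBC = one-sided canonical<->wobble; nonCBC =
    canonical-or-wobble replaced by noncanonical.  Everything else that
    changed is outside the three-way taxonomy ('other_paired').
    """
    table = {}
    states = ["".join(p) for p in product("ACGU", repeat=2)]
    for a in states:
        for b in states:
            if a == b:
                table[(a, b)] = None
                continue
            ka, kb = pair_class(a), pair_class(b)
            one_sided = (a[0] == b[0]) != (a[1] == b[1])
            if ka == "canonical" and kb == "canonical":
                cat = "CBC"
            elif "noncanonical" in (ka, kb) and ka != kb:
                cat = "nonCBC"
            elif {ka, kb} == {"canonical", "wobble"} and one_sided:
                cat = "hCBC"
            else:
                cat = "other_paired"
            table[(a, b)] = cat
    return table


@lru_cache(maxsize=None)
def enumerate_pair_sets(i: int, j: int, min_loop: int = 3):
    """All pseudoknot-free pair sets on positions i..j (1-based, inclusive)."""
    if j - i < min_loop + 1:
        return (frozenset(),)
    out = set(enumerate_pair_sets(i + 1, j, min_loop))
    for k in range(i + min_loop + 1, j + 1):
        for left in enumerate_pair_sets(i + 1, k - 1, min_loop):
            for right in enumerate_pair_sets(k + 1, j, min_loop):
                out.add(left | right | {(i, k)})
    return tuple(out)


def column_score(cols_i, cols_j, pair_threshold, covariation_bonus):
    n = len(cols_i)
    pairing = [x + y for x, y in zip(cols_i, cols_j)
               if (x + y) in WATSON_CRICK | GU_WOBBLE]
    frac = len(pairing) / n
    if frac < pair_threshold or not pairing:
        return None
    return frac + covariation_bonus * (len(set(pairing)) - 1)


def structure_sort_key(pairs, n):
    """5'->3' preference: paired beats unpaired, smaller partner beats larger."""
    partner = {}
    for (i, j) in pairs:
        partner[i] = j
        partner[j] = i
    return tuple(
        (0, partner[p]) if p in partner else (1, n + 2) for p in range(1, n + 1)
    )


def best_fold_bruteforce(rows, min_loop=3, pair_threshold=0.5,
                         covariation_bonus=1.0):
    """Max-scoring pseudoknot-free structure by full enumeration."""
    n = len(rows[0])
    cols = [[r[c] for r in rows] for c in range(n)]
    scores = {}
    for i in range(1, n + 1):
        for j in range(i + min_loop + 1, n + 1):
            scores[(i, j)] = column_score(cols[i - 1], cols[j - 1],
                                          pair_threshold, covariation_bonus)
    best_score, best = -1.0, frozenset()
    for pairs in enumerate_pair_sets(1, n, min_loop):
        if any(scores[p] is None for p in pairs):
            continue
        s = sum(scores[p] for p in pairs)
        if s > best_score + 1e-9:
            best_score, best = s, pairs
        elif abs(s - best_score) <= 1e-9 and \
                structure_sort_key(pairs, n) < structure_sort_key(best, n):
            best = pairs
    return best, best_score


def parsimony_length_bruteforce(tree, tip_state, alphabet):
    """Exhaustive minimum changes over all internal-node labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((node, child))
    best = None
    for labels in product(alphabet, repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), labels))
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = tip_state[leaf.taxon.label]
        changes = sum(1 for u, v in edges if assign[id(u)] != assign[id(v)])
        if best is None or changes < best:
            best = changes
    return best
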