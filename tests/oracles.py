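"""Independent slow oracles the test suite checks the package against.

Everything here is deliberately written against different representations
than the package uses (nested tuples, dict-based dynamic programs, explicit
enumeration) so agreement is informative.
"""

from __future__ import annotations

from itertools import combinations, product

INF = 10**9

# nested-tuple trees: a leaf is a label string, an internal node a tuple of children


def tuple_tree_leaves(t):
    if isinstance(t, str):
        return [t]
    out = []
    for c in t:
        out.extend(tuple_tree_leaves(c))
    return out


def brute_force_fitch(t, column, n_states):
    """Minimum changes over exhaustive single-state assignments to internal nodes.

    ``column`` maps leaf label -> set of allowed states (full set for
    missing/inapplicable cells).
    """
    internals = []

    def collect(node):
        if isinstance(node, str):
            return
        internals.append(node)
        for c in node:
            collect(c)

    collect(t)
    best = INF
    for assignment in product(range(n_states), repeat=len(internals)):
        states = dict(zip(map(id, internals), assignment))

        def changes(node, parent_state):
            if isinstance(node, str):
                # a tip takes any of its allowed states; a change on the
                # terminal edge costs one step
                return 0 if parent_state in column[node] else 1
            s = states[id(node)]
            total = 0 if parent_state is None or s == parent_state else 1
            for c in node:
                total += changes(c, s)
            return total

        best = min(best, changes(t, None))
    return best


def dp_fitch(t, column, n_states):
    """Uniform-cost DP on the tuple tree — an implementation-independent
    counterpart of the package's vectorized engine."""

    def cost(node):
        if isinstance(node, str):
            return {s: (0 if s in column[node] else INF) for s in range(n_states)}
        child_costs = [cost(c) for c in node]
        return {
            s: sum(min(cc[u] + (u != s) for u in cc) for cc in child_costs)
            for s in range(n_states)
        }

    return min(cost(t).values())


def brute_min_steps(column):
    """(size of minimum hitting set of observed state sets) − 1, by enumeration."""
    sets = [s for s in column.values() if s is not None]
    if not sets:
        return 0
    universe = sorted(set().union(*sets))
    for size in range(1, len(universe) + 1):
        for combo in combinations(universe, size):
            if all(set(combo) & s for s in sets):
                return size - 1
    raise AssertionError("unreachable")


def all_unrooted_topologies(labels):
    """Every unrooted binary topology on ``labels``, as rooted tuple trees.

    Built by sequential edge insertion; the classic (2n−5)!! count.
    """
    labels = list(labels)
    if len(labels) < 3:
        return [tuple(labels)] if len(labels) == 2 else [labels[0]]
    trees = [(labels[0], labels[1], labels[2])]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            for variant in _insert_everywhere(t, label):
                nxt.append(variant)
        trees = nxt
    return trees


def _insert_everywhere(t, label):
    out = []
    for i, child in enumerate(t):
        # attach onto the edge above child
        replaced = list(t)
        replaced[i] = (child, label)
        out.append(tuple(replaced))
        if not isinstance(child, str):
            for sub in _insert_everywhere(child, label):
                replaced = list(t)
                replaced[i] = sub
                out.append(tuple(replaced))
    return out


# ---------------------------------------------------------------------------
# naive fossil placement on tuple trees


def tuple_attachments(t):
    """All (bipartition-side, augmented-tree) pairs for grafting a new leaf.

    The bipartition side is the frozenset of leaves below the subtree whose
    edge is bisected.
    """
    out = []

    def rec(node, rebuild):
        for i, child in enumerate(node):
            def rebuilt(new_child, i=i, node=node, rebuild=rebuild):
                lst = list(node)
                lst[i] = new_child
                return rebuild(tuple(lst))

            out.append((frozenset(tuple_tree_leaves(child)), child, rebuilt))
            if not isinstance(child, str):
                rec(child, rebuilt)

    rec(t, lambda x: x)
    return out


def naive_place(t, columns, n_states, fossil, k):
    """Score every attachment of ``fossil`` on tuple-backbone ``t``.

    ``columns``: list of dicts label -> set of states (None = unobserved,
    handled by the caller as the full state set).  Returns
    {bipartition-side: (total_fit, total_length)} keyed by the raw child-side
    leaf set (caller canonicalizes).
    """
    results = {}
    for side, child, rebuilt in tuple_attachments(t):
        aug = rebuilt((child, fossil))
        total_fit = 0.0
        total_len = 0
        for col in columns:
            full = set(range(n_states))
            cells = {lf: (col[lf] if col[lf] is not None else full)
                     for lf in tuple_tree_leaves(aug)}
            s = dp_fitch(aug, cells, n_states)
            m = brute_min_steps({lf: col[lf] for lf in cells})
            e = s - m
            total_fit += e / (e + k)
            total_len += s
        results[side] = (total_fit, total_len)
    return results
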