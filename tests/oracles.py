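"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the dynamic programmes under test: parsimony is
checked by exhaustive minimisation over every assignment of states to
internal nodes (and unknown tips), and maximal derived clades by a direct
scan of all nodes.
"""

from __future__ import annotations

import random
from itertools import product

from euryalida.tree import Node, Tree


def brute_force_parsimony(tree, states, root_state=0):
    """Exhaustive small-parsimony summary.

    Returns (min_changes, gains_min, gains_max, per_node_state_sets) by
    enumerating every assignment of {0,1} to internal nodes and to tips
    with unknown state.  The root constraint is a phantom stem edge from
    ``root_state``; changes/gains on it are counted.
    """
    nodes = list(tree.root.preorder())
    internal = [n for n in nodes if not n.is_tip]
    unknown = [n for n in nodes if n.is_tip and len(states[n.label]) > 1]
    fixed = {n: next(iter(states[n.label]))
             for n in nodes if n.is_tip and len(states[n.label]) == 1}
    free = internal + unknown

    best = None
    gains_at_best = set()
    attainable = {n: set() for n in nodes}
    for combo in product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        changes = gains = 0
        for n in nodes:
            if n.parent is not None:
                parent_state = assign[n.parent]
                if parent_state != assign[n]:
                    changes += 1
                    if assign[n] == 1:
                        gains += 1
        if root_state is not None and assign[tree.root] != root_state:
            changes += 1
            if assign[tree.root] == 1:
                gains += 1
        if best is None or changes < best:
            best = changes
            gains_at_best = {gains}
            attainable = {n: {assign[n]} for n in nodes}
        elif changes == best:
            gains_at_best.add(gains)
            for n in nodes:
                attainable[n].add(assign[n])
    return best, min(gains_at_best), max(gains_at_best), attainable


def brute_force_maximal_derived(tree, states):
    """All nodes whose tips are entirely derived and whose parent is not."""
    def all_derived(node):
        return all(states[t] == frozenset({1}) for t in node.tip_labels())
    out = []
    for node in tree.root.preorder():
        if all_derived(node):
            if node.parent is None or not all_derived(node.parent):
                out.append(node)
    return out


def random_tree(rng: random.Random, n_tips: int, polytomy_prob: float = 0.0) -> Tree:
    """A random rooted tree by repeated joining, optionally with polytomies."""
    nodes = [Node(label=f"T{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        k = 2
        if len(nodes) > 2 and rng.random() < polytomy_prob:
            k = 3
        picked = rng.sample(range(len(nodes)), k)
        children = [nodes[i] for i in picked]
        for i in sorted(picked, reverse=True):
            nodes.pop(i)
        nodes.append(Node(children=children))
    return Tree(nodes[0])


def random_states(rng: random.Random, tree: Tree, unknown_prob: float = 0.0):
    states = {}
    for label in tree.tip_labels():
        if rng.random() < unknown_prob:
            states[label] = frozenset({0, 1})
        else:
            states[label] = frozenset({rng.randint(0, 1)})
    return states
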