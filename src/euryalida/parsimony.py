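"""Small parsimony for a binary character on a rooted cladogram.

The minimum number of unordered, unit-cost state changes is computed by the
standard dynamic programme over subtree costs (Sankoff recursion restricted
to two states, which on binary data coincides with Fitch counting).  On top
of the cost table a second pass reports, over *all* most-parsimonious
reconstructions (MPRs), the attainable range of gains (0 -> 1 changes) and
losses, and the set of states each node can take in some MPR — without ever
enumerating the reconstructions explicitly.

Ancestral-state polarisation follows the outgroup convention: passing
``root_state=0`` places a phantom stem lineage in state 0 above the root, so
a derived state at the root itself is possible but costs (and counts as) one
gain on the stem.  ``root_state=None`` leaves the root free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import MissingTaxonError
from .tree import Node, Tree

__all__ = ["MPRSummary", "fitch_min_changes", "mpr_gain_range"]

_BIG = 10 ** 9

TipStateMap = Mapping[str, frozenset]


@dataclass(frozen=True)
class MPRSummary:
    """Cost and gain/loss ranges over all most-parsimonious reconstructions.

    ``gains + losses = min_changes`` holds in every MPR, so the loss range
    mirrors the gain range.  ``per_node_state_sets`` maps each node to the
    subset of {0, 1} it attains in at least one MPR.
    """

    min_changes: int
    gains_min: int
    gains_max: int
    losses_min: int
    losses_max: int
    per_node_state_sets: dict[Node, frozenset]


def _resolve_scope(tree: Tree, scope: Optional[Node]) -> Node:
    return scope if scope is not None else tree.root


def _tip_costs(node: Node, states: TipStateMap) -> tuple[int, int]:
    try:
        allowed = states[node.label]
    except KeyError:
        raise MissingTaxonError(
            f"tip {node.label!r} missing from the tip-state map") from None
    if not allowed:
        raise ValueError(f"tip {node.label!r} has an empty state set")
    return (0 if 0 in allowed else _BIG, 0 if 1 in allowed else _BIG)


def _cost_table(root: Node, states: TipStateMap) -> dict[Node, tuple[int, int]]:
    cost: dict[Node, tuple[int, int]] = {}
    for node in root.postorder():
        if node.is_tip:
            cost[node] = _tip_costs(node, states)
        else:
            totals = [0, 0]
            for child in node.children:
                c0, c1 = cost[child]
                totals[0] += min(c0, c1 + 1)
                totals[1] += min(c0 + 1, c1)
            cost[node] = (totals[0], totals[1])
    return cost


def fitch_min_changes(tree: Tree, states: TipStateMap,
                      root_state: Optional[int] = 0,
                      scope: Optional[Node] = None) -> int:
    """Minimum number of binary state changes on the (sub)tree.

    Parameters
    ----------
    states:
        Map from tip label to allowed state set; ``{0, 1}`` marks unknown.
    root_state:
        Ancestral state enforced on a phantom stem above the (scope) root;
        ``None`` leaves the root unconstrained.
    scope:
        Restrict the computation to the subtree rooted at this node.
    """
    root = _resolve_scope(tree, scope)
    cost = _cost_table(root, states)
    c0, c1 = cost[root]
    if root_state is None:
        return min(c0, c1)
    if root_state == 0:
        return min(c0, c1 + 1)
    return min(c0 + 1, c1)


def mpr_gain_range(tree: Tree, states: TipStateMap,
                   root_state: Optional[int] = 0,
                   scope: Optional[Node] = None) -> MPRSummary:
    """Gain/loss ranges over all minimum-cost reconstructions.

    A gain is a 0 -> 1 change on an edge (including the phantom stem when
    ``root_state=0`` and the root resolves to 1); a loss is the reverse.
    The ranges are tight: both endpoints are attained by actual MPRs.
    """
    root = _resolve_scope(tree, scope)
    cost = _cost_table(root, states)

    # per-(node, state): min/max gains within the subtree, conditional on
    # the node taking that state in an optimal sub-reconstruction
    gmin: dict[Node, list[int]] = {}
    gmax: dict[Node, list[int]] = {}
    # optimal child states given a parent state, for the downward pass
    choice: dict[tuple[Node, int], tuple[int, ...]] = {}

    for node in root.postorder():
        if node.is_tip:
            c = cost[node]
            gmin[node] = [0 if c[0] < _BIG else _BIG, 0 if c[1] < _BIG else _BIG]
            gmax[node] = [0 if c[0] < _BIG else -_BIG, 0 if c[1] < _BIG else -_BIG]
            continue
        lo = [0, 0]
        hi = [0, 0]
        for child in node.children:
            c0, c1 = cost[child]
            for s in (0, 1):
                best = min(c0 + (s != 0), c1 + (s != 1))
                opts = tuple(t for t, ct in ((0, c0), (1, c1))
                             if ct + (s != t) == best)
                choice[(child, s)] = opts
                lo[s] += min(gmin[child][t] + (s == 0 and t == 1) for t in opts)
                hi[s] += max(gmax[child][t] + (s == 0 and t == 1) for t in opts)
        gmin[node] = lo
        gmax[node] = hi

    c0, c1 = cost[root]
    if root_state is None:
        total = min(c0, c1)
        root_opts = tuple(s for s, c in ((0, c0), (1, c1)) if c == total)
        stem_gain = {s: 0 for s in root_opts}
    else:
        total = min(c0 + (root_state != 0), c1 + (root_state != 1))
        root_opts = tuple(s for s, c in ((0, c0), (1, c1))
                          if c + (root_state != s) == total)
        stem_gain = {s: int(root_state == 0 and s == 1) for s in root_opts}

    gains_min = min(gmin[root][s] + stem_gain[s] for s in root_opts)
    gains_max = max(gmax[root][s] + stem_gain[s] for s in root_opts)

    # downward pass: states attainable at each node in some MPR
    allowed: dict[Node, set] = {root: set(root_opts)}
    for node in root.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            states_here = allowed.setdefault(child, set())
            for s in allowed[node]:
                states_here.update(choice[(child, s)])

    return MPRSummary(
        min_changes=total,
        gains_min=gains_min,
        gains_max=gains_max,
        losses_min=total - gains_max,
        losses_max=total - gains_min,
        per_node_state_sets={n: frozenset(s) for n, s in allowed.items()},
    )
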