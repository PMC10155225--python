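"""Sister-group comparisons of derived-state clades.

The core procedure of the analysis: locate every *maximal* clade whose tips
all carry the derived state (branched arms, pedicellariae, or a branching
pattern), pair it with its sister group, sum described-species richness on
both sides, and score the comparison ``plus`` / ``minus`` / ``zero``
according to whether the derived clade out-diversifies its sister.

Richness sums run over placed taxa only — *incertae sedis* records are not
tips and never enter a clade sum — except that, for comparisons whose sides
are entire families, unplaced members of those families can optionally be
folded in (``include_unplaced_families``), matching how family totals are
quoted in faunal tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .characters import CharacterMatrix
from .errors import AllDerivedWarning, PolytomyWarning
from .tree import Node, Tree

__all__ = [
    "SisterPair", "UnplacedDistal", "DistalComparisons",
    "find_derived_clades", "sister_of", "clade_richness",
    "build_sister_pairs", "distal_subcomparisons", "pairs_to_tsv",
]


@dataclass(frozen=True)
class SisterPair:
    """One derived-clade / sister-clade richness comparison."""

    focal_tips: tuple[str, ...]
    sister_tips: tuple[str, ...]
    focal_richness: int
    sister_richness: int
    outcome: str                  # "plus" | "minus" | "zero"
    sister_is_mixed: bool         # sister contains derived-state tips
    family_scope: str
    from_polytomy: bool = False

    @property
    def focal_label(self) -> str:
        return " + ".join(self.focal_tips)

    @property
    def sister_label(self) -> str:
        return " + ".join(self.sister_tips)


@dataclass(frozen=True)
class UnplacedDistal:
    """A distally-branching taxon with no cladogram position: its sister
    group, and hence its comparison, is unknown."""

    taxon_name: str
    species_count: int


@dataclass(frozen=True)
class DistalComparisons:
    pairs: tuple[SisterPair, ...]
    unplaced: tuple[UnplacedDistal, ...]


def _derived_tip_states(states: Mapping[str, frozenset], labels: Iterable[str]) -> dict[str, bool]:
    out = {}
    for label in labels:
        try:
            allowed = states[label]
        except KeyError:
            raise KeyError(f"tip {label!r} missing from the tip-state map") from None
        if len(allowed) != 1:
            raise ValueError(
                f"tip {label!r} has unknown state; sister comparisons need "
                "fully resolved binary states")
        out[label] = 1 in allowed
    return out


def find_derived_clades(tree: Tree, states: Mapping[str, frozenset],
                        scope: Optional[Node] = None) -> list[Node]:
    """Maximal monophyletic derived-state clades, in traversal order.

    Returns every node all of whose tips carry state 1 while its parent
    (within scope) subtends at least one state-0 tip.  If the scope root is
    itself entirely derived there is no sister group to compare against:
    an empty list is returned under an :class:`AllDerivedWarning`.
    """
    root = scope if scope is not None else tree.root
    derived = _derived_tip_states(states, root.tip_labels())
    all_derived: dict[Node, bool] = {}
    for node in root.postorder():
        if node.is_tip:
            all_derived[node] = derived[node.label]
        else:
            all_derived[node] = all(all_derived[c] for c in node.children)
    if all_derived[root]:
        warnings.warn("the whole scope carries the derived state; no sister "
                      "group exists", AllDerivedWarning, stacklevel=2)
        return []
    clades = []
    for node in root.preorder():
        if all_derived[node] and (node is root or not all_derived[node.parent]):
            clades.append(node)
    return clades


def sister_of(tree: Tree, node: Node, scope: Optional[Node] = None
              ) -> tuple[frozenset[str], bool]:
    """Tip set of the sister group of ``node``.

    At a polytomy the sister is the union of all co-siblings, and the second
    element of the returned pair is True (also signalled through a
    :class:`PolytomyWarning`).
    """
    root = scope if scope is not None else tree.root
    if node is root:
        raise ValueError("the (scope) root has no sister group")
    siblings = [c for c in node.parent.children if c is not node]
    from_polytomy = len(siblings) > 1
    if from_polytomy:
        warnings.warn("sister taken as the union of co-siblings at a "
                      "polytomy", PolytomyWarning, stacklevel=2)
    tips: set[str] = set()
    for sib in siblings:
        tips.update(sib.tip_labels())
    return frozenset(tips), from_polytomy


def clade_richness(tips: Iterable[str], matrix: CharacterMatrix) -> int:
    """Summed described-species richness over the named tips."""
    return matrix.richness(tips)


def _family_scope(tips: Iterable[str], matrix: CharacterMatrix) -> str:
    families = {matrix[t].family for t in tips}
    return families.pop() if len(families) == 1 else "mixed"


def _augmented_richness(tips: frozenset[str], matrix: CharacterMatrix,
                        include_unplaced: bool) -> int:
    richness = matrix.richness(tips)
    if include_unplaced:
        families = {matrix[t].family for t in tips}
        for family in families:
            placed = {r.taxon_name for r in matrix.family(family, placed=True)}
            if placed and placed <= set(tips):
                richness += sum(r.species_count
                                for r in matrix.family(family, placed=False))
    return richness


def _outcome(focal: int, sister: int) -> str:
    if focal > sister:
        return "plus"
    if focal < sister:
        return "minus"
    return "zero"


def _pair(tree: Tree, node: Node, states, matrix: CharacterMatrix,
          scope: Optional[Node], include_unplaced: bool) -> SisterPair:
    focal_tips = tuple(node.tip_labels())
    sister_tips_set, from_polytomy = sister_of(tree, node, scope=scope)
    # keep deterministic tree order for the sister label
    order = {label: i for i, label in enumerate(tree.tip_labels())}
    sister_tips = tuple(sorted(sister_tips_set, key=order.__getitem__))
    # maximality guard: the parent must subtend an ancestral-state tip
    assert any(states[t] == frozenset({0}) for t in sister_tips), \
        "focal clade is not maximal"
    focal_richness = _augmented_richness(frozenset(focal_tips), matrix,
                                         include_unplaced)
    sister_richness = _augmented_richness(frozenset(sister_tips), matrix,
                                          include_unplaced)
    return SisterPair(
        focal_tips=focal_tips,
        sister_tips=sister_tips,
        focal_richness=focal_richness,
        sister_richness=sister_richness,
        outcome=_outcome(focal_richness, sister_richness),
        sister_is_mixed=any(1 in states[t] and len(states[t]) == 1
                            for t in sister_tips),
        family_scope=_family_scope(focal_tips, matrix),
        from_polytomy=from_polytomy,
    )


def build_sister_pairs(tree: Tree, states: Mapping[str, frozenset],
                       matrix: CharacterMatrix,
                       scope: Optional[Node] = None,
                       include_unplaced_families: bool = False
                       ) -> list[SisterPair]:
    """One :class:`SisterPair` per maximal derived clade within scope."""
    clades = find_derived_clades(tree, states, scope=scope)
    return [_pair(tree, node, states, matrix, scope, include_unplaced_families)
            for node in clades]


def distal_subcomparisons(tree: Tree, pattern_map: Mapping[str, Optional[str]],
                          matrix: CharacterMatrix,
                          scope: Optional[Node] = None) -> DistalComparisons:
    """Sister comparisons for the distal-branching pattern.

    Maximal clades of distally-branching tips are paired with their sisters
    (which may be snakestars or basally-branching basketstars).  Unplaced
    distal taxa cannot be paired; they are reported separately with their
    richness so no census row is silently dropped.
    """
    root = scope if scope is not None else tree.root
    states = {}
    for label in root.tip_labels():
        pattern = pattern_map.get(label)
        if pattern is None:
            states[label] = frozenset({0, 1})  # rejected downstream if hit
        else:
            states[label] = frozenset({1 if pattern == "distal" else 0})
    pairs = build_sister_pairs(tree, states, matrix, scope=scope)
    unplaced = tuple(
        UnplacedDistal(r.taxon_name, r.species_count)
        for r in matrix
        if not r.placed and r.pattern == "distal")
    return DistalComparisons(pairs=tuple(pairs), unplaced=unplaced)


def pairs_to_tsv(pairs: Iterable[SisterPair],
                 unplaced: Iterable[UnplacedDistal] = ()) -> str:
    """Serialise comparisons in the five-column layout of the published
    comparison tables (clade, n, sister clade, n, outcome)."""
    symbol = {"plus": "+", "minus": "-", "zero": "0"}
    lines = ["derived_clade\tn_species\tsister_clade\tn_sister\toutcome"]
    for p in pairs:
        lines.append(f"{p.focal_label}\t{p.focal_richness}\t"
                     f"{p.sister_label}\t{p.sister_richness}\t{symbol[p.outcome]}")
    for u in unplaced:
        lines.append(f"{u.taxon_name}\t{u.species_count}\tUnknown\t\t")
    return "\n".join(lines) + "\n"
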