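"""Ancestral presence/absence reconstruction of protein families.

Two parsimony flavours are implemented over a rooted species tree and a
binary presence row (one family across the leaf panel):

* **Dollo parsimony** assumes each family was gained exactly once.  Its
  origin is then forced to the most recent common ancestor (MRCA) of the
  species possessing the family, with losses explaining every absence
  inside that clade.

* **Asymmetric Wagner parsimony** (Sankoff-style weighted parsimony)
  permits any number of gains and losses, each 0->1 transition costing
  ``gain_penalty`` and each 1->0 transition costing ``loss_penalty``.
  The loss penalty is the fixed reference (1) and the gain penalty is
  expressed relative to it, default 1.  A root in state 1 counts as a gain
  (the family predates the root).  The optimum is found by the classic
  two-pass dynamic program — post-order accumulation of per-state subtree
  costs, pre-order traceback — which handles polytomies natively.  When
  both states are optimal at a node the traceback picks absence (0), a
  deterministic convention that favours multiple independent gains and
  therefore younger origins.

A brute-force enumerator over all internal labelings is provided as an
exact oracle for small trees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ArgumentError, SizeError
from .species_tree import SpeciesTree, TreeNode, mrca

__all__ = [
    "CostScheme",
    "AncestralLabeling",
    "dollo_reconstruct",
    "wagner_reconstruct",
    "brute_force_reconstruct",
]


@dataclass(frozen=True)
class CostScheme:
    """Transition penalties: gain is 0->1 along a branch, loss is 1->0.

    ``loss_penalty`` is the reference unit (1 by convention);
    ``gain_penalty`` is relative to it.
    """

    gain_penalty: float = 1.0
    loss_penalty: float = 1.0

    def __post_init__(self):
        for name in ("gain_penalty", "loss_penalty"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ArgumentError(f"{name} must be strictly positive and finite")

    def transition(self, parent_state: int, child_state: int) -> float:
        if parent_state == 0 and child_state == 1:
            return self.gain_penalty
        if parent_state == 1 and child_state == 0:
            return self.loss_penalty
        return 0.0


@dataclass
class AncestralLabeling:
    """A full 0/1 state assignment for one family over all tree nodes.

    ``gains`` are nodes in state 1 whose parent is in state 0 (the root in
    state 1 is a gain); ``losses`` the converse.  ``cost`` equals
    gain_penalty * |gains| + loss_penalty * |losses| and is recomputable
    from the state map.
    """

    family: str
    state: dict[str, int]
    gains: set[str] = field(default_factory=set)
    losses: set[str] = field(default_factory=set)
    cost: float = 0.0
    method: str = ""

    @classmethod
    def from_states(
        cls,
        family: str,
        state: Mapping[str, int],
        tree: SpeciesTree,
        costs: CostScheme,
        method: str = "",
    ) -> "AncestralLabeling":
        gains, losses = set(), set()
        for node in tree.root.preorder():
            s = state[node.label]
            parent_s = state[node.parent.label] if node.parent is not None else 0
            if s == 1 and parent_s == 0:
                gains.add(node.label)
            elif s == 0 and parent_s == 1:
                losses.add(node.label)
        cost = costs.gain_penalty * len(gains) + costs.loss_penalty * len(losses)
        return cls(
            family=family,
            state=dict(state),
            gains=gains,
            losses=losses,
            cost=cost,
            method=method,
        )


def _present_leaves(row: Mapping[str, int], tree: SpeciesTree) -> list[str]:
    leaves = tree.leaf_labels
    missing = [s for s in leaves if s not in row]
    if missing:
        raise ArgumentError(
            "presence row lacks entries for leaves: " + ", ".join(missing)
        )
    present = [s for s in leaves if row[s]]
    if not present:
        raise ArgumentError("presence row is all-zero; family observed nowhere")
    if len(leaves) < 2:
        raise ArgumentError("reconstruction requires a tree with >= 2 leaves")
    return present


def dollo_reconstruct(
    row: Mapping[str, int], tree: SpeciesTree, family: str = ""
) -> AncestralLabeling:
    """Single-gain (Dollo) reconstruction of one family.

    The gain node is the MRCA of the present leaves.  Inside the gain clade
    a node is present iff its subtree still contains a present leaf, which
    places one loss on each maximal absent subtree — the minimal-loss Dollo
    labeling with a canonical (maximally high) loss placement.
    """
    present = set(_present_leaves(row, tree))
    gain = mrca(tree, present)

    has_present: dict[str, bool] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            has_present[node.label] = node.label in present
        else:
            has_present[node.label] = any(has_present[c.label] for c in node.children)

    in_gain_clade: dict[str, bool] = {}
    for node in tree.root.preorder():
        if node is gain:
            in_gain_clade[node.label] = True
        elif node.parent is not None:
            in_gain_clade[node.label] = in_gain_clade[node.parent.label]
        else:
            in_gain_clade[node.label] = False

    state = {
        node.label: int(in_gain_clade[node.label] and has_present[node.label])
        for node in tree.root.preorder()
    }
    return AncestralLabeling.from_states(
        family, state, tree, CostScheme(), method="dollo"
    )


def wagner_reconstruct(
    row: Mapping[str, int],
    tree: SpeciesTree,
    costs: CostScheme = CostScheme(),
    family: str = "",
) -> AncestralLabeling:
    """Minimum-cost asymmetric Wagner (Sankoff) reconstruction.

    Post-order pass: ``down[node][s]`` is the optimal cost of the subtree
    under ``node`` given that ``node`` is in state ``s`` (leaves are clamped
    to their observed state).  Root choice adds ``gain_penalty`` to state 1,
    treating presence at the root as a gain on the root branch.  Pre-order
    traceback resolves each child's state, preferring 0 on ties.
    """
    _present_leaves(row, tree)  # validates row
    INF = math.inf

    down: dict[str, tuple[float, float]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            obs = int(row[node.label])
            down[node.label] = (0.0 if obs == 0 else INF, 0.0 if obs == 1 else INF)
        else:
            totals = [0.0, 0.0]
            for child in node.children:
                c0, c1 = down[child.label]
                for s in (0, 1):
                    totals[s] += min(
                        c0 + costs.transition(s, 0), c1 + costs.transition(s, 1)
                    )
            down[node.label] = (totals[0], totals[1])

    state: dict[str, int] = {}
    r0, r1 = down[tree.root.label]
    state[tree.root.label] = 0 if r0 <= r1 + costs.gain_penalty else 1
    for node in tree.root.preorder():
        s = state[node.label]
        for child in node.children:
            c0, c1 = down[child.label]
            cost0 = c0 + costs.transition(s, 0)
            cost1 = c1 + costs.transition(s, 1)
            state[child.label] = 0 if cost0 <= cost1 else 1

    return AncestralLabeling.from_states(family, state, tree, costs, method="wagner")


def brute_force_reconstruct(
    row: Mapping[str, int],
    tree: SpeciesTree,
    costs: CostScheme = CostScheme(),
    family: str = "",
    max_internal: int = 20,
) -> tuple[float, list[AncestralLabeling]]:
    """Exhaustive minimum over all internal-state assignments.

    Exact oracle for small trees; returns the optimal cost and every
    labeling achieving it.
    """
    _present_leaves(row, tree)
    internal = [n for n in tree.root.preorder() if not n.is_leaf]
    if len(internal) > max_internal:
        raise SizeError(
            f"{len(internal)} internal nodes exceed the exhaustive limit "
            f"of {max_internal}"
        )
    base = {n.label: int(row[n.label]) for n in tree.root.leaves()}
    best_cost = math.inf
    best: list[AncestralLabeling] = []
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = dict(base)
        state.update({n.label: s for n, s in zip(internal, assignment)})
        lab = AncestralLabeling.from_states(
            family, state, tree, costs, method="brute_force"
        )
        if lab.cost < best_cost - 1e-12:
            best_cost = lab.cost
            best = [lab]
        elif abs(lab.cost - best_cost) <= 1e-12:
            best.append(lab)
    return best_cost, best
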