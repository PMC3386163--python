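"""Synthetic species trees and family histories with known ground truth.

Real inputs to the age pipeline are large cross-species family databases;
for testing and benchmarking we instead simulate histories whose true
origins are known.  Each simulated family is gained exactly once at a
sampled origin node and then, on every branch below the origin,
independently lost with a fixed per-branch probability (no regain), so the
true history is Dollo-consistent by construction: the family is present in
exactly the leaves under its origin that are not separated from it by a
lost branch.  Families whose descendants are all lost are discarded and
redrawn, so presence rows are never all-zero.

All randomness flows from an explicit integer seed; the same seed always
reproduces the same tree and histories.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .family_db import FamilyTable
from .species_tree import SpeciesTree, TreeNode

__all__ = [
    "SimulatedHistory",
    "simulate_tree",
    "simulate_families",
    "write_fixture_dir",
]


def simulate_tree(
    n_leaves: int, seed: int, polytomy: bool = False
) -> SpeciesTree:
    """Random rooted dated tree with ``n_leaves`` extant leaves.

    Topology is built by repeated random joins (a Yule-like coalescent of
    lineages); each new internal node is dated strictly older than all its
    children by a uniform(50, 150) mya increment above the oldest child, so
    ages strictly decrease root -> leaf.  With ``polytomy`` the first join
    merges three lineages, injecting one multifurcation.  Leaves are named
    ``S1..Sn``, internal nodes ``T1..``, deterministically per seed.
    """
    if n_leaves < 2:
        raise ArgumentError("simulate_tree requires n_leaves >= 2")
    rng = np.random.default_rng(seed)
    lineages: list[TreeNode] = [
        TreeNode(label=f"S{i + 1}", age_mya=0.0) for i in range(n_leaves)
    ]
    t_counter = 0
    first = True
    while len(lineages) > 1:
        k = 3 if (polytomy and first and len(lineages) >= 3) else 2
        first = False
        idx = sorted(rng.choice(len(lineages), size=k, replace=False).tolist())
        children = [lineages[i] for i in idx]
        for i in reversed(idx):
            lineages.pop(i)
        t_counter += 1
        parent = TreeNode(
            label=f"T{t_counter}",
            age_mya=max(c.age_mya for c in children) + float(rng.uniform(50, 150)),
            children=children,
        )
        for c in children:
            c.parent = parent
        lineages.append(parent)
    return SpeciesTree(lineages[0])


@dataclass
class SimulatedHistory:
    """Ground truth for a batch of simulated families."""

    tree: SpeciesTree
    origins: dict[str, str]  # family -> true origin node label
    losses: dict[str, set[str]]  # family -> child endpoints of lost branches
    matrix: pd.DataFrame  # families x leaves presence matrix
    family_table: FamilyTable
    params: dict = field(default_factory=dict)

    @property
    def families(self) -> list[str]:
        return list(self.matrix.index)


def _leaves_under(node: TreeNode) -> list[str]:
    return [n.label for n in node.preorder() if n.is_leaf]


def simulate_families(
    tree: SpeciesTree,
    n_families: int,
    loss_prob: float,
    seed: int,
    origin_weights: Optional[Mapping[str, float]] = None,
) -> SimulatedHistory:
    """Simulate ``n_families`` single-gain histories on ``tree``.

    Each family's origin node is sampled (uniformly over all nodes by
    default, or per ``origin_weights`` keyed by node label); every branch
    below the origin is lost independently with probability ``loss_prob``,
    pruning whole subtrees.  Families left with no surviving leaf are
    redrawn.  One member protein per surviving species is emitted, with ID
    ``<family>_<species>``.
    """
    if not (0.0 <= loss_prob < 1.0):
        raise ArgumentError("loss_prob must be in [0, 1)")
    if n_families < 0:
        raise ArgumentError("n_families must be nonnegative")
    rng = np.random.default_rng(seed)
    nodes = list(tree.root.preorder())
    labels = [n.label for n in nodes]
    if origin_weights is None:
        weights = np.ones(len(nodes))
    else:
        weights = np.array([float(origin_weights.get(l, 0.0)) for l in labels])
        if weights.sum() <= 0:
            raise ArgumentError("origin_weights sum to zero over tree nodes")
    weights = weights / weights.sum()

    leaves = tree.leaf_labels
    origins: dict[str, str] = {}
    losses: dict[str, set[str]] = {}
    rows: dict[str, list[int]] = {}
    table = FamilyTable()
    width = max(4, len(str(max(n_families, 1))))

    for i in range(n_families):
        fam = f"F{i + 1:0{width}d}"
        while True:
            origin = nodes[int(rng.choice(len(nodes), p=weights))]
            lost: set[str] = set()
            present: set[str] = set()
            stack = [origin]
            while stack:
                node = stack.pop()
                if node.is_leaf:
                    present.add(node.label)
                    continue
                for child in node.children:
                    if rng.random() < loss_prob:
                        lost.add(child.label)
                    else:
                        stack.append(child)
            if present:
                break
        origins[fam] = origin.label
        losses[fam] = lost
        rows[fam] = [1 if s in present else 0 for s in leaves]
        for sp in sorted(present):
            table.add(fam, sp, f"{fam}_{sp}")

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=leaves).astype(
        "int8"
    )
    return SimulatedHistory(
        tree=tree,
        origins=origins,
        losses=losses,
        matrix=matrix,
        family_table=table,
        params={
            "n_families": n_families,
            "loss_prob": loss_prob,
            "seed": seed,
        },
    )


def write_fixture_dir(history: SimulatedHistory, outdir: str) -> dict[str, str]:
    """Write tree, ages, family table, and truth table into ``outdir``.

    Returns the paths written.  Files: ``tree.nwk`` (Newick with branch
    lengths), ``node_ages.tsv``, ``families.tsv`` (3-column family table),
    ``truth.tsv`` (family, true origin, lost branches).
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tree": os.path.join(outdir, "tree.nwk"),
        "ages": os.path.join(outdir, "node_ages.tsv"),
        "families": os.path.join(outdir, "families.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    with open(paths["tree"], "w") as fh:
        fh.write(history.tree.to_newick() + "\n")
    with open(paths["ages"], "w") as fh:
        fh.write(history.tree.age_table())
    with open(paths["families"], "w") as fh:
        fh.write("#family\tspecies\tprotein\n")
        for fam in sorted(history.family_table.families):
            for sp, pid in sorted(history.family_table.families[fam]):
                fh.write(f"{fam}\t{sp}\t{pid}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("#family\ttrue_origin\tlost_branches\n")
        for fam in history.families:
            lost = ",".join(sorted(history.losses[fam]))
            fh.write(f"{fam}\t{history.origins[fam]}\t{lost}\n")
    return paths
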