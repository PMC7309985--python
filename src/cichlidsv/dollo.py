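"""Dollo-parsimony gain/loss reconstruction on a rooted, dated tree.

Each merged SV is a presence/absence character over the leaf species.  The
ancestral (root) state is absence — an SV is defined relative to the
reference genome, so presence is the derived state — and under Dollo
parsimony the derived state arises exactly once: the gain sits on the branch
subtending the most recent common ancestor of the present leaves, and one
loss is charged to each maximal subtree below it containing no present
leaf.  Branch durations (million years, MY) come from the user-supplied
newick tree; the net gain rate of a branch is (gains - losses) / MY.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .core import ConsensusSV

__all__ = [
    "PhyloTree",
    "GainLossReconstruction",
    "BranchSummary",
    "dollo_reconstruct",
    "per_branch_summary",
]


@dataclass(frozen=True)
class GainLossReconstruction:
    """One SV's inferred history: a single gain, zero or more losses."""

    gain_branch: str
    loss_branches: frozenset[str]

    @property
    def retained(self) -> bool:
        return not self.loss_branches


@dataclass(frozen=True)
class BranchSummary:
    branch: str
    length_my: float | None
    gains: int
    losses: int
    retained_gains: int
    net_gain_rate: float | None  # (gains - losses) / MY; None if undatable


class PhyloTree:
    """A rooted tree over the analyzed species with branch lengths in MY.

    Every node (including the root) identifies the branch subtending it.
    Branch identifiers are leaf names for terminal branches and the sorted
    leaf names joined with ``+`` for internal branches; the root branch
    represents the stem of the radiation.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        if tree.seed_node is None:
            raise ValueError("empty tree")
        self._tree = tree
        self.branch_id: dict[dendropy.Node, str] = {}
        self.node_of: dict[str, dendropy.Node] = {}
        self.leaves_below: dict[dendropy.Node, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None:
                    raise ValueError("leaf without a taxon label")
                leaves = frozenset({node.taxon.label})
            else:
                leaves = frozenset().union(
                    *(self.leaves_below[c] for c in node.child_nodes()))
            self.leaves_below[node] = leaves
            bid = (node.taxon.label if node.is_leaf()
                   else "+".join(sorted(leaves)))
            self.branch_id[node] = bid
            self.node_of[bid] = node
        self.leaves: frozenset[str] = self.leaves_below[tree.seed_node]
        self.root = tree.seed_node

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    def branch_length(self, branch: str) -> float | None:
        length = self.node_of[branch].edge.length
        return None if length is None else float(length)

    def branches(self) -> list[str]:
        """All branch ids in preorder (root stem first)."""
        return [self.branch_id[n] for n in self._tree.preorder_node_iter()]

    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        wanted = frozenset(species)
        unknown = wanted - self.leaves
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        node = self.root
        while True:
            for child in node.child_nodes():
                if wanted <= self.leaves_below[child]:
                    node = child
                    break
            else:
                return node


def dollo_reconstruct(presence: Iterable[str], tree: PhyloTree) -> GainLossReconstruction:
    """Place the single gain and the minimal loss set explaining ``presence``.

    The gain goes on the branch subtending the MRCA of the present leaves;
    each maximal clade below the MRCA with no present leaf receives one loss
    on its subtending branch.  This is the loss-minimal single-gain
    scenario.
    """
    present = frozenset(presence)
    if not present:
        raise ValueError("presence set must be non-empty")
    mrca = tree.mrca(present)
    losses: set[str] = set()

    def visit(node: dendropy.Node) -> None:
        below = tree.leaves_below[node]
        if not (below & present):
            losses.add(tree.branch_id[node])  # maximal absent clade
            return
        for child in node.child_nodes():
            visit(child)

    for child in mrca.child_nodes():
        visit(child)
    return GainLossReconstruction(tree.branch_id[mrca], frozenset(losses))


def per_branch_summary(
    svs: Sequence[ConsensusSV] | Mapping[str, Iterable[str]],
    tree: PhyloTree,
) -> list[BranchSummary]:
    """Tabulate gains, losses, retained gains and the net gain rate per branch.

    ``svs`` is either a sequence of consensus events or a mapping from event
    id to its presence set.  Branches without a length report the rate as
    None when they carry events.
    """
    if isinstance(svs, Mapping):
        presence_sets = {k: frozenset(v) for k, v in svs.items()}
    else:
        presence_sets = {sv.consensus_id: sv.species_present for sv in svs}

    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    retained: dict[str, int] = {}
    for pres in presence_sets.values():
        rec = dollo_reconstruct(pres, tree)
        gains[rec.gain_branch] = gains.get(rec.gain_branch, 0) + 1
        if rec.retained:
            retained[rec.gain_branch] = retained.get(rec.gain_branch, 0) + 1
        for b in rec.loss_branches:
            losses[b] = losses.get(b, 0) + 1

    out = []
    for branch in tree.branches():
        g = gains.get(branch, 0)
        lo = losses.get(branch, 0)
        length = tree.branch_length(branch)
        rate = None if not length else (g - lo) / length
        out.append(BranchSummary(branch, length, g, lo,
                                 retained.get(branch, 0), rate))
    return out


def branch_summary_frame(summaries: Sequence[BranchSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "branch": s.branch, "length_my": s.length_my, "gains": s.gains,
        "losses": s.losses, "retained_gains": s.retained_gains,
        "net_gain_rate": s.net_gain_rate,
    } for s in summaries])
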