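"""Ancestral TAP family sizes by asymmetric Wagner parsimony.

Family sizes are integer characters on a rooted species tree. A
branch from parent state ``s`` to child state ``t`` costs
``g * max(t - s, 0) + max(s - t, 0)``: every unit gained costs the
gain penalty ``g``, every unit lost costs 1. The reconstruction
minimises the total cost over all integer labelings of the internal
nodes (bounded Sankoff dynamic programming over states
``0..max_state``); the root state is free (no prior). Among
minimum-cost labelings every node takes the smallest optimal state in
a top-down pass, a deterministic, content-conservative tie-break.

Per-branch changes are then classified into four mutually exclusive
events: gain (0 -> >=1), loss (>=1 -> 0), expansion (increase between
non-zero counts) and contraction (decrease between non-zero counts).
Branch lengths are parsed and preserved but play no role in parsimony.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import dendropy

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "WagnerParams",
    "AncestralProfile",
    "EventSummary",
    "parse_newick",
    "tree_from_newick_string",
    "wagner_reconstruct",
    "brute_force_reconstruct",
    "classify_branch_events",
    "summarize_over_families",
]

PathLike = Union[str, Path]

EVENT_TYPES = ("gain", "loss", "expansion", "contraction")


@dataclass
class TreeNode:
    id: str
    label: str | None = None  # species code for leaves
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SpeciesTree:
    """Rooted tree with unique node ids; leaves labeled with species codes."""

    root: TreeNode

    def __post_init__(self) -> None:
        labels = [n.label for n in self.leaves()]
        dups = {x for x in labels if labels.count(x) > 1}
        if dups:
            raise ValueError(f"duplicate leaf labels: {sorted(dups)}")
        ids = [n.id for n in self.preorder()]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids")

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[TreeNode]:
        return list(reversed(self._reverse_postorder()))

    def _reverse_postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def parent_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for node in self.preorder():
            for child in node.children:
                out[child.id] = node.id
        return out

    def node_ids(self) -> list[str]:
        return [n.id for n in self.preorder()]

    def topology_hash(self) -> frozenset[frozenset[str]]:
        """The set of leaf-label clusters; equal for isomorphic rooted topologies."""
        clusters: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                c = frozenset([node.label or node.id])
            else:
                c = frozenset().union(*(walk(ch) for ch in node.children))
            clusters.add(c)
            return c

        walk(self.root)
        return frozenset(clusters)


def _from_dendropy(dtree: dendropy.Tree) -> SpeciesTree:
    counter = itertools.count()

    def convert(dnode) -> TreeNode:
        children = [convert(ch) for ch in dnode.child_nodes()]
        if children:
            node = TreeNode(id=f"N{next(counter)}", children=children)
        else:
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            label = label.replace(" ", "_")
            node = TreeNode(id=label, label=label)
        node.length = dnode.edge.length
        return node

    return SpeciesTree(root=convert(dtree.seed_node))


def parse_newick(path: PathLike) -> SpeciesTree:
    """Parse a rooted Newick tree; polytomies are preserved.

    Leaf labels become both node ids and species labels; internal
    nodes get deterministic ids N0, N1, ... in child-first order.
    """
    dtree = dendropy.Tree.get(path=str(path), schema="newick", suppress_internal_node_taxa=True)
    return _from_dendropy(dtree)


def tree_from_newick_string(newick: str) -> SpeciesTree:
    dtree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
    return _from_dendropy(dtree)


@dataclass
class WagnerParams:
    """Asymmetric Wagner parsimony parameters.

    ``gain_penalty`` is the cost of each unit increase; each unit
    decrease costs 1. The default of 1 mirrors the conventional
    default for asymmetric Wagner reconstruction of gene counts.
    ``max_state`` bounds the DP state space; None means
    max observed count + 2, which is sufficient slack for an optimum
    (an optimal labeling never needs states above the largest leaf
    count, and the slack is verified against the brute-force oracle).
    """

    gain_penalty: float = 1.0
    max_state: int | None = None

    def __post_init__(self) -> None:
        if self.gain_penalty <= 0:
            raise ValueError("gain_penalty must be > 0")


@dataclass
class AncestralProfile:
    """A complete labeling of the tree for one family, with its cost."""

    family: str
    node_counts: dict[str, int]
    total_cost: float


@dataclass
class EventSummary:
    """Per-branch event labels for one family, plus totals.

    Branches are keyed by their child node id. ``events`` carries one
    label per branch in {gain, loss, expansion, contraction, none}.
    """

    family: str
    events: dict[str, str]
    totals: dict[str, int]


def _branch_cost(s: int, t: int, g: float) -> float:
    return g * (t - s) if t >= s else float(s - t)


def _resolve_states(tree: SpeciesTree, leaf_counts: Mapping[str, int], params: WagnerParams):
    leaves = tree.leaf_labels()
    missing = [sp for sp in leaves if sp not in leaf_counts]
    if missing:
        raise KeyError(f"leaf counts missing for: {missing}")
    max_obs = max((leaf_counts[sp] for sp in leaves), default=0)
    max_state = params.max_state if params.max_state is not None else max_obs + 2
    if max_state < max_obs:
        raise ValueError(f"max_state={max_state} below max observed count {max_obs}")
    return max_state


def wagner_reconstruct(
    tree: SpeciesTree, leaf_counts: Mapping[str, int], params: WagnerParams, family: str = ""
) -> AncestralProfile:
    """Minimum-cost ancestral counts by bounded Sankoff DP.

    Bottom-up pass: for every node and state ``s``, the cheapest cost
    of its subtree given the node is in ``s``. Top-down pass: the root
    takes the smallest state achieving the global minimum; every child
    takes the smallest state minimising branch cost plus its subtree
    cost, given its parent's chosen state.
    """
    g = params.gain_penalty
    max_state = _resolve_states(tree, leaf_counts, params)
    n_states = max_state + 1
    INF = math.inf

    cost: dict[str, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = leaf_counts[node.label]  # type: ignore[index]
            cost[node.id] = [0.0 if s == c else INF for s in range(n_states)]
        else:
            row = [0.0] * n_states
            for child in node.children:
                child_cost = cost[child.id]
                for s in range(n_states):
                    row[s] += min(
                        _branch_cost(s, t, g) + child_cost[t] for t in range(n_states)
                    )
            cost[node.id] = row

    root_row = cost[tree.root.id]
    total = min(root_row)
    states: dict[str, int] = {}
    states[tree.root.id] = min(s for s in range(n_states) if root_row[s] == total)
    for node in tree.preorder():
        s = states[node.id]
        for child in node.children:
            child_cost = cost[child.id]
            best = min(_branch_cost(s, t, g) + child_cost[t] for t in range(n_states))
            states[child.id] = min(
                t
                for t in range(n_states)
                if _branch_cost(s, t, g) + child_cost[t] == best
            )
    return AncestralProfile(family=family, node_counts=states, total_cost=float(total))


_BRUTE_MAX_INTERNAL = 8
_BRUTE_MAX_STATE = 6


def brute_force_reconstruct(
    tree: SpeciesTree, leaf_counts: Mapping[str, int], params: WagnerParams, family: str = ""
) -> AncestralProfile:
    """Exhaustive-enumeration oracle for :func:`wagner_reconstruct`.

    Enumerates every internal labeling over ``0..max_state``, computes
    the same cost, and applies the same tie-break (lexicographically
    smallest internal states in preorder). The enumeration is
    vectorised (all labelings held as one array, branch costs looked
    up from a precomputed table) but remains exhaustive. Refuses
    instances beyond 8 internal nodes or max_state 6.
    """
    import numpy as np

    g = params.gain_penalty
    max_state = _resolve_states(tree, leaf_counts, params)
    internal = [n for n in tree.preorder() if not n.is_leaf]
    if len(internal) > _BRUTE_MAX_INTERNAL or max_state > _BRUTE_MAX_STATE:
        raise ValueError(
            f"instance too large for brute force ({len(internal)} internal nodes, "
            f"max_state {max_state})"
        )
    parent = tree.parent_map()
    leaf_state = {
        n.id: leaf_counts[n.label] for n in tree.leaves()  # type: ignore[index]
    }
    n_states = max_state + 1
    k = len(internal)
    idx_of = {n.id: i for i, n in enumerate(internal)}

    # all labelings, rows in lexicographic (itertools.product) order so
    # that argmin returns the lexicographically smallest optimum
    grids = np.meshgrid(*([np.arange(n_states)] * k), indexing="ij")
    assign = np.stack([gr.ravel() for gr in grids], axis=1)  # (n_states**k, k)

    s_grid, t_grid = np.meshgrid(np.arange(n_states), np.arange(n_states), indexing="ij")
    cost_table = np.where(
        t_grid >= s_grid, g * (t_grid - s_grid), (s_grid - t_grid).astype(float)
    )

    total = np.zeros(assign.shape[0])
    for child_id, parent_id in parent.items():
        ps = assign[:, idx_of[parent_id]]
        if child_id in idx_of:
            ts = assign[:, idx_of[child_id]]
            total += cost_table[ps, ts]
        else:
            total += cost_table[ps, leaf_state[child_id]]
    best_row = int(np.argmin(total))

    states = dict(leaf_state)
    for node, s in zip(internal, assign[best_row]):
        states[node.id] = int(s)
    return AncestralProfile(family=family, node_counts=states, total_cost=float(total[best_row]))


def classify_branch_events(tree: SpeciesTree, profile: AncestralProfile) -> EventSummary:
    """Label every branch with one of gain/loss/expansion/contraction/none.

    gain: 0 -> >=1; loss: >=1 -> 0; expansion: t > s >= 1;
    contraction: s > t >= 1; none: s == t. The labels are mutually
    exclusive: a 0 -> n branch is a gain, never also an expansion.
    """
    events: dict[str, str] = {}
    totals = {e: 0 for e in EVENT_TYPES}
    for child_id, parent_id in tree.parent_map().items():
        s = profile.node_counts[parent_id]
        t = profile.node_counts[child_id]
        if s == t:
            label = "none"
        elif s == 0 and t >= 1:
            label = "gain"
        elif s >= 1 and t == 0:
            label = "loss"
        elif t > s >= 1:
            label = "expansion"
        else:  # s > t >= 1
            label = "contraction"
        events[child_id] = label
        if label != "none":
            totals[label] += 1
    return EventSummary(family=profile.family, events=events, totals=totals)


def summarize_over_families(
    tree: SpeciesTree,
    summaries: Sequence[EventSummary],
    node_groups: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, dict[str, int]]:
    """Total event counts over all families, overall and per node group.

    ``node_groups`` maps a group label to node ids; a branch is
    attributed to its child node, so a group's subtotal counts the
    events on branches whose child lies in the group. Returns
    ``{"overall": {...}, <label>: {...}}`` with one count per event
    type.
    """
    valid = set(tree.node_ids())
    groups = dict(node_groups or {})
    for label, nodes in groups.items():
        unknown = [n for n in nodes if n not in valid]
        if unknown:
            raise KeyError(f"group {label!r} references unknown nodes: {unknown}")

    report: dict[str, dict[str, int]] = {"overall": {e: 0 for e in EVENT_TYPES}}
    for label in groups:
        report[label] = {e: 0 for e in EVENT_TYPES}
    for summary in summaries:
        for child_id, event in summary.events.items():
            if event == "none":
                continue
            report["overall"][event] += 1
            for label, nodes in groups.items():
                if child_id in set(nodes):
                    report[label][event] += 1
    return report
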