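"""Funnel clustering, superbasins and disconnectivity graphs.

Two complementary coarse-grainings of a landscape:

* **Superbasins** at an energy ceiling E: maximal sets of minima mutually
  connected through transition states with energy <= E (union-find over the
  TS-filtered edge set).  Raising the ceiling only merges blocks.

* **Threshold funnel clusters**: sets of minima that can interconvert
  without exceeding a fixed threshold above the set's LOWEST member.  The
  definition is self-referential, so clusters are grown greedily from seeds
  in ascending energy order: the globally lowest unassigned minimum seeds a
  cluster and claims every unassigned minimum reachable through transition
  states at or below seed energy + threshold.  Seeding in ascending order
  makes the seed provably the lowest member and the partition unique.

The disconnectivity graph stacks superbasin partitions at a descending
ladder of energy levels into a tree whose leaves are the minima — the
standard visual summary of which basins merge at which barriers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .ktn_io import KTN

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    members: list[int]
    seed: int            # lowest-energy member (ties: smaller id)
    seed_energy: float


@dataclass
class ClusterPartition:
    threshold: float
    clusters: list[Cluster]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def assignment(self) -> dict[int, int]:
        """Map minimum id -> cluster index."""
        return {m: c for c, cl in enumerate(self.clusters) for m in cl.members}


@dataclass
class TreeNode:
    level: int                    # index into DisconnectivityTree.levels
    members: frozenset[int]
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children and len(self.members) == 1


@dataclass
class DisconnectivityTree:
    levels: list[float]           # descending energy ceilings
    roots: list[TreeNode]
    leaves: dict[int, TreeNode]   # minimum id -> leaf node

    def nodes_at_level(self, level: int) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.level == level:
                out.append(node)
            for ch in node.children:
                if ch.level <= level:
                    walk(ch)

        for r in self.roots:
            walk(r)
        return [n for n in out if n.level == level]

    def to_json(self) -> str:
        nodes: list[dict] = []
        index: dict[int, int] = {}

        def walk(node: TreeNode, parent_idx: int | None) -> None:
            idx = len(nodes)
            index[id(node)] = idx
            nodes.append({
                "level": node.level,
                "parent": parent_idx,
                "n_members": len(node.members),
                "members": sorted(node.members) if len(node.members) <= 50 else None,
            })
            for ch in node.children:
                walk(ch, idx)

        for r in self.roots:
            walk(r, None)
        return json.dumps({"levels": self.levels, "nodes": nodes}, indent=1)


# ---------------------------------------------------------------------------
# Union-find partitions
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, a):
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def blocks(self) -> list[list[int]]:
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), []).append(x)
        out = [sorted(g) for g in groups.values()]
        out.sort(key=lambda g: (-len(g), g[0]))
        return out


def superbasins(
    ktn: KTN, energy_ceiling: float
) -> tuple[list[list[int]], set[int]]:
    """Partition minima into superbasins at an energy ceiling.

    Minima are in the same block iff connected through transition states at
    or below the ceiling.  Returns (blocks, inactive) where ``inactive`` are
    minima whose own energy lies above the ceiling (necessarily singleton
    blocks, flagged so renderers can mark them not-yet-born).
    """
    uf = _UnionFind(ktn.minima)
    for ts in ktn.transition_states:
        if ts.energy <= energy_ceiling:
            uf.union(ts.min1, ts.min2)
    inactive = {mid for mid, m in ktn.minima.items() if m.energy > energy_ceiling}
    return uf.blocks(), inactive


def threshold_clusters(ktn: KTN, threshold: float) -> ClusterPartition:
    """Greedy ascending-seed funnel clustering.

    Repeatedly seed at the globally lowest unassigned minimum and flood-fill
    unassigned minima reachable via transition states with
    E_TS <= E(seed) + threshold; ties on seed energy break by smaller id.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    order = sorted(ktn.minima.values(), key=lambda m: (m.energy, m.id))
    assigned: set[int] = set()
    clusters: list[Cluster] = []
    for seed in order:
        if seed.id in assigned:
            continue
        ceiling = seed.energy + threshold
        # traverse through any minimum below the ceiling (paths may pass
        # through already-claimed states), but claim only unassigned ones
        visited = {seed.id}
        frontier = [seed.id]
        while frontier:
            cur = frontier.pop()
            for ts in ktn.adjacency[cur]:
                if ts.energy > ceiling:
                    continue
                other = ts.min2 if ts.min1 == cur else ts.min1
                if other not in visited:
                    visited.add(other)
                    frontier.append(other)
        members = {m for m in visited if m not in assigned}
        assigned |= members
        clusters.append(
            Cluster(members=sorted(members), seed=seed.id,
                    seed_energy=seed.energy)
        )
    return ClusterPartition(threshold=threshold, clusters=clusters)


def cluster_representatives(partition: ClusterPartition) -> list[int]:
    """The 'selected minima': each cluster's lowest-energy member (its seed)."""
    return [c.seed for c in partition.clusters]


def disconnectivity_graph(
    ktn: KTN, n_levels: int, delta_E: float
) -> DisconnectivityTree:
    """Build a disconnectivity tree over a descending ladder of ceilings.

    Levels run from global-minimum energy + n_levels * delta_E downward in
    steps of delta_E; superbasins at consecutive levels are nested by
    inclusion and minima attach as leaves.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    if delta_E <= 0:
        raise ValueError("delta_E must be positive")
    energies = [m.energy for m in ktn.minima.values()]
    e_min = min(energies)
    span = max(energies) - e_min
    if delta_E > span and span > 0:
        logger.warning(
            "delta_E %.3g exceeds the landscape energy span %.3g; the tree "
            "degenerates to a single level", delta_E, span,
        )
    levels = [e_min + (n_levels - k) * delta_E for k in range(n_levels)]

    prev_nodes: dict[frozenset[int], TreeNode] = {}
    roots: list[TreeNode] = []
    for li, ceiling in enumerate(levels):
        blocks, _ = superbasins(ktn, ceiling)
        cur_nodes: dict[frozenset[int], TreeNode] = {}
        for block in blocks:
            key = frozenset(block)
            # reuse the parent node when the block did not split: the tree
            # records merge events, not every ladder rung
            parent = None
            for pkey, pnode in prev_nodes.items():
                if key <= pkey:
                    parent = pnode
                    break
            if parent is not None and parent.members == key:
                cur_nodes[key] = parent
                continue
            node = TreeNode(level=li, members=key, parent=parent)
            if parent is not None:
                parent.children.append(node)
            else:
                roots.append(node)
            cur_nodes[key] = node
        prev_nodes = cur_nodes

    leaves: dict[int, TreeNode] = {}
    for key, node in prev_nodes.items():
        for mid in key:
            if len(key) == 1:
                leaves[mid] = node
            else:
                leaf = TreeNode(level=len(levels) - 1,
                                members=frozenset([mid]), parent=node)
                node.children.append(leaf)
                leaves[mid] = leaf
    return DisconnectivityTree(levels=levels, roots=roots, leaves=leaves)


def write_tree_dump(tree: DisconnectivityTree, path) -> None:
    """Flat text dump (level, node, parent, n_members, members) for
    interoperability with existing disconnectivity plotters."""
    lines = ["# level node parent n_members members"]
    index: dict[int, int] = {}

    def walk(node: TreeNode, parent_idx) -> None:
        idx = len(index)
        index[id(node)] = idx
        members = ",".join(str(m) for m in sorted(node.members))
        lines.append(
            f"{node.level} {idx} "
            f"{-1 if parent_idx is None else parent_idx} "
            f"{len(node.members)} {members}"
        )
        for ch in node.children:
            walk(ch, idx)

    for r in tree.roots:
        walk(r, None)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def relative_energies(
    ktn: KTN, reference_id: int, ids: list[int] | None = None
) -> dict[int, float]:
    """Energies relative to a reference minimum (e.g. the deposited
    experimental structure, conventionally id 1)."""
    if reference_id not in ktn.minima:
        raise KeyError(f"reference minimum {reference_id} not in network")
    e_ref = ktn.energy(reference_id)
    if ids is None:
        ids = sorted(ktn.minima)
    return {mid: ktn.energy(mid) - e_ref for mid in ids}


def plot_disconnectivity(tree: DisconnectivityTree, ktn: KTN, ax=None):
    """Minimal disconnectivity-graph rendering (vertical energy axis).

    Requires matplotlib.  Leaves are ordered depth-first with larger basins
    first, which keeps crossings low for funnel-like landscapes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))

    xpos: dict[int, float] = {}
    counter = [0.0]

    def assign_x(node: TreeNode) -> float:
        if not node.children:
            mid = next(iter(node.members))
            x = counter[0]
            counter[0] += 1.0
            xpos[id(node)] = x
            ax.plot([x, x],
                    [tree.levels[node.level], ktn.energy(mid)], "k-", lw=0.6)
            return x
        kids = sorted(node.children, key=lambda c: -len(c.members))
        xs = [assign_x(c) for c in kids]
        x = sum(xs) / len(xs)
        xpos[id(node)] = x
        y = tree.levels[node.level]
        for c, cx in zip(kids, xs):
            ax.plot([x, cx], [y, tree.levels[c.level]], "k-", lw=0.6)
        return x

    for r in tree.roots:
        assign_x(r)
    ax.set_ylabel("energy / kcal mol$^{-1}$")
    ax.set_xticks([])
    return ax
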