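"""Counting independent tRNA-transfer events on a plasmid phylogeny.

Each tRNA type's presence/absence across plasmid leaves is mapped onto
the (possibly multifurcating, rooted) tree and the minimum number of
independent origins is computed by unit-cost Sankoff parsimony: gains
(0→1) and losses (1→0) each cost one, and a root reconstructed in the
"present" state counts as one gain, so any non-empty presence pattern
yields at least one origin. Among all minimum-cost ancestral labelings
the one with the fewest gains is reported, with deterministic
tie-breaking (prefer absence, preorder node order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy

INF = 10**9


@dataclass
class TransferEvents:
    """Per-tRNA-type minimum gain count and per-origin leaf sets."""

    trna_name: str
    gain_count: int
    loss_count: int
    total_cost: int
    origins: list[list[str]] = field(default_factory=list)


@dataclass
class TransferEventSet:
    per_trna: dict[str, TransferEvents] = field(default_factory=dict)

    @property
    def total_gains(self) -> int:
        return sum(e.gain_count for e in self.per_trna.values())


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def count_transfer_events(tree: dendropy.Tree,
                          presence: Mapping[str, Mapping[str, bool]] | Mapping[str, bool],
                          ) -> TransferEventSet:
    """Minimum independent gains for each tRNA type's presence pattern.

    ``presence`` maps tRNA type → {leaf label → bool} (a single flat
    {leaf → bool} map is treated as one unnamed type). Leaves absent from
    a type's map are scored absent; a leaf named in the map but missing
    from the tree raises ``KeyError`` naming the leaf.
    """
    if presence and not isinstance(next(iter(presence.values())), Mapping):
        presence = {"": presence}  # type: ignore[assignment]
    leaf_labels = {_leaf_label(l) for l in tree.leaf_node_iter()}
    out = TransferEventSet()
    for trna_name, pattern in presence.items():
        missing = sorted(set(pattern) - leaf_labels)
        if missing:
            raise KeyError(f"leaf {missing[0]!r} in presence map for "
                           f"{trna_name or 'capture'} is not on the tree")
        out.per_trna[trna_name] = _sankoff_min_gains(tree, dict(pattern), trna_name)
    return out


def _sankoff_min_gains(tree: dendropy.Tree, pattern: dict[str, bool],
                       trna_name: str) -> TransferEvents:
    # cost[node][state] = (total unit cost, gains) minimised lexicographically
    cost: dict[dendropy.Node, list[tuple[int, int]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = bool(pattern.get(_leaf_label(node), False))
            cost[node] = [(0, 0) if not state else (INF, INF),
                          (0, 0) if state else (INF, INF)]
        else:
            pair = []
            for s in (0, 1):
                tot = (0, 0)
                for child in node.child_nodes():
                    best = None
                    for t in (0, 1):
                        c_cost, c_gain = cost[child][t]
                        if c_cost >= INF:
                            continue
                        edge = int(s != t)
                        gain = int(s == 0 and t == 1)
                        cand = (c_cost + edge, c_gain + gain)
                        if best is None or cand < best:
                            best = cand
                    tot = (tot[0] + best[0], tot[1] + best[1])
                pair.append(tot)
            cost[node] = pair
    root = tree.seed_node
    # a root in state 1 is itself an origin: one gain, one unit of cost
    root_options = {
        0: cost[root][0],
        1: (cost[root][1][0] + 1, cost[root][1][1] + 1),
    }
    # lexicographic (cost, gains), tie prefers absence at the root
    root_state = min((0, 1), key=lambda s: (root_options[s], s))
    total_cost, gains = root_options[root_state]

    # backtrack one optimal labeling, preferring absence at each node
    labeling: dict[dendropy.Node, int] = {root: root_state}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        s = labeling[node.parent_node]
        if node.is_leaf():
            labeling[node] = bool(pattern.get(_leaf_label(node), False))
            continue
        best_t, best_key = None, None
        for t in (0, 1):
            c_cost, c_gain = cost[node][t]
            if c_cost >= INF:
                continue
            key = ((c_cost + int(s != t), c_gain + int(s == 0 and t == 1)), t)
            if best_key is None or key < best_key:
                best_t, best_key = t, key
        labeling[node] = best_t

    # origins: each gain edge (or a present root) roots one origin; captured
    # leaves attach to the nearest gain above them
    origins: dict[dendropy.Node, list[str]] = {}
    gain_nodes: dict[dendropy.Node, dendropy.Node] = {}
    n_loss = 0
    for node in tree.preorder_node_iter():
        s = labeling[node]
        parent = node.parent_node
        if parent is None:
            if s == 1:
                origins[node] = []
                gain_nodes[node] = node
        else:
            ps = labeling[parent]
            if ps == 0 and s == 1:
                origins[node] = []
                gain_nodes[node] = node
            elif ps == 1 and s == 0:
                n_loss += 1
            elif s == 1:
                gain_nodes[node] = gain_nodes[parent]
        if node.is_leaf() and s == 1:
            origins[gain_nodes[node]].append(_leaf_label(node))

    return TransferEvents(
        trna_name=trna_name, gain_count=gains, loss_count=n_loss,
        total_cost=total_cost,
        origins=sorted((sorted(v) for v in origins.values())))
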