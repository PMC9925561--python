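"""Tree utilities: a distance-based stand-in for the ML phylogeny step.

The analysis accepts an externally inferred tree (newick with bootstrap
supports as internal-node labels). When none is supplied, a
neighbor-joining tree on Poisson-corrected protein distances over the
concatenated polymerase alignments serves as a stand-in so that
transfer-event counting is runnable end to end. Midpoint rooting
approximates the root (there is no close outgroup for these plasmids),
and internal nodes below a support threshold can be collapsed into
polytomies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np


@dataclass
class Alignment:
    """Equal-length aligned rows keyed by ordered ids; gap character '-'."""

    ids: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]


def concat_alignments(a: Alignment, b: Alignment) -> Alignment:
    """Row-wise concatenation of two alignments over the same id set."""
    if set(a.ids) != set(b.ids):
        only_a = sorted(set(a.ids) - set(b.ids))
        only_b = sorted(set(b.ids) - set(a.ids))
        raise ValueError(f"id sets differ: only in first {only_a}, only in second {only_b}")
    rows = [a.row(i) + b.row(i) for i in a.ids]
    parts = [("first", 0, a.n_cols), ("second", a.n_cols, a.n_cols + b.n_cols)]
    return Alignment(ids=list(a.ids), rows=rows, partitions=parts)


def filter_columns(aln: Alignment, max_gap_fraction: float) -> Alignment:
    """Keep columns whose gap fraction is <= the threshold; order preserved."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    n = len(aln.rows)
    keep = [j for j in range(aln.n_cols)
            if sum(r[j] == "-" for r in aln.rows) / n <= max_gap_fraction]
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    return Alignment(ids=list(aln.ids), rows=rows)


def protein_distance(aln: Alignment, poisson: bool = True) -> np.ndarray:
    """Pairwise p-distance over mutually ungapped columns (optionally −ln(1−p))."""
    if len(aln.rows) < 2:
        raise ValueError("need at least two rows")
    n = len(aln.rows)
    arr = np.array([list(r) for r in aln.rows])
    gap = arr == "-"
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        shared = ~gap[i] & ~gap[j]
        m = int(shared.sum())
        if m == 0:
            raise ValueError(f"rows {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                             "ungapped columns; distance undefined")
        p = float((arr[i, shared] != arr[j, shared]).sum()) / m
        if poisson:
            if p >= 1.0:
                raise ValueError("p-distance of 1; Poisson correction undefined")
            d = -math.log(1.0 - p)
        else:
            d = p
        D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# Neighbor joining (deterministic lexicographic tie-break)


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Standard NJ on a symmetric zero-diagonal matrix; exact on additive input."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(labels) != n:
        raise ValueError("labels must match the matrix dimension")

    nodes = [f"{_quote(l)}" for l in labels]  # newick fragments
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def d(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))] if i != j else 0.0

    frag = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        m = len(active)
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12 or (
                        abs(q - best_q) <= 1e-12 and (i, j) < best):
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(new, k), max(new, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        frag[new] = f"({frag[i]}:{li:.10g},{frag[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [new]
    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    newick = (f"({frag[i]}:{max(li,0):.10g},{frag[j]}:{max(lj,0):.10g},"
              f"{frag[k]}:{max(lk,0):.10g});")
    return read_newick_string(newick)


def _quote(label: str) -> str:
    return label.replace(" ", "_")


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read newick; internal-node labels are kept as support values."""
    return dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def read_newick_string(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def node_support(node: dendropy.Node, default: float = 100.0) -> float:
    """Bootstrap support of an internal node, parsed from its label."""
    if node.label is None:
        return default
    try:
        return float(node.label)
    except ValueError:
        return default


# ---------------------------------------------------------------------------
# rooting and collapsing


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root halfway along the longest leaf-to-leaf path."""
    tree = tree.clone(depth=1)
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    total = sum(e.length or 0.0 for e in tree.edges())
    if total == 0.0:
        tree.is_rooted = True
        import logging
        logging.getLogger(__name__).warning(
            "zero-length tree: midpoint root placed arbitrarily")
        return tree
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def collapse_low_support(tree: dendropy.Tree, threshold: float = 95.0,
                         missing_support: float = 100.0) -> dendropy.Tree:
    """Contract internal edges whose child support is strictly below threshold.

    Leaf set and path lengths between retained nodes are unchanged;
    collapsed edges donate their length to the resulting polytomy edges
    (dendropy adds the removed edge's length to its children).
    """
    tree = tree.clone(depth=1)
    to_collapse = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if node_support(node, default=missing_support) < threshold:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse(adjust_collapsed_head_children_edge_lengths=True)
    return tree
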