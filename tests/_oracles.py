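"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: plain-Python dynamic
programming, codon-by-codon scanning and exhaustive enumeration, kept
slow and obvious.
"""

from __future__ import annotations

import itertools

NEG = -(10 ** 9)


def sw_best_score(q: str, s: str, match: int = 2, mismatch: int = -3,
                  gap_open: int = 5, gap_extend: int = 2) -> int:
    """Optimal local alignment score with affine gaps (gap k costs open+k*ext)."""
    m, n = len(q), len(s)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = match if q[i - 1] == s[j - 1] else mismatch
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def orf_scan(seq: str, codon_to_aa: dict[str, str], min_nt: int):
    """Stop-to-stop ORFs on both strands by explicit codon walking.

    Returns a set of (start, end, strand) in forward-strand half-open
    coordinates.
    """
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            run_start = frame
            pos = frame
            while pos + 3 <= L:
                codon = s[pos: pos + 3]
                aa = codon_to_aa.get(codon, "X") if "N" not in codon else "X"
                if aa == "*":
                    if pos - run_start >= min_nt:
                        out.add(_fwd(run_start, pos, strand, L))
                    run_start = pos + 3
                pos += 3
            if pos - run_start >= min_nt and pos > run_start:
                out.add(_fwd(run_start, pos, strand, L))
    return out


def _fwd(a: int, b: int, strand: str, L: int):
    return (a, b, strand) if strand == "+" else (L - b, L - a, strand)


def sankoff_enumerate(children: dict[int, list[int]], root: int,
                      leaf_state: dict[int, int]) -> tuple[int, int]:
    """Exhaustive minimum over internal labelings of (unit cost, gains).

    Gains are parent 0 → child 1 edges plus a root in state 1; losses are
    1 → 0 edges; both cost one unit. Returns (min cost, min gains among
    min-cost labelings).
    """
    internal = [n for n in children if children[n]]
    best = None
    for states in itertools.product((0, 1), repeat=len(internal)):
        lab = dict(zip(internal, states))
        lab.update(leaf_state)
        cost = gains = 0
        if lab[root] == 1:
            cost += 1
            gains += 1
        stack = [root]
        while stack:
            node = stack.pop()
            for ch in children[node]:
                if lab[node] != lab[ch]:
                    cost += 1
                    if lab[ch] == 1:
                        gains += 1
                stack.append(ch)
        key = (cost, gains)
        if best is None or key < best:
            best = key
    return best


def random_tree_table(rng, n_leaves: int):
    """A random rooted tree as (children, root, leaf ids); polytomies allowed."""
    nodes = list(range(n_leaves))
    children: dict[int, list[int]] = {i: [] for i in nodes}
    next_id = n_leaves
    frontier = nodes[:]
    while len(frontier) > 1:
        k = min(len(frontier), int(rng.integers(2, 4)))
        picks = [frontier.pop(int(rng.integers(len(frontier)))) for _ in range(k)]
        children[next_id] = picks
        frontier.append(next_id)
        next_id += 1
    return children, frontier[0], nodes


def tree_table_to_newick(children: dict[int, list[int]], root: int) -> str:
    def fmt(n: int) -> str:
        if not children[n]:
            return f"L{n}"
        return "(" + ",".join(fmt(c) for c in children[n]) + ")"

    return fmt(root) + ";"
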