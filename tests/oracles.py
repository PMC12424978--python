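"""Independent brute-force oracles used to validate the optimized
implementations. Kept deliberately naive: position-by-position scans and
explicit branch enumeration, sharing no code path with the package
internals they check."""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_mismatches(pattern: str, window: str) -> int:
    return sum(1 for p, w in zip(pattern, window) if w not in IUPAC_SETS[p])


def brute_force_sites(contig: str, primer: str, max_mismatch: int,
                      terminal_exact: int) -> list[tuple[int, str, int]]:
    """All (position, strand, mismatches) primer sites by exhaustive scan."""
    k = len(primer)
    t = min(terminal_exact, k)
    out = []
    for pos in range(len(contig) - k + 1):
        win = contig[pos:pos + k]
        # '+': primer against top-strand window, 3' end = window's right end
        m = naive_mismatches(primer, win)
        if m <= max_mismatch and naive_mismatches(primer[-t:], win[-t:]) == 0:
            out.append((pos, "+", m))
        # '-': primer against reverse complement of the window
        rc_win = revcomp(win)
        m = naive_mismatches(primer, rc_win)
        if m <= max_mismatch and naive_mismatches(primer[-t:], rc_win[-t:]) == 0:
            out.append((pos, "-", m))
    out.sort()
    return out


def enumerate_unifrac(tree, x: dict, y: dict, weighted: bool) -> float:
    """UniFrac by explicit per-branch descendant-leaf-set enumeration."""
    at = sum(x.values())
    bt = sum(y.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = {tip.name for tip in node.tips(include_self=True)}
        a = sum(x.get(l, 0) for l in leaves)
        b = sum(y.get(l, 0) for l in leaves)
        if weighted:
            num += length * abs(a / at - b / bt)
        else:
            pa, pb = a > 0, b > 0
            if pa != pb:
                num += length
            if pa or pb:
                den += length
    return num if weighted else (num / den if den else 0.0)


def random_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with random branch lengths over leaves L0..L{n-1}."""
    from skbio import TreeNode
    nodes = []
    for i in range(n_leaves):
        leaf = TreeNode(name=f"L{i}")
        leaf.length = float(rng.uniform(0.05, 1.0))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.05, 1.0))
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    root = nodes[0]
    root.length = None
    return root
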