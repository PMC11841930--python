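"""Independent brute-force oracles, kept deliberately separate from the
implementation paths they check."""

from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = _BLOSUM.alphabet
OPEN, EXTEND = -10.0, -1.0


def _sub(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_BLOSUM[_ALPHA.index(a), _ALPHA.index(b)])


def align_score_oracle(s: str, t: str) -> float:
    """Optimal global affine-gap score by memoized exhaustive recursion.

    Gap of length k costs OPEN + (k-1)*EXTEND; terminal gaps penalized.
    """

    @lru_cache(maxsize=None)
    def f(i: int, j: int, prev: str) -> float:
        if i == len(s) and j == len(t):
            return 0.0
        best = float("-inf")
        if i < len(s) and j < len(t):
            best = max(best, _sub(s[i], t[j]) + f(i + 1, j + 1, "m"))
        if i < len(s):
            best = max(best, (EXTEND if prev == "u" else OPEN) + f(i + 1, j, "u"))
        if j < len(t):
            best = max(best, (EXTEND if prev == "l" else OPEN) + f(i, j + 1, "l"))
        return best

    result = f(0, 0, "m")
    f.cache_clear()
    return result


def nes_oracle(sequence: str) -> list[tuple[int, int, int]]:
    """All (start, spacer1, spacer2) NES hits by regex per spacer combination."""
    hits = []
    for s1, s2 in itertools.product((2, 3), (2, 3)):
        pattern = re.compile(
            "(?=([LIVFM].{%d}[LIVFM].{%d}[LIVFM].[LIVFM]))" % (s1, s2)
        )
        for m in pattern.finditer(sequence.upper()):
            hits.append((m.start() + 1, s1, s2))
    return sorted(hits)


def parsimony_oracle(children: dict[str, list[str]], root: str,
                     leaf_states: dict[str, str]) -> int:
    """Minimum changes by exhaustive enumeration over internal labelings.

    ``children`` maps internal node name -> child names (leaves are names
    present in leaf_states).
    """
    internal = list(children)
    states = sorted(set(leaf_states.values()))
    best = float("inf")
    for combo in itertools.product(states, repeat=len(internal)):
        labels = dict(zip(internal, combo))
        labels.update(leaf_states)
        changes = sum(
            1
            for parent, kids in children.items()
            for k in kids
            if labels[parent] != labels[k]
        )
        best = min(best, changes)
    return int(best)


def random_tree(rng: np.random.Generator, n_leaves: int,
                polytomy_p: float = 0.3) -> tuple[str, dict[str, list[str]], str]:
    """Random rooted tree: newick, children map, root name.

    Merges 2 (or sometimes 3, producing polytomies) subtrees at a time.
    """
    nodes = [f"L{i}" for i in range(n_leaves)]
    newicks = {n: n for n in nodes}
    children: dict[str, list[str]] = {}
    counter = 0
    while len(nodes) > 1:
        k = 3 if (len(nodes) >= 3 and rng.random() < polytomy_p) else 2
        picks = list(rng.choice(len(nodes), size=k, replace=False))
        merged = [nodes[i] for i in sorted(picks)]
        for i in sorted(picks, reverse=True):
            nodes.pop(i)
        name = f"I{counter}"
        counter += 1
        children[name] = merged
        newicks[name] = "(" + ",".join(newicks[m] for m in merged) + ")" + name
        nodes.append(name)
    root = nodes[0]
    return newicks[root] + ";", children, root


def kabsch_rmsd_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Best-proper-rotation RMSD by direct numeric minimization over
    Euler angles (multi-start), independent of any SVD decomposition."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(angles: np.ndarray) -> float:
        R = Rotation.from_euler("zyx", angles).as_matrix()
        d = a - b @ R.T
        return float(np.mean(np.sum(d * d, axis=1)))

    best = float("inf")
    rng = np.random.default_rng(0)
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(20)]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best))
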