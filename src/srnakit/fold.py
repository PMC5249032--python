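"""RNA secondary structure by base-pair maximization.

Hairpin precursors are folded with a Nussinov-style dynamic program that
maximizes the total weight of nested base pairs (Watson-Crick pairs weight
1, G:U wobbles a configurable weight, default 1) subject to a minimum
hairpin loop of `min_loop` unpaired nucleotides.  Base-pair maximization is
used instead of free-energy minimization deliberately: it is dependency-free
and exactly checkable against exhaustive enumeration on short sequences,
and a thermodynamic folder can be substituted behind the same interface.

The traceback is deterministic: at each interval the 5'-most position is
resolved first, and when it pairs, the 3'-most co-optimal partner is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# A=0, C=1, G=2, T/U=3; code sums identify pair classes:
# Watson-Crick (A:T, C:G) sum to 3, the G:U wobble sums to 5.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

_EPS = 1e-9


def pair_weights(seq: str, gu_weight: float = 1.0) -> np.ndarray:
    """Symmetric matrix of pairing weights between sequence positions."""
    codes = np.array([_CODE.get(c, -10) for c in seq])
    s = codes[:, None] + codes[None, :]
    w = np.zeros((len(seq), len(seq)))
    w[s == 3] = 1.0
    w[s == 5] = gu_weight
    return w


@dataclass
class FoldResult:
    """A nested secondary structure over one sequence.

    ``partner[i]`` is the paired position of ``i`` or −1 when unpaired;
    ``score`` is the maximized total pair weight (equal to the pair count
    when all weights are 1).
    """

    sequence: str
    partner: np.ndarray
    score: float

    @property
    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.partner >= 0) // 2)

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner):
            out.append("." if j < 0 else "(" if j > i else ")")
        return "".join(out)


def fold_back(seq: str, min_loop: int = 3, gu_weight: float = 1.0) -> FoldResult:
    """Maximum-weight nested pairing of ``seq``.

    The DP is vectorized over anti-diagonals; worst case O(n^3) time and
    O(n^2) memory, comfortably fast for the ±150 nt precursor windows this
    package folds.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if n == 0:
        return FoldResult(seq, np.empty(0, dtype=int), 0.0)
    pw = pair_weights(seq, gu_weight)
    W = np.zeros((n, n))
    # D[d][i] == W[i, i+d], stored per diagonal for contiguous slicing
    D: list[np.ndarray] = [np.zeros(n)]
    idx = np.arange(n)
    for d in range(1, n):
        m = n - d
        cur = D[d - 1][:m].copy()                     # j unpaired
        np.maximum(cur, D[d - 1][1:m + 1], out=cur)   # i unpaired
        for t in range(1, d - 1):                     # bifurcation at i+t
            np.maximum(cur, D[t][:m] + D[d - 1 - t][t + 1:t + 1 + m], out=cur)
        if d >= min_loop + 1:
            inner = D[d - 2][1:1 + m] if d >= 2 else np.zeros(m)
            w_ij = pw[idx[:m], idx[:m] + d]
            cand = inner + w_ij
            # where w_ij == 0 the candidate equals W[i+1,j-1] <= cur: harmless
            np.maximum(cur, cand, out=cur)
        D.append(cur)
        W[idx[:m], idx[:m] + d] = cur

    partner = np.full(n, -1, dtype=int)
    _traceback(W, pw, partner, min_loop)
    return FoldResult(seq, partner, float(W[0, n - 1]))


def _traceback(W: np.ndarray, pw: np.ndarray, partner: np.ndarray, min_loop: int) -> None:
    n = W.shape[0]

    def w_at(a: int, b: int) -> float:
        return W[a, b] if a < b else 0.0

    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target = W[i, j]
            if target <= _EPS:
                break
            # resolve the 5'-most position i: paired (3'-most partner) or not
            found = False
            for k in range(j, i + min_loop, -1):
                if pw[i, k] <= 0:
                    continue
                if pw[i, k] + w_at(i + 1, k - 1) + w_at(k + 1, j) >= target - _EPS:
                    partner[i] = k
                    partner[k] = i
                    if k + 1 < j:
                        stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    found = True
                    break
            if not found:
                i += 1
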