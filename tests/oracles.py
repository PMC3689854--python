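"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or by an
independent route (naive scans, top-down memoized recursion, Biopython's
pairwise aligner) and never calls the implementation path it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


# ---------------------------------------------------------------------------
# assembly oracles


def overlap_oracle(a: str, b: str, min_overlap: int):
    """Longest suffix(a)==prefix(b) by scanning every length; 'contained'
    when one string is a substring of the other."""
    if b in a or a in b:
        return "contained"
    for L in range(min(len(a), len(b)) - 1, min_overlap - 1, -1):
        if a[-L:] == b[:L]:
            return L
    return None


def greedy_assemble_oracle(seqs: list[str], min_overlap: int) -> list[str]:
    """Greedy merge by repeated full rescans: containment absorbed first,
    then the longest overlap, ties toward the lexicographically smallest
    merged sequence.  Mirrors the documented greedy rule but recomputes
    everything from scratch each round."""
    pool = sorted(seqs)
    while len(pool) > 1:
        best = None  # (rank key, i, j, kind)
        for i, a in enumerate(pool):
            for j, b in enumerate(pool):
                if i == j:
                    continue
                r = overlap_oracle(a, b, min_overlap)
                if r is None:
                    continue
                if r == "contained":
                    if len(b) > len(a):
                        continue
                    cand = ((0, a, b), i, j, "contained")
                else:
                    merged = a + b[r:]
                    cand = ((1, -r, merged, a, b), i, j, r)
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is None:
            break
        _, i, j, kind = best
        a, b = pool[i], pool[j]
        merged = a if kind == "contained" else a + b[kind:]
        pool = [s for k, s in enumerate(pool) if k not in (i, j)] + [merged]
    return sorted(pool)


# ---------------------------------------------------------------------------
# alignment oracles


def _pair_score(a: str, b: str, match: float, wobble: float, mismatch: float):
    if (a, b) in WC:
        return match
    if (a, b) in WOBBLE:
        return wobble
    return mismatch


def align_score_recursive(
    top: str,
    rbot: str,
    match: float = 2.0,
    wobble: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Maximum global alignment score by top-down memoized recursion over
    (i, j, state of the previous column)."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def fwd(i: int, j: int, state: str) -> float:
        """Best score of aligning top[:i] with rbot[:j] where the last
        emitted column has the given state."""
        if state == "M":
            if i == 0 or j == 0:
                return NEG
            s = _pair_score(top[i - 1], rbot[j - 1], match, wobble, mismatch)
            if i == 1 and j == 1:
                return s
            return s + max(fwd(i - 1, j - 1, t) for t in "MXY")
        if state == "X":
            if i == 0:
                return NEG
            if i == 1 and j == 0:
                return gap_open
            prevs = []
            for t in "MXY":
                v = fwd(i - 1, j, t)
                if v > NEG:
                    prevs.append(v + (gap_extend if t == "X" else gap_open))
            return max(prevs) if prevs else NEG
        if j == 0:
            return NEG
        if j == 1 and i == 0:
            return gap_open
        prevs = []
        for t in "MXY":
            v = fwd(i, j - 1, t)
            if v > NEG:
                prevs.append(v + (gap_extend if t == "Y" else gap_open))
        return max(prevs) if prevs else NEG

    n, m = len(top), len(rbot)
    return max(fwd(n, m, t) for t in "MXY")


def enumerate_alignments_score(
    top: str,
    rbot: str,
    match: float = 2.0,
    wobble: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Complete enumeration of every gapped alignment (no memoization),
    scoring affine runs; feasible up to ~5 nt per side."""
    best = [float("-inf")]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(top) and j == len(rbot):
            if score > best[0]:
                best[0] = score
            return
        if i < len(top) and j < len(rbot):
            s = _pair_score(top[i], rbot[j], match, wobble, mismatch)
            rec(i + 1, j + 1, "M", score + s)
        if i < len(top):
            rec(i + 1, j, "X",
                score + (gap_extend if prev == "X" else gap_open))
        if j < len(rbot):
            rec(i, j + 1, "Y",
                score + (gap_extend if prev == "Y" else gap_open))

    rec(0, 0, "", 0.0)
    return best[0]


def overhang_align_oracle(top: str, bottom: str, core_scorer, max_overhang=2):
    """Best score over all 3'-overhang strip assignments, delegating the
    core global alignment to ``core_scorer(top_core, rbot_core)``."""
    rbot = bottom[::-1]
    best = float("-inf")
    for ot in range(max_overhang + 1):
        for ob in range(max_overhang + 1):
            core_top = top[: len(top) - ot] if ot else top
            core_rbot = rbot[ob:]
            if not core_top or not core_rbot:
                continue
            s = core_scorer(core_top, core_rbot)
            if s > best:
                best = s
    return best


def biopython_core_scorer(match=2.0, wobble=1.0, mismatch=-1.0,
                          gap_open=-5.0, gap_extend=-2.0):
    """Independent affine-gap global aligner built on Bio.Align with a
    complementarity substitution matrix."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    alphabet = "ACGU"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = _pair_score(a, b, match, wobble, mismatch)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    def score(top: str, rbot: str) -> float:
        return float(aligner.score(top, rbot))

    return score


# ---------------------------------------------------------------------------
# profile scoring oracle


def score_pattern_oracle(states: str, profile) -> float:
    """Sum over positions j of the max transition cell over ALL prior non-M
    positions, enumerating every (i, j) pair explicitly."""
    total = 0.0
    for j, st_j in enumerate(states):
        if st_j == "M":
            continue
        cells = [
            profile.cell(st_i, st_j, i, j)
            for i, st_i in enumerate(states[:j])
            if st_i != "M"
        ]
        if cells:
            total += max(cells)
    return total


# ---------------------------------------------------------------------------
# decision-tree split oracle


def best_split_oracle(X, y, w=None):
    """Exhaustive enumeration of every (feature, midpoint) binary split,
    returning (gain, feature, threshold) with the same deterministic
    tie-break (lower feature, lower threshold)."""
    import numpy as np

    X = np.asarray(X, float)
    y = np.asarray(y, int)
    w = np.ones(len(y)) if w is None else np.asarray(w, float)

    def gini_total(mask):
        ww = w[mask]
        tot = ww.sum()
        if tot <= 0:
            return 0.0
        p = ww[y[mask] == 1].sum() / tot
        return tot * (1 - p * p - (1 - p) * (1 - p))

    parent = gini_total(np.ones(len(y), bool))
    best = None  # (gain, feature, threshold)
    for f in range(X.shape[1]):
        vals = sorted(set(X[:, f]))
        for lo, hi in zip(vals, vals[1:]):
            thr = float((lo + hi) / 2)
            left = X[:, f] <= thr
            gain = float(max(parent - gini_total(left) - gini_total(~left), 0.0))
            if (
                best is None
                or gain > best[0] + 1e-12
                or (abs(gain - best[0]) <= 1e-12 and (f, thr) < best[1:])
            ):
                best = (gain, f, thr)
    return best
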