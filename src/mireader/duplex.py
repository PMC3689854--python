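"""Complementarity alignment of contig pairs into miRNA-like duplexes.

A mature miRNA duplex is the ~21-nt double-stranded Dicer product: the mature
strand paired, imperfectly, with its star (*) strand, typically leaving 2-nt
3' overhangs.  Partners are found by global alignment of one contig (written
5'->3') against the reverse of the other (so the bottom strand reads 3'->5'
under the top), scoring complementarity per column: Watson-Crick pairs (A:U,
G:C) as matches, the thermodynamically stable G:U wobble as a weaker match,
anything else as a mismatch.  Gaps are affine (open -5, extend -2); up to two
nucleotides at each strand's 3' terminus may be left unpaired free of charge,
reproducing Dicer-product overhang geometry (5' ends stay flush).

Each accepted duplex is re-expressed as a single pattern over the four
pairing states {M, X, I, D} — match (incl. wobble), mismatch, insertion
(gap in the star strand), deletion (gap in the top strand) — discarding
nucleotide identity.  These encoded patterns are the classifier's input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .assembly import Contig

NEG_INF = float("-inf")

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Column scores for complementarity alignment.

    Gap penalties follow the source convention: -5 charged on the first
    column of a gap run, -2 on each subsequent column.  ``max_overhang``
    unpenalised nucleotides are allowed at each strand's 3' end.
    """

    match_score: float = 2.0
    wobble_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    max_overhang: int = 2

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.max_overhang not in (0, 1, 2):
            raise ValueError("max_overhang must be 0, 1 or 2")

    def pair_score(self, a: str, b: str) -> float:
        if (a, b) in WATSON_CRICK:
            return self.match_score
        if (a, b) in WOBBLE:
            return self.wobble_score
        return self.mismatch_score


@dataclass(frozen=True)
class EncodedPattern:
    """Pairing-state string over the alphabet {M, X, I, D}."""

    states: str

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("empty pattern")
        bad = set(self.states) - set("MXID")
        if bad:
            raise ValueError(f"invalid pattern states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    def __str__(self) -> str:
        return self.states


@dataclass
class DuplexCandidate:
    """An aligned contig pair with its score, overhangs and encoded pattern.

    ``aligned_bottom`` is written 3'->5' so it sits base-by-base under
    ``aligned_top`` (5'->3').  The leading ``overhang_bottom3`` and trailing
    ``overhang_top3`` columns are unpaired 3' overhangs, excluded from the
    pattern.
    """

    top_id: str
    bottom_id: str
    aligned_top: str
    aligned_bottom: str
    score: float
    overhang_top3: int
    overhang_bottom3: int
    pattern: Optional[EncodedPattern] = None
    top_count: int = 0
    bottom_count: int = 0

    @property
    def paired_columns(self) -> int:
        return len(self.aligned_top) - self.overhang_top3 - self.overhang_bottom3


def _gotoh(top: str, rbot: str, s: ScoringScheme):
    """Affine-gap global alignment of ``top`` vs ``rbot`` with traceback.

    Returns (score, aligned_top, aligned_rbot).  Three-state Gotoh: M ends in
    a paired column, X in a gap-in-bottom column (top base unpaired -> state
    I downstream), Y in a gap-in-top column (state D).  Traceback prefers
    paired columns, then gap-in-bottom, which yields a deterministic,
    left-normalised gap placement among co-optimal alignments.
    """
    n, m = len(top), len(rbot)
    open_, ext = s.gap_open, s.gap_extend
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        ti = top[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            sc = s.pair_score(ti, rbot[j - 1])
            Mi[j] = sc + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] + open_, Xp[j] + ext, Yp[j] + open_)
            Yi[j] = max(Mi[j - 1] + open_, Xi[j - 1] + open_, Yi[j - 1] + ext)
    end_scores = (M[n][m], X[n][m], Y[n][m])
    best = max(end_scores)

    # traceback; state preference M > X > Y for determinism
    at, ab = [], []
    i, j = n, m
    state = "MXY"[end_scores.index(best)]
    while i > 0 or j > 0:
        if state == "M":
            sc = s.pair_score(top[i - 1], rbot[j - 1])
            at.append(top[i - 1])
            ab.append(rbot[j - 1])
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            target = M[i][j] - sc
            state = "MXY"[_index_close(prev, target)]
            i, j = i - 1, j - 1
        elif state == "X":
            at.append(top[i - 1])
            ab.append(GAP)
            cand = (M[i - 1][j] + s.gap_open, X[i - 1][j] + ext,
                    Y[i - 1][j] + s.gap_open)
            state = "MXY"[_index_close(cand, X[i][j])]
            i -= 1
        else:
            at.append(GAP)
            ab.append(rbot[j - 1])
            cand = (M[i][j - 1] + s.gap_open, X[i][j - 1] + s.gap_open,
                    Y[i][j - 1] + ext)
            state = "MXY"[_index_close(cand, Y[i][j])]
            j -= 1
    return best, "".join(reversed(at)), "".join(reversed(ab))


def _index_close(values, target, tol: float = 1e-9) -> int:
    for k, v in enumerate(values):
        if abs(v - target) <= tol:
            return k
    raise RuntimeError("traceback inconsistency")


def complement_align(
    top: str, bottom: str, scheme: ScoringScheme = ScoringScheme()
) -> DuplexCandidate:
    """Best complementarity alignment of two strands.

    ``top`` and ``bottom`` are both given 5'->3'; the bottom strand is
    reversed internally so columns read top 5'->3' over bottom 3'->5'.
    All overhang assignments (0..max_overhang unpaired 3'-terminal bases per
    strand) are enumerated and the affine-gap global alignment of the
    remaining cores is scored; the highest total wins, ties resolved toward
    fewer overhang columns.
    """
    if not top or not bottom:
        raise ValueError("empty sequence")
    rbot = bottom[::-1]  # bottom 3'->5': its 3' end is now leftmost
    best = None
    for ot, ob in itertools.product(range(scheme.max_overhang + 1), repeat=2):
        core_top = top[: len(top) - ot] if ot else top
        core_rbot = rbot[ob:]
        if not core_top or not core_rbot:
            continue
        score, at, ab = _gotoh(core_top, core_rbot, scheme)
        key = (-score, ot + ob, ob, ot)
        if best is None or key < best[0]:
            best = (key, score, at, ab, ot, ob)
    assert best is not None
    _, score, at, ab, ot, ob = best
    aligned_top = GAP * ob + at + top[len(top) - ot:] if ot else GAP * ob + at
    aligned_bottom = rbot[:ob] + ab + GAP * ot
    cand = DuplexCandidate(
        top_id="", bottom_id="",
        aligned_top=aligned_top, aligned_bottom=aligned_bottom,
        score=score, overhang_top3=ot, overhang_bottom3=ob,
    )
    cand.pattern = encode_duplex(cand)
    return cand


def encode_duplex(d: DuplexCandidate) -> EncodedPattern:
    """Collapse the paired region of an alignment into one {M,X,I,D} string.

    Watson-Crick or G:U column -> M; non-complementary base pair -> X; gap in
    the bottom (star) strand -> I; gap in the top strand -> D.  Overhang
    columns are excluded.
    """
    start = d.overhang_bottom3
    stop = len(d.aligned_top) - d.overhang_top3
    states = []
    for a, b in zip(d.aligned_top[start:stop], d.aligned_bottom[start:stop]):
        if a == GAP and b == GAP:
            raise ValueError("gap-over-gap column")
        if b == GAP:
            states.append("I")
        elif a == GAP:
            states.append("D")
        elif (a, b) in WATSON_CRICK or (a, b) in WOBBLE:
            states.append("M")
        else:
            states.append("X")
    return EncodedPattern("".join(states))


# ---------------------------------------------------------------------------
# duplex selection over a contig pool


def _align_task(args: tuple[str, str, ScoringScheme]) -> DuplexCandidate:
    top, bottom, scheme = args
    return complement_align(top, bottom, scheme)


def _orient(a: Contig, b: Contig) -> tuple[Contig, Contig]:
    """Top strand = the contig with the higher total read count (the more
    abundant arm, usually the mature strand); ties go lexicographic."""
    ka = (-a.total_count, a.sequence)
    kb = (-b.total_count, b.sequence)
    return (a, b) if ka <= kb else (b, a)


def select_duplexes(
    contigs: Sequence[Contig],
    scheme: ScoringScheme = ScoringScheme(),
    min_score: float = NEG_INF,
    policy: str = "mutual",
    contig_ids: Optional[Sequence[str]] = None,
    workers: int = 1,
) -> tuple[list[DuplexCandidate], list[str]]:
    """Pair each contig with its best-scoring complementary partner.

    With ``policy="mutual"`` (default) a duplex is emitted only when the two
    contigs are each other's best partner; ``policy="threshold"`` emits any
    one-sided best whose score is >= ``min_score``, greedily by descending
    score so each contig still joins at most one duplex.  Flagged (oversize)
    contigs are skipped.  Returns (duplexes, unpaired contig ids).
    """
    if policy not in ("mutual", "threshold"):
        raise ValueError(f"unknown policy {policy!r}")
    pool = [c for c in contigs if not c.flagged]
    if contig_ids is None:
        ids = [f"contig{i}" for i in range(1, len(contigs) + 1)]
        id_of = {id(c): ids[i] for i, c in enumerate(contigs)}
    else:
        id_of = {id(c): contig_ids[i] for i, c in enumerate(contigs)}
    if len(pool) < 2:
        return [], [id_of[id(c)] for c in pool]

    # all-pairs alignment; cache per unordered pair.  With workers > 1 the
    # quadratic alignment stage is precomputed in parallel; results are
    # merged in input order so the outcome is worker-count independent.
    align_cache: dict[tuple[int, int], DuplexCandidate] = {}
    if workers > 1:
        from .parallel import parallel_map

        pairs = [(i, j) for i in range(len(pool)) for j in range(i + 1, len(pool))]
        tasks = []
        for i, j in pairs:
            top, bot = _orient(pool[i], pool[j])
            tasks.append((top.sequence, bot.sequence, scheme))
        results = parallel_map(_align_task, tasks, workers)
        for (i, j), cand in zip(pairs, results):
            top, bot = _orient(pool[i], pool[j])
            cand.top_id = id_of[id(top)]
            cand.bottom_id = id_of[id(bot)]
            cand.top_count = top.total_count
            cand.bottom_count = bot.total_count
            align_cache[(i, j)] = cand

    def aligned(i: int, j: int) -> DuplexCandidate:
        key = (min(i, j), max(i, j))
        if key not in align_cache:
            a, b = pool[key[0]], pool[key[1]]
            top, bot = _orient(a, b)
            cand = complement_align(top.sequence, bot.sequence, scheme)
            cand.top_id = id_of[id(top)]
            cand.bottom_id = id_of[id(bot)]
            cand.top_count = top.total_count
            cand.bottom_count = bot.total_count
            align_cache[key] = cand
        return align_cache[key]

    def best_partner(i: int) -> tuple[int, float]:
        ranked = sorted(
            (j for j in range(len(pool)) if j != i),
            key=lambda j: (
                -aligned(i, j).score,
                -pool[j].total_count,
                pool[j].sequence,
            ),
        )
        j = ranked[0]
        return j, aligned(i, j).score

    best = {i: best_partner(i) for i in range(len(pool))}
    used: set[int] = set()
    duplexes: list[DuplexCandidate] = []
    if policy == "mutual":
        for i in range(len(pool)):
            j, score = best[i]
            if i < j and best[j][0] == i and score >= min_score:
                duplexes.append(aligned(i, j))
                used.update((i, j))
    else:
        order = sorted(
            range(len(pool)),
            key=lambda i: (-best[i][1], pool[i].sequence),
        )
        for i in order:
            j, score = best[i]
            if i in used or j in used or score < min_score:
                continue
            duplexes.append(aligned(i, j))
            used.update((i, j))
    duplexes.sort(key=lambda d: (-d.score, d.top_id, d.bottom_id))
    unpaired = [id_of[id(c)] for k, c in enumerate(pool) if k not in used]
    return duplexes, unpaired


def write_duplexes_tsv(duplexes: Sequence[DuplexCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "top_id\tbottom_id\tscore\toverhang_top3\toverhang_bottom3\t"
            "pattern\taligned_top\taligned_bottom\ttop_count\tbottom_count\n"
        )
        for d in duplexes:
            fh.write(
                f"{d.top_id}\t{d.bottom_id}\t{d.score:g}\t{d.overhang_top3}\t"
                f"{d.overhang_bottom3}\t{d.pattern}\t{d.aligned_top}\t"
                f"{d.aligned_bottom}\t{d.top_count}\t{d.bottom_count}\n"
            )


def write_duplex_alignment(d: DuplexCandidate, path: str | Path) -> None:
    """Two-line aligned-text dump (top 5'->3' over bottom 3'->5')."""
    with open(path, "w") as fh:
        fh.write(f"5' {d.aligned_top} 3'  ({d.top_id})\n")
        fh.write(f"3' {d.aligned_bottom} 5'  ({d.bottom_id})\n")
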