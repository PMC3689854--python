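"""Seeded synthetic duplex libraries, tiled reads and decoys.

No public small-RNA dataset is bundled: every test and the shipped benchmark
run on synthetic data with known ground truth, generated here as pure
functions of a seed.

The positive generating model emulates what distinguishes mature miRNA
duplexes in real libraries: arm lengths concentrated on 19-24 nt peaking at
21-22, pairing-state patterns dominated by matches, and sparse mismatch /
insertion / deletion states that co-occur at preferred position pairs
(structural conservation of the duplex).  Negatives are deliberately hard:
half are positives with their pairing states randomly permuted (identical
length and state composition, destroyed positional structure), half are
noise duplexes with a broader 18-30 nt length range and position-independent
states — so a classifier cannot win on length or composition alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assembly import find_overlap
from .duplex import WATSON_CRICK, WOBBLE, complement_align, encode_duplex, ScoringScheme
from .io_reads import Read

BASES = ("A", "C", "G", "U")

#: positive arm-length distribution (nt -> probability), peaked at 21-22
POSITIVE_LENGTH_PROBS = {19: 0.08, 20: 0.17, 21: 0.30, 22: 0.30, 23: 0.10, 24: 0.05}
#: negative (noise) length distribution: broader, flat-ish over 18-30
NEGATIVE_LENGTH_PROBS = {L: 1.0 / 13 for L in range(18, 31)}

#: structured co-occurrence motifs of the positive model:
#: (state at i, state at j, position i, position j, probability of planting)
POSITIVE_MOTIFS = (
    ("X", "X", 2, 16, 0.95),
    ("X", "X", 5, 14, 0.65),
    ("X", "X", 11, 13, 0.50),
    ("X", "I", 8, 18, 0.25),
    ("I", "I", 17, 20, 0.15),
    ("D", "D", 19, 21, 0.10),
)
#: per-position probability of a background (unstructured) mismatch
POSITIVE_BACKGROUND_X = 0.02
#: position-independent state probabilities of the noise-negative model
NEGATIVE_STATE_PROBS = {"M": 0.82, "X": 0.12, "I": 0.03, "D": 0.03}
#: fraction of negatives that are state-shuffled positives
SHUFFLED_NEGATIVE_FRACTION = 0.5
#: chance that a match column is a G:U wobble rather than Watson-Crick
WOBBLE_PROB = 0.15
#: 3' overhang length distribution per arm (Dicer leaves mostly 2 nt)
OVERHANG_PROBS = {0: 0.2, 1: 0.2, 2: 0.6}

_NONCOMPLEMENT = {
    a: [b for b in BASES if (a, b) not in WATSON_CRICK and (a, b) not in WOBBLE]
    for a in BASES
}
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SyntheticDuplexSpec:
    """Generator settings; the defaults are the study conditions."""

    n_positive: int = 500
    n_negative: int = 500
    seed: int = 0
    pos_length_probs: tuple = tuple(sorted(POSITIVE_LENGTH_PROBS.items()))
    neg_length_probs: tuple = tuple(sorted(NEGATIVE_LENGTH_PROBS.items()))
    shuffled_negative_fraction: float = SHUFFLED_NEGATIVE_FRACTION
    wobble_prob: float = WOBBLE_PROB
    #: plant every mismatch co-occurrence motif deterministically and omit
    #: gap motifs: unambiguous class members for plumbing-level fixtures
    clear_positives: bool = False

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 0:
            raise ValueError("need n_positive >= 1 and n_negative >= 0")
        for probs in (self.pos_length_probs, self.neg_length_probs):
            total = sum(p for _, p in probs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("length probabilities must sum to 1")


@dataclass(frozen=True)
class SimulatedDuplex:
    id: str
    top: str            # 5'->3'
    bottom: str         # 5'->3'
    pattern: str        # planted pairing states, paired region only
    label: int          # 1 = miRNA-like, 0 = decoy


def _draw_length(probs: tuple, rng: np.random.Generator) -> int:
    lengths = [L for L, _ in probs]
    p = np.array([q for _, q in probs])
    return int(rng.choice(lengths, p=p / p.sum()))


def _positive_pattern(L: int, rng: np.random.Generator, clear: bool = False) -> str:
    states = ["M"] * L
    for a, b, i, j, prob in POSITIVE_MOTIFS:
        if clear and (a != "X" or b != "X"):
            continue
        if i < L and j < L and rng.random() < (1.0 if clear else prob):
            states[i], states[j] = a, b
    for k in range(L):
        if states[k] == "M" and rng.random() < POSITIVE_BACKGROUND_X:
            states[k] = "X"
    return "".join(states)


def _noise_pattern(L: int, rng: np.random.Generator) -> str:
    names = list(NEGATIVE_STATE_PROBS)
    p = np.array([NEGATIVE_STATE_PROBS[s] for s in names])
    return "".join(rng.choice(names, size=L, p=p / p.sum()))


def _arms_from_pattern(
    pattern: str, rng: np.random.Generator, wobble_prob: float
) -> tuple[str, str]:
    """Sample concrete nucleotide arms consistent with a pairing pattern.

    M columns get complementary (or, with ``wobble_prob``, G:U) bases; X
    columns non-complementary bases; I columns exist on the top strand only,
    D columns on the bottom only.  Unpaired 3' overhang bases are appended
    to each arm.  Both arms are returned 5'->3'.
    """
    top: list[str] = []
    bottom_3to5: list[str] = []
    for st in pattern:
        if st == "M":
            if rng.random() < wobble_prob:
                t, b = ("G", "U") if rng.random() < 0.5 else ("U", "G")
            else:
                t = BASES[rng.integers(4)]
                b = _WC_PARTNER[t]
            top.append(t)
            bottom_3to5.append(b)
        elif st == "X":
            t = BASES[rng.integers(4)]
            choices = _NONCOMPLEMENT[t]
            top.append(t)
            bottom_3to5.append(choices[rng.integers(len(choices))])
        elif st == "I":
            top.append(BASES[rng.integers(4)])
        elif st == "D":
            bottom_3to5.append(BASES[rng.integers(4)])
        else:
            raise ValueError(f"bad state {st!r}")
    ov_lens = list(OVERHANG_PROBS)
    ov_p = np.array(list(OVERHANG_PROBS.values()))
    ot = int(rng.choice(ov_lens, p=ov_p / ov_p.sum()))
    ob = int(rng.choice(ov_lens, p=ov_p / ov_p.sum()))
    top_seq = "".join(top) + "".join(BASES[rng.integers(4)] for _ in range(ot))
    # bottom 5'->3' is the reverse of the 3'->5' row; its 3' overhang is
    # appended at its own 3' end
    bottom_seq = "".join(reversed(bottom_3to5)) + "".join(
        BASES[rng.integers(4)] for _ in range(ob)
    )
    return top_seq, bottom_seq


def simulate_duplexes(spec: SyntheticDuplexSpec) -> list[SimulatedDuplex]:
    """Draw labelled duplexes: state patterns from the class model, then
    nucleotide arms consistent with each pattern."""
    rng = np.random.default_rng(spec.seed)
    out: list[SimulatedDuplex] = []
    for k in range(spec.n_positive):
        L = _draw_length(spec.pos_length_probs, rng)
        pat = _positive_pattern(L, rng, spec.clear_positives)
        top, bottom = _arms_from_pattern(pat, rng, spec.wobble_prob)
        out.append(SimulatedDuplex(f"pos{k + 1}", top, bottom, pat, 1))
    for k in range(spec.n_negative):
        if rng.random() < spec.shuffled_negative_fraction:
            L = _draw_length(spec.pos_length_probs, rng)
            pat = "".join(rng.permutation(list(_positive_pattern(L, rng))))
        else:
            L = _draw_length(spec.neg_length_probs, rng)
            pat = _noise_pattern(L, rng)
        top, bottom = _arms_from_pattern(pat, rng, spec.wobble_prob)
        out.append(SimulatedDuplex(f"neg{k + 1}", top, bottom, pat, 0))
    return out


def simulate_reads(
    sources: Sequence[tuple[str, str]],
    read_length_range: tuple[int, int] = (15, 20),
    min_tile_overlap: int = 7,
    depth: int = 1,
    seed: int = 0,
) -> list[Read]:
    """Tile each (id, sequence) source into overlapping reads.

    Consecutive tiles overlap by at least ``min_tile_overlap`` (which must be
    >= the assembler's min_overlap for round-trip reassembly); each tile is
    emitted with copy count ``depth``.  A source shorter than the read length
    yields one full-length read.
    """
    lo, hi = read_length_range
    if min_tile_overlap < 1 or lo > hi:
        raise ValueError("bad tiling parameters")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for src_id, seq in sources:
        L = len(seq)
        tiles: list[str] = []
        start = 0
        while True:
            rl = min(int(rng.integers(lo, hi + 1)), L)
            if start + rl >= L:
                tiles.append(seq[L - rl:])
                break
            tiles.append(seq[start:start + rl])
            max_step = rl - min_tile_overlap
            step = int(rng.integers(1, max(2, max_step + 1)))
            start += step
        for i, t in enumerate(tiles, start=1):
            reads.append(Read(f"{src_id}_t{i}", t, depth))
    return reads


# ---------------------------------------------------------------------------
# the standard benchmark


@dataclass
class InstanceSet:
    duplexes: list[SimulatedDuplex]
    patterns: list[str]       # patterns recovered by alignment + encoding
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.duplexes)


@dataclass
class Benchmark:
    train: InstanceSet
    test: InstanceSet
    reads: list[Read]
    seed: int


def _recover_patterns(
    duplexes: Sequence[SimulatedDuplex], scheme: ScoringScheme
) -> list[str]:
    pats = []
    for d in duplexes:
        cand = complement_align(d.top, d.bottom, scheme)
        pats.append(str(cand.pattern))
    return pats


def make_benchmark(
    seed: int = 1,
    n_per_class: int = 500,
    scheme: ScoringScheme = ScoringScheme(),
    recover_patterns: bool = True,
    read_depth: int = 2,
) -> Benchmark:
    """The shipped synthetic benchmark: ``n_per_class`` positives and
    negatives for training and the same counts, freshly drawn, for testing.

    Patterns are re-derived from the nucleotide arms through the alignment
    and encoding path (not read off the generator), so the benchmark
    exercises the full duplex machinery.  Train and test duplexes are
    disjoint by construction (independent draws from distinct substreams).
    """
    spec_train = SyntheticDuplexSpec(n_per_class, n_per_class, seed=seed * 2 + 1)
    spec_test = SyntheticDuplexSpec(n_per_class, n_per_class, seed=seed * 2 + 2)
    train_dup = simulate_duplexes(spec_train)
    test_dup = simulate_duplexes(spec_test)
    if recover_patterns:
        train_pat = _recover_patterns(train_dup, scheme)
        test_pat = _recover_patterns(test_dup, scheme)
    else:
        train_pat = [d.pattern for d in train_dup]
        test_pat = [d.pattern for d in test_dup]
    reads = simulate_reads(
        [(d.id, d.top) for d in train_dup[:50]],
        read_length_range=(15, 18),
        min_tile_overlap=7,
        depth=read_depth,
        seed=seed,
    )
    return Benchmark(
        train=InstanceSet(train_dup, train_pat,
                          np.array([d.label for d in train_dup])),
        test=InstanceSet(test_dup, test_pat,
                         np.array([d.label for d in test_dup])),
        reads=reads,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# planted-recovery library


def _mutually_unmergeable(seqs: Sequence[str], min_overlap: int = 5) -> bool:
    for i, a in enumerate(seqs):
        for j, b in enumerate(seqs):
            if i != j and find_overlap(a, b, min_overlap) is not None:
                return False
    return True


@dataclass
class PlantedLibrary:
    reads: list[Read]
    planted: list[SimulatedDuplex]   # ground-truth positive duplexes
    decoys: list[str]                # decoy source sequences


def make_planted_library(
    seed: int = 0,
    n_planted: int = 10,
    n_decoys: int = 12,
    depth: int = 3,
) -> PlantedLibrary:
    """Reads simulated from planted positive duplex arms plus decoy sources.

    All sources (both arms of every planted duplex and every decoy) are
    drawn repeat-free: rejection sampling guarantees no cross suffix-prefix
    overlap of 5+ nt and no containment between distinct sources, the regime
    in which greedy assembly provably reassembles each source exactly.  The
    decoy set is additionally drawn so that no decoy out-scores a planted
    arm's true partner in complementarity alignment — decoys provide
    background, not competing duplexes, so recovery failures indicate
    pipeline defects rather than fixture ambiguity.
    """
    rng = np.random.default_rng(seed)
    scheme = ScoringScheme()
    planted: list[SimulatedDuplex] = []
    true_score: dict[str, float] = {}
    accepted: list[str] = []

    # draw planted duplexes one at a time; each must round-trip (its planted
    # pattern is the aligner's optimal alignment) and must not out-compete
    # any previously accepted arm's true partner
    attempts = 0
    while len(planted) < n_planted:
        attempts += 1
        if attempts > 2000:
            raise RuntimeError("could not sample a recoverable planted set")
        spec = SyntheticDuplexSpec(
            n_positive=1, n_negative=0,
            seed=int(rng.integers(2 ** 31 - 1)),
            clear_positives=True,
        )
        (d,) = simulate_duplexes(spec)
        cand = complement_align(d.top, d.bottom, scheme)
        if str(cand.pattern) != d.pattern:
            continue
        new = [d.top, d.bottom]
        pool = accepted + new
        if len(set(pool)) != len(pool) or not _mutually_unmergeable(pool):
            continue
        ok = True
        for arm in new:
            for other in accepted:
                rival = complement_align(arm, other, scheme).score
                if rival >= cand.score or rival >= true_score[other]:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        dd = SimulatedDuplex(f"pos{len(planted) + 1}", d.top, d.bottom,
                             d.pattern, 1)
        planted.append(dd)
        accepted.extend(new)
        true_score[d.top] = true_score[d.bottom] = cand.score
    # decoys: background only — unmergeable with everything and never
    # out-scoring an arm's true partner
    decoys: list[str] = []
    attempts = 0
    while len(decoys) < n_decoys:
        attempts += 1
        if attempts > 2000:
            raise RuntimeError("could not sample compatible decoys")
        dec = "".join(BASES[rng.integers(4)]
                      for _ in range(int(rng.integers(20, 29))))
        pool = accepted + [dec]
        if len(set(pool)) != len(pool) or not _mutually_unmergeable(pool):
            continue
        if any(complement_align(arm, dec, scheme).score >= true_score[arm]
               for arm in true_score):
            continue
        decoys.append(dec)
        accepted.append(dec)
    # the mature (top) arm accumulates more reads than the star arm, as in
    # real libraries; this read-count asymmetry is what orients each duplex
    # at discovery time, so training and discovery agree on strand order
    mature = [(f"{d.id}_5p", d.top) for d in planted]
    star = [(f"{d.id}_3p", d.bottom) for d in planted]
    background = [(f"decoy{i + 1}", s) for i, s in enumerate(decoys)]
    seed_a, seed_b, seed_c = (int(rng.integers(2 ** 31 - 1)) for _ in range(3))
    reads = (
        simulate_reads(mature, read_length_range=(15, 18), min_tile_overlap=8,
                       depth=depth * 5, seed=seed_a)
        + simulate_reads(star, read_length_range=(15, 18), min_tile_overlap=8,
                         depth=depth, seed=seed_b)
        + simulate_reads(background, read_length_range=(15, 18),
                         min_tile_overlap=8, depth=depth, seed=seed_c)
    )
    return PlantedLibrary(reads, planted, decoys)
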