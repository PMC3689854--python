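"""Greedy suffix-prefix overlap assembly of small RNA reads into contigs.

Unique reads are merged whenever the suffix of one exactly equals the prefix
of another over at least ``min_overlap`` (default 5) nucleotides, with no
mismatches.  Overlap detection runs the Knuth-Morris-Pratt failure function
over ``b + SEP + a`` so each pair costs linear time.  Merging is greedy
longest-overlap-first with a lexicographic tie-break on the merged sequence,
which makes the result deterministic and independent of input order; at
mature-miRNA scales (contigs below ~80 nt, effectively repeat-free) the
greedy order recovers the source sequence exactly.

Reads fully contained in another read (or in a growing contig) are absorbed
into the container rather than left as spurious singleton contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_reads import Read

#: sentinel separator for the KMP text; never occurs in {A,C,G,U}
_SEP = "#"

#: contigs longer than this are flagged and excluded from duplex search —
#: mature duplex arms are short, so oversized assemblies are suspect
DEFAULT_MAX_CONTIG_LENGTH = 80

CONTAINED = "contained"


def _failure_function(s: str) -> list[int]:
    """KMP failure (longest proper prefix that is also a suffix) table."""
    fail = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k > 0 and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return fail


def find_overlap(a: str, b: str, min_overlap: int = 5) -> Optional[int | str]:
    """Longest L >= min_overlap with suffix(a, L) == prefix(b, L).

    Returns the integer overlap length, the sentinel ``"contained"`` when one
    sequence is a substring of the other (including identity), or ``None``.
    Computed via the KMP failure function of ``b#a``: its final value is the
    longest prefix of ``b`` that is a suffix of ``a``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if b in a or a in b:
        return CONTAINED
    fail = _failure_function(b + _SEP + a)
    best = fail[-1]
    if best >= min_overlap:
        return best
    return None


@dataclass
class Contig:
    """An assembled sequence with the identity and multiplicity of members.

    ``members`` maps read id -> (offset of the read within ``sequence``,
    copy count).  ``depth`` is per-position coverage over member reads.
    """

    sequence: str
    members: dict[str, tuple[int, int]] = field(default_factory=dict)
    flagged: bool = False

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.members.values())

    @property
    def depth(self) -> list[int]:
        d = [0] * len(self.sequence)
        lengths = self._member_lengths
        for rid, (off, _) in self.members.items():
            for i in range(off, off + lengths[rid]):
                d[i] += 1
        return d

    _member_lengths: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_read(cls, read: Read) -> "Contig":
        c = cls(read.sequence, {read.id: (0, read.count)})
        c._member_lengths = {read.id: len(read.sequence)}
        return c

    def __len__(self) -> int:
        return len(self.sequence)


def _merge(a: Contig, b: Contig, overlap: int) -> Contig:
    """Merge b onto a's suffix with the given exact overlap."""
    shift = len(a.sequence) - overlap
    merged = Contig(a.sequence + b.sequence[overlap:])
    merged.members = dict(a.members)
    merged._member_lengths = dict(a._member_lengths)
    for rid, (off, cnt) in b.members.items():
        merged.members[rid] = (off + shift, cnt)
        merged._member_lengths[rid] = b._member_lengths[rid]
    return merged


def _absorb(container: Contig, inner: Contig) -> Contig:
    """Absorb a contained contig at its leftmost occurrence."""
    off = container.sequence.find(inner.sequence)
    assert off >= 0
    out = Contig(container.sequence, dict(container.members))
    out._member_lengths = dict(container._member_lengths)
    for rid, (ioff, cnt) in inner.members.items():
        out.members[rid] = (off + ioff, cnt)
        out._member_lengths[rid] = inner._member_lengths[rid]
    return out


def _best_pair(contigs: Sequence[Contig], min_overlap: int):
    """Best mergeable ordered pair under the greedy rule, or None.

    Containments rank above any terminal overlap (they add no sequence);
    among overlaps the longest wins, ties broken by the lexicographically
    smallest merged sequence, then by the operand sequences.
    """
    best = None  # (key tuple, i, j, overlap-or-CONTAINED)
    for i, a in enumerate(contigs):
        for j, b in enumerate(contigs):
            if i == j:
                continue
            r = find_overlap(a.sequence, b.sequence, min_overlap)
            if r is None:
                continue
            if r == CONTAINED:
                # orient so the container comes first
                if len(b.sequence) > len(a.sequence):
                    continue  # the (j, i) orientation will be seen instead
                key = (0, a.sequence, b.sequence)
                cand = (key, i, j, CONTAINED)
            else:
                merged = a.sequence + b.sequence[r:]
                key = (1, -r, merged, a.sequence, b.sequence)
                cand = (key, i, j, r)
            if best is None or cand[0] < best[0]:
                best = cand
    return best


def assemble(
    reads: Iterable[Read],
    min_overlap: int = 5,
    max_contig_length: int = DEFAULT_MAX_CONTIG_LENGTH,
) -> list[Contig]:
    """Assemble collapsed reads into mutually non-mergeable contigs.

    Repeatedly merges the pair with the longest exact suffix-prefix overlap
    (containment first, lexicographic tie-break) until no pair overlaps by at
    least ``min_overlap``.  Contigs longer than ``max_contig_length`` are kept
    but ``flagged`` for exclusion from duplex search.
    """
    contigs = [Contig.from_read(r) for r in sorted(reads, key=lambda r: (r.sequence, r.id))]
    while len(contigs) > 1:
        hit = _best_pair(contigs, min_overlap)
        if hit is None:
            break
        _, i, j, r = hit
        a, b = contigs[i], contigs[j]
        new = _absorb(a, b) if r == CONTAINED else _merge(a, b, r)
        contigs = [c for k, c in enumerate(contigs) if k not in (i, j)]
        contigs.append(new)
    for c in contigs:
        if len(c.sequence) > max_contig_length:
            c.flagged = True
    contigs.sort(key=lambda c: c.sequence)
    return contigs


def write_contigs_fasta(contigs: Sequence[Contig], path: str | Path) -> None:
    """FASTA export; header carries member count and summed copy number."""
    with open(path, "w") as fh:
        for i, c in enumerate(contigs, start=1):
            fh.write(
                f">contig{i} members={len(c.members)} total_count={c.total_count}"
                f"{' flagged' if c.flagged else ''}\n{c.sequence}\n"
            )


def write_contig_members_tsv(contigs: Sequence[Contig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tread_id\toffset\tcount\n")
        for i, c in enumerate(contigs, start=1):
            for rid, (off, cnt) in sorted(c.members.items()):
                fh.write(f"contig{i}\t{rid}\t{off}\t{cnt}\n")
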