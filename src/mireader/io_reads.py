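"""Reading, collapsing and reference-mapping of small RNA sequencing reads.

Small RNA libraries arrive either as raw FASTA/FASTQ records or as
pre-collapsed "sequence<TAB>count" tag files.  Internally every sequence is
normalised to the RNA alphabet {A, C, G, U}; reads are collapsed to unique
tags carrying a multiplicity, mapped to reference sets (known mature miRNAs,
other ncRNAs, a transcriptome) by same-strand substring search, and screened
against those sets in priority order before de novo discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: default acceptable read length window (nt), inclusive
DEFAULT_LENGTH_WINDOW = (15, 35)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class Read:
    """A unique small-RNA tag with its copy number across the library."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.id!r}: non-ACGU characters {sorted(bad)}"
            )
        if self.count < 1:
            raise ValueError(f"read {self.id!r}: count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    sequence: str


@dataclass
class ReferenceSet:
    """A named collection of labelled reference sequences (FASTA-backed)."""

    name: str
    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"reference set {self.name!r}: duplicate ids {dupes}")

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, name: str, path: str | Path) -> "ReferenceSet":
        records = [
            ReferenceRecord(rec.id, normalize_sequence(str(rec.seq)))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(name, records)


@dataclass(frozen=True)
class MappingRow:
    """One occurrence of a read as a (mismatched) substring of a reference.

    Offsets are 0-based on the reference, half-open convention: the read
    occupies ``[offset, offset + len(read))``.
    """

    read_id: str
    ref_id: str
    offset: int
    mismatches: int
    mismatch_positions: tuple[int, ...] = ()


@dataclass
class MappingTable:
    rows: list[MappingRow] = field(default_factory=list)
    #: per-reference total mapped copies (weighted by read count)
    ref_totals: dict[str, int] = field(default_factory=dict)
    #: per-reference set of distinct mapped read ids
    ref_reads: dict[str, set[str]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tref_id\toffset\tmismatches\tmismatch_positions\n")
            for r in self.rows:
                pos = ",".join(map(str, r.mismatch_positions))
                fh.write(f"{r.read_id}\t{r.ref_id}\t{r.offset}\t{r.mismatches}\t{pos}\n")

    def to_bed6(self, path: str | Path, read_lengths: dict[str, int]) -> None:
        """BED6 export; 0-based half-open, strand fixed '+'."""
        with open(path, "w") as fh:
            for r in self.rows:
                end = r.offset + read_lengths[r.read_id]
                fh.write(
                    f"{r.ref_id}\t{r.offset}\t{end}\t{r.read_id}\t{r.mismatches}\t+\n"
                )


# ---------------------------------------------------------------------------
# parsing


def _parse_tag_tsv(path: Path) -> list[Read]:
    reads: list[Read] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'SEQ<TAB>COUNT', got {line!r}"
                )
            seq, count_s = parts
            try:
                count = int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad count {count_s!r}") from exc
            reads.append(Read(f"tag{lineno}", normalize_sequence(seq), count))
    return reads


def read_fastx(
    path: str | Path,
    format: str | None = None,
    length_window: tuple[int, int] | None = DEFAULT_LENGTH_WINDOW,
) -> list[Read]:
    """Load reads from FASTA, FASTQ (4-line dialect; quality ignored) or
    tag-count TSV.

    ``format`` is inferred from the file suffix when omitted.  FASTA/FASTQ
    records get count 1 each (collapsing is a separate step); tag-TSV rows
    carry their stated count.  Reads outside ``length_window`` are dropped
    with a logged tally; pass ``length_window=None`` to keep everything.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
            ".fq": "fastq", ".fastq": "fastq",
            ".tsv": "tags", ".txt": "tags", ".tags": "tags",
        }.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    format = format.lower()

    if format == "tags":
        reads = _parse_tag_tsv(path)
    elif format in ("fasta", "fastq"):
        reads = [
            Read(rec.id, normalize_sequence(str(rec.seq)), 1)
            for rec in SeqIO.parse(str(path), format)
        ]
    else:
        raise ValueError(f"unknown format {format!r}")

    if not reads:
        logger.warning("no reads parsed from %s", path)
        return []
    if length_window is not None:
        lo, hi = length_window
        kept = [r for r in reads if lo <= len(r) <= hi]
        if len(kept) != len(reads):
            logger.info(
                "%d/%d reads outside length window %d-%d dropped",
                len(reads) - len(kept), len(reads), lo, hi,
            )
        reads = kept
    return reads


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id} count={r.count}\n{r.sequence}\n")


def write_tags(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.sequence}\t{r.count}\n")


# ---------------------------------------------------------------------------
# collapsing and mapping


def collapse_reads(reads: Iterable[Read]) -> list[Read]:
    """Collapse to one Read per distinct sequence; counts are summed.

    Output is ordered lexicographically by sequence and renamed ``tagN``,
    so collapsing is idempotent and independent of input order.
    """
    totals: dict[str, int] = {}
    for r in reads:
        totals[r.sequence] = totals.get(r.sequence, 0) + r.count
    return [
        Read(f"tag{i}", seq, totals[seq])
        for i, seq in enumerate(sorted(totals), start=1)
    ]


def _hamming_hits(read: str, ref: str, max_mismatch: int):
    """Yield (offset, mismatch_positions) for every window of ``ref`` within
    Hamming distance ``max_mismatch`` of ``read``."""
    n, m = len(read), len(ref)
    for off in range(m - n + 1):
        mism: list[int] = []
        window = ref[off:off + n]
        if max_mismatch == 0:
            if window != read:
                continue
        else:
            for i, (a, b) in enumerate(zip(read, window)):
                if a != b:
                    mism.append(i)
                    if len(mism) > max_mismatch:
                        break
            if len(mism) > max_mismatch:
                continue
        yield off, tuple(mism)


def map_reads_to_refs(
    reads: Sequence[Read],
    refset: ReferenceSet,
    max_mismatch: int = 0,
) -> MappingTable:
    """Same-strand substring mapping of reads onto a reference set.

    Every occurrence with <= ``max_mismatch`` substitutions is reported; no
    reverse-complement search (duplex partners are found later by alignment,
    not by mapping).  With ``max_mismatch=0`` exact matches use ``str.find``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    table = MappingTable()
    for ref in refset:
        for read in reads:
            if len(read) > len(ref.sequence):
                continue
            if max_mismatch == 0:
                start = ref.sequence.find(read.sequence)
                while start != -1:
                    table.rows.append(MappingRow(read.id, ref.id, start, 0))
                    start = ref.sequence.find(read.sequence, start + 1)
            else:
                for off, mism in _hamming_hits(
                    read.sequence, ref.sequence, max_mismatch
                ):
                    table.rows.append(
                        MappingRow(read.id, ref.id, off, len(mism), mism)
                    )
    counts = {r.id: r.count for r in reads}
    for row in table.rows:
        table.ref_reads.setdefault(row.ref_id, set()).add(row.read_id)
    for ref_id, ids in table.ref_reads.items():
        table.ref_totals[ref_id] = sum(counts[i] for i in ids)
    return table


@dataclass
class ScreenResult:
    """Partition of a read library over prioritised reference sets."""

    assigned: dict[str, list[Read]]      # set name -> reads
    novel: list[Read]                    # unmatched pool for de novo discovery
    totals: dict[str, tuple[int, int]]   # set name -> (n unique reads, copies)


def screen_reads(
    reads: Sequence[Read],
    refsets: Sequence[ReferenceSet],
    max_mismatch: int = 0,
) -> ScreenResult:
    """Assign each read to the first (highest-priority) reference set it maps
    to; unmatched reads form the novel-candidate pool.

    The conventional priority order is known mature miRNAs, then other
    ncRNAs, then the transcriptome — callers pass sets in that order.
    """
    assigned: dict[str, list[Read]] = {rs.name: [] for rs in refsets}
    novel: list[Read] = []
    for read in reads:
        placed = False
        for rs in refsets:
            hits = map_reads_to_refs([read], rs, max_mismatch)
            if hits.rows:
                assigned[rs.name].append(read)
                placed = True
                break
        if not placed:
            novel.append(read)
    totals = {
        name: (len(rds), sum(r.count for r in rds))
        for name, rds in assigned.items()
    }
    totals["novel"] = (len(novel), sum(r.count for r in novel))
    return ScreenResult(assigned, novel, totals)


def select_instance_refs(mapping: MappingTable, min_reads: int = 2) -> list[str]:
    """References with at least ``min_reads`` distinct mapped reads.

    Only such references seed training-instance assembly; a reference hit by
    a single read cannot be assembled into an informative contig.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return sorted(
        ref_id
        for ref_id, ids in mapping.ref_reads.items()
        if len(ids) >= min_reads
    )
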