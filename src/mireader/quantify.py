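"""Iso-miR grouping and read-count expression values.

Iso-miRs are length or substitution variants of a reference mature miRNA
produced by variable processing or editing.  Reads mapped to a reference are
partitioned by their variant signature — 5' offset, length, and the set of
substitution positions — and a partition qualifies as an iso-miR group when
it holds at least ~3.5% of the reads mapped to that reference and shows
substitutions at no more than two positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .io_reads import MappingTable, Read

DEFAULT_FRAC_THRESHOLD = 0.035
DEFAULT_MAX_SUBS = 2


@dataclass
class IsoMirGroup:
    ref_id: str
    family: str
    offset: int            # 5' offset on the reference, 0-based
    length: int
    substitution_positions: tuple[int, ...]
    member_read_ids: tuple[str, ...]
    copies: int            # count-weighted size of the group
    fraction: float        # share of all copies mapped to this reference
    expression_value: float = 0.0
    qualifies: bool = True

    @property
    def signature(self) -> tuple:
        return (self.offset, self.length, self.substitution_positions)


def group_isomirs(
    mapping: MappingTable,
    reads: Sequence[Read],
    frac_threshold: float = DEFAULT_FRAC_THRESHOLD,
    max_subs: int = DEFAULT_MAX_SUBS,
    per_reference: bool = True,
    total_library_reads: Optional[int] = None,
    families: Optional[dict[str, str]] = None,
) -> list[IsoMirGroup]:
    """Partition reads mapped to reference miRNAs into iso-miR groups.

    Grouping key is (5' offset, read length, substitution-position
    signature).  With ``per_reference`` (default) the qualifying fraction is
    taken over the copies mapped to that reference; otherwise over
    ``total_library_reads``.  Every partition is returned — suppressed ones
    carry ``qualifies=False`` — so the partitioning covers all mapped reads.
    """
    read_by_id = {r.id: r for r in reads}
    fam = families or {}
    per_ref: dict[str, dict[tuple, list]] = {}
    for row in mapping.rows:
        read = read_by_id[row.read_id]
        key = (row.offset, len(read), row.mismatch_positions)
        per_ref.setdefault(row.ref_id, {}).setdefault(key, []).append(read)
    groups: list[IsoMirGroup] = []
    for ref_id in sorted(per_ref):
        parts = per_ref[ref_id]
        ref_total = sum(r.count for rs in parts.values() for r in rs)
        denom = total_library_reads if not per_reference else ref_total
        if denom is None:
            raise ValueError("total_library_reads required when per_reference=False")
        for key in sorted(parts):
            offset, length, subs = key
            members = parts[key]
            copies = sum(r.count for r in members)
            frac = copies / denom if denom else 0.0
            qualifies = frac >= frac_threshold and len(subs) <= max_subs
            groups.append(
                IsoMirGroup(
                    ref_id=ref_id,
                    family=fam.get(ref_id, ref_id.split("-")[0]),
                    offset=offset,
                    length=length,
                    substitution_positions=subs,
                    member_read_ids=tuple(sorted(r.id for r in members)),
                    copies=copies,
                    fraction=frac,
                    qualifies=qualifies,
                )
            )
    return groups


def expression(
    mapped_count: float,
    total_reads: float,
    mode: str = "paper",
    length_nt: Optional[float] = None,
) -> float:
    """Read-count expression value for an assembled sequence.

    ``mode="paper"`` applies the original tool's published formula verbatim:
    ``mapped_count * 1e-9 / total_reads``.  ``mode="rpkm"`` is the standard
    reads-per-kilobase-per-million, ``mapped_count * 1e9 / (total_reads *
    length_kb)``, and requires ``length_nt``.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if mode == "paper":
        return mapped_count * 1e-9 / total_reads
    if mode == "rpkm":
        if length_nt is None or length_nt <= 0:
            raise ValueError("rpkm mode requires a positive sequence length")
        return mapped_count * 1e9 / (total_reads * (length_nt / 1000.0))
    raise ValueError(f"unknown mode {mode!r}")


def attach_expression(
    groups: Sequence[IsoMirGroup],
    total_reads: int,
    mode: str = "paper",
) -> None:
    for g in groups:
        g.expression_value = expression(
            g.copies, total_reads, mode=mode, length_nt=g.length
        )


def write_isomir_sheet(groups: Sequence[IsoMirGroup], path: str | Path) -> None:
    """The iso-miR information sheet: variant signature, copies, fraction
    and expression per reference miRNA."""
    with open(path, "w") as fh:
        fh.write(
            "reference\tfamily\toffset\tlength\tsubstitution_positions\t"
            "copies\tfraction\texpression\tqualifies\n"
        )
        for g in groups:
            subs = ",".join(map(str, g.substitution_positions))
            fh.write(
                f"{g.ref_id}\t{g.family}\t{g.offset}\t{g.length}\t{subs}\t"
                f"{g.copies}\t{g.fraction:.6g}\t{g.expression_value:.6g}\t"
                f"{int(g.qualifies)}\n"
            )
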