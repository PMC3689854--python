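"""Group reads mapped to a reference miRNA into iso-miR variants.

A variant partition qualifies when it holds at least 3.5% of the copies
mapped to that reference and differs by at most two substitutions."""

from mireader import Read, group_isomirs, map_reads_to_refs
from mireader.io_reads import ReferenceRecord, ReferenceSet
from mireader.quantify import attach_expression

MIR = "UGAGGUAGUAGGUUGUAUAGUU"
reads = [
    Read("canonical", MIR, 880),
    Read("trimmed", MIR[1:], 40),               # 4.0% of mapped copies
    Read("rare", MIR[2:], 30),                  # 3.0% -> below threshold
    Read("edited", "A" + MIR[1] + "C" + MIR[3:], 50),  # 2 substitutions
]
refs = ReferenceSet("known-mature", [ReferenceRecord("mir-ex", MIR)])
mapping = map_reads_to_refs(reads, refs, max_mismatch=2)
groups = group_isomirs(mapping, reads)
attach_expression(groups, total_reads=sum(r.count for r in reads))

for g in groups:
    status = "iso-miR" if g.qualifies else "suppressed"
    print(f"  offset={g.offset} len={g.length} subs={g.substitution_positions}"
          f" copies={g.copies} share={g.fraction:.3f} -> {status}")
# The printed share is per-reference; expression uses the read-count
# formula (copies * 1e-9 / library size).
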