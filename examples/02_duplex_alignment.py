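"""Pair two contigs into a miRNA duplex and encode its pairing states.

The star strand here is an imperfect reverse complement: one G:U wobble,
one mismatch, and a 2-nt 3' overhang — the geometry of a Dicer product."""

from mireader import ScoringScheme, complement_align

TOP = "UGAGGUAGUAGGUUGUAUAGUU"
#       perfect complement of TOP, then perturbed:
RC = {"A": "U", "U": "A", "G": "C", "C": "G"}
bottom = [RC[c] for c in reversed(TOP)]
bottom[21 - 1 - 10] = "U"   # column 10 becomes a G:U wobble (still pairs)
bottom[21 - 9] = "G"        # column 9 becomes an A:G mismatch
star = "".join(bottom) + "CA"  # 2-nt 3' overhang on the star strand

d = complement_align(TOP, star, ScoringScheme())
print("5'", d.aligned_top, "3'")
print("3'", d.aligned_bottom, "5'")
print(f"score={d.score}  overhangs: top3'={d.overhang_top3} "
      f"bottom3'={d.overhang_bottom3}")
print(f"pattern: {d.pattern}")
# M = paired column (Watson-Crick or G:U wobble), X = mismatch.
# The 20 matches + 1 wobble + 1 mismatch give 20*2 + 1 - 1 = 40; the
# overhang columns are free and are excluded from the encoded pattern.
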