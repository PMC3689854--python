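# Methods

## Problem setting and model

A mature miRNA duplex is the ~19–24 nt double-stranded Dicer product: the
mature strand and its partially complementary star strand, usually with
2-nt 3′ overhangs. Both strands are sequenced in small RNA libraries, so
a duplex can in principle be reconstructed from reads alone — without a
genome, a precursor model, or thermodynamics. The discriminative signal
this package exploits is *positional conservation of pairing states*:
where mismatches, insertions and deletions sit within real duplexes, and
how they co-occur across positions, differs from arbitrary complementary
RNA fragments. Nucleotide identity itself is deliberately discarded.

## Pipeline stages

**Read handling.** Sequences are normalised to {A,C,G,U}; reads outside a
15–35 nt window are dropped. Collapsing sums copy counts per distinct
sequence and orders tags lexicographically, making every downstream step
independent of input order. Reference mapping (used for training-set
construction and for screening) is same-strand substring search with a
configurable substitution tolerance (default 0); reverse-complement hits
are deliberately *not* mapping hits — duplex partners are found later by
alignment.

**Assembly.** Contigs are built by merging reads whose terminal
suffix–prefix overlap is exact and at least 5 nt, detected with the KMP
failure function in linear time. Merging is greedy: containments are
absorbed first, then the longest overlap wins, with ties broken by the
lexicographically smallest merged sequence. Greediness is a design
choice: the original method description specifies only pairwise merging, and in the
short, effectively repeat-free regime of miRNA arms the greedy order
reassembles tiled sources exactly (property-tested). Contigs longer than
80 nt are flagged and excluded from duplex search; mature arms are short,
so oversize assemblies indicate chimeras or non-miRNA transcripts.

**Duplex formation.** For a contig pair, the more abundant contig (summed
read copies; tie → lexicographic) is the top strand — in real libraries
the mature arm accumulates far more reads than the star arm, so abundance
orients the duplex. The top strand (5′→3′) is aligned against the
reversed partner under complementarity scoring: A:U/G:C +2, G:U +1,
other pairs −1, affine gaps (−5 first column of a run, −2 each further
column). The substitution values are package defaults — the original method
fixes only the gap penalties — and are exposed in `ScoringScheme`. Up to
two 3′-terminal bases per strand may be left unpaired at no cost; this is
implemented by enumerating the 9 overhang assignments and taking the
best-scoring core alignment (ties prefer fewer overhang columns). 5′ ends
are flush. Pairing over a pool is mutual-best by default (each contig in
at most one duplex), with a threshold policy available.

**Encoding.** Each paired-region column maps to one state: `M` for
Watson–Crick *or wobble* pairs, `X` for other base pairs, `I` for a gap
in the star strand, `D` for a gap in the top strand; overhang columns are
excluded. Which strand defines I vs D is fixed by the abundance
orientation above — a convention the original description leaves open but which must be
deterministic for profiles to be reproducible.

**Transition profiles.** Encoded patterns are clustered by exact length
(clusters with fewer than 5 patterns fold into the nearest length, with
inert `M` padding/truncation). Per cluster, five upper-triangular
matrices hold single-order transition probabilities for ordered position
pairs i < j: X–X, X–I, X–D, I–I, D–D. The two mixed families are
direction-symmetric (one matrix serving both orders); I–D transitions
have no family and score 0. The default normalisation is conditional —

    cell(i, j) = (n[a@i ∧ b@j] + κ) / (n[a@i] + 5κ),   κ = 0.5

with both orders counted and either state conditioning for the symmetric
families; a joint normalisation (denominator = cluster size) is available
behind a switch. The pseudocount κ keeps unobserved transitions non-zero;
max-scoring over exact zeros would be brittle. Scoring a query: every
non-match position j takes the maximum cell over all earlier non-match
positions; `M` positions and a leading non-match (no prior) score 0. The
cluster with the highest summed score is the representative profile;
clusters within ±2 nt of the query length are admissible, others are used
only as a flagged nearest-length fallback. Feature vectors have the
cluster's fixed width, with `M` positions contributing 0, so each
cluster's classifier sees constant-width input.

**Best-First trees.** The base classifier is a binary decision tree grown
best-first: a frontier of expandable leaves is ranked by weighted Gini
gain of each leaf's best split (candidate thresholds are midpoints
between consecutive distinct feature values), and the best leaf is
expanded next. Leaves stop at purity, at ≤ 2 instances, or when no
value-separating threshold exists. Zero-gain splits of impure nodes are
permitted: on parity-structured data (XOR) every first split is gain-free
yet the children separate, and the greedy criterion resolves one level
down. Because expansions are globally ordered, post-pruning reduces to
choosing the expansion count that minimises 5-fold cross-validated
misclassification (ties toward the shorter tree) and truncating.

**Multi-boosting.** The ensemble is boosting-with-wagging. Instance
weights start uniform (summing to n). The K iterations are divided into
⌈√K⌉ equal subcommittees; at each boundary the weights are reset to
wagging draws w = −ln U, U ∼ Uniform(0,1] (a continuous approximation to
Poisson resampling) and rescaled to sum n. Within a subcommittee,
classifier t has weighted error e = Σ_misclassified w / n and vote weight
log((1−e)/e); weights are multiplied by 1/(2e) (misclassified) and
1/(2(1−e)) (correct), which conserves Σw = n exactly — the trainer
records the residual after every step and the tests require < 1e-9. An
error-free classifier receives the capped vote log(1/β), β = 1e-10, and
closes its subcommittee; e > 0.5 triggers a wagging reset and refit, at
most 3 times, after which training stops. These numeric guards (β, the
1e-8 weight floor, the retry bound) follow the boosting literature the
algorithm descends from. Base trees inside the ensemble are grown with an
expansion budget (default 15) and no CV pruning — pruning every base
learner in every fold would multiply training cost ~25× for no measured
accuracy gain at these data sizes; the standalone tree API retains
pruning. Prediction sums vote weights per class; ties break toward the
class with the larger training prior, then negative. The positive vote
share in [0.5, 1] is the candidate score: 0.9 for novel discovery calls,
0.5 (plain argmax) in evaluation mode so sensitivity/specificity are
comparable across studies.

K defaults to 100; the shipped benchmark and acceptance runs use K = 30,
the lower end of the supported range, as the desk-scale problem size —
measured accuracy at K = 50–100 is within noise of K = 30 on this data.
Clusters with fewer than 40 training instances fold into the
nearest-length model.

**Iso-miRs and expression.** Reads mapped to a reference miRNA are
partitioned by (5′ offset, length, substitution-position signature); a
partition qualifies as an iso-miR group when it holds ≥ 3.5 % of the
reference's mapped copies and shows ≤ 2 substitution positions. The
qualifying share is per-reference by default (the original description is
ambiguous between per-reference and per-library; a switch selects the
other reading). The default expression value implements the original tool's
published read-count formula verbatim — mapped copies × 10⁻⁹ / library
size — although it is dimensionally odd (no length term, inverse-scaled);
a standard RPKM mode is provided and explicitly labelled as the
alternative.

## Synthetic data: what it emulates, and what it does not

`mireader.fixtures` generates all test data. Positives draw arm lengths
from a 19–24 nt distribution peaked at 21–22 and pairing patterns that
are mostly `M` with structured co-occurrences: three mismatch pairs at
fixed position pairs (planted with probabilities .95/.65/.50) and sparse
X–I, I–I, D–D motifs confined to the duplex tail (.25/.15/.10) — gap
states placed mid-pattern frame-shift the *recovered* encoding through
the aligner and would smear the positional signal the profiles rely on,
which is itself an observation about the method: its features are only as
positionally stable as the alignment. Matches are G:U wobbles 15 % of the
time; 0–2 nt 3′ overhangs are appended. Negatives are deliberately hard:
half are positives with their states randomly permuted (identical length
and composition, destroyed structure), half are noise duplexes over a
broader 18–30 nt range with position-independent states — so the
classifier cannot win on length or composition alone. Effect sizes were
chosen once so the benchmark is neither saturated nor impossible; the
documented benchmark seed is 1.

The benchmark (500+500 train, 500+500 test, independent substreams)
re-derives every pattern from the nucleotide arms through alignment and
encoding, so it exercises the full route, not just the classifier.

The planted-recovery library tiles reads from 10 planted duplexes plus
random decoy transcripts. Its constructor guarantees, by rejection
sampling, the preconditions under which recovery is a well-posed test of
the pipeline rather than of the fixture: sources are mutually
unmergeable (the repeat-free regime in which greedy assembly is exact),
each planted pattern is the aligner's optimal alignment of its own arms,
no decoy or foreign arm out-scores a true partner, and the mature arm is
tiled at 5× the star arm's depth so abundance orientation is
unambiguous. Planted positives carry all three mismatch motifs
(unambiguous class members): the test asks whether the *pipeline* loses
them, not whether borderline patterns classify correctly.

What passing these tests does **not** show: performance on real
libraries, where sequencing error, adapter remnants, expression skew far
beyond 5×, genuine repeats, and miRNA family structure all exist and none
is simulated. The synthetic results establish internal correctness and
that the pairing-state signal, when present, is recoverable end to end.

## Numerical and tie-break conventions

- Alignment traceback prefers paired columns, then gap-in-star; among
  equal-scoring overhang assignments the fewest overhang columns win.
  Scores are exact floats (half-integer arithmetic), compared with a
  1e-9 tolerance in traceback only.
- Split-search gains within 1e-12 are ties, broken toward the lower
  feature index then the lower threshold, so training is deterministic
  down to serialization bytes.
- All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; per-cluster model seeds are derived as
  (seed·1009 + cluster length) mod 2³¹−1.
- Serialized models/profiles store floats via `repr` for bit-exact
  round-trips; fixed seed ⇒ byte-identical JSON.
- Degenerate inputs: single-class training data yields a single-leaf
  model; references with one mapped read contribute no instance; empty
  duplex pools produce an empty report with stage-by-stage diagnostics.

## Parallelism contract

Worker counts parallelize the two embarrassingly parallel stages — the
per-reference assembly pool in training and the all-pairs duplex
alignment in discovery — through `parallel_map`, which merges results in
input order. Outputs are byte-identical for any worker count; the greedy
merge loop itself is inherently sequential.

## Known limitations

- The greedy assembler is not a general transcriptome assembler; it is
  correct in the short, repeat-free regime it targets and flags, rather
  than resolves, oversize contigs.
- A contig joins at most one duplex under the default mutual-best
  policy; precursors yielding several overlapping duplexes would need the
  threshold policy.
- Strand orientation relies on read-abundance asymmetry; duplexes with
  near-equal arm abundance may be encoded in the reversed frame relative
  to training.
- The score of the first non-match position is defined as 0 (no prior
  state); a marginal-probability fallback is conceivable but not
  implemented.
- Screening mismatch tolerance defaults to 0 and is a guess exposed as a
  flag; no adapter trimming or quality filtering is performed.
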