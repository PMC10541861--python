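# Methods

This note documents the models and procedures implemented in
`errantiscan`, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the design choices made where the
design was genuinely open.

## Small-RNA analysis

**Size classes.** Genome-mapping reads are classed purely by length:
piRNAs 23–29 nt, siRNAs 21 nt, everything else `other`
(`SizePolicy(pirna_min=23, pirna_max=29, sirna_len=21)`). The policy
rejects a siRNA length inside the piRNA window.

**Bounded-substitution mapping.** Reads are placed on both strands of a
target at every offset where the Hamming distance is within the policy
bound (defaults: 3 mismatches for piRNA→TE, 1 for siRNA→TE, 0 for
genome-unique filtering). Indels are not modelled — at 21–29 nt a read
with an indel against its source is better treated as unmapped. `N`
matches nothing, including another `N`. The batch mapper
(`map_reads`) uses pigeonhole seeding — a placement with ≤ k mismatches
must contain an exact probe among k+1 disjoint probes — and is tested to
return exactly the per-read exhaustive scan's output. A read whose
sequence equals its own reverse complement legitimately yields placements
on both strands at the same offset.

**Multimapper collapse.** A read counts once per target: the placement
with the fewest mismatches wins, ties broken by leftmost start, then `+`
before `-`. Fractional weighting was considered and rejected: the
ping-pong statistic is a pair count, and fractional pair counts have no
clean interpretation in the position-convolution form used here.

**Normalization.** RPM = count × 10⁶ / (genome-mapping reads of the same
class); RPKM additionally divides by target length in kb. In windowed
density profiles RPKM divides by the *window* length (91 nt for a
full-length element, 86 nt for the internal sequence, 140 nt for a
~20-kb cluster region are the profile sizes used in practice), so the
last, possibly partial window remains comparable.

**Ping-pong signature.** For a set of placements on one target, the
overlap histogram counts, for d = 1..23, pairs of a plus-strand 5′ end at
p with a minus-strand 5′ end at p + d − 1, as a convolution of
per-position 5′-end multiplicities (each read pair counts once, with
multiplicity). The Z-score of the d = 10 class is computed against the
other 22 classes: the tested value is excluded from its own background,
and the sample standard deviation (n−1) is used. Both conventions are
switchable (`include_d10_in_background`, `population_sd`) because the
field is not uniform about either; excluding the tested class is the
default here since including it shrinks and biases the score toward
non-significance at strong signals. Degenerate backgrounds (zero spread)
return Z = 0 when there is no excess at d = 10 and a None sentinel
otherwise — a constant background with a positive excess has no
meaningful Z. The spread comparison uses a 1e-9 tolerance because a
mathematically constant background accumulates ~1e-15 float noise.
Significance is Z > 1.96 (one-sided 5% under a normal background).

**Depletion flagging.** Condition-vs-control ratios below 0.3 flag a
target as depleted; a zero denominator yields an undefined (NaN) ratio
and never a flag.

## Long-read insertion census

**Built-in aligner** (`seedalign.SeedIndex`). Exact 15-mer seeds are
grouped per (reference, diagonal), merged across gaps of ≤ 120 bp when
the bridged segment has ≤ max(3, gap/2) mismatches and the merged run
keeps ≥ 90% identity, then extended with an X-drop rule (+1 match, −4
mismatch, drop 20, trimmed back to the best-scoring match). The X-drop
is what stops extension at a deletion junction: a global identity floor
would let a long upstream match absorb hundreds of junction mismatches.
No gapped alignment is attempted; substitution-only errors keep true
alignments on single diagonals, which is exactly what the simulator
produces and what the chaining stage consumes. Externally computed
BLAST6/PAF hits can be substituted for real (indel-rich) data.

**Chaining.** Internal-sequence hits of one read and orientation are
chained in read order with the TE coordinate advancing. A chain is split
when the TE coordinate resets backwards by > 30 bp (tandem copies) or
when the read gap exceeds 200 bp while the TE gap is smaller than the
read gap (unexplained intervening sequence). LTR hits attach to the
chain they are read-adjacent to; LTR hits with no internal chain are
kept as solo-LTR evidence but produce no insertion call.

**Deletion calling.** For consecutive internal hits, a deletion
(prev_end+1, next_start−1) is called when the TE gap exceeds the read
gap by ≥ 50 bp (`min_del`); a balanced gap is diverged sequence, not a
deletion. When the two hits overlap on the read (junction
microhomology), the overlap is restored to the left end so the deletion
length is preserved. Deletions flush with the internal-sequence
boundary (a removed 5′-UTR) leave no hit pair to gap between; they are
inferred when an LTR hit is read-adjacent (≤ 60 bp) to a truncated
internal edge (`infer_deletions`).

**Variant catalog.** Precedence v2 > v3 > v1 > other > fl, with ±30 bp
breakpoint tolerance (chosen to absorb alignment end-trimming at 2%
substitution error; the value is deliberately generous — variant classes
in the catalog differ by hundreds of bp). `fl` requires no deletion
≥ 50 bp and coverage of internal [1+50, L−50]. Chains covering < 50% of
the internal sequence, or matching no rule, are `fragment` and excluded
from locus variant votes.

**Localization.** Read flanks (≥ 500 bp outside the chain span) are
mapped to the insertion-free reference; the call position is the first
reference base after the junction, adjusted by any unaligned flank tail.
Both flanks on one chromosome within 100 bp give support `both`;
different chromosomes reject the call (reported with a reason, as are
unmappable and too-short flanks). Target-site duplications up to 20 bp
are tolerated, reporting the leftmost junction.

**Dedup, empty sites, novelty.** Calls cluster per chromosome by
single linkage within 100 bp; the locus variant is the majority vote of
non-fragment calls (ties to the most specific class), the position the
median call. Empty-site verification searches the reads for a ≥ 90%
identity match spanning the insertion-free junction with ≥ 100 bp
anchored on each side; it is off by default in the census pipeline
because the simulated insertions are homozygous (every locus is
trivially "absent"), and on small heterozygous fixtures it is exercised
by the tests. A locus is `shared` when a reference annotation interval
of the same family lies within 100 bp.

## RNA-seq variant quantification

Spliced records (QNAME/RNAME/POS/CIGAR subset of SAM) are resolved into
reference blocks; N gaps always split blocks, D gaps split at ≥ 20 bp
(aligners encode the same junction either way), shorter deletions merge
into the flanking block. A junction read must skip the deleted interval
with both breakpoints within ±5 nt (aligner wobble) and ≥ 10 aligned nt
on each side. Full-length expression counts reads with one block
covering the deletion's left edge ± 10 nt — only the left edge, because
the right edge is also reached by variants with other internal
deletions. "At the edge" is not defined more precisely by convention,
so the ±10-nt contiguous-window reading is a design choice here. Both
counts are normalized to the control transcript's mean per-base
coverage; the ratio is invariant under duplicating the whole record set.

## Synthetic data

The generators emulate the statistical structure the analyses consume,
not sequencing chemistry:

* **Consensus** — random 7500-bp internal sequence + 454-bp LTR with
  features 5′-UTR 1–800, gag 801–2700, pol 2701–6300, env 6301–7400, so
  the canonical v2 interval (5494–6120, 627 bp) sits at the pol 3′ end
  and v3 (303 bp) inside the UTR. The two canonical junctions are made
  microhomology-free (the bases flanking each breakpoint are forced to
  differ), so an error-free deletion call has exactly one coordinate
  representation; real consensus sequences can be swapped in.
* **Small-RNA libraries** — antisense reads uniform over the internal
  sequence; a configurable fraction receives a sense partner at exactly
  10-nt 5′ overlap; remaining sense reads independent; lengths from a
  size-weight table (default uniform 23–29 nt); the first base is forced
  to T with probability `u1_bias` (default 0.75, a typical 1U fraction
  for mature piRNAs), which may introduce one mismatch versus the
  consensus — intentionally, since real piRNA 5′ ends are selected, not
  templated, and the mapping bound must absorb it.
* **Genomes** — per-arm random sequence with planted LTR–internal–LTR
  elements at stated positions; truth tables and the reference
  annotation are in insertion-free coordinates so flank-mapped calls are
  scored directly. The shipped `fig1a` fixture plants 18 insertions (7
  fl with one reference-shared, 1 v1, 4 v2, 2 v3, 4 other) across five
  400-kb arms.
* **Long reads** — log-normal lengths (default mean 12 kb, sd 6 kb,
  floor 200 bp), uniform substitution errors (default 2%), random
  strand; reads are drawn until total bases reach depth × genome length,
  so realized depth is within one read of the request. Indel errors and
  quality models are deliberately absent — the built-in aligner and the
  chain/deletion logic are substitution-domain tools; for indel-rich
  reads an external aligner's BLAST6/PAF hits are the supported path.
* **RNA-seq** — single-end 150-nt reads from transcripts proportional to
  weight × (length − 149); deletion-transcript reads crossing the
  junction are emitted with the corresponding `N`-gap CIGAR. Paired-end
  sequencing adds nothing to the counted statistics and is not emulated.

Because the generators share none of the analysis code paths (they plant
sequence, the analyses recover coordinates), passing tests demonstrate
coordinate-exact recovery under substitution noise; they do not
demonstrate robustness to indels, chimeric reads, or non-uniform
coverage, which real ONT data exhibit.

## Reproducibility and problem sizes

Every stage takes a single integer seed; stage seeds are spawned from
the master seed via `numpy.random.SeedSequence`, so runs are exactly
reproducible and stages are independently perturbable. The analysis
drivers and acceptance script use a 2-Mb genome at 25× (≈ 4,500 reads)
and 20,000-read small-RNA libraries — sizes chosen so a full run
completes in about a minute on one CPU while keeping ≥ 30 reads of
support per locus and tight binomial bounds on the calibration checks.
The pipeline report carries a hash of its configuration and the seed.

## Known limitations

* The built-in aligner is substitution-only by design; indel-dominated
  reads need external hits.
* Variant classification requires reads spanning most of the element;
  at much shorter read lengths than simulated here loci would be
  recovered but typed only as fragments.
* The empty-site check is O(total read bases) per batch of loci and is
  intended for targeted verification, not genome-wide scans.
* Ping-pong Z-scores treat overlap-class percentages as an i.i.d.
  background; with very few pairs the normal approximation is poor, and
  the all-zero histogram is rejected rather than scored.
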