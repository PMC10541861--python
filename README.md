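# errantiscan

Analytics for errantivirus (insect endogenous LTR-retrovirus) reactivation
studies, built around the *Drosophila* ZAM element. The package implements
the three computational pillars of such a study, each with a seeded
synthetic-data generator standing in for the raw sequencing:

1. **Small-RNA analysis** (`errantiscan.smallrna`) — size classification of
   genome-mapping reads into piRNAs (23–29 nt) and siRNAs (21 nt),
   bounded-substitution mapping to TE consensus sequences (≤3 mismatches for
   piRNAs, ≤1 for siRNAs, 0 for genome-unique reads), RPM/RPKM
   normalization, windowed density profiles, and the **ping-pong signature**:
   for sense/antisense read pairs, the percentage of exactly 10-nt 5′
   overlaps among all 1–23-nt overlaps, scored as

   *Z = (pct₁₀ − mean(pct_d, d≠10)) / sd(pct_d, d≠10)*,

   significant when Z > 1.96. The 10-nt overlap is the geometric fingerprint
   of germline piRNA amplification (PIWI proteins cut their target 10 nt
   from the guide's 5′ end).

2. **Long-read insertion census** (`errantiscan.longread`) — detection of
   TE-carrying reads by seed-and-extend local alignment against the
   consensus (internal sequence + 454-bp LTR), chaining of per-read hits,
   internal-deletion calling from chain gaps, classification against a
   named variant catalog (`fl` full length; `v1` deleted 5′-UTR; `v2`
   pol-end deletion at internal positions 5494–6120; `v3` 303-bp 5′-UTR
   deletion; `other`), insertion-site localization by flank mapping,
   locus deduplication, empty-site (insertion-free allele) verification,
   and novelty annotation against a reference TE BED. External BLAST6/PAF
   hits can replace the built-in aligner anywhere.

3. **Variant expression from RNA-seq** (`errantiscan.rnaseq_quant`) —
   junction-split read counting for a deletion variant (gap matching the
   deleted interval within ±5 nt, ≥10 nt anchors) and contiguous read
   counting across the deletion's left edge for the full-length element,
   both normalized to a control transcript's mean coverage.

`errantiscan.synthetic_data` generates every input with planted truth:
small-RNA libraries with a configurable fraction of ping-pong pairs,
genomes with planted catalog variants, log-normal long reads with
substitution errors, and spliced alignments over variant transcripts.

## Worked example

```sh
python analysis/01_pingpong_signature.py
python analysis/02_genome_census.py
python analysis/03_variant_expression.py
```

Output from the census driver (seed 1):

```
reads: 4463, calls: 681, rejections: 30
loci: 18 (17 novel, 1 shared with the reference annotation)
by variant: {'fl': 7, 'other': 4, 'v1': 1, 'v2': 4, 'v3': 2}
recall 1.00, precision 1.00, variant agreement 1.00
```

A ~2-Mb five-arm genome is planted with 18 insertions (7 full-length, one
of them marked as present in the reference annotation, 1 v1, 4 v2, 2 v3,
4 other), sequenced to 25× with 2% substitution errors, and every planted
locus is recovered at its position with the correct variant label; the 17
loci absent from the reference annotation are flagged novel. The
ping-pong driver prints `Z = 36.13` for the strongly paired library and a
null calibration in which Z stays below 1.96 in 18/20 seeds. The
expression driver reports v2 and full-length expression normalized to the
control transcript's coverage (`v_norm 0.868`, `fl_norm 0.891` — close,
as expected for an equimolar mixture).

The same stages are scriptable via the CLI:

```sh
errantiscan simulate longreads --fixture fig1a --seed 1 --out sim/
errantiscan detect --te sim/consensus.fa --te-annot annot.yaml \
    --genome sim/genome_base.fa --reads sim/longreads.fq \
    --reference-bed sim/reference_te.bed --out loci.bed --report loci.tsv
errantiscan quantify --sam aln.sam --junction ZAM_I:5494-6120 --control pointed:1-2000
```

## Layout

```
src/errantiscan/     library: formats, smallrna, seedalign, longread,
                     rnaseq_quant, synthetic_data, pipeline, cli
analysis/            numbered narrative drivers writing results/
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      models, parameters, design choices, limitations
```
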