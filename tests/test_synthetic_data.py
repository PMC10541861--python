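"""Generator contracts: determinism, planted-truth consistency, and the
statistical structure each simulator promises."""

import numpy as np
import pandas as pd
import pytest

from errantiscan import longread, smallrna, synthetic_data
from errantiscan.formats import reverse_complement
from errantiscan.synthetic_data import (
    GenomeSimParams,
    LongReadSimParams,
    PlantedInsertion,
    RnaSeqSimParams,
    SmallRnaSimParams,
)


class TestGenTeConsensus:
    def test_default_geometry(self, te):
        assert len(te.ltr.sequence) == 454
        assert len(te.internal.sequence) == 7500
        assert te.features["five_prime_utr"] == (1, 800)

    def test_seed_determinism(self):
        a = synthetic_data.gen_te_consensus(seed=11)
        b = synthetic_data.gen_te_consensus(seed=11)
        assert a.internal.sequence == b.internal.sequence
        assert a.ltr.sequence == b.ltr.sequence
        c = synthetic_data.gen_te_consensus(seed=12)
        assert c.internal.sequence != a.internal.sequence

    def test_v2_removes_627_bases(self, te, catalog):
        out = catalog.apply("v2", te.internal.sequence)
        assert len(te.internal.sequence) - len(out) == 627

    def test_feature_outside_internal_rejected(self):
        with pytest.raises(ValueError):
            synthetic_data.gen_te_consensus(features={"five_prime_utr": (1, 9000)})


class TestGenSmallRnaLibrary:
    def test_truth_matches_reads(self, te):
        reads, truth = synthetic_data.gen_smallrna_library(
            te, SmallRnaSimParams(n_reads=500, seed=5)
        )
        assert len(reads) == len(truth) == 500
        by_id = {r.id: r for r in reads}
        internal = te.internal.sequence
        for row in truth.itertuples():
            seq = by_id[row.read_id].sequence
            assert len(seq) == row.length
            if row.strand == "+":
                planted = internal[row.five_prime - 1 : row.five_prime + row.length - 1]
            else:
                planted = reverse_complement(
                    internal[row.five_prime - row.length : row.five_prime]
                )
            if row.u1_forced:
                assert seq[0] == "T" and seq[1:] == planted[1:]
            else:
                assert seq == planted

    def test_pairs_overlap_by_ten(self, te):
        reads, truth = synthetic_data.gen_smallrna_library(
            te, SmallRnaSimParams(n_reads=2000, pp_fraction=1.0, seed=5)
        )
        t = truth.set_index("read_id")
        pairs = truth[truth.partner_of.notna()]
        assert len(pairs) > 0
        for row in pairs.itertuples():
            anti = t.loc[row.partner_of]
            assert anti.strand == "-" and row.strand == "+"
            assert anti.five_prime - row.five_prime + 1 == 10

    def test_size_histogram_matches_weights(self, te):
        weights = {23: 0.5, 26: 0.3, 29: 0.2}
        n = 10000
        reads, _ = synthetic_data.gen_smallrna_library(
            te, SmallRnaSimParams(n_reads=n, size_weights=weights, seed=6)
        )
        counts = pd.Series([len(r.sequence) for r in reads]).value_counts()
        for size, w in weights.items():
            sd = np.sqrt(n * w * (1 - w))
            assert abs(counts[size] - n * w) <= 3 * sd

    def test_u1_bias_within_binomial_bound(self, te):
        n = 10000
        reads, _ = synthetic_data.gen_smallrna_library(
            te, SmallRnaSimParams(n_reads=n, u1_bias=0.8, seed=7)
        )
        frac = smallrna.five_prime_base_composition(reads)["T"]
        sd = np.sqrt(0.8 * 0.2 / n)
        # background T at position 1 also occurs without forcing: bound loosely
        assert 0.8 - 3 * sd <= frac <= 0.8 + 0.25 * 0.2 + 3 * sd

    def test_seed_determinism(self, te):
        a, _ = synthetic_data.gen_smallrna_library(te, SmallRnaSimParams(n_reads=200, seed=9))
        b, _ = synthetic_data.gen_smallrna_library(te, SmallRnaSimParams(n_reads=200, seed=9))
        assert a == b


class TestGenGenomeWithInsertions:
    def _params(self, insertions, **kw):
        return GenomeSimParams(
            genome_length=200_000, n_chroms=2, insertions=insertions,
            chrom_names=("c1", "c2"), seed=3, **kw,
        )

    def test_length_accounting_fl(self, te, catalog):
        p = self._params([PlantedInsertion("fl", "c1", 10_000)])
        sim = synthetic_data.gen_genome_with_insertions(te, catalog, p)
        delta = len(sim.inserted[0].sequence) - len(sim.base[0].sequence)
        assert delta == 2 * 454 + 7500
        assert len(sim.inserted[1].sequence) == len(sim.base[1].sequence)

    def test_truth_rows_match_requests(self, te, catalog):
        ins = [
            PlantedInsertion("fl", "c1", 10_000, shared=True),
            PlantedInsertion("v2", "c1", 50_000),
            PlantedInsertion("v3", "c2", 30_000),
        ]
        sim = synthetic_data.gen_genome_with_insertions(te, catalog, self._params(ins))
        assert len(sim.truth) == 3
        assert len(sim.reference_annotation) == 1
        assert sim.reference_annotation[0].chrom == "c1"

    def test_overlapping_insertions_rejected(self, te, catalog):
        ins = [PlantedInsertion("fl", "c1", 10_000), PlantedInsertion("fl", "c1", 10_000)]
        with pytest.raises(ValueError, match="overlap"):
            synthetic_data.gen_genome_with_insertions(te, catalog, self._params(ins, tsd_len=5))

    def test_planted_elements_reclassify_to_requested_label(self, te, catalog):
        """Extract each planted element and push it back through the
        deletion caller + classifier."""
        ins = [
            PlantedInsertion("fl", "c1", 20_000),
            PlantedInsertion("v2", "c1", 60_000),
            PlantedInsertion("v1", "c2", 20_000),
            PlantedInsertion("v3", "c2", 60_000),
        ]
        sim = synthetic_data.gen_genome_with_insertions(te, catalog, self._params(ins))
        from errantiscan.formats import SequenceRecord

        offset = {"c1": 0, "c2": 0}
        for row in sim.truth.itertuples():
            chrom = next(g for g in sim.inserted if g.id == row.chrom)
            start0 = row.position - 1 + offset[row.chrom]
            element = chrom.sequence[start0 : start0 + row.element_length]
            offset[row.chrom] += row.element_length
            read = SequenceRecord(
                f"x_{row.chrom}_{row.position}",
                sim.base[0].sequence[:1000] + element + sim.base[0].sequence[-1000:],
            )
            hits = longread.find_te_hits(read, te)
            chain = [
                c for c in longread.chain_hits(hits, internal_id=te.internal.id)
                if c.te_coverage
            ][0]
            dels = longread.infer_deletions(chain, te)
            assert longread.classify_variant(dels, chain, te, catalog) == row.variant


class TestGenLongReads:
    def test_error_free_reads_are_substrings(self, rng):
        from conftest import random_seq
        from errantiscan.formats import SequenceRecord

        genome = [SequenceRecord("g", random_seq(rng, 60_000))]
        reads, truth = synthetic_data.gen_long_reads(
            genome, LongReadSimParams(depth=3, length_mean=4000, length_sd=1500,
                                      subst_rate=0.0, seed=4)
        )
        by_id = {r.id: r for r in reads}
        for row in truth.itertuples():
            seg = genome[0].sequence[row.start - 1 : row.end]
            read = by_id[row.read_id].sequence
            assert read == (seg if row.strand == "+" else reverse_complement(seg))

    def test_realized_depth_within_5pct(self, rng):
        from conftest import random_seq
        from errantiscan.formats import SequenceRecord

        genome = [SequenceRecord("g", random_seq(rng, 200_000))]
        reads, _ = synthetic_data.gen_long_reads(
            genome, LongReadSimParams(depth=20, length_mean=8000, length_sd=4000, seed=5)
        )
        realized = sum(len(r.sequence) for r in reads) / 200_000
        assert abs(realized - 20) / 20 <= 0.05

    def test_substitution_rate_close_to_requested(self, rng):
        from conftest import random_seq
        from errantiscan.formats import SequenceRecord

        genome = [SequenceRecord("g", random_seq(rng, 100_000))]
        reads, truth = synthetic_data.gen_long_reads(
            genome, LongReadSimParams(depth=5, subst_rate=0.02, seed=6)
        )
        by_id = {r.id: r for r in reads}
        mm = tot = 0
        for row in truth.itertuples():
            seg = genome[0].sequence[row.start - 1 : row.end]
            read = by_id[row.read_id].sequence
            if row.strand == "-":
                read = reverse_complement(read)
            mm += sum(1 for a, b in zip(read, seg) if a != b)
            tot += len(seg)
        assert abs(mm / tot - 0.02) < 0.005

    def test_seed_determinism_byte_identical(self, rng, tmp_path):
        from conftest import random_seq
        from errantiscan import formats
        from errantiscan.formats import SequenceRecord

        genome = [SequenceRecord("g", random_seq(rng, 50_000))]
        p = LongReadSimParams(depth=2, seed=8)
        a, _ = synthetic_data.gen_long_reads(genome, p)
        b, _ = synthetic_data.gen_long_reads(genome, p)
        fa, fb = tmp_path / "a.fq", tmp_path / "b.fq"
        formats.write_fastq(a, fa)
        formats.write_fastq(b, fb)
        assert fa.read_bytes() == fb.read_bytes()


class TestGenSplicedRnaseq:
    def test_junction_read_cigar(self, te, catalog):
        records, truth, _ = synthetic_data.gen_spliced_rnaseq(
            te, catalog, RnaSeqSimParams(n_reads=3000, seed=9)
        )
        by_id = {r.read_id: r for r in records}
        crossing = truth[truth.crosses_junction]
        assert len(crossing) > 0
        for row in crossing.itertuples():
            assert "627N" in by_id[row.read_id].cigar

    def test_zero_deletion_weight_zero_junction_count(self, te, catalog):
        from errantiscan import rnaseq_quant

        records, _, _ = synthetic_data.gen_spliced_rnaseq(
            te, catalog,
            RnaSeqSimParams(transcripts={"fl": 1.0, "control": 1.0}, n_reads=2000, seed=9),
        )
        spec = rnaseq_quant.JunctionSpec(te.internal.id, 5494, 6120)
        assert rnaseq_quant.count_junction_reads(records, spec) == 0

    def test_junction_fraction_matches_positional_expectation(self, te, catalog):
        p = RnaSeqSimParams(transcripts={"v2": 1.0}, n_reads=20000, seed=10)
        records, truth, _ = synthetic_data.gen_spliced_rnaseq(te, catalog, p)
        # a 150-nt read crosses the junction (needs >=1 base both sides)
        # iff its start lies in [dl - 149, dl - 1]: 149 of L - 149 positions
        tlen = 7500 - 627
        n_starts = tlen - 150 + 1
        expect = 149 / n_starts
        frac = truth.crosses_junction.mean()
        sd = np.sqrt(expect * (1 - expect) / len(truth))
        assert abs(frac - expect) <= 3 * sd

    def test_read_longer_than_transcript_rejected(self, te, catalog):
        with pytest.raises(ValueError):
            synthetic_data.gen_spliced_rnaseq(
                te, catalog,
                RnaSeqSimParams(transcripts={"control": 1.0}, read_length=150,
                                control_length=100, n_reads=10),
            )


class TestFixturesAndScoring:
    def test_fig1a_fixture_composition(self):
        cfg = synthetic_data.load_fixture("fig1a")
        variants = [e["variant"] for e in cfg["insertions"]]
        assert len(variants) == 18
        assert variants.count("fl") == 7
        assert variants.count("v2") == 4
        assert variants.count("v3") == 2
        assert variants.count("v1") == 1
        assert variants.count("other") == 4
        assert sum(bool(e.get("shared")) for e in cfg["insertions"]) == 1

    def test_score_detection_perfect_and_missed(self):
        truth = pd.DataFrame(
            [{"chrom": "c1", "position": 1000, "variant": "fl"},
             {"chrom": "c1", "position": 9000, "variant": "v2"}]
        )
        loci = [longread.InsertionLocus("c1", 1005, "fl", 3)]
        score = synthetic_data.score_detection(loci, truth)
        assert score["recall"] == 0.5 and score["precision"] == 1.0
        assert score["position_errors"] == [5]
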