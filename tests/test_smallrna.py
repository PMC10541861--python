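"""Small-RNA classification, bounded-mismatch mapping, normalization and
the ping-pong overlap statistic, each checked against an independent
brute-force oracle where one exists."""

import numpy as np
import pytest

from errantiscan import smallrna
from errantiscan.formats import SequenceRecord, reverse_complement
from errantiscan.smallrna import (
    DensityProfileSpec,
    MappingPolicy,
    NormalizationContext,
    OverlapHistogram,
    SizePolicy,
    TePlacement,
)

from conftest import random_seq


def _rec(seq, rid="r"):
    return SequenceRecord(rid, seq)


class TestClassifyBySize:
    def test_canonical_lengths(self):
        reads = [_rec("A" * n, f"r{n}") for n in (21, 25, 30)]
        bins = smallrna.classify_by_size(reads)
        assert len(bins["sirna"]) == 1 and bins["sirna"][0].id == "r21"
        assert len(bins["pirna"]) == 1 and bins["pirna"][0].id == "r25"
        assert len(bins["other"]) == 1 and bins["other"][0].id == "r30"

    def test_empty_input(self):
        bins = smallrna.classify_by_size([])
        assert all(len(v) == 0 for v in bins.values())

    def test_brute_force_recount(self, rng):
        reads = [_rec("A" * int(n), f"r{i}") for i, n in enumerate(rng.integers(18, 33, 1000))]
        bins = smallrna.classify_by_size(reads)
        lengths = [len(r.sequence) for r in reads]
        assert len(bins["pirna"]) == sum(23 <= n <= 29 for n in lengths)
        assert len(bins["sirna"]) == sum(n == 21 for n in lengths)
        assert len(bins["other"]) == sum(n < 21 or n == 22 or n > 29 for n in lengths)

    def test_inconsistent_policy_rejected(self):
        with pytest.raises(ValueError):
            SizePolicy(pirna_min=23, pirna_max=29, sirna_len=25)


def brute_force_placements(read, target, max_mm):
    """Exhaustive all-offsets Hamming scan, both strands; N matches nothing."""
    out = []
    for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        L = len(seq)
        for start in range(1, len(target.sequence) - L + 2):
            window = target.sequence[start - 1 : start + L - 1]
            mm = sum(1 for a, b in zip(seq, window) if a != b or a == "N" or b == "N")
            if mm <= max_mm:
                out.append((start, strand, mm))
    return sorted(out)


class TestMapRead:
    def test_exact_plus(self):
        (p,) = smallrna.map_read(_rec("AACCG"), _rec("TTAACCGTT", "t"), MappingPolicy(0))
        assert (p.start, p.strand, p.five_prime) == (3, "+", 3)

    def test_palindromic_read_matches_both_strands(self):
        hits = smallrna.map_read(_rec("ACGT"), _rec("TTACGTTT", "t"), MappingPolicy(0))
        assert [(p.start, p.strand) for p in hits] == [(3, "+"), (3, "-")]

    def test_exact_minus_five_prime(self):
        (p,) = smallrna.map_read(_rec("AACG"), _rec("TTCGTTAA", "t"), MappingPolicy(0))
        assert (p.start, p.strand) == (3, "-")
        assert p.five_prime == 6

    def test_n_matches_nothing(self):
        hits = smallrna.map_read(_rec("AANT"), _rec("CCAAGTCC", "t"), MappingPolicy(0))
        assert hits == []
        (p,) = smallrna.map_read(_rec("AANT"), _rec("CCAAGTCC", "t"), MappingPolicy(1))
        assert (p.start, p.strand, p.mismatches) == (3, "+", 1)

    @pytest.mark.parametrize("max_mm", [0, 1, 3])
    def test_matches_exhaustive_hamming_scan(self, rng, max_mm):
        target = _rec(random_seq(rng, 8000), "T")
        tseq = target.sequence
        for _ in range(20):
            # half planted (guaranteed hits), half random
            if rng.random() < 0.5:
                s = int(rng.integers(0, 8000 - 24))
                seq = list(tseq[s : s + 24])
                for i in rng.choice(24, size=int(rng.integers(0, max_mm + 1)), replace=False):
                    seq[i] = "ACGT"[int(rng.integers(0, 4))]
                seq = "".join(seq)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
            else:
                seq = random_seq(rng, 24)
            read = _rec(seq, "q")
            got = sorted(
                (p.start, p.strand, p.mismatches)
                for p in smallrna.map_read(read, target, MappingPolicy(max_mm))
            )
            assert got == brute_force_placements(read, target, max_mm)


class TestMapReadsBatch:
    def test_batch_equals_per_read(self, rng):
        """The seeded batch mapper returns exactly the per-read scan's
        placements, including N handling and multi-hit reads."""
        target = _rec(random_seq(rng, 5000), "T")
        reads = []
        for i in range(120):
            L = int(rng.integers(21, 30))
            if rng.random() < 0.6:
                s = int(rng.integers(0, 5000 - L))
                seq = list(target.sequence[s : s + L])
                for j in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
                    seq[j] = "ACGTN"[int(rng.integers(0, 5))]
                seq = "".join(seq)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
            else:
                seq = random_seq(rng, L)
            reads.append(_rec(seq, f"q{i}"))
        batch = smallrna.map_reads(reads, target, MappingPolicy(3))
        per = []
        for r in reads:
            per.extend(smallrna.map_read(r, target, MappingPolicy(3)))
        key = lambda p: (p.read_id, p.start, p.strand, p.mismatches)
        assert sorted(batch, key=key) == sorted(per, key=key)


class TestGenomeUniqueFilter:
    def test_unique_kept_revcomp_duplicate_dropped(self, rng):
        core = random_seq(rng, 25)
        genome = [_rec(random_seq(rng, 200) + core + random_seq(rng, 200), "g1")]
        assert smallrna.genome_unique_filter([_rec(core, "u")], genome) == [_rec(core, "u")]
        genome2 = [
            _rec(
                random_seq(rng, 100) + core + random_seq(rng, 100)
                + reverse_complement(core) + random_seq(rng, 100),
                "g1",
            )
        ]
        assert smallrna.genome_unique_filter([_rec(core, "u")], genome2) == []

    def test_agreement_with_enumeration(self, rng):
        genome = [_rec(random_seq(rng, 50000), "g1"), _rec(random_seq(rng, 50000), "g2")]
        reads = []
        for i in range(50):
            g = genome[int(rng.integers(0, 2))]
            s = int(rng.integers(0, len(g.sequence) - 25))
            reads.append(_rec(g.sequence[s : s + 25], f"p{i}"))
        kept = smallrna.genome_unique_filter(reads, genome)
        for r in reads:
            n = sum(
                len(smallrna.map_read(r, g, MappingPolicy(0))) for g in genome
            )
            assert (r in kept) == (n == 1)


class TestCounting:
    def test_antisense_counts(self):
        pls = [TePlacement(f"r{i}", "ZAM", 10 + i, "-", 0, 25) for i in range(3)]
        df = smallrna.count_by_target(pls)
        assert df.loc["ZAM", "antisense"] == 3 and df.loc["ZAM", "sense"] == 0

    def test_multi_placement_counts_once(self):
        pls = [
            TePlacement("r1", "ZAM", 10, "+", 1, 25),
            TePlacement("r1", "ZAM", 400, "+", 0, 25),
        ]
        df = smallrna.count_by_target(pls)
        assert df.loc["ZAM", "sense"] == 1

    def test_randomized_tally(self, rng):
        pls = [
            TePlacement(f"r{int(i)}", f"t{int(t)}", int(s), "+-"[int(st)], 0, 25)
            for i, t, s, st in zip(
                rng.integers(0, 200, 500), rng.integers(0, 3, 500),
                rng.integers(1, 1000, 500), rng.integers(0, 2, 500),
            )
        ]
        df = smallrna.count_by_target(pls)
        # independent tally: unique (read, target) pairs per strand of best placement
        seen = {}
        for p in pls:
            key = (p.read_id, p.target_id)
            cur = seen.get(key)
            rank = (p.mismatches, p.start, 0 if p.strand == "+" else 1)
            if cur is None or rank < cur[0]:
                seen[key] = (rank, p)
        expect = {}
        for (_, p) in seen.values():
            k = (p.target_id, p.strand)
            expect[k] = expect.get(k, 0) + 1
        for (t, strand), n in expect.items():
            col = "sense" if strand == "+" else "antisense"
            assert df.loc[t, col] == n


class TestNormalization:
    def test_rpm_formula(self):
        ctx = NormalizationContext(total_genome_mapping=1_000_000)
        assert smallrna.rpm(50, ctx) == 50.0
        assert smallrna.rpm(0, ctx) == 0.0

    def test_rpkm_formula(self):
        ctx = NormalizationContext(1_000_000, {"t": 2000, "u": 1000})
        assert smallrna.rpkm(100, "t", ctx) == 50.0
        assert smallrna.rpkm(100, "u", ctx) == smallrna.rpm(100, ctx)

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            smallrna.rpkm(1, "missing", NormalizationContext(10))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            NormalizationContext(total_genome_mapping=0)

    def test_linearity(self, rng):
        ctx = NormalizationContext(123457, {"t": 777})
        for _ in range(20):
            a, b = (int(x) for x in rng.integers(0, 10000, 2))
            assert smallrna.rpm(a + b, ctx) == pytest.approx(
                smallrna.rpm(a, ctx) + smallrna.rpm(b, ctx)
            )
            assert smallrna.rpkm(a, "t", ctx) == pytest.approx(
                smallrna.rpm(a, ctx) / 0.777
            )


def _pl(rid, fp, strand, length=25):
    start = fp if strand == "+" else fp - length + 1
    return TePlacement(rid, "T", start, strand, 0, length)


class TestOverlapHistogram:
    def test_canonical_pingpong_pair(self):
        hist = smallrna.overlap_histogram([_pl("a", 100, "+"), _pl("b", 109, "-")])
        assert hist.counts[10] == 1 and hist.total == 1

    def test_d1_boundary(self):
        hist = smallrna.overlap_histogram([_pl("a", 100, "+"), _pl("b", 100, "-")])
        assert hist.counts[1] == 1 and hist.total == 1

    def test_matches_quadratic_enumeration(self, rng):
        for _ in range(10):
            pls = [
                _pl(f"r{i}", int(fp), "+-"[int(s)])
                for i, (fp, s) in enumerate(zip(rng.integers(30, 130, 120), rng.integers(0, 2, 120)))
            ]
            hist = smallrna.overlap_histogram(pls)
            brute = {d: 0 for d in range(1, 24)}
            for a in pls:
                for b in pls:
                    if a.strand == "+" and b.strand == "-":
                        d = b.five_prime - a.five_prime + 1
                        if 1 <= d <= 23:
                            brute[d] += 1
            assert dict(hist.counts) == brute


class TestPingPongZscore:
    def test_uniform_histogram_z_zero(self):
        hist = OverlapHistogram({d: 5 for d in range(1, 24)})
        res = smallrna.pingpong_zscore(hist)
        assert res.pct10 == pytest.approx(100 / 23)
        assert res.zscore == 0.0 and res.significant is False

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            smallrna.pingpong_zscore(OverlapHistogram({d: 0 for d in range(1, 24)}))

    def test_degenerate_background_sentinel(self):
        counts = {d: 1 for d in range(1, 24)}
        counts[10] = 50
        res = smallrna.pingpong_zscore(OverlapHistogram(counts))
        assert res.zscore is None and res.significant is None

    def test_matches_spreadsheet_recomputation(self, rng):
        """Independent formula recomputation on random histograms."""
        import statistics

        for _ in range(50):
            counts = {d: int(c) for d, c in zip(range(1, 24), rng.integers(0, 1000, 23))}
            if sum(counts.values()) == 0 or len({counts[d] for d in counts if d != 10}) == 1:
                continue
            res = smallrna.pingpong_zscore(OverlapHistogram(counts))
            total = sum(counts.values())
            pcts = {d: 100 * c / total for d, c in counts.items()}
            bg = [pcts[d] for d in pcts if d != 10]
            expected = (pcts[10] - statistics.mean(bg)) / statistics.stdev(bg)
            assert res.zscore == pytest.approx(expected)
            assert res.significant == (expected > 1.96)

    def test_percentages_sum_to_100(self, rng):
        for _ in range(20):
            counts = {d: int(c) for d, c in zip(range(1, 24), rng.integers(0, 50, 23))}
            if sum(counts.values()) == 0:
                counts[3] = 1
            assert sum(OverlapHistogram(counts).percentages().values()) == pytest.approx(100.0)

    def test_background_inclusion_flag(self):
        counts = {d: 8 + d % 3 for d in range(1, 24)}
        counts[10] = 100
        incl = smallrna.pingpong_zscore(OverlapHistogram(counts), include_d10_in_background=True)
        excl = smallrna.pingpong_zscore(OverlapHistogram(counts))
        assert incl.zscore < excl.zscore  # self-inclusion dilutes the excess


class TestFivePrimeComposition:
    def test_t_fraction(self):
        reads = [_rec(s, f"r{i}") for i, s in enumerate(["TAAA", "TGGG", "AGGG", "TCCC"])]
        comp = smallrna.five_prime_base_composition(reads)
        assert comp["T"] == 0.75
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_all_t(self):
        reads = [_rec("TAAA", "a"), _rec("TCCC", "b")]
        assert smallrna.five_prime_base_composition(reads)["T"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            smallrna.five_prime_base_composition([])


class TestWindowedDensity:
    def test_region_273_gives_3_windows(self):
        spec = DensityProfileSpec("T", 1, 273, window=91)
        ctx = NormalizationContext(1_000_000)
        df = smallrna.windowed_density([], spec, ctx)
        assert sorted(set(zip(df.window_start, df.window_end))) == [
            (1, 91), (92, 182), (183, 273)
        ]

    def test_one_count_per_window(self):
        spec = DensityProfileSpec("T", 1, 273, window=91)
        ctx = NormalizationContext(1_000_000)
        pls = [_pl("a", 1, "+"), _pl("b", 92, "+"), _pl("c", 183, "+")]
        df = smallrna.windowed_density(pls, spec, ctx)
        plus = df[df.strand == "+"]
        assert list(plus["count"]) == [1, 1, 1]

    def test_counts_conserved(self, rng):
        spec = DensityProfileSpec("T", 50, 1000, window=86)
        ctx = NormalizationContext(1_000_000)
        pls = [
            _pl(f"r{i}", int(fp), "+-"[int(s)])
            for i, (fp, s) in enumerate(zip(rng.integers(30, 1100, 300), rng.integers(0, 2, 300)))
        ]
        df = smallrna.windowed_density(pls, spec, ctx)
        in_region = [p for p in pls if 50 <= p.five_prime <= 1000]
        for strand in "+-":
            assert df[df.strand == strand]["count"].sum() == sum(
                1 for p in in_region if p.strand == strand
            )

    def test_rpkm_uses_window_length(self):
        spec = DensityProfileSpec("T", 1, 100, window=91, normalization="RPKM")
        ctx = NormalizationContext(1_000_000, {"T": 7500})
        df = smallrna.windowed_density([_pl("a", 1, "+"), _pl("b", 95, "+")], spec, ctx)
        plus = df[df.strand == "+"].reset_index(drop=True)
        assert plus.loc[0, "value"] == pytest.approx(1.0 * 1 / 0.091)
        assert plus.loc[1, "value"] == pytest.approx(1.0 * 1 / 0.009)  # partial window 92..100


class TestDepletionFlags:
    def test_flagging_rule(self):
        df = smallrna.depletion_flags({"x": 10.0, "y": 10.0}, {"x": 2.0, "y": 5.0})
        assert bool(df.loc["x", "depleted"]) is True and df.loc["x", "ratio"] == 0.2
        assert bool(df.loc["y", "depleted"]) is False

    def test_zero_denominator_undefined_never_flagged(self):
        df = smallrna.depletion_flags({"x": 0.0}, {"x": 5.0})
        assert np.isnan(df.loc["x", "ratio"]) and bool(df.loc["x", "depleted"]) is False
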