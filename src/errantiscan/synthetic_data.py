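"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of an errantivirus
reactivation study: small-RNA libraries with a configurable fraction of
sense/antisense pairs at exactly 10-nt 5'-overlap (the ping-pong
configuration), genomes with planted LTR + internal + LTR insertions
drawn from the named variant catalog, long reads with log-normal lengths
and substitution errors, and spliced RNA-seq alignments over variant and
control transcripts.  Everything is deterministic given its seed, and
each generator emits a truth table sufficient to score the downstream
operations.

What is deliberately not modelled: indel errors in long reads (the
built-in aligner targets substitution-dominated reads), ONT quality
scores, and paired-end RNA-seq (pairing adds nothing to the counted
statistics).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .formats import BedInterval, SequenceRecord, SplicedRecord, reverse_complement
from .longread import InsertionLocus, TeConsensus, VariantCatalog, default_catalog

__all__ = [
    "SmallRnaSimParams",
    "PlantedInsertion",
    "GenomeSimParams",
    "LongReadSimParams",
    "RnaSeqSimParams",
    "gen_te_consensus",
    "gen_smallrna_library",
    "gen_genome_with_insertions",
    "gen_long_reads",
    "gen_spliced_rnaseq",
    "load_fixture",
    "score_detection",
]

_BASES = np.array(list("ACGT"))

DEFAULT_FEATURES = {
    "five_prime_utr": (1, 800),
    "gag": (801, 2700),
    "pol": (2701, 6300),
    "env": (6301, 7400),
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def gen_te_consensus(
    internal_length: int = 7500,
    ltr_length: int = 454,
    features: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
    internal_id: str = "ZAM_I",
    ltr_id: str = "ZAM_LTR",
) -> TeConsensus:
    """A random TE consensus with the shipped feature layout.

    Defaults follow the ZAM geometry: 7500-bp internal sequence, 454-bp
    LTR, 5'-UTR at 1-800, and the pol gene covering the 5494-6120
    interval removed by the v2 variant.
    """
    features = dict(features or DEFAULT_FEATURES)
    for name, (s, e) in features.items():
        if not (1 <= s <= e <= internal_length):
            raise ValueError(f"feature {name!r} ({s},{e}) outside internal sequence")
    rng = np.random.default_rng(seed)
    internal = list(_random_seq(rng, internal_length))
    # make the canonical catalog junctions unambiguous: no microhomology
    # at either breakpoint, so a deletion call from an error-free read
    # has exactly one coordinate representation
    for s, e in ((5494, 6120), (301, 603)):
        if e + 1 > internal_length:
            continue
        if internal[s - 2] == internal[e - 1]:  # x[s-1] == x[e] (1-based)
            internal[e - 1] = "ACGT"[("ACGT".index(internal[e - 1]) + 1) % 4]
        if internal[s - 1] == internal[e]:  # x[s] == x[e+1] (1-based)
            internal[e] = "ACGT"[("ACGT".index(internal[e]) + 1) % 4]
    internal_rec = SequenceRecord(internal_id, "".join(internal))
    ltr = SequenceRecord(ltr_id, _random_seq(rng, ltr_length))
    return TeConsensus(internal=internal_rec, ltr=ltr, features=features)


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmallRnaSimParams:
    """Library composition for the ping-pong simulator.

    ``pp_fraction`` is the fraction of antisense reads that receive a
    sense partner whose 5' end sits at exactly 10-nt 5'-overlap.  Sizes
    default to the piRNA range (uniform over 23-29 nt) and the 5'-U bias
    to 0.75, a typical 1U fraction for mature piRNA populations.
    """

    n_reads: int = 20000
    sense_fraction: float = 0.5
    pp_fraction: float = 0.5
    size_weights: Mapping[int, float] = field(
        default_factory=lambda: {n: 1 / 7 for n in range(23, 30)}
    )
    u1_bias: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.sense_fraction, self.pp_fraction, self.u1_bias):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        total = sum(self.size_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("size_weights must sum to 1")


def gen_smallrna_library(
    te: TeConsensus, p: SmallRnaSimParams
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate a small-RNA library over the internal consensus.

    Antisense reads are placed uniformly; a ``pp_fraction`` subset gets a
    sense partner at d=10; remaining sense reads are independent.  The
    first read base is forced to T with probability ``u1_bias`` (recorded
    in the truth table; this may introduce one mismatch vs the
    consensus).  Returns (reads, truth) with truth columns read_id,
    strand, five_prime, length, partner_of, u1_forced.
    """
    rng = np.random.default_rng(p.seed)
    internal = te.internal.sequence
    Li = len(internal)
    sizes = np.array(sorted(p.size_weights))
    probs = np.array([p.size_weights[s] for s in sizes], dtype=float)

    n_sense = int(round(p.n_reads * p.sense_fraction))
    n_anti = p.n_reads - n_sense

    reads: list[SequenceRecord] = []
    rows: list[dict] = []
    counter = 0

    def emit(seq: str, strand: str, five_prime: int, partner_of: str | None) -> str:
        nonlocal counter
        rid = f"sr{counter:06d}"
        counter += 1
        forced = False
        if rng.random() < p.u1_bias:
            forced = seq[0] != "T"
            seq = "T" + seq[1:]
        reads.append(SequenceRecord(rid, seq))
        rows.append(
            {
                "read_id": rid, "strand": strand, "five_prime": five_prime,
                "length": len(seq), "partner_of": partner_of, "u1_forced": forced,
            }
        )
        return rid

    # antisense reads, each possibly with a ping-pong sense partner
    partners_made = 0
    anti_lengths = rng.choice(sizes, size=n_anti, p=probs)
    for L in anti_lengths:
        L = int(L)
        start = int(rng.integers(1, Li - L + 2))
        q = start + L - 1  # minus-strand 5' end
        seq = reverse_complement(internal[start - 1 : start + L - 1])
        rid = emit(seq, "-", q, None)
        if partners_made < n_sense and rng.random() < p.pp_fraction:
            Ls = int(rng.choice(sizes, p=probs))
            s5 = q - 9  # sense 5' end at exactly 10-nt 5'-overlap
            if 1 <= s5 and s5 + Ls - 1 <= Li:
                pseq = internal[s5 - 1 : s5 + Ls - 1]
                emit(pseq, "+", s5, rid)
                partners_made += 1

    # independent sense reads fill the sense quota
    for _ in range(n_sense - partners_made):
        Ls = int(rng.choice(sizes, p=probs))
        s = int(rng.integers(1, Li - Ls + 2))
        emit(internal[s - 1 : s + Ls - 1], "+", s, None)

    truth = pd.DataFrame(rows)
    return reads, truth


# ---------------------------------------------------------------------------
# genome with insertions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInsertion:
    """One requested insertion: catalog variant at a base-genome position.

    ``position`` is 1-based; the element is inserted immediately before
    that base.  ``deletion`` supplies the interval for the open-ended
    ``other`` class; ``shared`` marks the copy as pre-existing in the
    reference annotation.
    """

    variant: str
    chrom: str
    position: int
    deletion: tuple[int, int] | None = None
    shared: bool = False


@dataclass(frozen=True)
class GenomeSimParams:
    genome_length: int = 2_000_000
    n_chroms: int = 5
    insertions: Sequence[PlantedInsertion] = ()
    chrom_names: Sequence[str] | None = None
    tsd_len: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tsd_len > 20:
            raise ValueError("tsd_len up to 20 bp supported")


@dataclass(frozen=True)
class SimulatedGenome:
    """Base and inserted genomes plus planted truth."""

    base: list[SequenceRecord]
    inserted: list[SequenceRecord]
    truth: pd.DataFrame  # chrom, position (base coords), variant, shared
    reference_annotation: list[BedInterval]  # shared copies only


def gen_genome_with_insertions(
    te: TeConsensus,
    catalog: VariantCatalog,
    p: GenomeSimParams,
) -> SimulatedGenome:
    """Plant LTR + variant-internal + LTR elements into a random genome.

    Positions are in base-genome coordinates; the truth table and the
    reference annotation (shared copies) therefore score flank-mapped
    insertion calls directly.  Overlapping insertions raise.
    """
    rng = np.random.default_rng(p.seed)
    chrom_len = p.genome_length // p.n_chroms
    names = list(p.chrom_names) if p.chrom_names else [f"chr{i+1}" for i in range(p.n_chroms)]
    if len(names) != p.n_chroms:
        raise ValueError("chrom_names length must equal n_chroms")
    unknown = {ins.chrom for ins in p.insertions} - set(names)
    if unknown:
        raise ValueError(f"insertions reference unknown chromosomes {sorted(unknown)}")
    base = [SequenceRecord(n, _random_seq(rng, chrom_len)) for n in names]

    by_chrom: dict[str, list[PlantedInsertion]] = {n: [] for n in names}
    for ins in p.insertions:
        if not 1 <= ins.position <= chrom_len:
            raise ValueError(f"insertion position {ins.position} outside {ins.chrom}")
        by_chrom[ins.chrom].append(ins)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda i: i.position)
        for a, b in zip(group, group[1:]):
            if b.position <= a.position + p.tsd_len:
                raise ValueError(f"overlapping insertions on {chrom}")

    ltr = te.ltr.sequence
    inserted: list[SequenceRecord] = []
    rows = []
    for rec in base:
        seq = rec.sequence
        # insert right-to-left so earlier coordinates stay valid
        for ins in sorted(by_chrom[rec.id], key=lambda i: -i.position):
            element = ltr + catalog.apply(ins.variant, te.internal.sequence, ins.deletion) + ltr
            cut = ins.position - 1  # insert before this 0-based offset
            tsd = seq[cut : cut + p.tsd_len] if p.tsd_len else ""
            seq = seq[:cut] + element + tsd + seq[cut:]
            rows.append(
                {
                    "chrom": rec.id, "position": ins.position, "variant": ins.variant,
                    "shared": ins.shared, "element_length": len(element),
                }
            )
        inserted.append(SequenceRecord(rec.id, seq))

    truth = pd.DataFrame(rows).sort_values(["chrom", "position"]).reset_index(drop=True)
    reference = [
        BedInterval(chrom=r["chrom"], start=r["position"], end=r["position"],
                    name="ZAM", strand="+")
        for _, r in truth.iterrows()
        if r["shared"]
    ]
    return SimulatedGenome(base=base, inserted=inserted, truth=truth,
                           reference_annotation=reference)


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongReadSimParams:
    """Log-normal read lengths with uniform substitution errors."""

    depth: float = 25.0
    length_mean: int = 12_000
    length_sd: int = 6_000
    subst_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.subst_rate <= 0.05:
            raise ValueError("subst_rate must be in [0, 0.05]")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def gen_long_reads(
    genome: Sequence[SequenceRecord], p: LongReadSimParams
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Sample reads uniformly from the genome until total bases reach
    depth x genome length.

    Substitutions are uniform at ``subst_rate``; strand is random; truth
    records (chrom, start, end, strand) in source-genome coordinates.
    """
    rng = np.random.default_rng(p.seed)
    lengths = np.array([len(g.sequence) for g in genome], dtype=float)
    total_target = p.depth * lengths.sum()
    chrom_probs = lengths / lengths.sum()
    mu, sigma = _lognormal_params(p.length_mean, p.length_sd)

    reads: list[SequenceRecord] = []
    rows = []
    emitted = 0
    i = 0
    while emitted < total_target:
        ci = int(rng.choice(len(genome), p=chrom_probs))
        clen = int(lengths[ci])
        L = int(round(rng.lognormal(mu, sigma)))
        L = max(200, min(L, clen))
        start = int(rng.integers(0, clen - L + 1))  # 0-based
        seq = genome[ci].sequence[start : start + L]
        if p.subst_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = np.flatnonzero(rng.random(L) < p.subst_rate)
            if hit.size:
                # shift each hit base by 1-3 within ACGT, never to itself
                codes = np.full(256, -1, dtype=np.int8)
                for j, b in enumerate(b"ACGT"):
                    codes[b] = j
                old = codes[arr[hit]]
                new = (old + rng.integers(1, 4, size=hit.size)) % 4
                arr[hit] = np.frombuffer(b"ACGT", dtype=np.uint8)[new]
                seq = arr.tobytes().decode()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        rid = f"lr{i:06d}"
        reads.append(SequenceRecord(rid, seq, "I" * L))
        rows.append(
            {"read_id": rid, "chrom": genome[ci].id, "start": start + 1,
             "end": start + L, "strand": strand}
        )
        emitted += L
        i += 1
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spliced RNA-seq
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaSeqSimParams:
    """Single-end RNA-seq over variant and control transcripts.

    ``transcripts`` maps transcript name to abundance weight; names
    "fl" and "v2" select the full-length / v2-deleted internal sequence,
    "control" a random control transcript (the role the pointed gene
    plays in ovary libraries).
    """

    transcripts: Mapping[str, float] = field(
        default_factory=lambda: {"fl": 1.0, "v2": 1.0, "control": 1.0}
    )
    read_length: int = 150
    n_reads: int = 20000
    control_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.transcripts.values()):
            raise ValueError("transcript weights must be > 0")


def gen_spliced_rnaseq(
    te: TeConsensus,
    catalog: VariantCatalog,
    p: RnaSeqSimParams,
    control_id: str = "pointed",
) -> tuple[list[SplicedRecord], pd.DataFrame, dict[str, int]]:
    """Simulate spliced alignments of transcript reads in reference
    coordinates.

    Reads are drawn from transcripts proportionally to
    weight x (length - read_length + 1) with uniform starts.  Reads from
    the deletion transcript that cross the junction carry the
    corresponding N-gap CIGAR against the internal sequence; control
    reads align to the control reference.  Returns (records, truth,
    reference_lengths).
    """
    rng = np.random.default_rng(p.seed)
    internal = te.internal.sequence
    rule = catalog.rule("v2")
    dl, dr = rule.deletion  # type: ignore[misc]
    gap = dr - dl + 1
    seqs = {
        "fl": internal,
        "v2": catalog.apply("v2", internal),
        "control": _random_seq(rng, p.control_length),
    }
    rl = p.read_length
    names = [n for n in p.transcripts if n in seqs]
    eff = np.array(
        [p.transcripts[n] * max(0, len(seqs[n]) - rl + 1) for n in names], dtype=float
    )
    for n in names:
        if len(seqs[n]) < rl:
            raise ValueError(f"read length {rl} exceeds transcript {n!r}")
    probs = eff / eff.sum()

    records: list[SplicedRecord] = []
    rows = []
    choices = rng.choice(len(names), size=p.n_reads, p=probs)
    for i, ti in enumerate(choices):
        name = names[ti]
        tlen = len(seqs[name])
        t0 = int(rng.integers(1, tlen - rl + 2))  # 1-based transcript start
        rid = f"rr{i:06d}"
        crosses = False
        if name == "control":
            rec = SplicedRecord(rid, control_id, t0, f"{rl}M")
        elif name == "fl":
            rec = SplicedRecord(rid, te.internal.id, t0, f"{rl}M")
        else:  # v2: transcript coords t map to internal t if t < dl else t + gap
            t_end = t0 + rl - 1
            if t_end < dl:
                rec = SplicedRecord(rid, te.internal.id, t0, f"{rl}M")
            elif t0 >= dl:
                rec = SplicedRecord(rid, te.internal.id, t0 + gap, f"{rl}M")
            else:
                a = dl - t0  # bases before the junction
                b = rl - a
                rec = SplicedRecord(rid, te.internal.id, t0, f"{a}M{gap}N{b}M")
                crosses = True
        records.append(rec)
        rows.append(
            {"read_id": rid, "transcript": name, "t_start": t0, "crosses_junction": crosses}
        )
    truth = pd.DataFrame(rows)
    ref_lengths = {te.internal.id: len(internal), control_id: p.control_length}
    return records, truth, ref_lengths


# ---------------------------------------------------------------------------
# fixtures and scoring
# ---------------------------------------------------------------------------

def load_fixture(name: str) -> dict:
    """Load one of the shipped YAML fixture configs by stem name."""
    ref = importlib.resources.files("errantiscan") / "fixtures" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def genome_params_from_fixture(cfg: dict, seed: int = 0) -> GenomeSimParams:
    insertions = tuple(
        PlantedInsertion(
            variant=e["variant"],
            chrom=e["chrom"],
            position=int(e["position"]),
            deletion=tuple(e["deletion"]) if e.get("deletion") else None,
            shared=bool(e.get("shared", False)),
        )
        for e in cfg["insertions"]
    )
    g = cfg["genome"]
    return GenomeSimParams(
        genome_length=int(g["chrom_length"]) * len(g["chroms"]),
        n_chroms=len(g["chroms"]),
        insertions=insertions,
        chrom_names=tuple(g["chroms"]),
        seed=seed,
    )


def score_detection(
    loci: Sequence[InsertionLocus],
    truth: pd.DataFrame,
    radius: int = 100,
) -> dict:
    """Recall/precision of detected loci against planted truth, plus the
    per-locus position errors and variant agreement of matched pairs."""
    matched_truth: set[int] = set()
    errors: list[int] = []
    variant_ok = 0
    tp = 0
    for locus in loci:
        best = None
        for idx, row in truth.iterrows():
            if idx in matched_truth or row["chrom"] != locus.chrom:
                continue
            err = abs(int(row["position"]) - locus.position)
            if err <= radius and (best is None or err < best[1]):
                best = (idx, err, row["variant"])
        if best is not None:
            matched_truth.add(best[0])
            errors.append(best[1])
            tp += 1
            if best[2] == locus.variant:
                variant_ok += 1
    recall = tp / len(truth) if len(truth) else float("nan")
    precision = tp / len(loci) if loci else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "position_errors": errors,
        "variant_agreement": variant_ok / tp if tp else float("nan"),
        "n_detected": len(loci),
        "n_planted": len(truth),
    }
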