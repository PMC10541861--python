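"""Small-RNA classification, mapping and ping-pong signature statistics.

The analyses here follow the standard ovarian small-RNA workflow for
LTR-retrotransposon regulation: genome-mapping reads are classed by length
into piRNAs (23-29 nt) and siRNAs (21 nt), mapped to transposon consensus
sequences with a bounded number of substitutions, and the amplification
("ping-pong") signature is quantified as a Z-score of the 10-nt 5'-overlap
class against the 1-23 nt overlap background.  Read counts are reported in
RPM (per million genome-mapping small RNAs) or RPKM (additionally per kb
of target), and depletion between two conditions is flagged at a ratio
threshold of 0.3.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import SequenceRecord, reverse_complement

__all__ = [
    "SizePolicy",
    "MappingPolicy",
    "TePlacement",
    "OverlapHistogram",
    "PingPongResult",
    "NormalizationContext",
    "DensityProfileSpec",
    "classify_by_size",
    "map_read",
    "map_reads",
    "best_placements",
    "genome_unique_filter",
    "count_by_target",
    "rpm",
    "rpkm",
    "overlap_histogram",
    "pingpong_zscore",
    "five_prime_base_composition",
    "windowed_density",
    "depletion_flags",
]

OVERLAP_MIN = 1
OVERLAP_MAX = 23
ZSCORE_THRESHOLD = 1.96

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class SizePolicy:
    """Length windows defining the piRNA and siRNA classes."""

    pirna_min: int = 23
    pirna_max: int = 29
    sirna_len: int = 21

    def __post_init__(self) -> None:
        if self.pirna_min > self.pirna_max:
            raise ValueError("pirna_min must be <= pirna_max")
        if self.pirna_min <= self.sirna_len <= self.pirna_max:
            raise ValueError("sirna_len must fall outside the piRNA range")


@dataclass(frozen=True)
class MappingPolicy:
    """Bounded-substitution mapping policy.

    Defaults follow common practice for TE-directed small RNAs: up to 3
    substitutions for piRNA-to-consensus mapping, 1 for siRNAs, 0 for
    genome-unique/cluster mapping.  Indels are never allowed; an N in the
    read mismatches every base.
    """

    max_mismatches: int = 3
    substitutions_only: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class TePlacement:
    """One placement of a small-RNA read on a target sequence.

    ``five_prime`` is the target coordinate of the read's 5' end: the
    leftmost position for a plus-strand placement, the rightmost for minus.
    """

    read_id: str
    target_id: str
    start: int  # 1-based leftmost
    strand: str  # '+' or '-'
    mismatches: int
    length: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.start + self.length - 1


@dataclass(frozen=True)
class OverlapHistogram:
    """Pair counts of 1-23 nt 5'-overlaps between opposite-strand reads."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(range(OVERLAP_MIN, OVERLAP_MAX + 1)):
            raise ValueError(f"domain must be exactly {OVERLAP_MIN}..{OVERLAP_MAX}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[int, float]:
        tot = self.total
        if tot == 0:
            raise ValueError("all-zero overlap histogram")
        return {d: 100.0 * c / tot for d, c in self.counts.items()}


@dataclass(frozen=True)
class PingPongResult:
    """The 10-nt overlap percentage and its Z-score.

    ``zscore`` is None when the background is degenerate (zero spread with
    a nonzero excess at d=10); ``significant`` is then None as well.
    """

    pct10: float
    zscore: float | None
    significant: bool | None


@dataclass(frozen=True)
class NormalizationContext:
    """Denominators for RPM/RPKM: library depth and target lengths."""

    total_genome_mapping: int
    te_lengths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_genome_mapping <= 0:
            raise ValueError("total_genome_mapping must be > 0")
        if any(v <= 0 for v in self.te_lengths.values()):
            raise ValueError("te_lengths must be > 0")


@dataclass(frozen=True)
class DensityProfileSpec:
    """A tiled density profile over a target region.

    Typical window sizes are 91 nt for a full-length errantivirus, 86 nt
    for its internal sequence, and 140 nt for a ~20-kb piRNA cluster
    region.
    """

    target_id: str
    start: int
    end: int
    window: int
    normalization: Literal["RPM", "RPKM"] = "RPM"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.start > self.end:
            raise ValueError("start must be <= end")


# ---------------------------------------------------------------------------
# classification and mapping
# ---------------------------------------------------------------------------

def classify_by_size(
    reads: Sequence[SequenceRecord], policy: SizePolicy = SizePolicy()
) -> dict[str, list[SequenceRecord]]:
    """Partition reads into {pirna, sirna, other} by sequence length."""
    bins: dict[str, list[SequenceRecord]] = {"pirna": [], "sirna": [], "other": []}
    for r in reads:
        n = len(r.sequence)
        if policy.pirna_min <= n <= policy.pirna_max:
            bins["pirna"].append(r)
        elif n == policy.sirna_len:
            bins["sirna"].append(r)
        else:
            bins["other"].append(r)
    return bins


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _TargetCache:
    """Per-target encoded sequence and per-length sliding windows."""

    def __init__(self, target: SequenceRecord) -> None:
        self.record = target
        self.enc = _encode(target.sequence)
        self._windows: dict[int, np.ndarray] = {}

    def windows(self, length: int) -> np.ndarray | None:
        if length > len(self.enc):
            return None
        if length not in self._windows:
            self._windows[length] = np.lib.stride_tricks.sliding_window_view(
                self.enc, length
            )
        return self._windows[length]


def _scan(
    read_enc: np.ndarray, cache: _TargetCache, max_mm: int
) -> list[tuple[int, int]]:
    """All (0-based offset, mismatch count) placements of read on target."""
    win = cache.windows(len(read_enc))
    if win is None:
        return []
    mm = (win != read_enc).sum(axis=1)
    # N matches nothing: ASCII inequality already charges N-vs-base pairs;
    # only the spurious N==N byte match needs a correction.
    n_cols = np.flatnonzero(read_enc == ord("N"))
    if n_cols.size:
        mm = mm + (win[:, n_cols] == read_enc[n_cols]).sum(axis=1)
    hits = np.flatnonzero(mm <= max_mm)
    return [(int(i), int(mm[i])) for i in hits]


def map_read(
    read: SequenceRecord,
    target: SequenceRecord | _TargetCache,
    policy: MappingPolicy = MappingPolicy(),
) -> list[TePlacement]:
    """All placements of ``read`` on both strands of ``target`` within the
    mismatch bound, sorted by (start, strand).

    Minus-strand placements match the reverse complement of the read; their
    5' end is the rightmost target coordinate.
    """
    cache = target if isinstance(target, _TargetCache) else _TargetCache(target)
    L = len(read.sequence)
    placements: list[TePlacement] = []
    for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        for off, mm in _scan(_encode(seq), cache, policy.max_mismatches):
            placements.append(
                TePlacement(
                    read_id=read.id,
                    target_id=cache.record.id,
                    start=off + 1,
                    strand=strand,
                    mismatches=mm,
                    length=L,
                )
            )
    placements.sort(key=lambda p: (p.start, p.strand))
    return placements


_CODE4 = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE4[_b] = _i


def _encode4(seq: str) -> np.ndarray:
    """0-3 base codes; N (or anything else) becomes -1."""
    return _CODE4[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def map_reads(
    reads: Sequence[SequenceRecord],
    target: SequenceRecord,
    policy: MappingPolicy = MappingPolicy(),
) -> list[TePlacement]:
    """Map many reads against one target (batched :func:`map_read`).

    Pigeonhole seeding: a read placed with at most ``max_mismatches``
    substitutions must match the target exactly in at least one of
    ``max_mismatches + 1`` disjoint probes, so only probe-hit offsets
    need verification.  Output equals per-read :func:`map_read` on both
    strands; N matches nothing (a probe containing N simply never
    seeds, and another clean probe must exist within the bound).
    """
    enc_target = _encode4(target.sequence)
    T = len(enc_target)
    n_probes = policy.max_mismatches + 1
    placements: list[tuple[int, TePlacement]] = []

    by_length: dict[int, list[tuple[int, str, np.ndarray]]] = defaultdict(list)
    for idx, r in enumerate(reads):
        by_length[len(r.sequence)].append((idx, "+", _encode4(r.sequence)))
        by_length[len(r.sequence)].append(
            (idx, "-", _encode4(reverse_complement(r.sequence)))
        )

    kmer_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def target_kmers(k: int) -> tuple[np.ndarray, np.ndarray]:
        if k not in kmer_cache:
            win = np.lib.stride_tricks.sliding_window_view(enc_target, k)
            powers = 4 ** np.arange(k, dtype=np.int64)
            h = win @ powers
            h[(win < 0).any(axis=1)] = -1
            valid = np.flatnonzero(h >= 0)
            order = np.argsort(h[valid], kind="stable")
            kmer_cache[k] = (h[valid][order], valid[order])
        return kmer_cache[k]

    for L, items in sorted(by_length.items()):
        if L > T:
            continue
        k = max(1, L // n_probes)
        t_hash, t_pos = target_kmers(k)
        powers = 4 ** np.arange(k, dtype=np.int64)
        mat = np.stack([enc for _, _, enc in items])  # (n, L)
        n = mat.shape[0]
        cand_rows: list[np.ndarray] = []
        cand_starts: list[np.ndarray] = []
        for p in range(n_probes):
            off = p * k
            probe = mat[:, off : off + k]
            h = probe @ powers
            h[(probe < 0).any(axis=1)] = -1
            lo = np.searchsorted(t_hash, h, side="left")
            hi = np.searchsorted(t_hash, h, side="right")
            counts = np.where(h >= 0, hi - lo, 0)
            rows_rep = np.repeat(np.arange(n), counts)
            if rows_rep.size == 0:
                continue
            gathered = np.concatenate(
                [t_pos[l:h_] for l, h_ in zip(lo, hi) if h_ > l]
            )
            starts = gathered - off
            keep = (starts >= 0) & (starts <= T - L)
            cand_rows.append(rows_rep[keep])
            cand_starts.append(starts[keep])
        if not cand_rows:
            continue
        rows = np.concatenate(cand_rows)
        starts = np.concatenate(cand_starts)
        uniq = np.unique(rows.astype(np.int64) * T + starts)
        rows = (uniq // T).astype(np.intp)
        starts = (uniq % T).astype(np.intp)
        win = np.lib.stride_tricks.sliding_window_view(enc_target, L)
        a = mat[rows]
        b = win[starts]
        mm = L - ((a == b) & (a >= 0)).sum(axis=1)
        ok = np.flatnonzero(mm <= policy.max_mismatches)
        for j in ok:
            idx, strand, _ = items[rows[j]]
            r = reads[idx]
            placements.append(
                (
                    idx,
                    TePlacement(
                        read_id=r.id, target_id=target.id, start=int(starts[j]) + 1,
                        strand=strand, mismatches=int(mm[j]), length=L,
                    ),
                )
            )
    placements.sort(key=lambda t: (t[0], t[1].start, _STRAND_ORDER[t[1].strand]))
    return [p for _, p in placements]


_STRAND_ORDER = {"+": 0, "-": 1}


def best_placements(placements: Iterable[TePlacement]) -> list[TePlacement]:
    """Collapse multi-placements to one per (read, target).

    Best = fewest mismatches; ties broken by leftmost start, then '+'
    before '-'.  This is the collapse rule used before per-target counting
    and overlap statistics.
    """
    best: dict[tuple[str, str], TePlacement] = {}
    for p in placements:
        key = (p.read_id, p.target_id)
        cur = best.get(key)
        if cur is None or (p.mismatches, p.start, _STRAND_ORDER[p.strand]) < (
            cur.mismatches, cur.start, _STRAND_ORDER[cur.strand]
        ):
            best[key] = p
    return list(best.values())


def _count_exact_occurrences(genome_seqs: list[str], read: str) -> int:
    """Occurrences of ``read`` and its reverse complement across sequences
    (overlapping occurrences counted; a palindromic site counts twice)."""
    rc = reverse_complement(read)
    total = 0
    for seq in genome_seqs:
        for probe in (read, rc):
            i = seq.find(probe)
            while i != -1:
                total += 1
                i = seq.find(probe, i + 1)
    return total


def genome_unique_filter(
    reads: Sequence[SequenceRecord], genome: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """Keep reads with exactly one perfect placement over both genome strands."""
    seqs = [g.sequence for g in genome]
    return [r for r in reads if _count_exact_occurrences(seqs, r.sequence) == 1]


def count_by_target(placements: Iterable[TePlacement]) -> pd.DataFrame:
    """Per-target sense/antisense read counts, one count per read per target.

    Multi-placements are collapsed with :func:`best_placements` first.
    Returns a DataFrame indexed by target_id with columns ``sense`` (+)
    and ``antisense`` (-).
    """
    collapsed = best_placements(placements)
    counts: dict[str, Counter] = defaultdict(Counter)
    for p in collapsed:
        counts[p.target_id][p.strand] += 1
    rows = {
        t: {"sense": c.get("+", 0), "antisense": c.get("-", 0)}
        for t, c in counts.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "target_id"
    return df


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def rpm(count: float, ctx: NormalizationContext) -> float:
    """Reads per million genome-mapping small RNAs."""
    return count * 1_000_000 / ctx.total_genome_mapping


def rpkm(count: float, target_id: str, ctx: NormalizationContext) -> float:
    """RPM additionally divided by target length in kb."""
    if target_id not in ctx.te_lengths:
        raise KeyError(f"unknown target {target_id!r}")
    return rpm(count, ctx) / (ctx.te_lengths[target_id] / 1000)


# ---------------------------------------------------------------------------
# ping-pong signature
# ---------------------------------------------------------------------------

def overlap_histogram(placements: Sequence[TePlacement]) -> OverlapHistogram:
    """Count 1-23 nt 5'-overlaps between plus- and minus-strand reads.

    A plus read with 5' end p and a minus read with 5' end q overlap by
    d = q - p + 1; each read pair contributes one count, implemented as a
    convolution of per-position 5'-end multiplicities.
    """
    n_plus: Counter = Counter()
    n_minus: Counter = Counter()
    for p in placements:
        (n_plus if p.strand == "+" else n_minus)[p.five_prime] += 1
    counts = {d: 0 for d in range(OVERLAP_MIN, OVERLAP_MAX + 1)}
    for pos, np_ in n_plus.items():
        for d in range(OVERLAP_MIN, OVERLAP_MAX + 1):
            nm = n_minus.get(pos + d - 1)
            if nm:
                counts[d] += np_ * nm
    return OverlapHistogram(counts=counts)


def pingpong_zscore(
    hist: OverlapHistogram,
    include_d10_in_background: bool = False,
    population_sd: bool = False,
) -> PingPongResult:
    """Z-score of the 10-nt 5'-overlap percentage.

    The background is the set of overlap-class percentages; by default the
    tested class d=10 is excluded from its own background and the sample
    standard deviation (n-1) is used.  Both conventions are switchable.
    """
    pct = hist.percentages()
    pct10 = pct[10]
    bg = [v for d, v in pct.items() if include_d10_in_background or d != 10]
    mean = float(np.mean(bg))
    sd = float(np.std(bg, ddof=0 if population_sd else 1))
    num = pct10 - mean
    # a constant background accumulates ~1e-15 float noise; treat as zero
    eps = 1e-9
    if sd < eps:
        if abs(num) < eps:
            return PingPongResult(pct10=pct10, zscore=0.0, significant=False)
        return PingPongResult(pct10=pct10, zscore=None, significant=None)
    z = num / sd
    return PingPongResult(pct10=pct10, zscore=z, significant=z > ZSCORE_THRESHOLD)


def five_prime_base_composition(reads: Sequence[SequenceRecord]) -> dict[str, float]:
    """Fractions of A/C/G/T/N at read position 1 (the 5'-most base)."""
    if not reads:
        raise ValueError("empty read set")
    c = Counter(r.sequence[0] for r in reads)
    n = len(reads)
    return {b: c.get(b, 0) / n for b in "ACGTN"}


# ---------------------------------------------------------------------------
# density profiles and depletion
# ---------------------------------------------------------------------------

def windowed_density(
    placements: Iterable[TePlacement],
    spec: DensityProfileSpec,
    ctx: NormalizationContext,
) -> pd.DataFrame:
    """Tile ``spec``'s region into non-overlapping windows and count reads
    by the window containing their 5' end, per strand.

    RPKM normalization divides by the window length (so partial terminal
    windows stay comparable), not the full target length.
    """
    edges = list(range(spec.start, spec.end + 1, spec.window))
    windows = [(s, min(s + spec.window - 1, spec.end)) for s in edges]
    counts = {(w, strand): 0 for w in windows for strand in "+-"}
    for p in placements:
        if p.target_id != spec.target_id:
            continue
        fp = p.five_prime
        if not spec.start <= fp <= spec.end:
            continue
        idx = (fp - spec.start) // spec.window
        counts[(windows[idx], p.strand)] += 1
    rows = []
    for (ws, we), strand in sorted(counts, key=lambda k: (k[0], k[1])):
        c = counts[((ws, we), strand)]
        value = rpm(c, ctx)
        if spec.normalization == "RPKM":
            value /= (we - ws + 1) / 1000
        rows.append(
            {"window_start": ws, "window_end": we, "strand": strand,
             "count": c, "value": value}
        )
    return pd.DataFrame(rows)


def depletion_flags(
    rpm_a: Mapping[str, float],
    rpm_b: Mapping[str, float],
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-target b/a ratio with a depletion flag at ratio < threshold.

    Targets with a zero denominator get ratio NaN and are never flagged.
    """
    targets = sorted(set(rpm_a) & set(rpm_b))
    rows = []
    for t in targets:
        a, b = rpm_a[t], rpm_b[t]
        ratio = b / a if a > 0 else float("nan")
        flagged = bool(a > 0 and ratio < threshold)
        rows.append({"target_id": t, "a": a, "b": b, "ratio": ratio, "depleted": flagged})
    return pd.DataFrame(rows).set_index("target_id")
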