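"""Plain-text sequence and alignment formats.

All biology-free plumbing lives here: FASTA/FASTQ records, BLAST outfmt-6
and PAF alignment hits, a minimal SAM subset (QNAME/FLAG/RNAME/POS/CIGAR),
BED6 intervals and CIGAR block arithmetic.

Coordinate conventions
----------------------
Internal coordinates are 1-based inclusive throughout the package; BED is
written and read as 0-based half-open, with conversion only at this
boundary.  Minus-strand alignment hits are encoded BLAST-style, with
``subject_start > subject_end``, so one record shape serves both the
blast6 and PAF dialects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

__all__ = [
    "SequenceRecord",
    "AlignmentHit",
    "SplicedRecord",
    "BedInterval",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_bed",
    "write_bed",
    "read_sam",
    "write_sam",
    "parse_cigar",
    "parse_cigar_blocks",
    "reverse_complement",
    "to_zero_based_half_open",
    "to_one_based_inclusive",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised on malformed input, naming the offending line where known."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with optional per-base quality."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            self.id,
            reverse_complement(self.sequence),
            self.quality[::-1] if self.quality is not None else None,
        )


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query and a subject sequence.

    Coordinates are 1-based inclusive.  ``subject_start > subject_end``
    encodes a minus-strand hit; query coordinates always increase.
    """

    query_id: str
    query_start: int
    query_end: int
    subject_id: str
    subject_start: int
    subject_end: int
    identity: float
    length: int

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start must be <= query_end")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def strand(self) -> str:
        return "-" if self.subject_start > self.subject_end else "+"

    @property
    def subject_low(self) -> int:
        return min(self.subject_start, self.subject_end)

    @property
    def subject_high(self) -> int:
        return max(self.subject_start, self.subject_end)


@dataclass(frozen=True)
class SplicedRecord:
    """A block-structured (possibly spliced) alignment record."""

    read_id: str
    reference_id: str
    start: int  # 1-based leftmost reference position
    cigar: str

    def __post_init__(self) -> None:
        ops = parse_cigar(self.cigar)
        if not any(op in "MDN=X" for _, op in ops):
            raise FormatError(
                f"record {self.read_id!r}: CIGAR {self.cigar!r} consumes no reference"
            )


@dataclass(frozen=True)
class BedInterval:
    """One BED6 line, held internally as 1-based inclusive coordinates."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# coordinate conversion (only at the I/O boundary)
# ---------------------------------------------------------------------------

def to_zero_based_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based_inclusive(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _validate_sequence(seq: str, lineno: int) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise FormatError(f"line {lineno}: invalid characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into records, preserving order.

    Sequences are uppercased; folded lines are joined.  Malformed headers
    or empty sequences raise :class:`FormatError` naming the line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise FormatError(f"line {header_line}: record {header!r} has no sequence")
        records.append(SequenceRecord(header, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence before any header")
                chunks.append(_validate_sequence(line.strip(), lineno))
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FormatError(f"line {len(lines)}: truncated FASTQ (not a multiple of 4 lines)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"line {i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"line {i + 3}: expected '+' separator")
        rec_id = head[1:].split()[0] if head[1:].split() else ""
        if not rec_id:
            raise FormatError(f"line {i + 1}: empty FASTQ header")
        records.append(SequenceRecord(rec_id, _validate_sequence(seq, i + 2), qual))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# tabular alignment hits: BLAST outfmt 6 and PAF
# ---------------------------------------------------------------------------

Dialect = Literal["blast6", "paf"]


def read_tabular_hits(path: str | Path, dialect: Dialect) -> list[AlignmentHit]:
    """Read alignment hits from BLAST outfmt-6 or PAF tabular text.

    PAF's 0-based half-open coordinates are converted to 1-based inclusive;
    a PAF '-' strand is re-encoded as ``subject_start > subject_end``.
    """
    if dialect not in ("blast6", "paf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if dialect == "blast6":
                if len(cols) != 12:
                    raise FormatError(f"line {lineno}: expected 12 blast6 columns, got {len(cols)}")
                (qseqid, sseqid, pident, length, _mm, _go, qstart, qend, sstart, send, _ev, _bs) = cols
                hits.append(
                    AlignmentHit(
                        query_id=qseqid,
                        query_start=int(qstart),
                        query_end=int(qend),
                        subject_id=sseqid,
                        subject_start=int(sstart),
                        subject_end=int(send),
                        identity=float(pident),
                        length=int(length),
                    )
                )
            else:
                if len(cols) < 12:
                    raise FormatError(f"line {lineno}: expected >= 12 PAF columns, got {len(cols)}")
                qname, _qlen, qstart0, qend0, strand, tname, _tlen, tstart0, tend0, nmatch, alen, _mapq = cols[:12]
                qs, qe = to_one_based_inclusive(int(qstart0), int(qend0))
                ts, te = to_one_based_inclusive(int(tstart0), int(tend0))
                if strand == "-":
                    ts, te = te, ts
                elif strand != "+":
                    raise FormatError(f"line {lineno}: bad PAF strand {strand!r}")
                alen_i = int(alen)
                identity = 100.0 * int(nmatch) / alen_i if alen_i else 0.0
                hits.append(
                    AlignmentHit(
                        query_id=qname,
                        query_start=qs,
                        query_end=qe,
                        subject_id=tname,
                        subject_start=ts,
                        subject_end=te,
                        identity=round(identity, 3),
                        length=alen_i,
                    )
                )
    return hits


def write_tabular_hits(
    hits: Iterable[AlignmentHit],
    path: str | Path,
    dialect: Dialect,
    query_lengths: dict[str, int] | None = None,
    subject_lengths: dict[str, int] | None = None,
) -> None:
    """Serialize hits as blast6 or PAF.

    PAF requires query/subject lengths; pass 0 placeholders via None maps
    only when the lengths are genuinely unknown.
    """
    with open(path, "w") as fh:
        for h in hits:
            if dialect == "blast6":
                mismatches = round(h.length * (1 - h.identity / 100.0))
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            h.query_id, h.subject_id, f"{h.identity:.3f}", h.length,
                            mismatches, 0, h.query_start, h.query_end,
                            h.subject_start, h.subject_end, "0.0", "0",
                        )
                    )
                    + "\n"
                )
            elif dialect == "paf":
                qlen = (query_lengths or {}).get(h.query_id, 0)
                tlen = (subject_lengths or {}).get(h.subject_id, 0)
                qs0, qe0 = to_zero_based_half_open(h.query_start, h.query_end)
                ts0, te0 = to_zero_based_half_open(h.subject_low, h.subject_high)
                nmatch = round(h.length * h.identity / 100.0)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            h.query_id, qlen, qs0, qe0, h.strand,
                            h.subject_id, tlen, ts0, te0, nmatch, h.length, 255,
                        )
                    )
                    + "\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            start1, end1 = to_one_based_inclusive(int(cols[1]), int(cols[2]))
            out.append(
                BedInterval(
                    chrom=cols[0],
                    start=start1,
                    end=end1,
                    name=cols[3] if len(cols) > 3 else ".",
                    score=float(cols[4]) if len(cols) > 4 else 0.0,
                    strand=cols[5] if len(cols) > 5 else ".",
                )
            )
    return out


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            s0, e0 = to_zero_based_half_open(iv.start, iv.end)
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(f"{iv.chrom}\t{s0}\t{e0}\t{iv.name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# SAM subset
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> list[SplicedRecord]:
    """Read the QNAME/RNAME/POS/CIGAR subset of a SAM file.

    Unmapped records (FLAG 0x4 or '*' fields) are skipped; flags beyond
    strand are ignored by design.
    """
    out: list[SplicedRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if raw.startswith("@"):
                continue
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise FormatError(f"line {lineno}: SAM needs >= 11 columns")
            qname, flag, rname, pos, _mapq, cigar = cols[0], int(cols[1]), cols[2], int(cols[3]), cols[4], cols[5]
            if flag & 0x4 or rname == "*" or cigar == "*":
                continue
            out.append(SplicedRecord(read_id=qname, reference_id=rname, start=pos, cigar=cigar))
    return out


def write_sam(
    records: Iterable[SplicedRecord],
    path: str | Path,
    reference_lengths: dict[str, int],
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{ref}\tLN:{length}\n")
        for rec in records:
            fh.write(
                f"{rec.read_id}\t0\t{rec.reference_id}\t{rec.start}\t255\t{rec.cigar}\t*\t0\t0\t*\t*\n"
            )


# ---------------------------------------------------------------------------
# CIGAR arithmetic
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSH=X])")
_REF_CONSUMING = set("MDN=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) pairs; unknown ops raise."""
    pairs = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in pairs) != cigar:
        raise FormatError(f"invalid CIGAR {cigar!r}")
    if any(n < 1 for n, _ in pairs):
        raise FormatError(f"invalid CIGAR {cigar!r}: zero-length op")
    return pairs


@dataclass(frozen=True)
class ReferenceBlocks:
    """Reference blocks of a spliced record plus the gaps between them."""

    blocks: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping
    gaps: list[tuple[int, int, str]]  # (skipped_start, skipped_end, kind in {N, D})


def parse_cigar_blocks(rec: SplicedRecord, min_gap: int = 20) -> ReferenceBlocks:
    """Resolve a spliced record into reference-coordinate blocks.

    M/=/X and D consume reference; N always splits blocks, D splits only
    when its length is >= ``min_gap`` (shorter deletions — sequencing
    error scale — are merged into the flanking block).  I/S/H consume no
    reference.
    """
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int, str]] = []
    ref = rec.start
    block_start = rec.start
    open_block = False
    for n, op in parse_cigar(rec.cigar):
        if op in "M=X":
            if not open_block:
                block_start = ref
                open_block = True
            ref += n
        elif op == "D":
            if n >= min_gap:
                if open_block:
                    blocks.append((block_start, ref - 1))
                    open_block = False
                gaps.append((ref, ref + n - 1, "D"))
            # else: short deletion absorbed into the current block
            ref += n
        elif op == "N":
            if open_block:
                blocks.append((block_start, ref - 1))
                open_block = False
            gaps.append((ref, ref + n - 1, "N"))
            ref += n
        elif op in "ISH":
            pass
        else:  # pragma: no cover — parse_cigar already rejects
            raise FormatError(f"unknown CIGAR op {op!r}")
    if open_block:
        blocks.append((block_start, ref - 1))
    return ReferenceBlocks(blocks=blocks, gaps=gaps)
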