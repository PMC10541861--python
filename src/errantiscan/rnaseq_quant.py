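"""Deletion-variant expression from spliced RNA-seq alignments.

A transcript carrying an internal deletion shows up, after alignment to
the full-length internal sequence, as reads whose CIGAR skips exactly the
deleted interval.  Variant expression is quantified as the number of
split reads matching the deletion junction; full-length expression as the
number of contiguous (nonsplit) reads covering the left edge of the
deletion — only the left edge, because the right edge is also reached by
reads from variants with other internal deletions.  Both counts are
normalized to the mean coverage of a control transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats import SplicedRecord, parse_cigar_blocks

__all__ = [
    "JunctionSpec",
    "VariantExpression",
    "count_junction_reads",
    "count_contiguous_at",
    "mean_coverage",
    "variant_expression",
]


@dataclass(frozen=True)
class JunctionSpec:
    """A deletion junction on a target: first and last deleted base."""

    target_id: str
    left: int  # first deleted base (e.g. 5494)
    right: int  # last deleted base (e.g. 6120)
    tol: int = 5  # per-breakpoint tolerance, aligner wobble

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("left must be <= right")


@dataclass(frozen=True)
class VariantExpression:
    split_count: int
    nonsplit_count: int
    control_mean_coverage: float

    def __post_init__(self) -> None:
        if self.control_mean_coverage <= 0:
            raise ValueError("control_mean_coverage must be > 0")

    @property
    def v_norm(self) -> float:
        return self.split_count / self.control_mean_coverage

    @property
    def fl_norm(self) -> float:
        return self.nonsplit_count / self.control_mean_coverage


def count_junction_reads(
    records: Sequence[SplicedRecord],
    junction: JunctionSpec,
    min_anchor: int = 10,
    min_gap: int = 20,
) -> int:
    """Reads whose alignment skips exactly the junction interval.

    A record counts when it has an N gap (or deletion >= ``min_gap``,
    since aligners encode the same event either way) whose skipped
    interval matches (left, right) within ±tol on both breakpoints, with
    >= ``min_anchor`` aligned bases flanking the gap on each side.
    """
    n = 0
    for rec in records:
        if rec.reference_id != junction.target_id:
            continue
        rb = parse_cigar_blocks(rec, min_gap=min_gap)
        for gs, ge, _kind in rb.gaps:
            if (
                abs(gs - junction.left) <= junction.tol
                and abs(ge - junction.right) <= junction.tol
            ):
                left_ok = any(e == gs - 1 and e - s + 1 >= min_anchor for s, e in rb.blocks)
                right_ok = any(s == ge + 1 and e - s + 1 >= min_anchor for s, e in rb.blocks)
                if left_ok and right_ok:
                    n += 1
                    break
    return n


def count_contiguous_at(
    records: Sequence[SplicedRecord],
    target_id: str,
    pos: int,
    anchor: int = 10,
) -> int:
    """Reads with one aligned block covering [pos-anchor, pos+anchor].

    No gap may open inside that window — a single block must span it.
    """
    lo, hi = pos - anchor, pos + anchor
    n = 0
    for rec in records:
        if rec.reference_id != target_id:
            continue
        rb = parse_cigar_blocks(rec)
        if any(s <= lo and e >= hi for s, e in rb.blocks):
            n += 1
    return n


def mean_coverage(
    records: Sequence[SplicedRecord],
    target_id: str,
    interval: tuple[int, int],
) -> float:
    """Mean per-base depth from aligned blocks over a 1-based interval."""
    s, e = interval
    if e < s:
        raise ValueError("empty interval")
    length = e - s + 1
    depth = np.zeros(length + 1, dtype=np.int64)  # diff array
    for rec in records:
        if rec.reference_id != target_id:
            continue
        for bs, be in parse_cigar_blocks(rec).blocks:
            lo = max(bs, s)
            hi = min(be, e)
            if lo <= hi:
                depth[lo - s] += 1
                depth[hi - s + 1] -= 1
    covered = np.cumsum(depth[:-1])
    return float(covered.sum()) / length


def variant_expression(
    records: Sequence[SplicedRecord],
    junction: JunctionSpec,
    control: tuple[str, tuple[int, int]],
    edge_anchor: int = 10,
) -> VariantExpression:
    """Variant vs full-length expression normalized to control coverage.

    Split reads matching the junction measure the deletion variant;
    nonsplit reads across the junction's left edge (first deleted base)
    measure the full-length element.
    """
    control_id, control_interval = control
    cov = mean_coverage(records, control_id, control_interval)
    if cov <= 0:
        raise ValueError("control transcript has zero coverage")
    split = count_junction_reads(records, junction)
    nonsplit = count_contiguous_at(
        records, junction.target_id, junction.left, anchor=edge_anchor
    )
    return VariantExpression(
        split_count=split, nonsplit_count=nonsplit, control_mean_coverage=cov
    )
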