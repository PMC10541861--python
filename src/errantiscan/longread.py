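"""Long-read detection and classification of LTR-retrotransposon insertions.

The census pipeline for an errantivirus like ZAM: reads carrying the
element are found by local alignment against the consensus (internal
sequence + LTR), per-read hits are chained, internal deletions are called
from chain gaps, each insertion is classified against a named variant
catalog (full-length, 5'-UTR-deleted, pol-end-deleted, ...), localized on
the reference genome by flank mapping, deduplicated into loci, checked
for a segregating insertion-free allele, and annotated as novel or shared
with a reference TE annotation.

Variant catalog
---------------
The shipped catalog mirrors the classes observed for ZAM:

* ``fl`` — full-length: no internal deletion >= ``min_del`` and coverage
  of essentially the whole internal sequence;
* ``v1`` — the 5'-UTR is deleted (>= 80% of the feature);
* ``v2`` — one deletion at the C-terminal end of pol, breakpoints at
  internal positions 5494-6120 (627 bp) within tolerance;
* ``v3`` — one 303-bp deletion contained in the 5'-UTR;
* ``other`` — any other internal deletion >= ``min_del``.

Precedence v2 > v3 > v1 > other > fl resolves overlapping rules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .formats import AlignmentHit, BedInterval, SequenceRecord
from .seedalign import SeedIndex

__all__ = [
    "TeConsensus",
    "VariantCatalog",
    "TeChain",
    "InsertionCall",
    "CallRejection",
    "InsertionLocus",
    "find_te_hits",
    "chain_hits",
    "call_internal_deletions",
    "infer_deletions",
    "classify_variant",
    "locate_insertion",
    "deduplicate_calls",
    "verify_empty_site",
    "annotate_novelty",
]

V2_BREAKPOINTS = (5494, 6120)
V3_LENGTH = 303

# precedence: most specific first; "fragment" is the fallthrough label for
# chains that satisfy no rule (or cover < 50% of the internal sequence)
VARIANT_PRECEDENCE = ["v2", "v3", "v1", "other", "fl"]
_SPECIFICITY = {name: i for i, name in enumerate(VARIANT_PRECEDENCE)}


@dataclass(frozen=True)
class TeConsensus:
    """TE reference: internal sequence, LTR, and internal-coordinate features."""

    internal: SequenceRecord
    ltr: SequenceRecord
    features: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        L = len(self.internal.sequence)
        for name, (s, e) in self.features.items():
            if not (1 <= s <= e <= L):
                raise ValueError(f"feature {name!r} ({s},{e}) outside internal 1..{L}")

    @property
    def internal_length(self) -> int:
        return len(self.internal.sequence)

    @property
    def full_insert_length(self) -> int:
        return self.internal_length + 2 * len(self.ltr.sequence)


@dataclass(frozen=True)
class VariantRule:
    """One catalog entry.

    ``kind`` selects the matcher; ``deletion`` is the canonical deleted
    interval used both for classification anchors and for sequence
    generation (None for ``fl`` and the open-ended ``other``).
    """

    name: str
    kind: str  # {"full_length", "feature_deleted", "breakpoints", "length_in_feature", "any_deletion"}
    deletion: tuple[int, int] | None = None
    feature: str | None = None
    min_feature_fraction: float = 0.8
    length: int | None = None


@dataclass(frozen=True)
class VariantCatalog:
    """Named, mutually exclusive (under precedence) internal-deletion rules."""

    entries: Mapping[str, VariantRule]
    precedence: Sequence[str] = tuple(VARIANT_PRECEDENCE)

    def rule(self, name: str) -> VariantRule:
        return self.entries[name]

    def apply(self, name: str, internal: str, deletion: tuple[int, int] | None = None) -> str:
        """Return the internal sequence with the named variant's deletion
        applied (``other`` requires an explicit interval)."""
        rule = self.entries[name]
        dele = deletion or rule.deletion
        if rule.kind == "full_length":
            return internal
        if dele is None:
            raise ValueError(f"variant {name!r} needs an explicit deletion interval")
        s, e = dele
        return internal[: s - 1] + internal[e:]


def default_catalog() -> VariantCatalog:
    """The shipped ZAM-style catalog (see module docstring)."""
    return VariantCatalog(
        entries={
            "fl": VariantRule(name="fl", kind="full_length"),
            "v1": VariantRule(
                name="v1", kind="feature_deleted", feature="five_prime_utr",
                deletion=(1, 800), min_feature_fraction=0.8,
            ),
            "v2": VariantRule(name="v2", kind="breakpoints", deletion=V2_BREAKPOINTS),
            "v3": VariantRule(
                name="v3", kind="length_in_feature", feature="five_prime_utr",
                deletion=(301, 603), length=V3_LENGTH,
            ),
            "other": VariantRule(name="other", kind="any_deletion"),
        }
    )


@dataclass(frozen=True)
class TeChain:
    """Co-linear per-read hits representing one TE occurrence on a read."""

    read_id: str
    hits: tuple[AlignmentHit, ...]  # ordered by read coordinate
    orientation: str  # '+' or '-'
    read_span: tuple[int, int]  # 1-based inclusive on the read, incl. LTR hits
    te_coverage: tuple[tuple[int, int], ...]  # covered internal intervals, ascending

    @property
    def internal_hits(self) -> list[AlignmentHit]:
        return [h for h in self.hits if not h.subject_id.endswith("LTR")]

    def covered_internal_bases(self) -> int:
        return sum(e - s + 1 for s, e in self.te_coverage)


@dataclass(frozen=True)
class InsertionCall:
    """A per-read TE insertion with inferred deletions and genomic site."""

    read_id: str
    chrom: str
    position: int  # 1-based first reference base after the junction
    variant: str
    deletions: tuple[tuple[int, int], ...]
    flank_support: str  # {"both", "left_only", "right_only"}


@dataclass(frozen=True)
class CallRejection:
    """A read whose insertion could not be localized, with the reason."""

    read_id: str
    reason: str


@dataclass(frozen=True)
class InsertionLocus:
    chrom: str
    position: int
    variant: str
    supporting_reads: int
    novelty: str = "untested"  # {"shared", "new", "untested"}
    empty_allele: str = "untested"  # {"present", "absent", "untested"}


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def build_te_index(te: TeConsensus, k: int = 15) -> SeedIndex:
    return SeedIndex([te.internal, te.ltr], k=k)


def find_te_hits(
    read: SequenceRecord,
    te: TeConsensus | SeedIndex,
    k: int = 15,
    min_identity: float = 0.90,
) -> list[AlignmentHit]:
    """Local hits of ``read`` against the consensus internal/LTR sequences.

    Uses the built-in exact-k-mer seed-and-extend engine; externally
    computed BLAST6/PAF hits (``formats.read_tabular_hits``) are accepted
    by every downstream step in place of this output.
    """
    index = te if isinstance(te, SeedIndex) else build_te_index(te, k=k)
    return index.hits(read, min_identity=min_identity)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _hit_te_interval(h: AlignmentHit) -> tuple[int, int]:
    return h.subject_low, h.subject_high


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    if not ivs:
        return ()
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def chain_hits(
    hits: Sequence[AlignmentHit],
    internal_id: str | None = None,
    max_read_gap: int = 200,
    te_reset_tol: int = 30,
    ltr_attach_gap: int = 600,
) -> list[TeChain]:
    """Chain one read's hits into TE occurrences.

    Internal-sequence hits of the same orientation are chained in read
    order with the TE coordinate advancing (for '+'; receding for '-').
    A new chain starts when the TE coordinate resets backwards by more
    than ``te_reset_tol`` (tandem copies) or when the read gap exceeds
    ``max_read_gap`` while the TE gap is smaller than the read gap
    (unexplained read sequence between copies).  LTR hits attach to the
    chain whose read span they are adjacent to.
    """
    if not hits:
        return []
    read_ids = {h.query_id for h in hits}
    if len(read_ids) != 1:
        raise ValueError("chain_hits expects hits from a single read")
    read_id = next(iter(read_ids))
    if internal_id is None:
        non_ltr = [h.subject_id for h in hits if not h.subject_id.endswith("LTR")]
        internal_id = non_ltr[0] if non_ltr else None

    internal = sorted(
        (h for h in hits if h.subject_id == internal_id),
        key=lambda h: h.query_start,
    )
    ltr_hits = [h for h in hits if h.subject_id != internal_id]

    chains: list[list[AlignmentHit]] = []
    for strand in "+-":
        cur: list[AlignmentHit] = []
        for h in (x for x in internal if x.strand == strand):
            if cur:
                prev = cur[-1]
                read_gap = h.query_start - prev.query_end - 1
                if strand == "+":
                    te_step = h.subject_low - prev.subject_high - 1
                else:
                    te_step = prev.subject_low - h.subject_high - 1
                reset = te_step < -te_reset_tol
                tandem = read_gap > max_read_gap and te_step < read_gap
                if reset or tandem:
                    chains.append(cur)
                    cur = []
            cur.append(h)
        if cur:
            chains.append(cur)

    out: list[TeChain] = []
    used_ltr: set[int] = set()
    for chain in chains:
        orientation = chain[0].strand
        span_s = min(h.query_start for h in chain)
        span_e = max(h.query_end for h in chain)
        attached: list[AlignmentHit] = []
        for i, lh in enumerate(ltr_hits):
            if i in used_ltr or lh.strand != orientation:
                continue
            if (
                span_s - ltr_attach_gap <= lh.query_end
                and lh.query_start <= span_e + ltr_attach_gap
            ):
                attached.append(lh)
                used_ltr.add(i)
        all_hits = sorted(chain + attached, key=lambda h: h.query_start)
        span_s = min(h.query_start for h in all_hits)
        span_e = max(h.query_end for h in all_hits)
        out.append(
            TeChain(
                read_id=read_id,
                hits=tuple(all_hits),
                orientation=orientation,
                read_span=(span_s, span_e),
                te_coverage=_merge_intervals([_hit_te_interval(h) for h in chain]),
            )
        )
    # solo-LTR occurrences: LTR hits not attached to any internal chain
    leftovers = [lh for i, lh in enumerate(ltr_hits) if i not in used_ltr]
    for lh in leftovers:
        out.append(
            TeChain(
                read_id=read_id,
                hits=(lh,),
                orientation=lh.strand,
                read_span=(lh.query_start, lh.query_end),
                te_coverage=(),
            )
        )
    out.sort(key=lambda c: c.read_span)
    return out


# ---------------------------------------------------------------------------
# deletion calling and classification
# ---------------------------------------------------------------------------

def call_internal_deletions(chain: TeChain, min_del: int = 50) -> list[tuple[int, int]]:
    """Deletions in internal coordinates from gaps between consecutive
    internal hits of a chain.

    For consecutive hits the TE gap must exceed the read gap by at least
    ``min_del`` (a balanced gap is diverged sequence, not a deletion);
    breakpoints come from the flanking hit ends.
    """
    ih = sorted(chain.internal_hits, key=lambda h: h.query_start)
    dels: list[tuple[int, int]] = []
    for prev, nxt in zip(ih, ih[1:]):
        read_gap = nxt.query_start - prev.query_end - 1
        if chain.orientation == "+":
            te_lo, te_hi = prev.subject_high, nxt.subject_low
        else:
            te_lo, te_hi = nxt.subject_high, prev.subject_low
        te_gap = te_hi - te_lo - 1
        if te_gap - read_gap >= min_del:
            # hits overlapping on the read (junction microhomology) would
            # understate the deletion; restore the overlap on the left end
            overlap = max(0, -read_gap)
            dels.append((te_lo - overlap + 1, te_hi - 1))
    dels.sort()
    return dels


def infer_deletions(
    chain: TeChain,
    te: TeConsensus,
    min_del: int = 50,
    ltr_adjacency: int = 60,
) -> list[tuple[int, int]]:
    """Inter-hit deletions plus boundary deletions anchored by an LTR.

    A deletion flush with the internal-sequence start (e.g. a removed
    5'-UTR) leaves no hit pair to gap between; it is inferred when an LTR
    hit is read-adjacent to a truncated internal edge.
    """
    dels = call_internal_deletions(chain, min_del=min_del)
    if not chain.te_coverage:
        return dels
    cov_s, cov_e = chain.te_coverage[0][0], chain.te_coverage[-1][1]
    L = te.internal_length
    ih = chain.internal_hits
    if not ih:
        return dels
    first = min(ih, key=lambda h: h.query_start)
    last = max(ih, key=lambda h: h.query_end)
    for lh in chain.hits:
        if lh.subject_id == te.internal.id:
            continue
        # LTR immediately upstream of a truncated internal start
        gap_left = first.query_start - lh.query_end - 1
        if 0 <= gap_left <= ltr_adjacency and cov_s - 1 >= min_del and chain.orientation == "+":
            dels.append((1, cov_s - 1))
        gap_right = lh.query_start - last.query_end - 1
        if 0 <= gap_right <= ltr_adjacency and L - cov_e >= min_del and chain.orientation == "+":
            dels.append((cov_e + 1, L))
        if chain.orientation == "-":
            if 0 <= gap_left <= ltr_adjacency and L - cov_e >= min_del:
                dels.append((cov_e + 1, L))
            if 0 <= gap_right <= ltr_adjacency and cov_s - 1 >= min_del:
                dels.append((1, cov_s - 1))
    return sorted(set(dels))


def _covers_fraction(dele: tuple[int, int], feature: tuple[int, int]) -> float:
    s = max(dele[0], feature[0])
    e = min(dele[1], feature[1])
    if e < s:
        return 0.0
    return (e - s + 1) / (feature[1] - feature[0] + 1)


def classify_variant(
    deletions: Sequence[tuple[int, int]],
    chain: TeChain,
    te: TeConsensus,
    catalog: VariantCatalog | None = None,
    breakpoint_tol: int = 30,
    min_del: int = 50,
    coverage_slack: int = 50,
) -> str:
    """Classify a chain against the variant catalog.

    Chains covering < 50% of the internal sequence are "fragment".  Rules
    are tested in catalog precedence order; ``fl`` additionally requires
    coverage of [1+slack, L-slack].  Chains matching no rule (e.g. a
    truncated read with no called deletion) are "fragment".
    """
    catalog = catalog or default_catalog()
    L = te.internal_length
    covered = chain.covered_internal_bases()
    if covered < 0.5 * L:
        return "fragment"
    big = [d for d in deletions if d[1] - d[0] + 1 >= min_del]
    for name in catalog.precedence:
        rule = catalog.entries.get(name)
        if rule is None:
            continue
        if rule.kind == "breakpoints":
            bs, be = rule.deletion  # type: ignore[misc]
            if any(abs(s - bs) <= breakpoint_tol and abs(e - be) <= breakpoint_tol for s, e in big):
                return name
        elif rule.kind == "length_in_feature":
            feat = te.features[rule.feature]  # type: ignore[index]
            for s, e in big:
                if (
                    abs((e - s + 1) - rule.length) <= breakpoint_tol  # type: ignore[operator]
                    and s >= feat[0] - breakpoint_tol
                    and e <= feat[1] + breakpoint_tol
                ):
                    return name
        elif rule.kind == "feature_deleted":
            feat = te.features[rule.feature]  # type: ignore[index]
            if any(_covers_fraction(d, feat) >= rule.min_feature_fraction for d in big):
                return name
        elif rule.kind == "any_deletion":
            if big:
                return name
        elif rule.kind == "full_length":
            cov_s = chain.te_coverage[0][0]
            cov_e = chain.te_coverage[-1][1]
            if not big and cov_s <= 1 + coverage_slack and cov_e >= L - coverage_slack:
                return name
    return "fragment"


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

def locate_insertion(
    read: SequenceRecord,
    chain: TeChain,
    genome: Sequence[SequenceRecord] | SeedIndex,
    min_flank: int = 500,
    pair_radius: int = 100,
    variant: str = "untyped",
    deletions: Sequence[tuple[int, int]] = (),
) -> InsertionCall | CallRejection:
    """Localize a chain's insertion by mapping its read flanks to the
    (insertion-free) reference genome.

    The reported position is the 1-based reference base immediately after
    the junction; with a target-site duplication the leftmost junction is
    reported.  Both flanks on the same chromosome within ``pair_radius``
    give flank_support "both"; flanks on different chromosomes reject the
    call.
    """
    index = genome if isinstance(genome, SeedIndex) else SeedIndex(list(genome))
    span_s, span_e = chain.read_span
    L = len(read.sequence)
    left_len = span_s - 1
    right_len = L - span_e
    if max(left_len, right_len) < min_flank:
        return CallRejection(read.id, "no flank >= min_flank")

    def best_hit(flank: SequenceRecord) -> AlignmentHit | None:
        hs = index.hits(flank)
        return max(hs, key=lambda h: h.length) if hs else None

    pos_left = pos_right = None
    chrom_left = chrom_right = None
    if left_len >= min_flank:
        lh = best_hit(SequenceRecord(read.id + "/L", read.sequence[:left_len]))
        if lh is not None:
            chrom_left = lh.subject_id
            tail = left_len - lh.query_end  # unaligned read bases before the TE
            if lh.strand == "+":
                pos_left = lh.subject_end + tail + 1
            else:
                pos_left = lh.subject_end - tail
    if right_len >= min_flank:
        rh = best_hit(SequenceRecord(read.id + "/R", read.sequence[span_e:]))
        if rh is not None:
            chrom_right = rh.subject_id
            head = rh.query_start - 1  # unaligned read bases after the TE
            if rh.strand == "+":
                pos_right = rh.subject_start - head
            else:
                pos_right = rh.subject_start + head + 1

    if pos_left is None and pos_right is None:
        return CallRejection(read.id, "flanks unmappable")
    if pos_left is not None and pos_right is not None:
        if chrom_left != chrom_right:
            return CallRejection(read.id, "flanks on different chromosomes")
        if abs(pos_left - pos_right) > pair_radius:
            return CallRejection(read.id, "flank positions disagree")
        support = "both"
        position = min(pos_left, pos_right)
        chrom = chrom_left
    elif pos_left is not None:
        support, position, chrom = "left_only", pos_left, chrom_left
    else:
        support, position, chrom = "right_only", pos_right, chrom_right
    return InsertionCall(
        read_id=read.id,
        chrom=chrom,  # type: ignore[arg-type]
        position=max(1, position),  # type: ignore[arg-type]
        variant=variant,
        deletions=tuple(deletions),
        flank_support=support,
    )


# ---------------------------------------------------------------------------
# locus-level operations
# ---------------------------------------------------------------------------

def deduplicate_calls(
    calls: Sequence[InsertionCall], radius: int = 100
) -> list[InsertionLocus]:
    """Single-linkage clustering of calls per chromosome within ``radius``.

    Locus variant is the majority vote over non-fragment call variants
    (ties broken toward the most specific class); position is the median
    call position.  Idempotent and independent of input order.
    """
    by_chrom: dict[str, list[InsertionCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    loci: list[InsertionLocus] = []
    for chrom in sorted(by_chrom):
        cluster: list[InsertionCall] = []
        for c in sorted(by_chrom[chrom], key=lambda x: x.position):
            if cluster and c.position - cluster[-1].position > radius:
                loci.append(_make_locus(chrom, cluster))
                cluster = []
            cluster.append(c)
        if cluster:
            loci.append(_make_locus(chrom, cluster))
    return loci


def _make_locus(chrom: str, cluster: list[InsertionCall]) -> InsertionLocus:
    positions = sorted(c.position for c in cluster)
    median = positions[len(positions) // 2]
    votes = Counter(c.variant for c in cluster if c.variant not in ("fragment", "untyped"))
    if votes:
        top = max(votes.values())
        tied = [v for v, n in votes.items() if n == top]
        variant = min(tied, key=lambda v: _SPECIFICITY.get(v, len(_SPECIFICITY)))
    else:
        variant = "fragment"
    return InsertionLocus(
        chrom=chrom, position=median, variant=variant, supporting_reads=len(cluster)
    )


def verify_empty_site(
    locus: InsertionLocus,
    genome: Sequence[SequenceRecord],
    reads: Sequence[SequenceRecord],
    flank: int = 500,
    anchor: int = 100,
    min_identity: float = 0.90,
) -> str:
    """Search reads for the insertion-free junction of a locus.

    The junction sequence is the reference ±``flank`` around the insertion
    point (the TE being absent from the reference).  The empty allele is
    "present" iff any read carries a contiguous >= 90%-identity match
    spanning the junction with >= ``anchor`` bases on each side.
    """
    ref = {g.id: g.sequence for g in genome}[locus.chrom]
    pos = locus.position  # 1-based first base after the junction
    s = max(1, pos - flank)
    e = min(len(ref), pos + flank - 1)
    junction = SequenceRecord(f"{locus.chrom}:{pos}:empty", ref[s - 1 : e])
    # junction coordinate of the insertion point within the query
    j = pos - s  # 0-based offset of the first post-junction base
    index = SeedIndex(reads if isinstance(reads, list) else list(reads))
    for h in index.hits(junction, min_identity=min_identity):
        if h.query_start <= j - anchor + 1 and h.query_end >= j + anchor:
            return "present"
    return "absent"


def annotate_novelty(
    loci: Sequence[InsertionLocus],
    reference: Sequence[BedInterval],
    radius: int = 100,
    family: str | None = None,
) -> list[InsertionLocus]:
    """Mark each locus shared/new against a reference TE annotation.

    A locus is "shared" iff a reference interval of the same family lies
    within ``radius`` of its position.
    """
    out = []
    for locus in loci:
        shared = any(
            iv.chrom == locus.chrom
            and (family is None or iv.name == family)
            and iv.start - radius <= locus.position <= iv.end + radius
            for iv in reference
        )
        out.append(replace(locus, novelty="shared" if shared else "new"))
    return out
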