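"""Exact k-mer seeding with co-diagonal merging and identity-bounded extension.

A deliberately small local aligner for substitution-dominated long reads:
exact k-mer matches between query and reference are grouped per diagonal,
bridged across small gaps when the bridged segment keeps >= 90% identity,
and extended outwards base by base while identity stays above the floor.
No gapped alignment is attempted — indels move hits onto new diagonals,
which is exactly the behaviour the downstream chaining logic consumes.
Externally produced BLAST6/PAF hits can be substituted anywhere this
engine's output is used.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .formats import AlignmentHit, SequenceRecord, reverse_complement

__all__ = ["SeedIndex"]

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer hashes; windows containing non-ACGT get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k, dtype=np.int64)
    hashes = win @ powers
    invalid = (win < 0).any(axis=1)
    hashes[invalid] = -1
    return hashes


class SeedIndex:
    """A k-mer index over one or more reference sequences.

    Build once, query many times with :meth:`hits`.  References are
    concatenated with an invalid-base separator so no k-mer spans two
    sequences; the index itself is a sorted hash array plus positions,
    which keeps memory linear and lookups vectorised.
    """

    def __init__(self, refs: list[SequenceRecord], k: int = 15):
        self.k = k
        self.refs = {r.id: r.sequence for r in refs}
        self._ids = [r.id for r in refs]
        self._ref_codes = {r.id: _encode(r.sequence) for r in refs}
        self._starts: list[int] = []
        parts = []
        pos = 0
        for r in refs:
            self._starts.append(pos)
            parts.append(_encode(r.sequence))
            parts.append(np.array([-1], dtype=np.int64))  # separator
            pos += len(r.sequence) + 1
        codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        hashes = _kmer_hashes(codes, k)
        valid = np.flatnonzero(hashes >= 0)
        order = np.argsort(hashes[valid], kind="stable")
        self._sorted_hashes = hashes[valid][order]
        self._sorted_pos = valid[order]  # global 0-based reference offsets
        self._bounds = np.array(self._starts + [pos], dtype=np.int64)

    def _locate(self, global_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ref_idx = np.searchsorted(self._bounds, global_pos, side="right") - 1
        local = global_pos - self._bounds[ref_idx]
        return ref_idx, local

    # -- seed collection ----------------------------------------------------

    def _seeds(self, query_codes: np.ndarray) -> dict[tuple[int, int], list[int]]:
        """Map (ref_idx, diagonal) -> sorted query offsets of seed matches."""
        qh = _kmer_hashes(query_codes, self.k)
        qpos = np.flatnonzero(qh >= 0)
        if qpos.size == 0:
            return {}
        lo = np.searchsorted(self._sorted_hashes, qh[qpos], side="left")
        hi = np.searchsorted(self._sorted_hashes, qh[qpos], side="right")
        counts = hi - lo
        matched = np.flatnonzero(counts > 0)
        if matched.size == 0:
            return {}
        q_rep = np.repeat(qpos[matched], counts[matched])
        gather = np.concatenate(
            [self._sorted_pos[l:h] for l, h in zip(lo[matched], hi[matched])]
        )
        ref_idx, local = self._locate(gather)
        diag = local - q_rep
        groups: dict[tuple[int, int], list[int]] = defaultdict(list)
        for ri, d, q in zip(ref_idx.tolist(), diag.tolist(), q_rep.tolist()):
            groups[(ri, d)].append(q)
        return groups

    # -- run building -------------------------------------------------------

    def _runs_on_diagonal(
        self,
        q_codes: np.ndarray,
        r_codes: np.ndarray,
        diag: int,
        q_offsets: list[int],
        min_identity: float,
        max_bridge: int,
    ) -> list[tuple[int, int, int]]:
        """Merge seeds on one diagonal into (q_start, q_end, mismatches) runs
        (0-based inclusive query offsets of whole matched segments)."""
        q_offsets = sorted(q_offsets)
        runs: list[tuple[int, int, int]] = []
        cur_s = q_offsets[0]
        cur_e = q_offsets[0] + self.k - 1
        cur_mm = 0
        for q in q_offsets[1:]:
            e = q + self.k - 1
            if q <= cur_e + 1:
                cur_e = max(cur_e, e)
                continue
            gap_len = q - cur_e - 1
            gap_q = np.arange(cur_e + 1, q)
            gap_mm = int((q_codes[gap_q] != r_codes[gap_q + diag]).sum())
            new_len = e - cur_s + 1
            # isolated errors (1-2 mismatches between clean k-mer stretches)
            # must bridge; unrelated sequence (~75% mismatch) must not
            if (
                gap_len <= max_bridge
                and gap_mm <= max(3, gap_len // 2)
                and (new_len - cur_mm - gap_mm) / new_len >= min_identity
            ):
                cur_e = e
                cur_mm += gap_mm
            else:
                runs.append((cur_s, cur_e, cur_mm))
                cur_s, cur_e, cur_mm = q, e, 0
        runs.append((cur_s, cur_e, cur_mm))
        return runs

    @staticmethod
    def _extend(
        q_codes: np.ndarray,
        r_codes: np.ndarray,
        diag: int,
        s: int,
        e: int,
        mm: int,
        min_identity: float,
        mismatch_penalty: int = 4,
        xdrop: int = 20,
    ) -> tuple[int, int, int]:
        """X-drop extension in both directions, trimmed to the best-scoring
        endpoint so runs end on a match.

        A local score (+1 match, -penalty mismatch) stops extension once it
        falls ``xdrop`` below its running maximum: isolated substitutions
        are absorbed, but unrelated sequence (e.g. beyond a deletion
        junction) terminates the run within a few bases regardless of how
        long the upstream match is.
        """
        # right
        score = 0
        best = 0
        best_e, best_mm = e, mm
        cur_mm = mm
        j = e + 1
        while j < len(q_codes) and 0 <= j + diag < len(r_codes) and r_codes[j + diag] >= 0:
            if q_codes[j] < 0:
                break
            if q_codes[j] == r_codes[j + diag]:
                score += 1
                if score > best:
                    best, best_e, best_mm = score, j, cur_mm
            else:
                cur_mm += 1
                score -= mismatch_penalty
                if best - score > xdrop:
                    break
            j += 1
        e, mm = best_e, best_mm
        # left
        score = 0
        best = 0
        best_s, best_mm = s, mm
        cur_mm = mm
        j = s - 1
        while j >= 0 and 0 <= j + diag < len(r_codes) and r_codes[j + diag] >= 0:
            if q_codes[j] < 0:
                break
            if q_codes[j] == r_codes[j + diag]:
                score += 1
                if score > best:
                    best, best_s, best_mm = score, j, cur_mm
            else:
                cur_mm += 1
                score -= mismatch_penalty
                if best - score > xdrop:
                    break
            j -= 1
        return best_s, e, best_mm

    # -- public API ---------------------------------------------------------

    def hits(
        self,
        query: SequenceRecord,
        min_identity: float = 0.90,
        min_length: int = 30,
        max_bridge: int = 120,
    ) -> list[AlignmentHit]:
        """All seeded local hits of ``query`` against the index, both strands.

        Minus-strand hits carry ``subject_start > subject_end``; query
        coordinates are always in the original read frame.
        """
        out: list[AlignmentHit] = []
        L = len(query.sequence)
        for strand, seq in (
            ("+", query.sequence),
            ("-", reverse_complement(query.sequence)),
        ):
            q_codes = _encode(seq)
            groups = self._seeds(q_codes)
            for (ri, diag), q_offs in groups.items():
                ref_id = self._ids[ri]
                r_codes = self._ref_codes[ref_id]
                runs = self._runs_on_diagonal(
                    q_codes, r_codes, diag, q_offs, min_identity, max_bridge
                )
                for s, e, mm in runs:
                    s, e, mm = self._extend(
                        q_codes, r_codes, diag, s, e, mm, min_identity
                    )
                    length = e - s + 1
                    if length < min_length:
                        continue
                    identity = 100.0 * (length - mm) / length
                    ss, se = s + diag + 1, e + diag + 1  # 1-based subject
                    if strand == "+":
                        qs, qe = s + 1, e + 1
                    else:
                        qs, qe = L - e, L - s
                        ss, se = se, ss
                    out.append(
                        AlignmentHit(
                            query_id=query.id,
                            query_start=qs,
                            query_end=qe,
                            subject_id=ref_id,
                            subject_start=ss,
                            subject_end=se,
                            identity=round(identity, 3),
                            length=length,
                        )
                    )
        out.sort(key=lambda h: (h.query_start, h.subject_id, h.subject_low))
        return self._dedup(out)

    @staticmethod
    def _dedup(hits: list[AlignmentHit]) -> list[AlignmentHit]:
        """Drop hits wholly contained in a longer hit on the same subject
        and strand (seed noise inside a real alignment)."""
        kept: list[AlignmentHit] = []
        for h in sorted(hits, key=lambda x: -x.length):
            contained = any(
                h.subject_id == k.subject_id
                and h.strand == k.strand
                and h.query_start >= k.query_start
                and h.query_end <= k.query_end
                and h.subject_low >= k.subject_low
                and h.subject_high <= k.subject_high
                for k in kept
            )
            if not contained:
                kept.append(h)
        kept.sort(key=lambda h: (h.query_start, h.subject_id, h.subject_low))
        return kept
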