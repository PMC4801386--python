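"""Exhaustive reference aligner used as an independent oracle in tests.

Evaluates every start position of every CDS on both strands (no seeding or
candidate pruning) under the same published rules as the mapper: admission
requires a shared exact word (word size 25), at most one gap opening of
length <= 3, identity >= 95%, retention of maximal-score ties capped at five
lexicographically smallest CDS ids.  The gapless/single-gap score landscape
is enumerated with full sliding-window match matrices.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from Bio.Seq import reverse_complement

from sialoquant.readmap import CdsRecord, MapParams, ReadRecord


def _enc(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)


def _shares_word(read_seq: str, cds_seq: str, k: int) -> bool:
    words = {cds_seq[i : i + k] for i in range(len(cds_seq) - k + 1)}
    return any(read_seq[j : j + k] in words for j in range(len(read_seq) - k + 1))


def _best_score(read_seq: str, cds_seq: str, p: MapParams) -> Optional[int]:
    """Max alignment score over all placements, or None if none pass identity."""
    r, c = _enc(read_seq), _enc(cds_seq)
    L, M = r.size, c.size
    if L > M:
        return None
    cands: List[int] = []

    # gapless: every start position
    B = sliding_window_view(c, L) == r  # (M-L+1, L)
    n0 = int(B.sum(axis=1).max())
    if 100.0 * n0 / L >= p.min_identity:
        cands.append(p.match_score * n0 + p.mismatch_score * (L - n0))

    pre = np.concatenate(
        [np.zeros((B.shape[0], 1), dtype=int), np.cumsum(B, axis=1)], axis=1
    )
    suf = pre[:, -1:] - pre
    for g in range(1, p.max_gap_length + 1):
        pen = p.gap_open + p.gap_extend * (g - 1)
        # deletion from the read (reference consumes L+g bases); the gap sits
        # at read split point p in 1..L-1, prefix on diagonal s, suffix on s+g
        if B.shape[0] > g and L >= 2:
            tot = pre[:-g, 1:L] + suf[g:, 1:L]
            if tot.size:
                n = int(tot.max())
                if 100.0 * n / (L + g) >= p.min_identity:
                    cands.append(p.match_score * n + p.mismatch_score * (L - n) + pen)
        # insertion in the read (g read bases over gap columns); reference
        # consumes L-g bases
        if L - g - 1 >= 1 and M >= L - g:
            Wg = sliding_window_view(c, L - g)
            Bp = Wg == r[: L - g]
            Bs = Wg == r[g:]
            pre_p = np.concatenate(
                [np.zeros((Bp.shape[0], 1), dtype=int), np.cumsum(Bp, axis=1)], axis=1
            )
            cs = np.cumsum(Bs, axis=1)
            # matches(s, p) = prefix matches up to p + suffix matches from p
            tot = pre_p[:, 1 : L - g] + (Bs.sum(axis=1, keepdims=True) - cs)[:, 0 : L - g - 1]
            if tot.size:
                n = int(tot.max())
                if 100.0 * n / L >= p.min_identity:
                    cands.append(
                        p.match_score * n + p.mismatch_score * (L - g - n) + pen
                    )
    return max(cands) if cands else None


def exhaustive_map(
    read: ReadRecord, reference: Sequence[CdsRecord], params: Optional[MapParams] = None
) -> List[Tuple[str, int]]:
    """Retained (cds_id, score) pairs for one read, by brute force."""
    params = params or MapParams()
    k = params.word_size
    if len(read.sequence) < k:
        return []
    per_cds = {}
    for rec in reference:
        best = None
        for seq in (read.sequence.upper(), reverse_complement(read.sequence.upper())):
            if not _shares_word(seq, rec.sequence.upper(), k):
                continue
            score = _best_score(seq, rec.sequence.upper(), params)
            if score is not None and (best is None or score > best):
                best = score
        if best is not None:
            per_cds[rec.cds_id] = best
    if not per_cds:
        return []
    top = max(per_cds.values())
    tied = sorted(cid for cid, s in per_cds.items() if s == top)
    return [(cid, top) for cid in tied[: params.max_hits]]
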