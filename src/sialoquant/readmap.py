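"""Read trimming and read-to-CDS assignment.

Reads are assigned to coding sequences with a blastn-like seed-and-extend
strategy: candidate CDS are found through shared exact k-mers (word size 25),
each candidate is scored by a banded extension that allows at most one gap
opening (length <= 3), alignments below 95% identity are discarded, and only
assignments tied at the maximal score are retained (at most five per read).
Multi-mapped reads contribute a whole count to each tied CDS by default; a
fractional 1/k policy is available for the count matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import InputError

logger = logging.getLogger(__name__)

LIBRARIES: Tuple[str, ...] = ("FSG", "MSG", "FWB", "MWB")

DEFAULT_TRIM_THRESHOLD = 13  # Phred; bases below this are trimmed off the 3' end
MIN_READ_LENGTH = 25  # the seed word size; shorter reads cannot seed


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CdsRecord:
    """One reference coding sequence."""

    cds_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise InputError(
                f"CDS {self.cds_id}: illegal characters {sorted(bad)} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int]
    library_label: str = "FSG"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise InputError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )


@dataclass(frozen=True)
class Assignment:
    """A retained read-to-CDS alignment."""

    read_id: str
    cds_id: str
    score: int
    identity: float
    gaps: int
    strand: str


@dataclass
class MapParams:
    """Alignment parameters.

    The scoring scheme (match +2, mismatch -3, gap open -5, gap extend -2)
    is megablast-like; "one gap allowed" means at most one gap opening of
    length up to ``max_gap_length`` bases on either sequence.
    """

    word_size: int = 25
    min_identity: float = 95.0
    max_gap_length: int = 3
    max_hits: int = 5
    match_score: int = 2
    mismatch_score: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def gap_penalty(self, g: int) -> int:
        return self.gap_open + self.gap_extend * (g - 1)


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


def trim_read(
    read: ReadRecord,
    threshold: int = DEFAULT_TRIM_THRESHOLD,
    min_length: int = MIN_READ_LENGTH,
    mode: str = "trim",
) -> Optional[ReadRecord]:
    """Quality-trim a read; return None when it is dropped.

    ``mode="trim"`` (default) removes the trailing run of bases whose quality
    is below ``threshold`` and drops the read if fewer than ``min_length``
    bases remain.  ``mode="discard"`` drops the whole read if any base falls
    below the threshold.
    """
    if mode == "discard":
        if any(q < threshold for q in read.qualities):
            return None
        return read
    if mode != "trim":
        raise InputError(f"unknown trim mode {mode!r}")
    end = len(read.sequence)
    quals = read.qualities
    while end > 0 and quals[end - 1] < threshold:
        end -= 1
    if end < min_length:
        return None
    if end == len(read.sequence):
        return read
    return replace(read, sequence=read.sequence[:end], qualities=list(quals[:end]))


# ---------------------------------------------------------------------------
# reference index
# ---------------------------------------------------------------------------

_PAD = 4  # sentinel bytes flanking each encoded CDS; zero never matches a base


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


class ReferenceIndex:
    """Exact k-mer index over the forward strand of a CDS set."""

    def __init__(self, reference: Sequence[CdsRecord], word_size: int = 25):
        self.word_size = word_size
        self.records: List[CdsRecord] = list(reference)
        self.lengths = np.array([r.length for r in self.records], dtype=np.int64)
        # padded encodings so banded windows near the ends stay in-bounds
        self.encoded: List[np.ndarray] = []
        self.kmers: Dict[str, List[Tuple[int, int]]] = {}
        for idx, rec in enumerate(self.records):
            seq = rec.sequence.upper()
            arr = np.zeros(len(seq) + 2 * _PAD, dtype=np.uint8)
            arr[_PAD : _PAD + len(seq)] = _encode(seq)
            self.encoded.append(arr)
            for pos in range(len(seq) - word_size + 1):
                self.kmers.setdefault(seq[pos : pos + word_size], []).append((idx, pos))

    def __len__(self) -> int:
        return len(self.records)


def read_reference_fasta(path) -> List[CdsRecord]:
    return [CdsRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# alignment of one oriented read against one CDS
# ---------------------------------------------------------------------------


def _best_alignment_for_cds(
    read_arr: np.ndarray,
    cds_arr: np.ndarray,
    cds_len: int,
    seed_diagonals: Iterable[int],
    params: MapParams,
) -> Optional[Tuple[int, float, int]]:
    """Best (score, identity, gaps) for one read/CDS/strand, or None.

    Only alignments with identity >= params.min_identity are eligible.  A
    start diagonal ``s`` places read base 0 on reference position ``s``; the
    read must be fully contained in the reference.  A single gap of length g
    moves the active diagonal by +-g, so every alignment reachable from a
    seed lives on a start diagonal within ``max_gap_length`` of a seed
    diagonal.
    """
    L = read_arr.size
    G = params.max_gap_length
    seeds = sorted(set(seed_diagonals))

    match_cache: Dict[int, Optional[np.ndarray]] = {}

    def matches_on(s: int) -> Optional[np.ndarray]:
        # boolean per-base match vector for the gapless window at diagonal s
        if s not in match_cache:
            if s < -G or s + L > cds_len + G:
                match_cache[s] = None
            else:
                window = cds_arr[_PAD + s : _PAD + s + L]
                match_cache[s] = read_arr == window
        return match_cache[s]

    # fast path: a perfect gapless hit (score 2L) cannot be beaten or tied by
    # any alignment containing a mismatch or gap
    perfect = False
    best: Optional[Tuple[int, float, int]] = None
    for s in seeds:
        if 0 <= s and s + L <= cds_len:
            m = matches_on(s)
            if m is not None and m.all():
                perfect = True
                best = (params.match_score * L, 100.0, 0)
                break
    if perfect:
        return best

    min_ident = params.min_identity

    def consider(score: int, matches: int, columns: int, gaps: int) -> None:
        nonlocal best
        identity = 100.0 * matches / columns
        if identity < min_ident:
            return
        if best is None or (score, identity, -gaps) > (best[0], best[1], -best[2]):
            best = (score, identity, gaps)

    start_diags = sorted({s + d for s in seeds for d in range(-G, G + 1)})
    for s in start_diags:
        m0 = matches_on(s)
        gapless_ok = 0 <= s and s + L <= cds_len
        if gapless_ok and m0 is not None:
            n_match = int(m0.sum())
            score = params.match_score * n_match + params.mismatch_score * (L - n_match)
            consider(score, n_match, L, 0)
        if m0 is None:
            continue
        pre0 = np.concatenate(([0], np.cumsum(m0)))
        for g in range(1, G + 1):
            pen = params.gap_penalty(g)
            # deletion from the read: reference consumes L + g bases
            if 0 <= s and s + L + g <= cds_len:
                mg = matches_on(s + g)
                if mg is not None:
                    suf = np.concatenate((np.cumsum(mg[::-1])[::-1], [0]))
                    # gap strictly internal: read split point p in 1..L-1
                    tot = pre0[1:L] + suf[1:L]
                    p_best = int(np.argmax(tot))
                    n_match = int(tot[p_best])
                    score = (
                        params.match_score * n_match
                        + params.mismatch_score * (L - n_match)
                        + pen
                    )
                    consider(score, n_match, L + g, 1)
            # insertion in the read: g read bases sit over gap columns
            if 0 <= s and s + L - g <= cds_len and L - g - 1 >= 1:
                mi = matches_on(s - g)
                if mi is not None:
                    suf = np.concatenate((np.cumsum(mi[::-1])[::-1], [0]))
                    tot = pre0[1 : L - g] + suf[1 + g : L]
                    p_best = int(np.argmax(tot))
                    n_match = int(tot[p_best])
                    score = (
                        params.match_score * n_match
                        + params.mismatch_score * (L - g - n_match)
                        + pen
                    )
                    consider(score, n_match, L, 1)
    return best


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def map_read(
    read: ReadRecord,
    reference: ReferenceIndex | Sequence[CdsRecord],
    params: Optional[MapParams] = None,
) -> List[Assignment]:
    """Assign a read to CDS under the seed-and-extend rules.

    Returns the retained assignments: identity >= 95%, at most one gap, all
    sharing the maximal score, at most ``max_hits`` of them (ties beyond the
    cap resolved by ascending lexicographic cds_id).
    """
    params = params or MapParams()
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(reference, params.word_size)
    if len(reference) == 0:
        return []
    k = reference.word_size
    if len(read.sequence) < k:
        return []

    # best (score, identity, gaps, strand) per candidate CDS index
    per_cds: Dict[int, Tuple[int, float, int, str]] = {}
    for strand, seq in (("+", read.sequence.upper()), ("-", reverse_complement(read.sequence.upper()))):
        read_arr = _encode(seq)
        L = read_arr.size
        seed_diags: Dict[int, set] = {}
        kmer_table = reference.kmers
        for q in range(L - k + 1):
            hits = kmer_table.get(seq[q : q + k])
            if hits:
                for idx, pos in hits:
                    seed_diags.setdefault(idx, set()).add(pos - q)
        for idx, diags in seed_diags.items():
            result = _best_alignment_for_cds(
                read_arr,
                reference.encoded[idx],
                int(reference.lengths[idx]),
                diags,
                params,
            )
            if result is None:
                continue
            score, identity, gaps = result
            prev = per_cds.get(idx)
            if prev is None or (score, identity, -gaps) > (prev[0], prev[1], -prev[2]):
                per_cds[idx] = (score, identity, gaps, strand)

    if not per_cds:
        return []
    top = max(v[0] for v in per_cds.values())
    tied = sorted(
        (reference.records[idx].cds_id, v) for idx, v in per_cds.items() if v[0] == top
    )
    return [
        Assignment(read.read_id, cds_id, score, identity, gaps, strand)
        for cds_id, (score, identity, gaps, strand) in tied[: params.max_hits]
    ]


def map_reads(
    reads: Iterable[ReadRecord],
    reference: ReferenceIndex | Sequence[CdsRecord],
    params: Optional[MapParams] = None,
    trim: bool = True,
    trim_threshold: int = DEFAULT_TRIM_THRESHOLD,
    trim_mode: str = "trim",
) -> Dict[str, List[Assignment]]:
    """Trim and map a stream of reads; returns assignments grouped by library.

    Logs summary counts of trimmed-away and unassigned reads per library.
    """
    params = params or MapParams()
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(reference, params.word_size)
    out: Dict[str, List[Assignment]] = {}
    n_in: Dict[str, int] = {}
    n_dropped: Dict[str, int] = {}
    n_unassigned: Dict[str, int] = {}
    for read in reads:
        lib = read.library_label
        n_in[lib] = n_in.get(lib, 0) + 1
        if trim:
            trimmed = trim_read(read, trim_threshold, mode=trim_mode)
            if trimmed is None:
                n_dropped[lib] = n_dropped.get(lib, 0) + 1
                continue
            read = trimmed
        hits = map_read(read, reference, params)
        if not hits:
            n_unassigned[lib] = n_unassigned.get(lib, 0) + 1
            continue
        out.setdefault(lib, []).extend(hits)
    for lib in sorted(n_in):
        logger.info(
            "library %s: %d reads in, %d dropped by trimming, %d unassigned",
            lib,
            n_in[lib],
            n_dropped.get(lib, 0),
            n_unassigned.get(lib, 0),
        )
    return out


def read_fastq(path, library_label: str) -> Iterable[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id,
            str(rec.seq),
            rec.letter_annotations["phred_quality"],
            library_label,
        )


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Per-CDS mapped-read counts per library, plus library totals R.

    ``counts`` is a DataFrame indexed by cds_id with one column per library;
    ``totals[L]`` is the total number of reads mapped to all CDS in library L
    (under the whole-count multi-mapping policy this equals the column sum).
    """

    counts: pd.DataFrame
    totals: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)


def build_count_matrix(
    assignments: Mapping[str, Sequence[Assignment]],
    cds_ids: Sequence[str],
    libraries: Sequence[str] = LIBRARIES,
    policy: str = "whole",
) -> CountMatrix:
    """Aggregate retained assignments into the count matrix.

    Under the default whole-count policy each retained assignment adds 1 to
    its (cds, library) cell, so a read tied between k CDS contributes k to
    the library total.  ``policy="fractional"`` adds 1/k instead.
    """
    if policy not in ("whole", "fractional"):
        raise InputError(f"unknown multi-mapping policy {policy!r}")
    unknown = set(assignments) - set(libraries)
    if unknown:
        raise InputError(f"unknown library labels {sorted(unknown)}")
    counts = pd.DataFrame(0.0, index=list(cds_ids), columns=list(libraries))
    counts.index.name = "cds_id"
    for lib, hits in assignments.items():
        if policy == "whole":
            weights: Dict[str, float] = {}
            for a in hits:
                weights[a.cds_id] = weights.get(a.cds_id, 0.0) + 1.0
        else:
            per_read: Dict[str, List[str]] = {}
            for a in hits:
                per_read.setdefault(a.read_id, []).append(a.cds_id)
            weights = {}
            for cds_list in per_read.values():
                w = 1.0 / len(cds_list)
                for cid in cds_list:
                    weights[cid] = weights.get(cid, 0.0) + w
        for cid, w in weights.items():
            if cid not in counts.index:
                raise InputError(f"assignment to unknown CDS {cid!r}")
            counts.at[cid, lib] += w
    if policy == "whole":
        counts = counts.astype(np.int64)
    return CountMatrix(counts)


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    df = matrix.counts.reset_index()
    df.columns = ["cds_id"] + [f"r_{lib}" for lib in matrix.counts.columns]
    df.to_csv(path, sep="\t", index=False)
    totals_path = str(path) + ".totals"
    matrix.totals.rename_axis("library").rename("R").reset_index().to_csv(
        totals_path, sep="\t", index=False
    )


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("cds_id")
    df.columns = [c[2:] if c.startswith("r_") else c for c in df.columns]
    totals_path = str(path) + ".totals"
    try:
        tot = pd.read_csv(totals_path, sep="\t").set_index("library")["R"]
    except FileNotFoundError:
        tot = None
    return CountMatrix(df, tot)
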