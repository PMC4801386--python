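"""ORF bookkeeping and outgroup-validation thresholds.

Extracts the longest open reading frame of a contig across all six frames
(an ORF is a maximal stop-free codon run, optionally bounded by a stop;
a methionine start is recorded as a flag, not required), applies the 25%
protein-extension rule, and applies cross-proteome validation thresholds to
externally supplied alignment summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq, reverse_complement

from .errors import InputError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# frame evaluation order used for tie-breaking
FRAMES: Tuple[int, ...] = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfResult:
    contig_id: str
    frame: int
    start: int  # 0-based half-open on the forward strand; includes the
    end: int    # terminal stop codon when present
    protein: str
    starts_with_met: bool
    ends_with_stop: bool

    @property
    def protein_length(self) -> int:
        return len(self.protein)


def _translate(codon_seq: str) -> str:
    """Translate a stop-free codon run; ambiguous codons become X."""
    return str(Seq(codon_seq).translate()).replace("*", "X")


def longest_orf(contig: str, contig_id: str = "") -> OrfResult:
    """Longest ORF over all six frames.

    Runs are ranked by their total codon span, counting a bounding stop
    codon when present, with stop-bounded runs preferred on span ties (a
    complete ORF outranks one truncated by the contig edge); remaining ties
    are broken by frame order +1, +2, +3, -1, -2, -3 and then by the
    leftmost start within a frame.  Codons containing N translate to X and
    do not terminate a run; only exact TAA/TAG/TGA do.
    """
    seq = contig.upper()
    if len(seq) < 3:
        raise InputError("contig shorter than one codon")
    best: Optional[Tuple[int, int, int, str, bool]] = None  # frame,start,end,protein,stop
    best_key = (-1, False)
    rc = reverse_complement(seq)
    for frame in FRAMES:
        if frame > 0:
            template, offset = seq, frame - 1
        else:
            template, offset = rc, -frame - 1
        n_codons = (len(template) - offset) // 3
        if n_codons == 0:
            continue
        codons = [
            template[offset + 3 * i : offset + 3 * i + 3] for i in range(n_codons)
        ]
        run_start = 0
        i = 0
        while run_start < n_codons:
            i = run_start
            while i < n_codons and codons[i] not in STOP_CODONS:
                i += 1
            run_len = i - run_start
            has_stop = i < n_codons
            key = (run_len + (1 if has_stop else 0), has_stop)
            if key > best_key:
                a = offset + 3 * run_start
                b = offset + 3 * (i + (1 if has_stop else 0))
                if frame < 0:  # map [a, b) on the reverse strand to forward
                    a, b = len(seq) - b, len(seq) - a
                protein = _translate(
                    "".join(codons[run_start:i])
                ) if run_len else ""
                best = (frame, a, b, protein, has_stop)
                best_key = key
            run_start = i + 1
    assert best is not None
    frame, start, end, protein, has_stop = best
    return OrfResult(
        contig_id=contig_id,
        frame=frame,
        start=start,
        end=end,
        protein=protein,
        starts_with_met=protein.startswith("M"),
        ends_with_stop=has_stop,
    )


def orf_table(contigs: Sequence[Tuple[str, str]]) -> pd.DataFrame:
    """Longest-ORF table for (contig_id, sequence) pairs."""
    rows = []
    for cid, seq in contigs:
        orf = longest_orf(seq, cid)
        rows.append(
            (
                cid,
                orf.frame,
                orf.start,
                orf.end,
                orf.starts_with_met,
                orf.ends_with_stop,
                orf.protein_length,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "frame",
            "start",
            "end",
            "starts_with_met",
            "ends_with_stop",
            "protein_len",
        ],
    )


def assess_extension(new_protein_len: int, ref_protein_len: int) -> bool:
    """True when the new protein is extended by 25% or more in length."""
    if new_protein_len <= 0 or ref_protein_len <= 0:
        raise InputError("protein lengths must be > 0")
    return new_protein_len >= 1.25 * ref_protein_len


@dataclass(frozen=True)
class AlignmentSummary:
    """Summary of one externally computed protein alignment."""

    query_id: str
    subject_id: str
    evalue: float
    identity_pct: float
    query_coverage_pct: float
    query_len: int
    subject_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.identity_pct <= 100 and 0 <= self.query_coverage_pct <= 100):
            raise InputError("percent fields must lie in [0, 100]")
        if self.query_len <= 0 or self.subject_len <= 0:
            raise InputError("lengths must be > 0")


def validate_against_outgroup(summary: AlignmentSummary, mode: str) -> bool:
    """Cross-proteome validation of an extended protein.

    mode "drosophila": e-value below 1e-15 and query length within 10% of
    the subject length.  mode "culex": query coverage above 90% of the
    subject protein and identity below 95%.
    """
    if mode == "drosophila":
        return summary.evalue < 1e-15 and abs(
            summary.query_len - summary.subject_len
        ) <= 0.10 * summary.subject_len
    if mode == "culex":
        return summary.query_coverage_pct > 90.0 and summary.identity_pct < 95.0
    raise InputError(f"unknown validation mode {mode!r}")


def read_alignment_summaries(
    path, query_lengths=None, subject_lengths=None
) -> List[AlignmentSummary]:
    """Read alignment summaries from TSV.

    Accepts either a headered table with the AlignmentSummary column names,
    or the standard 12-column tabular alignment format (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore), in
    which case ``query_lengths`` and ``subject_lengths`` mappings are
    required to derive coverage and lengths.
    """
    df = pd.read_csv(path, sep="\t", header=None if query_lengths else 0)
    if query_lengths is None:
        need = {"query_id", "subject_id", "evalue", "identity_pct",
                "query_coverage_pct", "query_len", "subject_len"}
        if not need <= set(df.columns):
            raise InputError(f"summary table must have columns {sorted(need)}")
        return [
            AlignmentSummary(
                str(r.query_id), str(r.subject_id), float(r.evalue),
                float(r.identity_pct), float(r.query_coverage_pct),
                int(r.query_len), int(r.subject_len),
            )
            for r in df.itertuples()
        ]
    out = []
    for row in df.itertuples(index=False):
        qid, sid, pident = str(row[0]), str(row[1]), float(row[2])
        qstart, qend, evalue = int(row[6]), int(row[7]), float(row[10])
        qlen = int(query_lengths[qid])
        slen = int(subject_lengths[sid])
        coverage = 100.0 * (abs(qend - qstart) + 1) / qlen
        out.append(
            AlignmentSummary(qid, sid, evalue, pident, min(coverage, 100.0), qlen, slen)
        )
    return out
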