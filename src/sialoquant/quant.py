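"""Per-CDS expression quantities.

RPKM (reads per kilobase of CDS per million mapped reads), TPM (transcripts
per million), the Expression Index (per-CDS mapped reads scaled to 100 at
the most-read CDS of a designated reference library, FSG by default), the
pseudocounted normalized read ratio r1*R2 / (R1*(r2+1)), and pairwise TPM
ratios with +0.1 added to the denominator.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .readmap import LIBRARIES, CountMatrix

logger = logging.getLogger(__name__)

#: the six directed library pairs reported throughout the analysis
RATIO_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("FSG", "MSG"),
    ("FSG", "FWB"),
    ("FSG", "MWB"),
    ("FWB", "MWB"),
    ("MSG", "MWB"),
    ("MSG", "FWB"),
)

TPM_PSEUDOCOUNT = 0.1


def rpkm(r, cds_length, R):
    """Reads per kilobase per million mapped reads: 1e9 * r / (length * R).

    Accepts scalars or aligned arrays.  R == 0 yields 0 with a warning
    (nothing mapped, the quantity is undefined).
    """
    r = np.asarray(r, dtype=float)
    cds_length = np.asarray(cds_length, dtype=float)
    if np.any(cds_length <= 0):
        raise ValueError("cds_length must be > 0")
    R = np.asarray(R, dtype=float)
    if np.any(R == 0):
        logger.warning("RPKM with zero mapped-read total: returning 0")
        out = np.where(R > 0, 1e9 * r / (cds_length * np.where(R > 0, R, 1.0)), 0.0)
    else:
        out = 1e9 * r / (cds_length * R)
    return float(out) if out.ndim == 0 else out


def tpm_vector(counts, lengths) -> np.ndarray:
    """TPM from per-CDS counts and lengths; an all-zero library stays zero."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be > 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


def expression_index(r, r_max) -> float:
    """Expression Index: 100 * r / r_max, anchored at 100 for the largest
    mapped-read count in the reference library."""
    if np.any(np.asarray(r_max) <= 0):
        raise ValueError("expression index undefined: reference maximum is 0")
    out = 100.0 * np.asarray(r, dtype=float) / np.asarray(r_max, dtype=float)
    return float(out) if out.ndim == 0 else out


def normalized_ratio(r1, R1, r2, R2):
    """Pseudocounted cross-library read ratio r1*R2 / (R1*(r2+1))."""
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if np.any(R1 <= 0) or np.any(R2 <= 0):
        raise ValueError("library totals must be > 0")
    out = np.asarray(r1, dtype=float) * R2 / (R1 * (np.asarray(r2, dtype=float) + 1.0))
    return float(out) if out.ndim == 0 else out


def tpm_ratio(tpm_num, tpm_den):
    """Directed TPM ratio with the +0.1 denominator pseudocount."""
    out = np.asarray(tpm_num, dtype=float) / (
        np.asarray(tpm_den, dtype=float) + TPM_PSEUDOCOUNT
    )
    return float(out) if out.ndim == 0 else out


def build_expression_table(
    matrix: CountMatrix,
    lengths: Sequence[int] | pd.Series,
    ei_reference: str = "FSG",
    libraries: Sequence[str] = LIBRARIES,
) -> pd.DataFrame:
    """Full per-CDS expression table.

    Columns: cds_id (index), length, r_<lib>, rpkm_<lib>, tpm_<lib>, ei,
    nr_<A>_over_<B> (normalized read ratios) and tpm_<A>_over_<B> for the six
    directed pairs.
    """
    counts = matrix.counts
    if isinstance(lengths, pd.Series):
        lengths = lengths.reindex(counts.index)
        length_arr = lengths.to_numpy(dtype=float)
    else:
        length_arr = np.asarray(lengths, dtype=float)
    out = pd.DataFrame(index=counts.index)
    out["length"] = length_arr.astype(int)
    for lib in libraries:
        out[f"r_{lib}"] = counts[lib]
    for lib in libraries:
        out[f"rpkm_{lib}"] = rpkm(
            counts[lib].to_numpy(), length_arr, float(matrix.totals[lib])
        )
    tpms = {}
    for lib in libraries:
        tpms[lib] = tpm_vector(counts[lib].to_numpy(), length_arr)
        out[f"tpm_{lib}"] = tpms[lib]
    ref_counts = counts[ei_reference].to_numpy(dtype=float)
    r_max = ref_counts.max() if len(ref_counts) else 0.0
    if r_max > 0:
        out["ei"] = expression_index(ref_counts, r_max)
    else:
        logger.warning("no reads mapped in EI reference library %s", ei_reference)
        out["ei"] = 0.0
    for num, den in RATIO_PAIRS:
        out[f"nr_{num}_over_{den}"] = normalized_ratio(
            counts[num].to_numpy(),
            float(matrix.totals[num]),
            counts[den].to_numpy(),
            float(matrix.totals[den]),
        )
        out[f"tpm_{num}_over_{den}"] = tpm_ratio(tpms[num], tpms[den])
    return out


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.reset_index().to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("cds_id")
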