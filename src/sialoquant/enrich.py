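"""Enrichment testing and the salivary-gland classification scheme.

Each CDS is tested with a Pearson chi-square on the 2x2 table
[[r1, R1-r1], [r2, R2-r2]] built from pooled salivary-gland versus pooled
whole-body counts, corrected by Bonferroni and Benjamini-Hochberg.  CDS at
least 10-fold salivary-enriched (pseudocounted TPM ratio of summed SG over
summed WB) with BH q below alpha are partitioned at a fivefold boundary
into female-enriched, male-enriched and shared; an extreme-specificity
screen flags TPM ratios above 1,000 against the opposite sex's whole body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .quant import TPM_PSEUDOCOUNT, normalized_ratio, tpm_ratio
from .readmap import LIBRARIES

CATEGORIES: Tuple[str, ...] = (
    "female_enriched",
    "male_enriched",
    "shared",
    "not_sg_enriched",
)

DEFAULT_SG_FOLD = 10.0
DEFAULT_SEX_FOLD = 5.0
DEFAULT_EXTREME = 1000.0
DEFAULT_ALPHA = 0.05


def chi2_counts(r1, R1, r2, R2, yates: bool = False):
    """Pearson chi-square (1 df) comparing read proportions r1/R1 vs r2/R2.

    Vectorised over aligned arrays; a zero marginal (r1 + r2 == 0 or both
    counts equal to their totals) gives statistic 0 and p 1.  No continuity
    correction by default.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if np.any(R1 <= 0) or np.any(R2 <= 0):
        raise ValueError("library totals must be > 0")
    if np.any(r1 < 0) or np.any(r2 < 0) or np.any(r1 > R1) or np.any(r2 > R2):
        raise ValueError("counts must satisfy 0 <= r <= R")
    a, b = r1, R1 - r1
    c, d = r2, R2 - r2
    n = R1 + R2
    col1 = a + c
    col2 = b + d
    denom = R1 * R2 * col1 * col2
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * diff**2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(denom > 0, p, 1.0)
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


def adjust_pvalues(p_list, method: str):
    """Bonferroni or Benjamini-Hochberg adjusted p-values (order-preserving)."""
    p = np.asarray(p_list, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise InputError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise InputError(f"unknown adjustment method {method!r}")


def salivary_filter(
    sg_wb_fold: float,
    q_bh: float,
    fold_threshold: float = DEFAULT_SG_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Tenfold salivary filter: fold >= threshold (inclusive) and q <= alpha."""
    return bool(sg_wb_fold >= fold_threshold and q_bh <= alpha)


def sex_partition(
    tpm_fsg: float, tpm_msg: float, fold: float = DEFAULT_SEX_FOLD
) -> str:
    """Three-way partition of a salivary-enriched CDS at a fivefold boundary.

    Uses the pseudocounted TPM ratios in both directions; if both exceed the
    threshold (possible only near zero TPM on both sides) the larger ratio
    wins.
    """
    f_ratio = tpm_ratio(tpm_fsg, tpm_msg)
    m_ratio = tpm_ratio(tpm_msg, tpm_fsg)
    if f_ratio >= fold and m_ratio >= fold:
        return "female_enriched" if f_ratio >= m_ratio else "male_enriched"
    if f_ratio >= fold:
        return "female_enriched"
    if m_ratio >= fold:
        return "male_enriched"
    return "shared"


def extreme_screen(
    tpm_fsg: float,
    tpm_msg: float,
    tpm_fwb: float,
    tpm_mwb: float,
    threshold: float = DEFAULT_EXTREME,
) -> Tuple[bool, bool]:
    """Extreme-specificity flags (female, male): TPM ratio against the
    opposite sex's whole body strictly above the threshold."""
    return (
        bool(tpm_ratio(tpm_fsg, tpm_mwb) > threshold),
        bool(tpm_ratio(tpm_msg, tpm_fwb) > threshold),
    )


def zscore_rows(matrix) -> np.ndarray:
    """Row-wise Z scores with sample SD (ddof=1); constant rows map to zero."""
    x = np.asarray(matrix, dtype=float)
    if x.size == 0:
        raise InputError("empty matrix")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


@dataclass
class EnrichmentParams:
    sg_fold: float = DEFAULT_SG_FOLD
    sex_fold: float = DEFAULT_SEX_FOLD
    extreme: float = DEFAULT_EXTREME
    alpha: float = DEFAULT_ALPHA
    yates: bool = False


def call_enrichment(
    expr: pd.DataFrame,
    totals: pd.Series,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Per-CDS enrichment calls from the expression table.

    ``expr`` must carry r_<lib> and tpm_<lib> columns for the four libraries
    (as produced by quant.build_expression_table); ``totals`` are the
    mapped-read totals R per library.  Returns one row per CDS with the
    chi-square on pooled SG vs pooled WB counts, raw/Bonferroni/BH p-values,
    the SG/WB TPM fold and pooled normalized read ratio, both sex-direction
    TPM folds, the category and the extreme flags.
    """
    params = params or EnrichmentParams()
    missing = [
        c
        for lib in LIBRARIES
        for c in (f"r_{lib}", f"tpm_{lib}")
        if c not in expr.columns
    ]
    if missing:
        raise InputError(f"expression table lacks columns {missing}")
    r_sg = expr["r_FSG"].to_numpy(float) + expr["r_MSG"].to_numpy(float)
    r_wb = expr["r_FWB"].to_numpy(float) + expr["r_MWB"].to_numpy(float)
    R_sg = float(totals["FSG"] + totals["MSG"])
    R_wb = float(totals["FWB"] + totals["MWB"])
    stat, p_raw = chi2_counts(r_sg, R_sg, r_wb, R_wb, yates=params.yates)
    p_bonf = adjust_pvalues(p_raw, "bonferroni")
    q_bh = adjust_pvalues(p_raw, "bh")

    tpm_fsg = expr["tpm_FSG"].to_numpy(float)
    tpm_msg = expr["tpm_MSG"].to_numpy(float)
    tpm_fwb = expr["tpm_FWB"].to_numpy(float)
    tpm_mwb = expr["tpm_MWB"].to_numpy(float)
    sg_wb_fold = (tpm_fsg + tpm_msg) / (tpm_fwb + tpm_mwb + TPM_PSEUDOCOUNT)
    nr_sg_wb = normalized_ratio(r_sg, R_sg, r_wb, R_wb)
    fsg_msg_fold = tpm_ratio(tpm_fsg, tpm_msg)
    msg_fsg_fold = tpm_ratio(tpm_msg, tpm_fsg)

    passes = (sg_wb_fold >= params.sg_fold) & (q_bh <= params.alpha)
    category = np.full(len(expr), "not_sg_enriched", dtype=object)
    for i in np.flatnonzero(passes):
        category[i] = sex_partition(tpm_fsg[i], tpm_msg[i], params.sex_fold)
    extreme_female = tpm_ratio(tpm_fsg, tpm_mwb) > params.extreme
    extreme_male = tpm_ratio(tpm_msg, tpm_fwb) > params.extreme

    return pd.DataFrame(
        {
            "chi2_stat": stat,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "q_bh": q_bh,
            "sg_wb_fold": sg_wb_fold,
            "nr_sg_over_wb": nr_sg_wb,
            "fsg_msg_fold": fsg_msg_fold,
            "msg_fsg_fold": msg_fsg_fold,
            "passes_salivary_filter": passes,
            "category": category,
            "extreme_female": extreme_female,
            "extreme_male": extreme_male,
            "extreme": extreme_female | extreme_male,
        },
        index=expr.index,
    )


def zscore_table(
    expr: pd.DataFrame, libraries: Sequence[str] = LIBRARIES
) -> pd.DataFrame:
    """Row-wise Z-score matrix of the per-library TPM values (heatmap input)."""
    cols = [f"tpm_{lib}" for lib in libraries]
    z = zscore_rows(expr[cols].to_numpy())
    return pd.DataFrame(z, index=expr.index, columns=[f"z_{lib}" for lib in libraries])
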