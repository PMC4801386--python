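"""qPCR relative quantification (2^-ddCt) and RNA-seq concordance.

Technical duplicates are averaged per biological replicate; delta-Ct is the
target-minus-reference Ct per replicate; delta-delta-Ct is the difference of
group means, with its standard error combined in quadrature across the two
groups; fold change is 2^-ddCt with a +-SE interval.  No amplification-
efficiency correction is applied.  Concordance between log2 qPCR and log2
RNA-seq fold changes is summarised by Pearson correlation and an ordinary
least-squares fit with 95% confidence-band parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

CT_COLUMNS = ("gene", "role", "group", "bio_rep", "tech_rep", "ct")


@dataclass(frozen=True)
class FoldChange:
    point: float  # 2^-ddCt
    ddct: float
    se_ddct: Optional[float]  # None with a single biological replicate
    interval: Optional[Tuple[float, float]]  # (2^-(ddCt+SE), 2^-(ddCt-SE))
    n_test: int
    n_control: int


def _delta_ct_per_replicate(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    group: str,
    average_technical: bool = True,
) -> np.ndarray:
    sub = ct[ct["group"] == group]
    tgt = sub[sub["gene"] == target_gene]
    ref = sub[sub["gene"] == reference_gene]
    if tgt.empty or ref.empty:
        raise InputError(
            f"group {group!r}: missing Ct rows for target or reference gene"
        )
    by = ["bio_rep"] if average_technical else ["bio_rep", "tech_rep"]
    tgt_means = tgt.groupby(by)["ct"].mean()
    ref_means = ref.groupby(by)["ct"].mean()
    joined = pd.concat([tgt_means, ref_means], axis=1, keys=["t", "r"]).dropna()
    if joined.empty:
        raise InputError(f"group {group!r}: no paired replicates")
    return (joined["t"] - joined["r"]).to_numpy()


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    test_group: str,
    control_group: str,
    reference_gene: str = "S7",
    average_technical: bool = True,
) -> FoldChange:
    """Fold change of the target gene in the test group vs the control group.

    ``ct_table`` is tidy with columns gene, role, group, bio_rep, tech_rep,
    ct.  With a single biological replicate in either group the point
    estimate is still returned but the SE and interval are None.
    """
    missing = set(CT_COLUMNS) - set(ct_table.columns)
    if missing:
        raise InputError(f"Ct table lacks columns {sorted(missing)}")
    if not np.isfinite(ct_table["ct"]).all() or (ct_table["ct"] <= 0).any():
        raise InputError("Ct values must be finite and positive")
    d_test = _delta_ct_per_replicate(
        ct_table, target_gene, reference_gene, test_group, average_technical
    )
    d_ctrl = _delta_ct_per_replicate(
        ct_table, target_gene, reference_gene, control_group, average_technical
    )
    ddct = float(d_test.mean() - d_ctrl.mean())
    point = 2.0 ** (-ddct)
    if len(d_test) < 2 or len(d_ctrl) < 2:
        return FoldChange(point, ddct, None, None, len(d_test), len(d_ctrl))
    se_test = d_test.std(ddof=1) / math.sqrt(len(d_test))
    se_ctrl = d_ctrl.std(ddof=1) / math.sqrt(len(d_ctrl))
    se = float(math.hypot(se_test, se_ctrl))
    interval = (2.0 ** (-(ddct + se)), 2.0 ** (-(ddct - se)))
    return FoldChange(point, ddct, se, interval, len(d_test), len(d_ctrl))


@dataclass(frozen=True)
class ConcordanceResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    resid_sd: float
    n: int

    def confidence_band(self, x, level: float = 0.95):
        """Half-width of the mean-response confidence band at x."""
        x = np.asarray(x, dtype=float)
        t_crit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        xbar = self._xbar
        sxx = self._sxx
        return t_crit * self.resid_sd * np.sqrt(1.0 / self.n + (x - xbar) ** 2 / sxx)

    # filled post-construction by concordance()
    _xbar: float = 0.0
    _sxx: float = 1.0


def concordance(pairs: Sequence[Tuple[float, float]]) -> ConcordanceResult:
    """Pearson R and OLS line between log2 qPCR and log2 RNA-seq folds."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise InputError("need at least 3 (qPCR, RNA-seq) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise InputError("zero variance in one coordinate: correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    dof = max(len(x) - 2, 1)
    resid_sd = float(np.sqrt((resid**2).sum() / dof))
    return ConcordanceResult(
        r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        resid_sd=resid_sd,
        n=len(x),
        _xbar=float(x.mean()),
        _sxx=float(((x - x.mean()) ** 2).sum()),
    )


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"Ct table lacks columns {sorted(missing)}")
    return df


def fold_table(
    ct_table: pd.DataFrame,
    test_group: str,
    control_group: str,
    reference_gene: Optional[str] = None,
) -> pd.DataFrame:
    """Per-target-gene fold-change table from a tidy Ct table."""
    if reference_gene is None:
        refs = ct_table.loc[ct_table["role"] == "reference", "gene"].unique()
        if len(refs) != 1:
            raise InputError("reference gene ambiguous; pass reference_gene")
        reference_gene = str(refs[0])
    rows = []
    for gene in sorted(ct_table.loc[ct_table["role"] == "target", "gene"].unique()):
        fc = delta_delta_ct(ct_table, gene, test_group, control_group, reference_gene)
        rows.append(
            (
                gene,
                fc.point,
                fc.ddct,
                fc.se_ddct if fc.se_ddct is not None else np.nan,
                fc.interval[0] if fc.interval else np.nan,
                fc.interval[1] if fc.interval else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene", "fold", "ddct", "se_ddct", "fold_low", "fold_high"]
    )
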